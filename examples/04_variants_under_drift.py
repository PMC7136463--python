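"""Compare decoder variants on drifting recordings (desk-scale, 2 seeds).

ECPNN-EF is the full method; ECPNN drops the error feedback; RNN-EF is a
fully connected recurrent baseline.  On late test days, the error feedback
supplies fresh kinematic information each bin and partially compensates for
the drifted spike-to-velocity mapping, so ECPNN-EF should degrade least.
"""

from evodecode.evolution import EvolutionConfig
from evodecode.experiment import ExperimentConfig, compare_variants, run_experiment
from evodecode.netcore import TrainingConfig
from evodecode.synthetic import SyntheticConfig

config = ExperimentConfig(
    synthetic=SyntheticConfig(k_units=8, n_days=8, trials_per_day=20),
    variants=("ECPNN-EF", "ECPNN", "RNN-EF"),
    evolution=EvolutionConfig(population_size=12, max_generations=15),
    training=TrainingConfig(epochs=30, learning_rate=0.1),
    n_replicate_seeds=2,
    out_dir="scratch/variants_under_drift",
)
reports = run_experiment(config)

for variant, report in reports.items():
    per_day = report.daily.groupby("day")["r_mean"].mean()
    print(f"{variant}: " + "  ".join(f"d{d}={r:.2f}" for d, r in per_day.items()))

table = compare_variants([reports["ECPNN-EF"], reports["ECPNN"], reports["RNN-EF"]])
print("\npaired per-day differences (positive favours ECPNN-EF):")
print(table.round(3).to_string(index=False))
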