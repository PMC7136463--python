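"""Evolve an error-feedback decoder on stationary data and score it daily.

Days 1-2 train and validate the decoder; later days test it.  The printed
Pearson r measures how well the decoded velocity series tracks the actual
forelimb velocity (1 = perfect linear agreement).
"""

import numpy as np

from evodecode.evolution import EvolutionConfig
from evodecode.netcore import TrainingConfig, count_metrics
from evodecode.pipeline import _split_train_val, evaluate_daily, train_decoder
from evodecode.synthetic import DriftConfig, SyntheticConfig, generate_dataset

dataset, _ = generate_dataset(
    SyntheticConfig(k_units=8, n_days=4, trials_per_day=40, drift=DriftConfig.stationary(), seed=7)
)
train, val = _split_train_val(dataset.for_days([1, 2]), np.random.default_rng(7))

decoder = train_decoder(
    train,
    val,
    EvolutionConfig(population_size=16, max_generations=25, seed=7),
    TrainingConfig(epochs=40, learning_rate=0.1),
    variant="ECPNN-EF",
)

for axis in ("horizontal", "vertical"):
    trace = decoder.traces[axis]
    genome = decoder.genome_horizontal if axis == "horizontal" else decoder.genome_vertical
    m = count_metrics(genome)
    print(
        f"{axis}: stopped at generation {trace.termination_generation}, "
        f"N_h={m.n_hidden}, N_c={m.n_connections}, R_c={m.connection_ratio:.2f}"
    )
    # R_c < 1 means the evolved decoder is partially connected.

for report in evaluate_daily(decoder, dataset.for_days([3, 4])):
    print(
        f"day {report.day}: r_horizontal={report.r_horizontal:.3f} "
        f"r_vertical={report.r_vertical:.3f} r_mean={report.r_mean:.3f}"
    )
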