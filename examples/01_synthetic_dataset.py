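"""Generate a synthetic multi-day spike-count dataset and write it to CSV.

The simulator emulates a rodent lever-press recording: 8 cosine-tuned
Poisson units, 12 days of trials (11 bins of 33 ms each), with recording
conditions drifting from day to day.
"""

import numpy as np

from evodecode.pipeline import write_dataset_csv
from evodecode.synthetic import SyntheticConfig, generate_dataset

config = SyntheticConfig(k_units=8, n_days=12, trials_per_day=35, seed=42)
dataset, truth = generate_dataset(config)

print(f"days: {dataset.days()}")
print(f"trials: {len(dataset)}  ({config.trials_per_day} per day, {dataset.k_units} units)")
counts = np.concatenate([t.spike_counts for t in dataset.trials], axis=1)
print(f"mean spike count per bin: {counts.mean():.2f}  (max {counts.max()})")

# how far the preferred directions have rotated by the last day
rot = [
    abs(b.preferred_direction - a.preferred_direction)
    for a, b in zip(truth[1], truth[12])
]
print(f"mean |PD rotation| day 1 -> day 12: {np.mean(rot):.2f} rad")
# The rotation is the across-day nonstationarity a fixed decoder must absorb.

manifest = write_dataset_csv(dataset, "scratch/example_dataset")
print(f"wrote {manifest}")
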