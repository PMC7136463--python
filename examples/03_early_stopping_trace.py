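"""Inspect the early-stopping quantities of an evolution run.

Evolution stops when the generalization loss GL (relative excess of the
validation error over its running minimum) exceeds the training-progress
statistic P_k computed over a strip of the 5 most recent generations —
the point where further structural growth starts to overfit.
"""

import numpy as np

from evodecode.evolution import EvolutionConfig, evolve
from evodecode.netcore import TrainingConfig
from evodecode.pipeline import (
    FeatureScaler,
    TargetScaler,
    _split_train_val,
    build_training_arrays,
)
from evodecode.synthetic import DriftConfig, SyntheticConfig, generate_dataset

dataset, _ = generate_dataset(
    SyntheticConfig(k_units=6, n_days=2, trials_per_day=30, drift=DriftConfig.stationary(), seed=3)
)
train_trials, val_trials = _split_train_val(dataset.for_days([1, 2]), np.random.default_rng(3))

fscaler = FeatureScaler.fit(train_trials)
tscaler = TargetScaler.fit(np.concatenate([t.velocities[0] for t in train_trials]))
train = build_training_arrays(train_trials, 0, fscaler, tscaler)
val = build_training_arrays(val_trials, 0, fscaler, tscaler)

best, trace = evolve(
    train,
    val,
    EvolutionConfig(population_size=12, max_generations=40, seed=3),
    k_units=6,
    training=TrainingConfig(epochs=30, learning_rate=0.1),
)

frame = trace.to_frame()
print(frame[["generation", "E_tr", "E_va", "GL", "P_k", "best_N_h", "best_R_c"]].round(4).to_string(index=False))
print(f"\nterminated at generation {trace.termination_generation} "
      f"(first generation where GL > P_k, or the budget)")
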