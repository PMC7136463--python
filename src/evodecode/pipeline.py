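"""From trial recordings to features, closed-loop decoding and daily scores.

A *trial* is a k-unit x 11-bin spike-count matrix aligned with a 2 x 11
velocity matrix (horizontal and vertical components, 33-ms bins).  The
decoder input at bin t is the length-(2k+1) concatenation
``[N(t), N(t_pre), v_error]``: spike counts of the current and preceding bin
plus the error feedback |v(t_pre) - v_hat(t_pre)|.  Horizontal and vertical
velocities are decoded by two separate networks.

Because the networks are tanh-bounded, velocities are affinely rescaled per
axis to [-0.9, 0.9] (fit on the training set) before training and
inverse-scaled on prediction; spike counts are z-scored per unit with
training-set statistics.  The feedback signal lives on the scaled velocity
axis, so training and test-time decoding see the same magnitudes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .evolution import EvolutionConfig, EvolutionTrace, evolve, make_variant
from .netcore import CompiledNetwork, NetworkGenome, TrainingConfig

N_BINS = 11
BIN_WIDTH_MS = 33

FeedbackModeName = Literal["observed", "zero", "self"]

__all__ = [
    "TrialData",
    "DecodingDataset",
    "DailyReport",
    "FeatureScaler",
    "TargetScaler",
    "KinematicDecoder",
    "differentiate_positions",
    "bin_window",
    "compute_error_feedback",
    "build_feature_vector",
    "feature_length",
    "build_training_arrays",
    "decode_trial",
    "pearson_r",
    "evaluate_daily",
    "daily_reports_frame",
    "train_decoder",
    "cross_validate_grid",
    "write_dataset_csv",
    "read_dataset_csv",
]


@dataclass
class TrialData:
    """One trial: spike counts (k x 11) and velocities (2 x 11)."""

    spike_counts: np.ndarray
    velocities: np.ndarray
    day: int
    trial_id: int

    def __post_init__(self) -> None:
        self.spike_counts = np.asarray(self.spike_counts)
        self.velocities = np.asarray(self.velocities, dtype=float)
        if self.spike_counts.ndim != 2 or self.spike_counts.shape[1] != N_BINS:
            raise ValueError(f"spike_counts must be (k, {N_BINS})")
        if self.velocities.shape != (2, N_BINS):
            raise ValueError(f"velocities must be (2, {N_BINS})")
        if np.any(self.spike_counts < 0):
            raise ValueError("spike counts must be nonnegative")
        if not np.all(np.isfinite(self.velocities)):
            raise ValueError("velocities must be finite")

    @property
    def k_units(self) -> int:
        return self.spike_counts.shape[0]


@dataclass
class DecodingDataset:
    """A multi-day collection of trials with shared unit count."""

    trials: list[TrialData]
    k_units: int
    bin_width_ms: int = BIN_WIDTH_MS

    def days(self) -> list[int]:
        return sorted({t.day for t in self.trials})

    def for_days(self, days: Iterable[int]) -> list[TrialData]:
        dayset = set(days)
        return [t for t in self.trials if t.day in dayset]

    def __len__(self) -> int:
        return len(self.trials)


@dataclass(frozen=True)
class DailyReport:
    day: int
    r_horizontal: float
    r_vertical: float
    r_mean: float
    n_trials: int


# ---------------------------------------------------------------------------
# kinematic preprocessing


def differentiate_positions(positions: np.ndarray, frame_rate: float = 30.0) -> np.ndarray:
    """Two-point digital differentiation of marker positions.

    ``positions`` is (2, T) at ``frame_rate`` Hz; v(t) = (p(t) - p(t-1)) *
    frame_rate, with the first sample duplicated so the output keeps length T.
    """
    p = np.asarray(positions, dtype=float)
    if p.ndim != 2 or p.shape[1] < 2:
        raise ValueError("positions must be (2, T) with T >= 2")
    v = np.diff(p, axis=1) * frame_rate
    return np.concatenate([v[:, :1], v], axis=1)


def bin_window(press_bin_index: int, n_bins: int = N_BINS) -> list[int]:
    """Trial bin window relative to the lever press.

    The window spans 8 bins before and 2 bins after the anchor bin, which is
    the 3rd bin (99 ms) prior to the press — i.e. bins press-11 .. press-1
    under 0-based, half-open [t*33, (t+1)*33) ms binning.
    """
    if press_bin_index < n_bins:
        raise ValueError("insufficient pre-press history for the trial window")
    anchor = press_bin_index - 3
    return list(range(anchor - 8, anchor + 3))


def compute_error_feedback(actual_prev: float, predicted_prev: float) -> float:
    """Error feedback |v(t_pre) - v_hat(t_pre)|; 0 at a trial's first bin."""
    if not (np.isfinite(actual_prev) and np.isfinite(predicted_prev)):
        raise ValueError("feedback inputs must be finite")
    return abs(float(actual_prev) - float(predicted_prev))


def feature_length(k_units: int, include_error: bool = True) -> int:
    return 2 * k_units + (1 if include_error else 0)


def build_feature_vector(
    trial: TrialData, t: int, v_error: float, include_error: bool = True
) -> np.ndarray:
    """Input vector [N(t), N(t_pre), v_error] at 1-based bin ``t``.

    At the first bin there is no preceding bin: N(t_pre) is all zeros.  The
    no-feedback (ECPNN) variant omits the error slot and has length 2k.
    """
    if not 1 <= t <= N_BINS:
        raise ValueError(f"t must be in [1, {N_BINS}]")
    now = trial.spike_counts[:, t - 1].astype(float)
    prev = trial.spike_counts[:, t - 2].astype(float) if t > 1 else np.zeros(trial.k_units)
    parts = [now, prev] + ([np.array([v_error])] if include_error else [])
    return np.concatenate(parts)


# ---------------------------------------------------------------------------
# scalers


@dataclass
class FeatureScaler:
    """Per-unit z-scoring of the two spike-count blocks; identity on feedback."""

    mean: np.ndarray = field(default_factory=lambda: np.zeros(0))
    std: np.ndarray = field(default_factory=lambda: np.ones(0))

    @classmethod
    def fit(cls, trials: Sequence[TrialData]) -> "FeatureScaler":
        counts = np.concatenate([t.spike_counts for t in trials], axis=1).astype(float)
        mean = counts.mean(axis=1)
        std = np.maximum(counts.std(axis=1), 1e-6)
        return cls(mean=mean, std=std)

    def transform_counts(self, counts: np.ndarray) -> np.ndarray:
        return (counts.astype(float) - self.mean[:, None]) / self.std[:, None]


@dataclass
class TargetScaler:
    """Symmetric max-abs map of one velocity axis into [-0.9, 0.9].

    Velocity is a signed quantity whose physical zero (rest) is meaningful,
    so the map is a pure gain: v = 0 stays 0 and the training-set extremum
    lands on +/-0.9.  This keeps "relax toward zero output" equivalent to
    "relax toward rest", which degrades gracefully when the decoder is
    uncertain.
    """

    scale: float

    @classmethod
    def fit(cls, values: np.ndarray, headroom: float = 0.9) -> "TargetScaler":
        vmax = float(np.max(np.abs(values)))
        if vmax < 1e-12:
            vmax = 1e-12
        return cls(scale=headroom / vmax)

    def transform(self, v: np.ndarray) -> np.ndarray:
        return np.asarray(v, dtype=float) * self.scale

    def inverse(self, s: np.ndarray) -> np.ndarray:
        return np.asarray(s, dtype=float) / self.scale


# ---------------------------------------------------------------------------
# training-array construction


def build_training_arrays(
    trials: Sequence[TrialData],
    axis: int,
    feature_scaler: FeatureScaler,
    target_scaler: TargetScaler,
    include_error: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Stacked (B, T, n_in) features and (B, T) scaled targets for one axis.

    The error-feedback column (when present) is zero-initialized; it is
    filled dynamically during BPTT training and during decoding.
    """
    B = len(trials)
    k = trials[0].k_units
    n_in = feature_length(k, include_error)
    X = np.zeros((B, N_BINS, n_in))
    V = np.zeros((B, N_BINS))
    for b, trial in enumerate(trials):
        z = feature_scaler.transform_counts(trial.spike_counts)
        for t in range(N_BINS):
            X[b, t, :k] = z[:, t]
            if t > 0:
                X[b, t, k : 2 * k] = z[:, t - 1]
        V[b] = target_scaler.transform(trial.velocities[axis])
    return X, V


# ---------------------------------------------------------------------------
# decoder bundle and closed-loop decoding


@dataclass
class KinematicDecoder:
    """Trained two-axis decoder: one genome per axis plus the fitted scalers."""

    genome_horizontal: NetworkGenome
    genome_vertical: NetworkGenome
    feature_scaler: FeatureScaler
    scaler_horizontal: TargetScaler
    scaler_vertical: TargetScaler
    k_units: int
    include_error: bool = True
    traces: dict = field(default_factory=dict)

    def genome(self, axis: int) -> NetworkGenome:
        return self.genome_horizontal if axis == 0 else self.genome_vertical

    def target_scaler(self, axis: int) -> TargetScaler:
        return self.scaler_horizontal if axis == 0 else self.scaler_vertical


def decode_trial(
    decoder: KinematicDecoder,
    trial: TrialData,
    mode: FeedbackModeName = "observed",
) -> np.ndarray:
    """Decode one trial bin by bin; returns (2, 11) predicted velocities.

    Hidden states start at zero.  The feedback input at bin t uses only
    information up to bin t-1:

    - ``observed``: |v(t_pre) - v_hat(t_pre)| with the recorded velocity of
      the preceding bin (offline evaluation as in the closed-loop equation);
    - ``zero``: the feedback input is clamped to 0;
    - ``self``: a ground-truth-free proxy, the absolute change between the
      two most recent decoded outputs |v_hat(t-1) - v_hat(t-2)|.
    """
    if mode not in ("observed", "zero", "self"):
        raise ValueError(f"unknown feedback mode {mode!r}")
    preds = np.zeros((2, N_BINS))
    z = decoder.feature_scaler.transform_counts(trial.spike_counts)
    k = decoder.k_units
    for axis in range(2):
        net = CompiledNetwork(decoder.genome(axis))
        tscaler = decoder.target_scaler(axis)
        v_scaled = tscaler.transform(trial.velocities[axis])
        h = np.zeros(net.n_h)
        y_hist: list[float] = []
        for t in range(N_BINS):
            x = np.zeros(net.n_in)
            x[:k] = z[:, t]
            if t > 0:
                x[k : 2 * k] = z[:, t - 1]
            if decoder.include_error and net.error_slot is not None:
                if t == 0 or mode == "zero":
                    v_err = 0.0
                elif mode == "observed":
                    v_err = compute_error_feedback(v_scaled[t - 1], y_hist[t - 1])
                else:  # self
                    prev2 = y_hist[t - 2] if t >= 2 else 0.0
                    v_err = abs(y_hist[t - 1] - prev2)
                x[net.error_slot] = v_err
            y, h = net.step(x, h)
            y_hist.append(float(y))
        preds[axis] = tscaler.inverse(np.array(y_hist))
    return preds


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation; errors on short or zero-variance input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input: correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


def evaluate_daily(
    decoder: KinematicDecoder,
    dataset: DecodingDataset | Sequence[TrialData],
    mode: FeedbackModeName = "observed",
) -> list[DailyReport]:
    """Per-day decoding accuracy.

    For each day label present, all trials' predicted and observed velocity
    series are concatenated per axis and scored with Pearson's r; ``r_mean``
    averages the two axes.  (Concatenation, rather than averaging per-trial
    r, keeps the correlation stable given only 11 bins per trial.)
    """
    trials = dataset.trials if isinstance(dataset, DecodingDataset) else list(dataset)
    reports = []
    for day in sorted({t.day for t in trials}):
        day_trials = [t for t in trials if t.day == day]
        if len(day_trials) < 2:
            warnings.warn(f"day {day} has fewer than 2 trials; r computed on available bins")
        pred = np.concatenate([decode_trial(decoder, t, mode) for t in day_trials], axis=1)
        obs = np.concatenate([t.velocities for t in day_trials], axis=1)
        r_h = pearson_r(pred[0], obs[0])
        r_v = pearson_r(pred[1], obs[1])
        reports.append(
            DailyReport(
                day=day,
                r_horizontal=r_h,
                r_vertical=r_v,
                r_mean=(r_h + r_v) / 2.0,
                n_trials=len(day_trials),
            )
        )
    return reports


def daily_reports_frame(reports: Sequence[DailyReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "day": [r.day for r in reports],
            "r_horizontal": [r.r_horizontal for r in reports],
            "r_vertical": [r.r_vertical for r in reports],
            "r_mean": [r.r_mean for r in reports],
            "n_trials": [r.n_trials for r in reports],
        }
    )


# ---------------------------------------------------------------------------
# training entry point


def train_decoder(
    train_trials: Sequence[TrialData],
    val_trials: Sequence[TrialData],
    config: EvolutionConfig,
    training: TrainingConfig | None = None,
    variant: str = "ECPNN-EF",
) -> KinematicDecoder:
    """Evolve (or construct) and train a two-axis decoder.

    The feature scaler and per-axis target scalers are fitted on the training
    trials only.  Each axis runs its own structure search; the search seed is
    offset per axis so the two decoders do not share random streams.
    """
    cfg = make_variant(config, variant)
    training = training or TrainingConfig()
    k = train_trials[0].k_units
    fscaler = FeatureScaler.fit(train_trials)
    genomes: list[NetworkGenome] = []
    tscalers: list[TargetScaler] = []
    traces: dict[str, EvolutionTrace] = {}
    for axis, name in enumerate(("horizontal", "vertical")):
        tscaler = TargetScaler.fit(
            np.concatenate([t.velocities[axis] for t in train_trials])
        )
        include = cfg.use_error_input
        train = build_training_arrays(train_trials, axis, fscaler, tscaler, include)
        val = build_training_arrays(val_trials, axis, fscaler, tscaler, include)
        axis_cfg = EvolutionConfig(**{**cfg.__dict__, "seed": cfg.seed + 7919 * axis})
        genome, trace = evolve(train, val, axis_cfg, k, training=training)
        genomes.append(genome)
        tscalers.append(tscaler)
        traces[name] = trace
    return KinematicDecoder(
        genome_horizontal=genomes[0],
        genome_vertical=genomes[1],
        feature_scaler=fscaler,
        scaler_horizontal=tscalers[0],
        scaler_vertical=tscalers[1],
        k_units=k,
        include_error=cfg.use_error_input,
        traces=traces,
    )


def _split_train_val(
    trials: Sequence[TrialData], rng: np.random.Generator, val_fraction: float = 0.2
) -> tuple[list[TrialData], list[TrialData]]:
    idx = rng.permutation(len(trials))
    n_val = max(1, int(round(val_fraction * len(trials))))
    val_idx = set(idx[:n_val].tolist())
    train = [t for i, t in enumerate(trials) if i not in val_idx]
    val = [t for i, t in enumerate(trials) if i in val_idx]
    return train, val


def cross_validate_grid(
    trials: Sequence[TrialData],
    grid_pc: Sequence[float],
    grid_pm: Sequence[float],
    config: EvolutionConfig,
    training: TrainingConfig | None = None,
    n_folds: int = 5,
    variant: str = "ECPNN-EF",
    mode: FeedbackModeName = "observed",
) -> tuple[float, float, pd.DataFrame]:
    """K-fold cross-validation over the crossover/mutation probability grid.

    Trials are randomly partitioned into ``n_folds`` equal-sized disjoint
    folds.  For each (p_c, p_m) cell a decoder is evolved on the other folds
    and scored (mean-axis Pearson r on concatenated held-out trials); cell
    scores are fold averages.  Returns the argmax cell and the full surface.
    """
    if len(grid_pc) == 0 or len(grid_pm) == 0:
        raise ValueError("empty probability grid")
    if len(trials) < n_folds:
        raise ValueError("need at least n_folds trials")
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(len(trials))
    folds = [sorted(perm[i::n_folds].tolist()) for i in range(n_folds)]
    rows = []
    for pc in grid_pc:
        for pm in grid_pm:
            r_folds = []
            for f in range(n_folds):
                held = [trials[i] for i in folds[f]]
                rest = [trials[i] for i in perm if i not in set(folds[f])]
                cfg = EvolutionConfig(
                    **{**config.__dict__, "p_crossover": pc, "p_mutation": pm}
                )
                dec = train_decoder(rest, held, cfg, training, variant=variant)
                pred = np.concatenate([decode_trial(dec, t, mode) for t in held], axis=1)
                obs = np.concatenate([t.velocities for t in held], axis=1)
                r_folds.append(
                    (pearson_r(pred[0], obs[0]) + pearson_r(pred[1], obs[1])) / 2.0
                )
            rows.append({"p_c": pc, "p_m": pm, "r_mean": float(np.mean(r_folds))})
    surface = pd.DataFrame(rows)
    best = surface.loc[surface["r_mean"].idxmax()]
    return float(best["p_c"]), float(best["p_m"]), surface


# ---------------------------------------------------------------------------
# trial file I/O


def write_dataset_csv(dataset: DecodingDataset, out_dir: str | Path) -> Path:
    """One CSV per day plus a JSON manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    k = dataset.k_units
    unit_cols = [f"unit_{i + 1}" for i in range(k)]
    files = {}
    for day in dataset.days():
        rows = []
        for t in dataset.for_days([day]):
            for b in range(N_BINS):
                row = {"day": t.day, "trial_id": t.trial_id, "bin": b + 1}
                row.update({c: int(t.spike_counts[i, b]) for i, c in enumerate(unit_cols)})
                row["vx"] = t.velocities[0, b]
                row["vy"] = t.velocities[1, b]
                rows.append(row)
        fname = f"day_{day:02d}.csv"
        pd.DataFrame(rows).to_csv(out / fname, index=False)
        files[str(day)] = fname
    manifest = {
        "k_units": k,
        "bin_width_ms": dataset.bin_width_ms,
        "n_bins": N_BINS,
        "days": files,
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    return mpath


def read_dataset_csv(manifest_path: str | Path) -> DecodingDataset:
    mpath = Path(manifest_path)
    manifest = json.loads(mpath.read_text())
    k = int(manifest["k_units"])
    unit_cols = [f"unit_{i + 1}" for i in range(k)]
    trials: list[TrialData] = []
    for day, fname in sorted(manifest["days"].items(), key=lambda kv: int(kv[0])):
        df = pd.read_csv(mpath.parent / fname)
        for trial_id, g in df.groupby("trial_id"):
            g = g.sort_values("bin")
            if len(g) != N_BINS or list(g["bin"]) != list(range(1, N_BINS + 1)):
                raise ValueError(
                    f"trial {trial_id} on day {day} does not have exactly bins 1..{N_BINS}"
                )
            trials.append(
                TrialData(
                    spike_counts=g[unit_cols].to_numpy().T,
                    velocities=np.vstack([g["vx"].to_numpy(), g["vy"].to_numpy()]),
                    day=int(day),
                    trial_id=int(trial_id),
                )
            )
    return DecodingDataset(trials=trials, k_units=k, bin_width_ms=int(manifest["bin_width_ms"]))
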