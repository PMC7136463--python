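"""Config-driven multi-seed, multi-variant decoding experiments.

Reproduces the study design at desk scale: the first two days of a dataset
train and validate the decoder, the remaining days test it, and replicate
seeds play the role of subjects.  Descriptive per-day means and SDs across
seeds replace formal mixed-model inference.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .evolution import EvolutionConfig, VARIANTS
from .netcore import TrainingConfig, count_metrics
from .pipeline import (
    DecodingDataset,
    cross_validate_grid,
    evaluate_daily,
    read_dataset_csv,
    train_decoder,
    _split_train_val,
)
from .synthetic import DriftConfig, SyntheticConfig, TrajectoryConfig, generate_dataset

logger = logging.getLogger("evodecode")

__all__ = ["ExperimentConfig", "VariantReport", "run_experiment", "compare_variants"]


@dataclass
class ExperimentConfig:
    """Everything one experiment needs, serializable to JSON/YAML.

    ``synthetic`` is ignored when ``manifest_path`` points at an on-disk
    dataset.  ``train_days`` default to the first two days; test days are all
    remaining days.  Each replicate seed offsets both the dataset seed and
    the evolution seed, so variants compared within a replicate share data.
    """

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    manifest_path: str | None = None
    variants: tuple[str, ...] = ("ECPNN-EF", "ECPNN", "RNN-EF")
    evolution: EvolutionConfig = field(default_factory=EvolutionConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    cv_grid_pc: tuple[float, ...] = ()
    cv_grid_pm: tuple[float, ...] = ()
    n_replicate_seeds: int = 3
    base_seed: int = 0
    val_fraction: float = 0.2
    train_days: tuple[int, ...] = (1, 2)
    out_dir: str = "results"

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha1(blob).hexdigest()[:10]


@dataclass
class VariantReport:
    variant: str
    daily: pd.DataFrame  # columns: seed, day, r_horizontal, r_vertical, r_mean
    structure: pd.DataFrame  # per seed: N_h, N_c, R_c, G_T, r_val


def _load_or_generate(config: ExperimentConfig, seed: int) -> DecodingDataset:
    if config.manifest_path is not None:
        return read_dataset_csv(config.manifest_path)
    syn = SyntheticConfig(**{**asdict(config.synthetic), "seed": seed})
    # dataclass re-hydration: nested configs come back as dicts from asdict
    if isinstance(syn.drift, dict):
        syn.drift = DriftConfig(**syn.drift)
    if isinstance(syn.trajectory, dict):
        syn.trajectory = TrajectoryConfig(**syn.trajectory)
    dataset, _ = generate_dataset(syn)
    return dataset


def run_experiment(config: ExperimentConfig) -> dict[str, VariantReport]:
    """Run every (seed, variant) cell and write traces, daily CSVs and a summary.

    Per replicate seed: generate (or load) the dataset, split the training
    days into train/validation trials, optionally grid-search p_c/p_m by
    cross-validation, train each variant, and score daily Pearson r on the
    test days.  Test-day trials never enter training, validation or CV folds.
    """
    for v in config.variants:
        if v not in VARIANTS:
            raise ValueError(f"unknown variant {v!r}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = config.config_hash()
    reports: dict[str, VariantReport] = {v: VariantReport(v, pd.DataFrame(), pd.DataFrame()) for v in config.variants}
    daily_rows: dict[str, list[dict]] = {v: [] for v in config.variants}
    struct_rows: dict[str, list[dict]] = {v: [] for v in config.variants}

    for rep in range(config.n_replicate_seeds):
        seed = config.base_seed + rep
        dataset = _load_or_generate(config, seed)
        train_days = set(config.train_days)
        test_days = [d for d in dataset.days() if d not in train_days]
        pool = dataset.for_days(train_days)
        rng = np.random.default_rng(seed + 10_000)
        train_trials, val_trials = _split_train_val(pool, rng, config.val_fraction)
        logger.info(
            "seed %d: %d train / %d val trials, %d test days",
            seed, len(train_trials), len(val_trials), len(test_days),
        )

        evo = EvolutionConfig(**{**config.evolution.__dict__, "seed": seed + 20_000})
        if config.cv_grid_pc and config.cv_grid_pm:
            pc, pm, surface = cross_validate_grid(
                pool, config.cv_grid_pc, config.cv_grid_pm, evo, config.training
            )
            surface.to_csv(out / f"cv_surface_{tag}_seed{seed}.csv", index=False)
            evo = EvolutionConfig(**{**evo.__dict__, "p_crossover": pc, "p_mutation": pm})
            logger.info("seed %d: CV selected p_c=%.2f p_m=%.2f", seed, pc, pm)

        for variant in config.variants:
            decoder = train_decoder(train_trials, val_trials, evo, config.training, variant=variant)
            for name, trace in decoder.traces.items():
                trace.to_csv(out / f"trace_{tag}_seed{seed}_{variant}_{name}.csv")
            for rep_day in evaluate_daily(decoder, dataset.for_days(test_days)):
                daily_rows[variant].append(
                    {
                        "seed": seed,
                        "day": rep_day.day,
                        "r_horizontal": rep_day.r_horizontal,
                        "r_vertical": rep_day.r_vertical,
                        "r_mean": rep_day.r_mean,
                    }
                )
            val_reports = evaluate_daily(decoder, val_trials)
            r_val = float(np.mean([r.r_mean for r in val_reports]))
            mh = count_metrics(decoder.genome_horizontal)
            mv = count_metrics(decoder.genome_vertical)
            struct_rows[variant].append(
                {
                    "seed": seed,
                    "r_val": r_val,
                    "N_h": (mh.n_hidden + mv.n_hidden) / 2.0,
                    "N_c": (mh.n_connections + mv.n_connections) / 2.0,
                    "R_c": (mh.connection_ratio + mv.connection_ratio) / 2.0,
                    "G_T": float(
                        np.mean(
                            [t.termination_generation for t in decoder.traces.values()]
                        )
                    ),
                }
            )

    summary: dict[str, dict] = {"config_hash": tag, "variants": {}}
    for variant in config.variants:
        daily = pd.DataFrame(daily_rows[variant])
        structure = pd.DataFrame(struct_rows[variant])
        reports[variant] = VariantReport(variant, daily, structure)
        daily.to_csv(out / f"daily_{tag}_{variant}.csv", index=False)
        structure.to_csv(out / f"structure_{tag}_{variant}.csv", index=False)
        per_day = daily.groupby("day")["r_mean"].agg(["mean", "std"])
        summary["variants"][variant] = {
            "daily_r_mean": per_day["mean"].round(6).to_dict(),
            "daily_r_sd": per_day["std"].round(6).fillna(0.0).to_dict(),
            "structure": {
                c: [round(structure[c].mean(), 6), round(float(structure[c].std() or 0.0), 6)]
                for c in ("r_val", "N_h", "N_c", "R_c", "G_T")
            },
            "n_seeds": config.n_replicate_seeds,
        }
    (out / f"summary_{tag}.json").write_text(json.dumps(summary, indent=2))
    return reports


def compare_variants(reports: Sequence[VariantReport]) -> pd.DataFrame:
    """Per-day paired differences of r_mean between the first report and the rest.

    All reports must share the same replicate seeds.  Returns one row per
    (comparison, day) with the mean and SD of the paired seed differences.
    """
    if len(reports) < 2:
        raise ValueError("need at least two variant reports")
    ref = reports[0]
    ref_seeds = set(ref.daily["seed"].unique())
    rows = []
    for other in reports[1:]:
        if set(other.daily["seed"].unique()) != ref_seeds:
            raise ValueError("variant reports have mismatched seeds")
        a = ref.daily.set_index(["seed", "day"])["r_mean"]
        b = other.daily.set_index(["seed", "day"])["r_mean"]
        diff = (a - b).reset_index().rename(columns={"r_mean": "r_diff"})
        g = diff.groupby("day")["r_diff"].agg(["mean", "std"]).reset_index()
        g.insert(0, "comparison", f"{ref.variant} - {other.variant}")
        rows.append(g)
    return pd.concat(rows, ignore_index=True)
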