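"""Orchestration of the calibration-error tolerance experiment.

The experiment: split a methylation dataset 70/30 once, fit a baseline
clock on the exact training ages, then for each error level in a sweep
grid repeatedly {inject bounded relative error into the *training* ages
only -> refit the clock -> evaluate on the fixed, unperturbed test
partition}.  Per-sample test errors are pooled across repetitions at
each level and compared with the baseline's by unpaired t-test and
Cohen's d; the first level at which each criterion triggers is the
detected tolerance threshold, and an OLS line of mean d against error
percentage summarises the degradation.

Randomness flows from one master seed through a deterministic ladder:
each (level, repetition) gets its own child seed, so levels are
independent and individually re-runnable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .clock import SplitSpec, fit_clock, predict_ages, split_train_test
from .datasets import MethylationDataset
from .metrics import PerformanceSummary, summarize
from .noise import inject_age_error
from .stats import (
    EffectSizeModel,
    EffectThresholds,
    cohens_d,
    classify_effect,
    fit_effect_size_model,
    unpaired_t_test,
)

__all__ = [
    "SweepConfig",
    "SweepResult",
    "ThresholdReport",
    "run_baseline",
    "run_error_sweep",
    "detect_thresholds",
    "aggregate_datasets",
    "subsample_experiment",
]


def child_seed(master: int, *key: int) -> int:
    """Deterministic per-(level, repetition) seed below 2**31."""
    ss = np.random.SeedSequence([int(master), *[int(k) for k in key]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class SweepConfig:
    """Declarative description of one sweep experiment.

    ``levels`` defaults to the full 1..100 percent grid; ``desk_scale``
    gives a reduced grid (step 5, 5 repetitions) for quick runs.
    ``redraw_per_repetition`` controls whether perturbation noise is
    drawn fresh for every repetition (default) or once per level and
    shared across repetitions.
    """

    levels: tuple[float, ...] = tuple(range(1, 101))
    repetitions: int = 10
    split: SplitSpec = field(default_factory=SplitSpec)
    alpha_mix: float = 0.5
    cv_folds: int = 10
    n_alphas: int = 20
    master_seed: int = 0
    redraw_per_repetition: bool = True
    pooled_tests: bool = True
    checkpoint_dir: str | None = None

    def __post_init__(self) -> None:
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        for lv in self.levels:
            if not (0.0 <= lv <= 100.0):
                raise ValueError(f"error level {lv} outside [0, 100]")

    @classmethod
    def desk_scale(cls, **overrides) -> "SweepConfig":
        defaults = dict(levels=tuple(range(5, 101, 5)), repetitions=5)
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class SweepResult:
    """Outputs of one sweep: baseline repetitions plus per-level repetitions."""

    baseline: list[PerformanceSummary]
    per_level: dict[float, list[PerformanceSummary]]
    test_ages: np.ndarray  # held fixed and unperturbed across the sweep
    config: SweepConfig

    @property
    def levels(self) -> list[float]:
        return sorted(self.per_level)

    def _pool(self, summaries: list[PerformanceSummary], which: str) -> np.ndarray:
        attr = "per_sample_abs" if which == "abs" else "per_sample_rel"
        return np.concatenate([getattr(s, attr) for s in summaries])

    def pooled_errors(self, level: float | None = None, which: str = "abs") -> np.ndarray:
        """Per-sample test errors pooled across repetitions; ``level=None``
        gives the baseline pool."""
        summaries = self.baseline if level is None else self.per_level[level]
        return self._pool(summaries, which)

    def repetition_means(self, level: float | None = None, which: str = "abs") -> np.ndarray:
        summaries = self.baseline if level is None else self.per_level[level]
        attr = "mean_absolute_error" if which == "abs" else "mean_relative_error"
        return np.array([getattr(s, attr) for s in summaries])

    def d_curve(self) -> tuple[np.ndarray, np.ndarray]:
        """Cohen's d of pooled absolute errors vs baseline, per level."""
        levels = np.array(self.levels, dtype=float)
        base = self.pooled_errors(None, "abs")
        d = np.array([cohens_d(base, self.pooled_errors(lv, "abs")) for lv in levels])
        return levels, d

    def mean_summary(self, level: float | None = None) -> dict:
        summaries = self.baseline if level is None else self.per_level[level]
        return {
            "correlation": float(np.nanmean([s.correlation for s in summaries])),
            "mean_absolute_error": float(np.mean([s.mean_absolute_error for s in summaries])),
            "mean_relative_error": float(np.mean([s.mean_relative_error for s in summaries])),
            "n_selected_sites": float(np.mean([s.n_selected_sites for s in summaries])),
        }

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per (level, repetition), baseline as level 'baseline'."""
        rows = []
        for label, summaries in [("baseline", self.baseline)] + [
            (lv, self.per_level[lv]) for lv in self.levels
        ]:
            for rep, s in enumerate(summaries):
                rows.append(
                    {
                        "level": label,
                        "repetition": rep,
                        "correlation": s.correlation,
                        "mean_absolute_error": s.mean_absolute_error,
                        "mean_relative_error": s.mean_relative_error,
                        "n_selected_sites": s.n_selected_sites,
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class ThresholdReport:
    """First error levels at which each detection criterion triggers.

    ``None`` means the criterion was never reached on the sweep grid.
    ``table`` holds the per-level statistics (t, p for absolute and
    relative errors; Cohen's d and its classification).
    """

    first_significant_absolute: float | None
    first_significant_relative: float | None
    first_small_effect: float | None
    effect_size_model: EffectSizeModel
    table: pd.DataFrame
    thresholds: EffectThresholds = field(default_factory=EffectThresholds)

    def to_json_dict(self) -> dict:
        m = self.effect_size_model
        return {
            "first_significant_absolute": self.first_significant_absolute,
            "first_significant_relative": self.first_significant_relative,
            "first_small_effect": self.first_small_effect,
            "effect_size_model": {
                "slope": m.slope,
                "intercept": m.intercept,
                "r_squared": m.r_squared,
                "slope_stderr": m.slope_stderr,
                "n_points": m.n_points,
            },
        }


def _fit_and_evaluate(
    train: MethylationDataset,
    test: MethylationDataset,
    train_ages: np.ndarray,
    config: SweepConfig,
    fit_seed: int,
) -> PerformanceSummary:
    model = fit_clock(
        train.with_ages(train_ages),
        alpha_mix=config.alpha_mix,
        cv_folds=config.cv_folds,
        seed=fit_seed,
        n_alphas=config.n_alphas,
    )
    pred = predict_ages(model, test)
    return summarize(pred, test.ages, model)


def run_baseline(dataset: MethylationDataset, config: SweepConfig) -> PerformanceSummary:
    """Fit a clock on the unperturbed training ages and evaluate on the
    held-out test partition."""
    train, test = split_train_test(dataset, config.split, cv_folds=config.cv_folds)
    return _fit_and_evaluate(
        train, test, train.ages, config, child_seed(config.master_seed, 0, 0)
    )


def _checkpoint_path(config: SweepConfig, label: str) -> Path | None:
    if config.checkpoint_dir is None:
        return None
    d = Path(config.checkpoint_dir)
    d.mkdir(parents=True, exist_ok=True)
    return d / f"level_{label}.json"


def _summary_to_doc(s: PerformanceSummary) -> dict:
    return {
        "correlation": s.correlation,
        "mean_absolute_error": s.mean_absolute_error,
        "mean_relative_error": s.mean_relative_error,
        "n_selected_sites": s.n_selected_sites,
        "per_sample_abs": s.per_sample_abs.tolist(),
        "per_sample_rel": s.per_sample_rel.tolist(),
    }


def _summary_from_doc(doc: dict) -> PerformanceSummary:
    return PerformanceSummary(
        correlation=doc["correlation"],
        mean_absolute_error=doc["mean_absolute_error"],
        mean_relative_error=doc["mean_relative_error"],
        n_selected_sites=doc["n_selected_sites"],
        per_sample_abs=np.asarray(doc["per_sample_abs"]),
        per_sample_rel=np.asarray(doc["per_sample_rel"]),
    )


def _run_level(
    train: MethylationDataset,
    test: MethylationDataset,
    level: float,
    level_index: int,
    config: SweepConfig,
) -> list[PerformanceSummary]:
    label = "baseline" if level_index == 0 and level == 0.0 else f"{level:g}"
    ckpt = _checkpoint_path(config, label)
    if ckpt is not None and ckpt.exists():
        docs = json.loads(ckpt.read_text())
        if len(docs) == config.repetitions:
            return [_summary_from_doc(d) for d in docs]
    summaries = []
    shared_noise_seed = child_seed(config.master_seed, level_index, 10_000)
    for rep in range(config.repetitions):
        noise_seed = (
            child_seed(config.master_seed, level_index, 2 * rep + 1)
            if config.redraw_per_repetition
            else shared_noise_seed
        )
        fit_seed = child_seed(config.master_seed, level_index, 2 * rep + 2)
        ages = (
            train.ages
            if level == 0.0
            else inject_age_error(train.ages, level, noise_seed)
        )
        summaries.append(_fit_and_evaluate(train, test, ages, config, fit_seed))
    if ckpt is not None:
        ckpt.write_text(json.dumps([_summary_to_doc(s) for s in summaries]))
    return summaries


def run_error_sweep(dataset: MethylationDataset, config: SweepConfig) -> SweepResult:
    """Run the full error sweep on one dataset.

    The train/test partition is made once; the test partition and its
    ages are held fixed and unperturbed across all levels.  The baseline
    (level 0) is run with the same number of repetitions as each level
    so its per-sample errors can be pooled symmetrically.
    """
    train, test = split_train_test(dataset, config.split, cv_folds=config.cv_folds)
    baseline = _run_level(train, test, 0.0, 0, config)
    per_level: dict[float, list[PerformanceSummary]] = {}
    for idx, level in enumerate(config.levels, start=1):
        per_level[float(level)] = _run_level(train, test, float(level), idx, config)
    return SweepResult(baseline, per_level, test.ages.copy(), config)


def detect_thresholds(
    sweep: SweepResult,
    thresholds: EffectThresholds = EffectThresholds(),
    sustained: int = 1,
) -> ThresholdReport:
    """Apply the three detection instruments to a sweep.

    For every level, the pooled per-sample test errors are compared with
    the baseline's by unpaired t-test (absolute and relative errors) and
    by Cohen's d (absolute errors).  The reported thresholds are the
    FIRST levels at which p < alpha or d > small; ``sustained=k``
    requires the criterion to hold at k consecutive grid levels instead
    (it reports the first level of the run).  ``pooled_tests=False`` in
    the sweep config switches the t-tests to per-repetition mean errors.
    """
    if sustained < 1:
        raise ValueError("sustained must be >= 1")
    pooled = sweep.config.pooled_tests
    if pooled:
        base_abs = sweep.pooled_errors(None, "abs")
        base_rel = sweep.pooled_errors(None, "rel")
    else:
        base_abs = sweep.repetition_means(None, "abs")
        base_rel = sweep.repetition_means(None, "rel")
    base_abs_pooled = sweep.pooled_errors(None, "abs")

    rows = []
    for lv in sweep.levels:
        if pooled:
            lv_abs = sweep.pooled_errors(lv, "abs")
            lv_rel = sweep.pooled_errors(lv, "rel")
        else:
            lv_abs = sweep.repetition_means(lv, "abs")
            lv_rel = sweep.repetition_means(lv, "rel")
        t_abs, p_abs = unpaired_t_test(base_abs, lv_abs)
        t_rel, p_rel = unpaired_t_test(base_rel, lv_rel)
        d = cohens_d(base_abs_pooled, sweep.pooled_errors(lv, "abs"))
        rows.append(
            {
                "level": lv,
                "t_abs": t_abs,
                "p_abs": p_abs,
                "t_rel": t_rel,
                "p_rel": p_rel,
                "d": d,
                "classification": classify_effect(d, thresholds),
            }
        )
    table = pd.DataFrame(rows)

    def first_crossing(flags: np.ndarray) -> float | None:
        for i in range(len(flags) - sustained + 1):
            if flags[i : i + sustained].all():
                return float(table["level"].iloc[i])
        return None

    alpha = thresholds.significance_alpha
    report = ThresholdReport(
        first_significant_absolute=first_crossing((table["p_abs"] < alpha).to_numpy()),
        first_significant_relative=first_crossing((table["p_rel"] < alpha).to_numpy()),
        first_small_effect=first_crossing((table["d"] > thresholds.small).to_numpy()),
        effect_size_model=fit_effect_size_model(
            table["level"].to_numpy(), table["d"].to_numpy()
        ),
        table=table,
        thresholds=thresholds,
    )
    return report


def aggregate_datasets(
    sweeps: list[SweepResult],
) -> tuple[pd.DataFrame, EffectSizeModel]:
    """Mean Cohen's d per level across datasets, and the OLS line on it.

    All sweeps must share the same level grid.
    """
    if not sweeps:
        raise ValueError("need at least one sweep")
    grids = [tuple(s.levels) for s in sweeps]
    if len(set(grids)) != 1:
        raise ValueError(f"level grids differ across sweeps: {sorted(set(grids))}")
    levels = np.array(grids[0], dtype=float)
    curves = np.vstack([s.d_curve()[1] for s in sweeps])
    mean_d = curves.mean(axis=0)
    frame = pd.DataFrame({"level": levels, "mean_d": mean_d})
    model = fit_effect_size_model(levels, mean_d)
    return frame, model


def subsample_experiment(
    dataset: MethylationDataset,
    target_n: int,
    config: SweepConfig,
) -> SweepResult:
    """Run the sweep on a random subset of ``target_n`` samples.

    Mirrors the sample-size control experiment: a larger cohort is
    reduced to the size of a smaller one to ask whether the tolerance
    threshold depends on n.  ``target_n == n`` leaves the dataset
    untouched so results match the plain sweep exactly.
    """
    n = dataset.n_samples
    if target_n > n:
        raise ValueError(f"target_n={target_n} exceeds dataset size {n}")
    min_viable = int(np.ceil(2 * config.cv_folds / config.split.train_fraction))
    if target_n < min_viable:
        raise ValueError(
            f"target_n={target_n} below minimum viable size {min_viable} for "
            f"{config.cv_folds}-fold CV at train fraction {config.split.train_fraction}"
        )
    if target_n == n:
        return run_error_sweep(dataset, config)
    rng = np.random.default_rng(child_seed(config.master_seed, 999_983))
    chosen = np.sort(rng.choice(n, size=target_n, replace=False))
    return run_error_sweep(dataset.subset_samples(chosen), config)
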