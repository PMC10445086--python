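"""Detection instruments for excess calibration error.

Three instruments decide when injected training-age error has degraded a
clock beyond tolerance:

1. an unpaired two-sample t-test between the baseline model's per-sample
   test errors and a perturbed model's (Student's pooled-variance test by
   default, Welch behind a flag);
2. Cohen's d, the standardised mean difference with pooled SD, read
   against the conventional small/medium/large anchors 0.2/0.5/0.8;
3. an ordinary-least-squares line relating mean Cohen's d to the error
   percentage, which can then be inverted to report the error level at
   which a target effect size is first predicted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "EffectThresholds",
    "EffectSizeModel",
    "unpaired_t_test",
    "cohens_d",
    "classify_effect",
    "fit_effect_size_model",
    "solve_threshold",
]


@dataclass(frozen=True)
class EffectThresholds:
    """Conventional effect-size anchors and significance level."""

    small: float = 0.2
    medium: float = 0.5
    large: float = 0.8
    significance_alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (self.small < self.medium < self.large):
            raise ValueError("require small < medium < large")


@dataclass(frozen=True)
class EffectSizeModel:
    """OLS line d(x) = intercept + slope * x, x = error percent."""

    slope: float
    intercept: float
    r_squared: float = float("nan")
    slope_stderr: float = float("nan")
    n_points: int = 0

    def predict(self, level_percent: float | np.ndarray) -> float | np.ndarray:
        return self.intercept + self.slope * np.asarray(level_percent, dtype=float)


def unpaired_t_test(
    x: np.ndarray,
    y: np.ndarray,
    welch: bool = False,
) -> tuple[float, float]:
    """Two-sample unpaired t-test, two-sided.

    Student's pooled-variance test by default (matching the pooled-SD
    Cohen's d it accompanies); ``welch=True`` drops the equal-variance
    assumption.  Degenerate zero-variance cases are resolved explicitly:
    equal constants give (0, 1); distinct constants give (+/-inf, 0) with
    a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        warnings.warn("zero variance with unequal means: p reported as 0")
        return float(np.sign(x.mean() - y.mean()) * np.inf), 0.0
    res = sps.ttest_ind(x, y, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Cohen's d = (mean(y) - mean(x)) / pooled SD.

    ``x`` is the baseline error sample and ``y`` the perturbed one, so d
    is positive when the perturbed model's errors exceed the baseline's.
    The pooled SD is sqrt(((n_x-1)s_x^2 + (n_y-1)s_y^2) / (n_x+n_y-2)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    nx, ny = x.size, y.size
    pooled_var = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if pooled_var == 0:
        raise ValueError("pooled SD is zero; Cohen's d undefined")
    return float((y.mean() - x.mean()) / np.sqrt(pooled_var))


def classify_effect(d: float, thresholds: EffectThresholds = EffectThresholds()) -> str:
    """Label |d| against the small/medium/large anchors."""
    m = abs(d)
    if m >= thresholds.large:
        return "large"
    if m >= thresholds.medium:
        return "medium"
    if m >= thresholds.small:
        return "small"
    return "negligible"


def fit_effect_size_model(
    levels: np.ndarray,
    mean_d: np.ndarray,
) -> EffectSizeModel:
    """OLS fit of mean Cohen's d against error percentage."""
    levels = np.asarray(levels, dtype=float)
    mean_d = np.asarray(mean_d, dtype=float)
    if levels.shape != mean_d.shape:
        raise ValueError("levels and mean_d must have equal length")
    if np.unique(levels).size < 2:
        raise ValueError("need at least 2 distinct error levels for the OLS fit")
    res = sps.linregress(levels, mean_d)
    return EffectSizeModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        slope_stderr=float(res.stderr),
        n_points=levels.size,
    )


def solve_threshold(
    model: EffectSizeModel,
    d_target: float,
) -> tuple[float, int]:
    """Invert the effect-size line: the error percent where d reaches
    ``d_target``.

    Returns both the real-valued crossing ``(d_target - intercept) / slope``
    and its nearest-integer percent (halves rounded up).  Requires a
    positive slope (otherwise the line never crosses from below).
    """
    if model.slope <= 0:
        raise ValueError("effect-size slope must be positive to solve for a crossing")
    x = (d_target - model.intercept) / model.slope
    return float(x), int(np.floor(x + 0.5))
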