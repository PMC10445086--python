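"""Test-partition performance measures for epigenetic clocks.

Three accuracy measures are computed on held-out samples with exact known
ages: the Pearson correlation between predicted and true age, the mean of
per-sample absolute errors |pred - true| (age units), and the mean of
per-sample relative errors |pred - true| / true * 100 (percent).  The
per-sample vectors are retained because the downstream statistics (t-tests,
Cohen's d) operate on them, not on the summary values.

"Absolute error" and "relative error" default to the MEAN of the
per-sample values; median variants are available via ``aggregate``.
Relative error is normalised by each individual's true age (a
range-normalised variant is available via ``relative_errors``'s
``denominator``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .clock import ClockModel, count_selected_sites

__all__ = [
    "PerformanceSummary",
    "absolute_errors",
    "relative_errors",
    "summarize",
]


@dataclass
class PerformanceSummary:
    """Accuracy of one clock on one test partition."""

    correlation: float  # Pearson r; NaN when undefined (<3 samples)
    mean_absolute_error: float
    mean_relative_error: float  # percent
    n_selected_sites: int
    per_sample_abs: np.ndarray
    per_sample_rel: np.ndarray

    @property
    def n_test(self) -> int:
        return self.per_sample_abs.size


def _check_pair(predicted: np.ndarray, true: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    predicted = np.asarray(predicted, dtype=float)
    true = np.asarray(true, dtype=float)
    if predicted.shape != true.shape:
        raise ValueError(f"length mismatch: {predicted.shape} vs {true.shape}")
    return predicted, true


def absolute_errors(predicted: np.ndarray, true: np.ndarray) -> np.ndarray:
    """Element-wise |predicted - true| in age units."""
    predicted, true = _check_pair(predicted, true)
    return np.abs(predicted - true)


def relative_errors(
    predicted: np.ndarray,
    true: np.ndarray,
    denominator: str = "individual",
) -> np.ndarray:
    """Element-wise absolute error as a percentage.

    ``denominator='individual'`` divides by each sample's true age (the
    default); ``'range'`` divides every error by the true-age range of
    the test set instead.
    """
    predicted, true = _check_pair(predicted, true)
    if (true <= 0).any():
        raise ValueError("true ages must be > 0 for relative error")
    err = np.abs(predicted - true)
    if denominator == "individual":
        return err / true * 100.0
    if denominator == "range":
        rng = np.ptp(true)
        if rng == 0:
            raise ValueError("true-age range is zero; range-normalised error undefined")
        return err / rng * 100.0
    raise ValueError(f"unknown denominator {denominator!r}")


def summarize(
    predicted: np.ndarray,
    true: np.ndarray,
    model: ClockModel | None = None,
    aggregate: str = "mean",
) -> PerformanceSummary:
    """Full performance summary: r, aggregated absolute/relative error,
    selected-site count, and the raw per-sample error vectors.

    With fewer than 3 test samples the correlation is undefined and
    reported as NaN with a warning.  ``aggregate`` may be ``'mean'``
    (default) or ``'median'``.
    """
    predicted, true = _check_pair(predicted, true)
    agg = {"mean": np.mean, "median": np.median}.get(aggregate)
    if agg is None:
        raise ValueError(f"aggregate must be 'mean' or 'median', got {aggregate!r}")

    abs_err = absolute_errors(predicted, true)
    rel_err = relative_errors(predicted, true)
    if predicted.size < 3 or np.ptp(predicted) == 0 or np.ptp(true) == 0:
        warnings.warn("Pearson correlation undefined (too few samples or zero variance)")
        r = float("nan")
    else:
        r = float(sps.pearsonr(predicted, true).statistic)
    return PerformanceSummary(
        correlation=r,
        mean_absolute_error=float(agg(abs_err)),
        mean_relative_error=float(agg(rel_err)),
        n_selected_sites=count_selected_sites(model) if model is not None else 0,
        per_sample_abs=abs_err,
        per_sample_rel=rel_err,
    )
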