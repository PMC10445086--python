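"""Elastic-net epigenetic clocks.

A clock is a sparse linear model ``age = intercept + sum_j w_j * beta_j``
fitted by elastic-net regression with the penalty mixing parameter
alpha = 0.5 (equal L1/L2 weight), the standard choice for methylation
clocks where CpG sites far outnumber samples.  The penalty strength is
chosen by internal k-fold cross-validation minimising mean squared
prediction error; site selection is the set of nonzero coefficients and
is data-driven on every fit.

Features are standardised to unit variance internally before
penalisation; coefficients are reported back on the original beta scale.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold

from .datasets import MethylationDataset

__all__ = [
    "SplitSpec",
    "ClockModel",
    "split_train_test",
    "fit_clock",
    "predict_ages",
    "count_selected_sites",
    "selection_overlap",
    "prune_outliers_and_refit",
]


@dataclass(frozen=True)
class SplitSpec:
    """Random train/test partition: 70/30 by default."""

    train_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError(f"train_fraction must be in (0, 1), got {self.train_fraction}")


@dataclass
class ClockModel:
    """A fitted sparse linear age predictor.

    ``weights`` holds only the sites with nonzero coefficients (age units
    per beta unit); ``selected_sites`` is their set.
    """

    intercept: float
    weights: dict[str, float]
    alpha_mix: float = 0.5
    penalty_strength: float = 0.0
    training_meta: dict = field(default_factory=dict)

    @property
    def selected_sites(self) -> set[str]:
        return set(self.weights)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "intercept": self.intercept,
            "weights": self.weights,
            "alpha_mix": self.alpha_mix,
            "penalty_strength": self.penalty_strength,
            "training_meta": self.training_meta,
        }
        Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "ClockModel":
        doc = json.loads(Path(path).read_text())
        return cls(
            intercept=float(doc["intercept"]),
            weights={k: float(v) for k, v in doc["weights"].items()},
            alpha_mix=float(doc.get("alpha_mix", 0.5)),
            penalty_strength=float(doc.get("penalty_strength", 0.0)),
            training_meta=doc.get("training_meta", {}),
        )


def split_train_test(
    dataset: MethylationDataset,
    spec: SplitSpec,
    cv_folds: int = 10,
) -> tuple[MethylationDataset, MethylationDataset]:
    """Randomly partition samples into disjoint train and test datasets.

    The train count is ``round(n * train_fraction)`` with halves rounded
    up, so e.g. n=63 at fraction 0.7 gives 44 train / 19 test.  The
    partition is exhaustive and reproducible under ``spec.seed``.
    """
    n = dataset.n_samples
    n_train = int(np.floor(n * spec.train_fraction + 0.5))
    if n_train < 2 * cv_folds:
        raise ValueError(
            f"training size {n_train} too small for {cv_folds}-fold internal CV "
            f"(need >= {2 * cv_folds} training samples)"
        )
    if n - n_train < 1:
        raise ValueError("test partition would be empty")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    return dataset.subset_samples(perm[:n_train]), dataset.subset_samples(perm[n_train:])


def fit_clock(
    train: MethylationDataset,
    alpha_mix: float = 0.5,
    cv_folds: int = 10,
    seed: int = 0,
    n_alphas: int = 20,
    max_iter: int = 2000,
    tol: float = 1e-3,
) -> ClockModel:
    """Calibrate an elastic-net clock on a training dataset.

    The penalty strength lambda is selected on a log-spaced path of
    ``n_alphas`` candidates by ``cv_folds``-fold cross-validation
    minimising mean squared prediction error (not the one-SE rule).

    Raises ``ValueError`` if the training ages are constant; degenerates
    to an intercept-only model (predicting the mean training age) with a
    warning when every CpG site is constant.
    """
    if train.n_samples < cv_folds:
        raise ValueError(
            f"need at least cv_folds={cv_folds} training samples, got {train.n_samples}"
        )
    y = train.ages
    if np.ptp(y) == 0:
        raise ValueError("training ages are constant; clock cannot be calibrated")

    X = train.betas.T  # samples x sites
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    usable = sd > 0
    meta = {"seed": int(seed), "n_train": train.n_samples, "cv_folds": int(cv_folds)}
    if not usable.any():
        warnings.warn("all CpG sites constant; returning intercept-only clock")
        return ClockModel(float(y.mean()), {}, alpha_mix, 0.0, meta)

    Xs = (X[:, usable] - mu[usable]) / sd[usable]
    cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed % (2**31))
    enet = ElasticNetCV(
        l1_ratio=alpha_mix,
        alphas=n_alphas,
        cv=cv,
        max_iter=max_iter,
        tol=tol,
    )
    with warnings.catch_warnings():
        # coordinate descent may report slow convergence at the loosest
        # path points; the CV-selected model itself converges
        warnings.simplefilter("ignore")
        enet.fit(Xs, y)

    coef_std = enet.coef_
    site_names = [s for s, u in zip(train.sites, usable) if u]
    coef_orig = coef_std / sd[usable]
    intercept = float(enet.intercept_ - np.sum(coef_orig * mu[usable]))
    weights = {s: float(c) for s, c in zip(site_names, coef_orig) if c != 0.0}
    meta["lambda_path_min"] = float(np.min(enet.alphas_))
    meta["lambda_path_max"] = float(np.max(enet.alphas_))
    return ClockModel(intercept, weights, alpha_mix, float(enet.alpha_), meta)


def predict_ages(model: ClockModel, dataset: MethylationDataset) -> np.ndarray:
    """Apply a clock to a dataset: ``intercept + sum_j w_j * beta_ji``.

    Negative predictions are reported raw (with a warning), never
    clamped.  Raises ``KeyError`` listing any selected site absent from
    the dataset.
    """
    site_index = {s: i for i, s in enumerate(dataset.sites)}
    missing = [s for s in model.weights if s not in site_index]
    if missing:
        raise KeyError(f"dataset lacks sites required by the clock: {sorted(missing)[:10]}")
    pred = np.full(dataset.n_samples, model.intercept, dtype=float)
    for site, w in model.weights.items():
        pred += w * dataset.betas[site_index[site], :]
    if (pred < 0).any():
        warnings.warn(f"{int((pred < 0).sum())} negative age predictions (reported unclamped)")
    return pred


def count_selected_sites(model: ClockModel) -> int:
    """Number of CpG sites with strictly nonzero weight."""
    return sum(1 for w in model.weights.values() if w != 0.0)


def selection_overlap(model_a: ClockModel, model_b: ClockModel) -> int:
    """Number of CpG sites selected by both clocks."""
    return len(model_a.selected_sites & model_b.selected_sites)


def prune_outliers_and_refit(
    dataset: MethylationDataset,
    spec: SplitSpec,
    k_sd: float = 3.0,
    max_iter: int = 5,
    cv_folds: int = 10,
    seed: int = 0,
) -> tuple[ClockModel, list[str]]:
    """Iterative outlier pruning for suspect calibration samples.

    Fits a clock, flags training samples whose absolute residual exceeds
    ``k_sd`` times the residual SD, removes them, refits, and repeats
    until no sample is flagged or ``max_iter`` rounds have run.  Stops
    early (with a warning) if pruning would leave fewer training samples
    than the internal CV needs.

    Returns the final model and the removed training sample ids.
    """
    if k_sd <= 0:
        raise ValueError("k_sd must be > 0")
    train, _test = split_train_test(dataset, spec, cv_folds=cv_folds)
    model = fit_clock(train, cv_folds=cv_folds, seed=seed)
    removed: list[str] = []
    for _ in range(max_iter):
        pred = predict_ages(model, train)
        resid = pred - train.ages
        sd = resid.std(ddof=1)
        if sd == 0:
            break
        outliers = np.abs(resid) > k_sd * sd
        if not outliers.any():
            break
        keep = np.flatnonzero(~outliers)
        if keep.size < cv_folds:
            warnings.warn("pruning stopped: would leave too few training samples for CV")
            break
        removed.extend(train.samples[i] for i in np.flatnonzero(outliers))
        train = train.subset_samples(keep)
        model = fit_clock(train, cv_folds=cv_folds, seed=seed)
    return model, removed
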