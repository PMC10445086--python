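"""Synthetic DNA methylation datasets with known age structure.

An epigenetic clock is calibrated from a beta-value matrix (CpG sites x
samples, each entry the methylated proportion in [0, 1]) and a vector of
chronological ages.  Real calibration sets of this kind come from
methylation arrays or bisulfite sequencing; here we generate synthetic
matrices whose structure mimics them: a minority of *informative* CpG
sites whose methylation drifts approximately linearly with age (in either
direction), and a majority of age-independent *noise* sites.

Four named profiles reproduce the sample sizes and age ranges of the
published calibration cohorts this package's experiments are modelled on
(human whole blood n=394 ages 16-88 y; zebrafish caudal fin n=96 ages
11.9-60.1 wk; mouse multi-tissue n=153 ages 1-31 wk; green turtle flipper
skin n=63 ages 1-43 y).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DatasetProfile",
    "SignalSpec",
    "MethylationDataset",
    "PROFILES",
    "DEFAULT_PROFILE",
    "DEFAULT_SIGNAL",
    "generate_ages",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
]


@dataclass(frozen=True)
class DatasetProfile:
    """Sample size and age range of a calibration cohort.

    Ages are expressed in ``age_unit`` (years for long-lived species,
    weeks for short-lived ones); nothing downstream depends on the unit
    beyond reporting.
    """

    name: str
    n_samples: int
    age_min: float
    age_max: float
    age_unit: str = "years"

    def __post_init__(self) -> None:
        if self.n_samples < 10:
            raise ValueError(f"n_samples must be >= 10, got {self.n_samples}")
        if not (0 < self.age_min < self.age_max):
            raise ValueError(
                f"require 0 < age_min < age_max, got [{self.age_min}, {self.age_max}]"
            )
        if self.age_unit not in ("years", "weeks"):
            raise ValueError(f"age_unit must be 'years' or 'weeks', got {self.age_unit!r}")


#: The four cohort profiles the simulation experiments emulate.
PROFILES: dict[str, DatasetProfile] = {
    "human": DatasetProfile("human", 394, 16.0, 88.0, "years"),
    "zebrafish": DatasetProfile("zebrafish", 96, 11.9, 60.1, "weeks"),
    "mouse": DatasetProfile("mouse", 153, 1.0, 31.0, "weeks"),
    "turtle": DatasetProfile("turtle", 63, 1.0, 43.0, "years"),
}

#: Desk-scale default cohort for simulation experiments: adult-human-like
#: age range at a sample size that keeps repeated elastic-net fits cheap.
DEFAULT_PROFILE = DatasetProfile("default", 150, 16.0, 88.0, "years")


@dataclass(frozen=True)
class SignalSpec:
    """How age signal and noise are planted in the beta matrix.

    Parameters
    ----------
    n_informative, n_noise
        Counts of age-associated and age-independent CpG sites.
    slope_magnitude
        Absolute change in beta across the full (min-max normalised) age
        range of an informative site.
    direction_mix
        Fraction of informative sites whose methylation *increases* with
        age; the remainder decrease.
    noise_sd
        SD of the Gaussian measurement noise added on the beta scale.
    baseline_range
        Interval from which each site's age-min intercept is drawn.
    """

    n_informative: int = 100
    n_noise: int = 900
    slope_magnitude: float = 0.4
    direction_mix: float = 0.5
    noise_sd: float = 0.05
    baseline_range: tuple[float, float] = (0.1, 0.5)

    def __post_init__(self) -> None:
        if self.n_informative < 1:
            raise ValueError("n_informative must be >= 1 (all-noise datasets are degenerate)")
        if self.n_noise < 0:
            raise ValueError("n_noise must be >= 0")
        if not (0.0 <= self.direction_mix <= 1.0):
            raise ValueError(f"direction_mix must lie in [0, 1], got {self.direction_mix}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.baseline_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"baseline_range must be within [0, 1], got {self.baseline_range}")


DEFAULT_SIGNAL = SignalSpec()


@dataclass
class MethylationDataset:
    """A beta-value matrix with per-sample chronological ages.

    ``betas`` has shape (n_sites, n_samples), rows aligned with ``sites``
    and columns with ``samples``.  This is the unit every experiment in
    the package operates on.
    """

    sites: list[str]
    samples: list[str]
    betas: np.ndarray
    ages: np.ndarray
    age_unit: str = "years"

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        self.ages = np.asarray(self.ages, dtype=float)
        if self.betas.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"betas shape {self.betas.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        if self.ages.shape != (len(self.samples),):
            raise ValueError("ages length must equal number of samples")
        if len(set(self.sites)) != len(self.sites):
            raise ValueError("duplicate site identifiers")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample identifiers")
        if np.isnan(self.ages).any():
            raise ValueError("missing ages are not allowed")
        if (self.ages <= 0).any():
            raise ValueError("all ages must be > 0")
        if np.isnan(self.betas).any():
            raise ValueError("beta matrix contains missing values")
        if (self.betas < 0).any() or (self.betas > 1).any():
            raise ValueError("beta values must lie in [0, 1]")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset_samples(self, indices: np.ndarray) -> "MethylationDataset":
        """Dataset restricted to the given sample indices (order kept)."""
        indices = np.asarray(indices, dtype=int)
        return MethylationDataset(
            sites=list(self.sites),
            samples=[self.samples[i] for i in indices],
            betas=self.betas[:, indices].copy(),
            ages=self.ages[indices].copy(),
            age_unit=self.age_unit,
        )

    def with_ages(self, ages: np.ndarray) -> "MethylationDataset":
        """Copy of the dataset with the age vector replaced."""
        return MethylationDataset(
            sites=list(self.sites),
            samples=list(self.samples),
            betas=self.betas,
            ages=np.asarray(ages, dtype=float).copy(),
            age_unit=self.age_unit,
        )


def generate_ages(profile: DatasetProfile, seed: int) -> np.ndarray:
    """Draw ``profile.n_samples`` ages uniformly from the profile range.

    The real cohorts' age distributions are unpublished; a uniform draw is
    the simplest distribution covering the stated range.
    """
    rng = np.random.default_rng(seed)
    return rng.uniform(profile.age_min, profile.age_max, size=profile.n_samples)


def generate_dataset(
    profile: DatasetProfile,
    signal: SignalSpec = DEFAULT_SIGNAL,
    seed: int = 0,
) -> MethylationDataset:
    """Generate a synthetic methylation dataset under ``profile`` and ``signal``.

    Informative site j follows

        beta_ij = clamp(b0_j + s_j * (age_i - age_min) / (age_max - age_min)
                        + eps_ij, 0, 1)

    with intercept ``b0_j`` uniform on ``signal.baseline_range``, slope
    ``s_j = +/- slope_magnitude`` (sign per ``direction_mix``) and
    ``eps_ij ~ N(0, noise_sd^2)``.  Noise sites share the intercept and
    noise model but have zero slope.  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    ages = rng.uniform(profile.age_min, profile.age_max, size=profile.n_samples)
    norm_age = (ages - profile.age_min) / (profile.age_max - profile.age_min)

    n_info, n_noise = signal.n_informative, signal.n_noise
    n_sites = n_info + n_noise
    lo, hi = signal.baseline_range
    intercepts = rng.uniform(lo, hi, size=n_sites)

    slopes = np.zeros(n_sites)
    n_up = int(round(signal.direction_mix * n_info))
    signs = np.concatenate([np.ones(n_up), -np.ones(n_info - n_up)])
    rng.shuffle(signs)
    slopes[:n_info] = signs * signal.slope_magnitude

    clean = intercepts[:, None] + slopes[:, None] * norm_age[None, :]
    if signal.noise_sd > 0:
        clean = clean + rng.normal(0.0, signal.noise_sd, size=clean.shape)
    betas = np.clip(clean, 0.0, 1.0)

    sites = [f"cg{j:06d}" for j in range(n_sites)]
    samples = [f"{profile.name}_s{i:04d}" for i in range(profile.n_samples)]
    return MethylationDataset(sites, samples, betas, ages, profile.age_unit)


def write_dataset(dataset: MethylationDataset, path: str | Path) -> tuple[Path, Path]:
    """Write a dataset as a beta-matrix TSV plus a metadata CSV.

    ``<path>.betas.tsv`` holds one row per CpG site (first column
    ``site_id``, remaining columns one per sample), mirroring the
    site-by-sample orientation of GEO series matrices.
    ``<path>.meta.csv`` holds ``sample_id, age, age_unit`` rows.
    Betas are stored at full precision so the round trip is exact.
    """
    path = Path(path)
    betas_path = Path(str(path) + ".betas.tsv")
    meta_path = Path(str(path) + ".meta.csv")

    df = pd.DataFrame(dataset.betas, index=dataset.sites, columns=dataset.samples)
    df.index.name = "site_id"
    df.to_csv(betas_path, sep="\t", float_format="%.17g")

    meta = pd.DataFrame(
        {"sample_id": dataset.samples, "age": dataset.ages, "age_unit": dataset.age_unit}
    )
    meta.to_csv(meta_path, index=False, float_format="%.17g")
    return betas_path, meta_path


def read_dataset(path: str | Path) -> MethylationDataset:
    """Read a dataset written by :func:`write_dataset`.

    Raises ``ValueError`` naming the offending row/column for malformed
    input (non-numeric or out-of-range betas, missing or non-positive
    ages, duplicated identifiers).
    """
    path = Path(path)
    betas_path = Path(str(path) + ".betas.tsv")
    meta_path = Path(str(path) + ".meta.csv")
    if not betas_path.exists():
        raise FileNotFoundError(betas_path)
    if not meta_path.exists():
        raise FileNotFoundError(meta_path)

    df = pd.read_csv(betas_path, sep="\t", index_col="site_id", float_precision="round_trip")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicated site id {dup!r} in {betas_path}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"duplicated sample id {dup!r} in {betas_path}")
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy()
    bad = np.argwhere(np.isnan(values))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"non-numeric or missing beta at site {df.index[i]!r}, sample {df.columns[j]!r}"
        )
    out = np.argwhere((values < 0) | (values > 1))
    if out.size:
        i, j = out[0]
        raise ValueError(
            f"beta {values[i, j]} out of [0, 1] at site {df.index[i]!r}, "
            f"sample {df.columns[j]!r}"
        )

    meta = pd.read_csv(meta_path, float_precision="round_trip")
    if "sample_id" not in meta or "age" not in meta:
        raise ValueError(f"{meta_path} must have sample_id and age columns")
    if meta["sample_id"].duplicated().any():
        dup = meta["sample_id"][meta["sample_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicated sample id {dup!r} in {meta_path}")
    ages_by_id = dict(zip(meta["sample_id"], pd.to_numeric(meta["age"], errors="coerce")))
    missing = [s for s in df.columns if s not in ages_by_id]
    if missing:
        raise ValueError(f"samples without age metadata: {missing[:5]}")
    ages = np.array([ages_by_id[s] for s in df.columns], dtype=float)
    if np.isnan(ages).any():
        bad_id = df.columns[int(np.argmax(np.isnan(ages)))]
        raise ValueError(f"non-numeric age for sample {bad_id!r} in {meta_path}")
    if (ages <= 0).any():
        bad_id = df.columns[int(np.argmax(ages <= 0))]
        raise ValueError(f"non-positive age for sample {bad_id!r} in {meta_path}")
    age_unit = str(meta["age_unit"].iloc[0]) if "age_unit" in meta else "years"

    return MethylationDataset(
        sites=list(df.index),
        samples=list(df.columns),
        betas=values,
        ages=ages,
        age_unit=age_unit,
    )
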