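"""Bounded symmetric perturbation of training ages.

The experiment's independent variable is the *error level*: a percentage
p such that every training sample's recorded age may deviate from its
true age by up to p% of that age, in either direction.  At level p each
age a_i becomes

    a_i * (1 + u_i),   u_i ~ Uniform(-p/100, +p/100), independent per sample

so |perturbed - true| <= (p/100) * true always holds, and levels above
100% are rejected because they could produce negative ages.  The uniform
draw is the maximum-entropy distribution on the stated support; other
bounded distributions can be substituted via the ``draw`` hook.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["ErrorLevel", "inject_age_error"]


@dataclass(frozen=True)
class ErrorLevel:
    """An error magnitude as a percentage of true age, in [0, 100]."""

    percent: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.percent <= 100.0):
            raise ValueError(
                f"error level must lie in [0, 100] percent (higher levels could "
                f"produce negative ages); got {self.percent}"
            )

    @property
    def fraction(self) -> float:
        return self.percent / 100.0


def inject_age_error(
    ages: np.ndarray,
    level: ErrorLevel | float,
    seed: int,
    draw: Callable[[np.random.Generator, int, float], np.ndarray] | None = None,
) -> np.ndarray:
    """Perturb each age by an independent bounded relative deviation.

    Parameters
    ----------
    ages
        True chronological ages, all strictly positive.
    level
        Error level (an :class:`ErrorLevel` or a plain percent).
    seed
        Seed for the perturbation draws; each call with a fresh seed
        draws fresh independent noise.
    draw
        Optional replacement for the relative-deviation sampler; called
        as ``draw(rng, n, bound)`` and must return n values in
        [-bound, +bound].  Defaults to the uniform draw.

    Returns
    -------
    Perturbed age vector, same shape; element-wise within
    ``[age*(1-p/100), age*(1+p/100)]``.
    """
    if not isinstance(level, ErrorLevel):
        level = ErrorLevel(float(level))
    ages = np.asarray(ages, dtype=float)
    if (ages <= 0).any():
        raise ValueError("all ages must be > 0 before error injection")
    if level.percent == 0.0:
        return ages.copy()
    rng = np.random.default_rng(seed)
    bound = level.fraction
    if draw is None:
        u = rng.uniform(-bound, bound, size=ages.shape)
    else:
        u = np.asarray(draw(rng, ages.size, bound), dtype=float).reshape(ages.shape)
        if (np.abs(u) > bound).any():
            raise ValueError("custom draw produced deviations outside the level bound")
    return ages * (1.0 + u)
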