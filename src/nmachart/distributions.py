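"""Exponential time-between-events model and its normalising power transform.

Times between rare events are modelled as exponential with scale (mean)
``theta``.  Raising an exponential variate to the power ``1/3.6`` yields a
Weibull variate with shape 3.6, which is close enough to normal for
Shewhart-type control limits to apply (Nelson's transformation).  The
transformed variate has

    mean  = theta* . Gamma(1 + 1/3.6)
    var   = theta*^2 . [Gamma(1 + 2/3.6) - Gamma(1 + 1/3.6)^2]

with ``theta* = theta^(1/3.6)``, so both moments scale linearly in
``theta*``.  The shape 3.6 is kept as a module constant so that tests can
exercise other powers, but the charts in this package are designed for 3.6.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gamma as _gamma

__all__ = [
    "WEIBULL_SHAPE",
    "TransformedMoments",
    "sample_exponential",
    "transform_time",
    "transformed_moments",
    "subgroup_mean_transformed",
]

#: Power such that exponential data raised to 1/WEIBULL_SHAPE is near-normal.
WEIBULL_SHAPE: float = 3.6


@dataclass(frozen=True)
class TransformedMoments:
    """Mean and standard deviation of a transformed (Weibull) observation."""

    mean: float
    sd: float


def standard_moments(shape: float = WEIBULL_SHAPE) -> tuple[float, float]:
    """Moments of the transformed variate at unit scale (``theta = 1``)."""
    m1 = _gamma(1.0 + 1.0 / shape)
    m2 = _gamma(1.0 + 2.0 / shape)
    return m1, float(np.sqrt(m2 - m1 * m1))


def sample_exponential(
    scale: float, count: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``count`` i.i.d. exponential times with mean ``scale``."""
    if not scale > 0:
        raise ValueError(f"scale must be positive, got {scale!r}")
    if not (isinstance(count, (int, np.integer)) and count >= 1):
        raise ValueError(f"count must be a positive integer, got {count!r}")
    return rng.exponential(scale=scale, size=int(count))


def transform_time(t, shape: float = WEIBULL_SHAPE):
    """Raise event times to the power ``1/shape`` (scalar or array).

    Exponential(theta) input becomes Weibull with shape ``shape`` and scale
    ``theta**(1/shape)``; the map is monotone increasing on ``t >= 0``.
    """
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0):
        raise ValueError("event times must be non-negative")
    out = arr ** (1.0 / shape)
    return float(out) if np.isscalar(t) or arr.ndim == 0 else out


def transformed_moments(
    theta0: float, shape: float = WEIBULL_SHAPE
) -> TransformedMoments:
    """Mean and SD of a transformed observation at in-control scale ``theta0``."""
    if not theta0 > 0:
        raise ValueError(f"theta0 must be positive, got {theta0!r}")
    theta_star = theta0 ** (1.0 / shape)
    m1, s = standard_moments(shape)
    return TransformedMoments(mean=theta_star * m1, sd=theta_star * s)


def subgroup_mean_transformed(times, shape: float = WEIBULL_SHAPE) -> float:
    """Arithmetic mean of the transformed times of one subgroup."""
    arr = np.asarray(times, dtype=float)
    if arr.size == 0:
        raise ValueError("subgroup must contain at least one observation")
    return float(np.mean(transform_time(arr, shape=shape)))
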