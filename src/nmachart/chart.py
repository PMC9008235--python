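"""Moving-average control chart for transformed time-between-events data.

The plotted statistic at subgroup ``i`` is the mean of the last ``w``
transformed subgroup means (the full span once ``i >= w``; shorter partial
windows exist for ``i < w`` but carry a larger variance than the limits
assume, so they are not evaluated against the limits by default).  For
``i >= w`` the statistic has

    E[MA_i]   = theta0* . Gamma(1 + 1/3.6)
    Var[MA_i] = theta0*^2 . [Gamma(1 + 2/3.6) - Gamma^2(1 + 1/3.6)] / (n w)

giving symmetric limits ``center -/+ k * sqrt(Var)``.  ``w = 1`` reduces to
the Shewhart chart on subgroup means of transformed exponential data.

Subgroup numbering is 1-based in every reported index (``first_signal``),
matching the usual Sr# presentation of subgrouped data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, OutlierMixin

from .distributions import WEIBULL_SHAPE, standard_moments, transform_time

__all__ = [
    "ControlLimits",
    "MonitorResult",
    "moving_average_series",
    "control_limits",
    "monitor",
    "MovingAverageChart",
]


@dataclass(frozen=True)
class ControlLimits:
    """Symmetric control limits ``(lcl, center, ucl)`` in transformed units."""

    lcl: float
    center: float
    ucl: float

    @property
    def half_width(self) -> float:
        return self.ucl - self.center


@dataclass
class MonitorResult:
    """Per-subgroup monitoring outcome.

    ``out_of_control[i]`` is True iff subgroup ``i + 1`` was evaluated against
    the limits and fell strictly outside them; ``first_signal`` is the 1-based
    index of the first such subgroup, or None.
    """

    ma_values: np.ndarray
    out_of_control: np.ndarray
    first_signal: Optional[int]
    limits: ControlLimits = field(repr=False, default=None)

    @property
    def flags(self) -> list[str]:
        return ["out" if o else "in" for o in self.out_of_control]


def moving_average_series(means: Sequence[float], w: int) -> np.ndarray:
    """Moving average of subgroup means with span ``w``.

    Element ``i`` (1-based) averages the last ``min(i, w)`` means, so the head
    of the series uses partial windows and ``w = 1`` returns the input.
    """
    if not (isinstance(w, (int, np.integer)) and w >= 1):
        raise ValueError(f"span w must be a positive integer, got {w!r}")
    x = np.asarray(means, dtype=float)
    if x.size == 0:
        raise ValueError("means must be a non-empty sequence")
    w = int(w)
    if w == 1:
        return x.copy()
    out = np.empty_like(x)
    csum = np.concatenate([[0.0], np.cumsum(x)])
    for i in range(x.size):
        lo = max(0, i + 1 - w)
        out[i] = (csum[i + 1] - csum[lo]) / (i + 1 - lo)
    return out


def control_limits(
    theta0: float, n: int, w: int, k: float, shape: float = WEIBULL_SHAPE
) -> ControlLimits:
    """Control limits of the span-``w`` moving average at in-control scale ``theta0``."""
    if not theta0 > 0:
        raise ValueError(f"theta0 must be positive, got {theta0!r}")
    if not (isinstance(n, (int, np.integer)) and n >= 1):
        raise ValueError(f"subgroup size n must be a positive integer, got {n!r}")
    if not (isinstance(w, (int, np.integer)) and w >= 1):
        raise ValueError(f"span w must be a positive integer, got {w!r}")
    if not k >= 0:
        raise ValueError(f"limit coefficient k must be non-negative, got {k!r}")
    theta_star = theta0 ** (1.0 / shape)
    m1, s = standard_moments(shape)
    center = theta_star * m1
    half = k * theta_star * s / np.sqrt(n * w)
    return ControlLimits(lcl=center - half, center=center, ucl=center + half)


def monitor(
    ma_values: Sequence[float], limits: ControlLimits, start: int = 1
) -> MonitorResult:
    """Flag moving-average values against fixed control limits.

    Values equal to a limit count as in-control (ties have probability zero
    under the continuous model).  Points before the 1-based index ``start``
    are not evaluated; monitoring a span-``w`` chart uses ``start = w`` so
    that only full-window statistics, whose variance the limits describe,
    are judged.
    """
    x = np.asarray(ma_values, dtype=float)
    out = (x < limits.lcl) | (x > limits.ucl)
    if start > 1:
        out[: min(start - 1, x.size)] = False
    idx = np.flatnonzero(out)
    return MonitorResult(
        ma_values=x,
        out_of_control=out,
        first_signal=int(idx[0]) + 1 if idx.size else None,
        limits=limits,
    )


class MovingAverageChart(OutlierMixin, BaseEstimator):
    """Moving-average control chart as an outlier-detection style estimator.

    Parameters
    ----------
    window : int, default 3
        Span ``w`` of the moving average; 1 gives the Shewhart special case.
    k : float, default 2.738
        Control-limit coefficient (standard deviations of the plotted
        statistic between center line and each limit).  The default is the
        span-3, n=4 coefficient for an in-control ARL near 200.
    theta0 : float or None, default None
        In-control exponential scale (mean time between events).  When None,
        :meth:`fit` estimates it as the grand mean of the raw fitting times.
    shape : float, default 3.6
        Power-transformation shape; transformed data are Weibull(shape).
    evaluate_partial : bool, default False
        Whether partial-window head statistics (subgroup index < window) are
        evaluated against the limits.  Off by default: the limits describe
        the full-window variance only.

    Attributes
    ----------
    n_ : int
        Subgroup size seen during :meth:`fit`.
    theta0_ : float
        In-control scale actually used (given or estimated).
    limits_ : ControlLimits
        Center line and control limits in transformed units.

    Examples
    --------
    >>> from nmachart.datasets import betaine_dataset
    >>> chart = MovingAverageChart(window=3, k=2.95, theta0=1 / 0.0042)
    >>> data = betaine_dataset().lower
    >>> chart.fit(data).monitor(data).first_signal is None
    True
    """

    def __init__(
        self,
        window: int = 3,
        k: float = 2.738,
        theta0: Optional[float] = None,
        shape: float = WEIBULL_SHAPE,
        evaluate_partial: bool = False,
    ):
        self.window = window
        self.k = k
        self.theta0 = theta0
        self.shape = shape
        self.evaluate_partial = evaluate_partial

    def _validate(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-d: one row per subgroup of raw event times")
        if np.any(X < 0):
            raise ValueError("event times must be non-negative")
        return X

    def fit(self, X, y=None) -> "MovingAverageChart":
        """Set the control limits from subgrouped raw times ``X`` (m, n)."""
        X = self._validate(X)
        self.n_ = X.shape[1]
        self.theta0_ = float(X.mean()) if self.theta0 is None else float(self.theta0)
        self.limits_ = control_limits(
            self.theta0_, self.n_, self.window, self.k, shape=self.shape
        )
        return self

    def transform(self, X) -> np.ndarray:
        """Moving-average series of the transformed subgroup means of ``X``."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "limits_")
        X = self._validate(X)
        means = transform_time(X, shape=self.shape).mean(axis=1)
        return moving_average_series(means, self.window)

    def monitor(self, X) -> MonitorResult:
        """Full per-subgroup monitoring of ``X`` against the fitted limits."""
        start = 1 if self.evaluate_partial else self.window
        return monitor(self.transform(X), self.limits_, start=start)

    def predict(self, X) -> np.ndarray:
        """+1 for in-control subgroups, -1 for out-of-control ones."""
        return np.where(self.monitor(X).out_of_control, -1, 1)

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).predict(X)
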