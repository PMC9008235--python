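"""Bundled Betaine example data and a paired-endpoint synthetic generator.

The Betaine data record the disappearance of betaine from incubated ruminal
fluid, expressed as interval-valued (lower/upper endpoint) event times in 24
subgroups of 4 observations.  The head of the series is laboratory data; the
remainder was generated from exponential distributions with rates
0.0042 (lower endpoint) and 0.0076 (upper), i.e. scales of roughly 238 and
132.  The fixture stores the values exactly as published (2 decimals).

The synthetic generator emulates that structure: two endpoint series of
exponential event times, optionally comonotone within each cell (common
uniform draws through the inverse CDF), with a step change in scale at a
configurable subgroup for shift-detection studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib.resources import files
from typing import Optional, Union

import numpy as np
import pandas as pd

__all__ = ["SubgroupSeries", "betaine_dataset", "generate_series"]

BETAINE_RATES = (0.0042, 0.0076)  # per-endpoint exponential rates of the generated rows


@dataclass
class SubgroupSeries:
    """Paired-endpoint subgrouped event times.

    ``lower`` and ``upper`` are (m, n) arrays of non-negative times; their
    subgroup sizes may differ when the study design is itself
    interval-valued (e.g. n in [4, 6]).  ``shift_index`` is the 1-based
    subgroup at which the scale changes, when the series contains a shift.
    """

    lower: np.ndarray
    upper: np.ndarray
    shift_index: Optional[int] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if self.lower.ndim != 2 or self.upper.ndim != 2:
            raise ValueError("endpoint series must be 2-d (subgroups x observations)")
        if self.lower.shape[0] != self.upper.shape[0]:
            raise ValueError("endpoint series must have the same number of subgroups")
        if np.any(self.lower < 0) or np.any(self.upper < 0):
            raise ValueError("event times must be non-negative")
        if self.shift_index is not None and not (
            1 <= self.shift_index <= self.lower.shape[0]
        ):
            raise ValueError("shift_index must lie within 1..m")

    @property
    def m(self) -> int:
        return self.lower.shape[0]


def betaine_dataset() -> SubgroupSeries:
    """The Betaine data: 24 subgroups x 4 observations per endpoint, as published."""
    path = files("nmachart").joinpath("data/betaine.csv")
    with path.open("r") as fh:
        frame = pd.read_csv(fh)
    lo = frame[[c for c in frame.columns if c.endswith("_lo")]].to_numpy(float)
    hi = frame[[c for c in frame.columns if c.endswith("_hi")]].to_numpy(float)
    return SubgroupSeries(
        lower=lo,
        upper=hi,
        meta={"name": "betaine", "rates": BETAINE_RATES, "source": "published table"},
    )


def generate_series(
    theta_lower: float,
    theta_upper: float,
    n: Union[int, tuple[int, int]],
    m: int,
    shift_index: Optional[int] = None,
    c: float = 1.0,
    seed: int = 0,
    coupled: bool = False,
) -> SubgroupSeries:
    """Simulate a paired-endpoint series with an optional step change in scale.

    Subgroups before ``shift_index`` (1-based) are drawn at scale ``theta``;
    from ``shift_index`` on, at ``c * theta``, per endpoint.  ``n`` may be a
    single subgroup size or an (n_lower, n_upper) pair.  In ``coupled`` mode
    (equal sizes only) both endpoints share the same uniform draws through
    the inverse CDF, making the two series comonotone within each cell.
    """
    if isinstance(n, (int, np.integer)):
        n_lo = n_hi = int(n)
    else:
        n_lo, n_hi = (int(v) for v in n)
    for name, value in (
        ("theta_lower", theta_lower),
        ("theta_upper", theta_upper),
        ("c", c),
    ):
        if not value > 0:
            raise ValueError(f"{name} must be positive, got {value!r}")
    if not (n_lo >= 1 and n_hi >= 1 and m >= 1):
        raise ValueError("subgroup size and count must be positive integers")
    if shift_index is not None and not 1 <= shift_index <= m:
        raise ValueError(f"shift_index must lie in 1..{m}, got {shift_index!r}")
    if coupled and n_lo != n_hi:
        raise ValueError("coupled mode requires equal subgroup sizes")

    rng_lo, rng_hi = (
        np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(2)
    )
    scale_mult = np.ones((m, 1))
    if shift_index is not None:
        scale_mult[shift_index - 1 :] = c

    if coupled:
        u = rng_lo.uniform(size=(m, n_lo))
        base = -np.log1p(-u)  # unit-scale exponential via the inverse CDF
        lower = theta_lower * scale_mult * base
        upper = theta_upper * scale_mult * base
    else:
        lower = theta_lower * scale_mult * rng_lo.exponential(size=(m, n_lo))
        upper = theta_upper * scale_mult * rng_hi.exponential(size=(m, n_hi))

    return SubgroupSeries(
        lower=lower,
        upper=upper,
        shift_index=shift_index,
        meta={
            "theta_lower": theta_lower,
            "theta_upper": theta_upper,
            "c": c,
            "seed": seed,
            "coupled": coupled,
        },
    )
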