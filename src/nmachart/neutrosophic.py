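"""Interval-valued (neutrosophic) quantities.

Neutrosophic statistics extends classical statistics to data or parameters
that are only known up to an indeterminacy interval.  A neutrosophic quantity
``x_N`` is reported here as an ordered pair of values evaluated at the two
ends of that interval: the *lower-indeterminacy* configuration first, the
*upper* one second.  The pair is ordered by endpoint label, never by
magnitude — control-limit coefficients such as ``(2.738, 2.66)`` are a valid
pair even though the first entry is the larger.

The equivalent ``a + b*I`` representation, with the measure of indeterminacy
``I`` running over ``[0, I_max]``, is available through
:meth:`NeutrosophicValue.to_interval_form`.  When both endpoints coincide the
quantity is classical and every downstream operation reduces to its
classical counterpart.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

__all__ = ["NeutrosophicValue"]


@dataclass(frozen=True)
class NeutrosophicValue:
    """An ordered endpoint pair ``(lower, upper)`` of an indeterminacy interval."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        for name in ("lower", "upper"):
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ValueError(f"{name} endpoint must be finite, got {value!r}")

    @property
    def is_degenerate(self) -> bool:
        """True when both endpoints coincide (classical, indeterminacy-free)."""
        return self.lower == self.upper

    def map(self, fn: Callable[[float], float]) -> "NeutrosophicValue":
        """Apply ``fn`` endpoint-wise, preserving the (lower, upper) labelling."""
        return NeutrosophicValue(fn(self.lower), fn(self.upper))

    def astuple(self) -> tuple[float, float]:
        return (self.lower, self.upper)

    def to_interval_form(self) -> tuple[float, float, float]:
        """Return ``(a, b, i_max)`` such that ``x(I) = a + b*I`` for ``I in [0, i_max]``.

        The convention writes ``x(I) = x_L - x_U * I`` with
        ``i_max = (x_L - x_U) / x_U``, so ``x(0)`` is the lower-endpoint value
        and ``x(i_max)`` the upper one; ``i_max`` is the relative measure of
        indeterminacy.  Undefined when the upper endpoint is zero.
        """
        if self.upper == 0.0:
            raise ValueError(
                "a + b*I form is undefined for a zero upper endpoint "
                "(the measure of indeterminacy divides by it)"
            )
        if self.is_degenerate:
            return (self.lower, -self.upper, 0.0)
        return (self.lower, -self.upper, (self.lower - self.upper) / self.upper)

    @classmethod
    def from_interval_form(cls, a: float, b: float, i_max: float) -> "NeutrosophicValue":
        """Inverse of :meth:`to_interval_form`: endpoints ``(a, a + b*i_max)``."""
        return cls(a, a + b * i_max)
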