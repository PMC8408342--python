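"""Endpoint growth metrics: total percent change and annualized compound growth.

Both statistics use only the two endpoint values — no regression through the
intermediate years:

* percent change      (x_end / x_base − 1) × 100
* annualized growth   ((x_end / x_base)^(1/(end_year − base_year)) − 1) × 100

Compounding the annualized rate over the period reproduces the endpoint
ratio to machine precision, and both are invariant to rescaling base and
end by the same positive constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

TOTAL = "total_percent_change"
ANNUALIZED = "annualized_percent"


def percent_change(x_base: float, x_end: float) -> float:
    """Total percent change from ``x_base`` to ``x_end`` (may be negative)."""
    if not (isinstance(x_base, (int, float)) and math.isfinite(x_base)) or x_base <= 0:
        raise ValueError(f"base value must be positive and present, got {x_base!r}")
    if not math.isfinite(x_end):
        raise ValueError(f"end value must be present, got {x_end!r}")
    return (x_end / x_base - 1.0) * 100.0


def annualized_growth(
    x_base: float, x_end: float, base_year: int, end_year: int
) -> float:
    """Annualized compound growth rate in percent per year.

    The exponent denominator is the calendar-year difference (15 for a
    2000→2015 window).
    """
    if end_year <= base_year:
        raise ValueError(f"end_year {end_year} must exceed base_year {base_year}")
    for label, v in (("base", x_base), ("end", x_end)):
        if not math.isfinite(v) or v <= 0:
            raise ValueError(f"{label} value must be positive, got {v!r}")
    years = end_year - base_year
    return ((x_end / x_base) ** (1.0 / years) - 1.0) * 100.0


@dataclass(frozen=True)
class GrowthRate:
    """A growth statistic together with the endpoints that produced it."""

    base_year: int
    end_year: int
    kind: str  # TOTAL | ANNUALIZED
    value: float  # percent
    base_value: float
    end_value: float

    def __post_init__(self) -> None:
        if self.end_year <= self.base_year:
            raise ValueError("end_year must exceed base_year")

    @classmethod
    def total(cls, x_base: float, x_end: float,
              base_year: int, end_year: int) -> "GrowthRate":
        return cls(base_year, end_year, TOTAL,
                   percent_change(x_base, x_end), x_base, x_end)

    @classmethod
    def annualized(cls, x_base: float, x_end: float,
                   base_year: int, end_year: int) -> "GrowthRate":
        return cls(base_year, end_year, ANNUALIZED,
                   annualized_growth(x_base, x_end, base_year, end_year),
                   x_base, x_end)


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Presentation rounding: round half away from zero (so 57.755 → 57.8,
    −37.75 → −37.8). Stored values are never rounded; only report cells are."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
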