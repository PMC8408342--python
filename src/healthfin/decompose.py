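"""Log-additive decomposition of domestic government health-expenditure growth.

GGHE-D factors exactly into three drivers:

    GGHE-D = GDP × (GGE/GDP) × (GGHE-D/GGE)

so with endpoint growth rates g (GGHE-D), y (GDP), e (GGE/GDP — the size of
government in the economy) and h (GGHE-D/GGE — the priority of health in the
budget),

    1 + g = (1 + y)(1 + e)(1 + h)
    ln(1+g) = ln(1+y) + ln(1+e) + ln(1+h)

The share of GGHE-D growth attributable to each driver is its log term
divided by ln(1+g). When the decomposition is computed from one consistent
set of six levels the identity is exact (residual at machine precision);
when reproduced from separately rounded published rates the residual is
reported, never redistributed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass


@dataclass(frozen=True)
class DecompositionResult:
    """Growth rates, their log terms (nats), driver shares, and the residual.

    ``shares_defined`` is False when GGHE-D did not change (ln(1+g) = 0), in
    which case the shares are NaN.
    """

    g: float  # GGHE-D growth (fraction)
    y: float  # GDP growth
    e: float  # growth of GGE/GDP
    h: float  # growth of GGHE-D/GGE
    log_g: float
    log_y: float
    log_e: float
    log_h: float
    share_y: float
    share_e: float
    share_h: float
    residual: float  # log_g − (log_y + log_e + log_h), nats
    shares_defined: bool


def _require_positive(**levels: float) -> None:
    for name, v in levels.items():
        if not (isinstance(v, (int, float)) and math.isfinite(v)) or v <= 0:
            raise ValueError(f"{name} must be a positive finite level, got {v!r}")


def _result(g: float, y: float, e: float, h: float) -> DecompositionResult:
    for name, rate in (("g", g), ("y", y), ("e", e), ("h", h)):
        if 1.0 + rate <= 0.0:
            raise ValueError(f"growth rate {name} = {rate} implies a non-positive level")
    lg, ly, le, lh = (math.log1p(r) for r in (g, y, e, h))
    residual = lg - (ly + le + lh)
    defined = lg != 0.0
    if defined:
        sy, se, sh = ly / lg, le / lg, lh / lg
    else:
        sy = se = sh = float("nan")
    return DecompositionResult(g, y, e, h, lg, ly, le, lh, sy, se, sh,
                               residual, defined)


def decompose_gghed(
    gdp_0: float, gdp_1: float,
    gge_0: float, gge_1: float,
    gghed_0: float, gghed_1: float,
) -> DecompositionResult:
    """Decompose GGHE-D growth from six observed levels (the exact route).

    The driver rates are computed from the level pairs themselves
    (y from GDP, e from GGE/GDP, h from GGHE-D/GGE), so the log identity
    holds by construction up to floating-point error. GGHE-D exceeding GGE
    in either year is implausible but not impossible in reported data, so it
    raises a warning, not an error.
    """
    _require_positive(gdp_0=gdp_0, gdp_1=gdp_1, gge_0=gge_0, gge_1=gge_1,
                      gghed_0=gghed_0, gghed_1=gghed_1)
    if gghed_0 > gge_0 or gghed_1 > gge_1:
        warnings.warn("GGHE-D exceeds GGE in at least one year", stacklevel=2)
    g = gghed_1 / gghed_0 - 1.0
    y = gdp_1 / gdp_0 - 1.0
    e = (gge_1 / gdp_1) / (gge_0 / gdp_0) - 1.0
    h = (gghed_1 / gge_1) / (gghed_0 / gge_0) - 1.0
    return _result(g, y, e, h)


def decompose_from_rates(
    y: float, e: float, h: float, g: float | None = None
) -> DecompositionResult:
    """Decompose from pre-computed driver rates (the published-table route).

    When ``g`` is supplied separately (e.g. read off a published table built
    from unrounded data), the residual measures how far the rounded inputs
    are from the exact identity; when omitted, g = (1+y)(1+e)(1+h) − 1 and
    the residual vanishes to machine precision.
    """
    if g is None:
        g = growth_from_component_rates(y, e, h)
    return _result(g, y, e, h)


def growth_from_component_rates(y: float, e: float, h: float) -> float:
    """Combine driver growth rates multiplicatively: g = (1+y)(1+e)(1+h) − 1."""
    for name, rate in (("y", y), ("e", e), ("h", h)):
        if not math.isfinite(rate) or 1.0 + rate <= 0.0:
            raise ValueError(f"1 + {name} must be positive, got {name} = {rate!r}")
    return (1.0 + y) * (1.0 + e) * (1.0 + h) - 1.0


def component_share(
    comp_0: float, comp_1: float, gghed_0: float, gghed_1: float
) -> float:
    """Share of GGHE-D log growth attributable to one driver (fraction).

    ln(comp_1/comp_0) / ln(gghed_1/gghed_0). The component pair may be levels
    or ratio values — only the ratio of the pair enters.
    """
    _require_positive(comp_0=comp_0, comp_1=comp_1,
                      gghed_0=gghed_0, gghed_1=gghed_1)
    denom = math.log(gghed_1 / gghed_0)
    if denom == 0.0:
        raise ValueError("GGHE-D did not change; component share undefined")
    return math.log(comp_1 / comp_0) / denom
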