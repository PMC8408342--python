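"""Group-level aggregation: sums, aggregate ratios, per-capita values,
CHE composition shares, and country-weighted alternatives.

The central methodological choice is *expenditure weighting*: a group
indicator is the sum of member levels, and a group ratio is the ratio of
the summed numerator to the summed denominator — so large economies carry
proportionally large weight, and the group value generalizes to the group's
population. The country-weighted average (each country counted once,
regardless of size) is provided for methodology comparison only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import GroupAssignment
from .panel import CHE_COMPONENTS, NUMERIC_COLUMNS, Panel

AGGREGATE = "aggregate"
COUNTRY_WEIGHTED = "country_weighted"


@dataclass(frozen=True)
class AggregateCell:
    """One group × year aggregate: a level sum, ratio, or per-capita value."""

    group: str
    year: int
    indicator: str
    value: float
    weighting: str
    n_countries: int


@dataclass(frozen=True)
class CompositionShares:
    """Financing-source shares of group CHE (fractions of aggregate CHE)."""

    group: str
    year: int
    shares: dict[str, float]
    missing_components: tuple[str, ...]
    n_countries: int

    def total(self) -> float:
        return float(sum(self.shares.values()))


def _check(indicator: str) -> None:
    if indicator not in NUMERIC_COLUMNS:
        raise KeyError(f"unknown indicator {indicator!r}")


def _member_values(
    panel: Panel, members: tuple[str, ...], indicator: str, year: int
) -> pd.Series:
    """Present (non-missing) values of one indicator for group members, by iso3."""
    _check(indicator)
    df = panel.data
    sel = df[(df["year"] == year) & (df["iso3"].isin(members))]
    s = sel.set_index("iso3")[indicator].dropna().sort_index()
    return s


def aggregate_level(
    panel: Panel, assignment: GroupAssignment, group: str, indicator: str, year: int
) -> AggregateCell:
    """Sum a level indicator over group members with present values.

    Members missing the value are skipped; ``n_countries`` records coverage.
    The value is NaN when no member reports.
    """
    members = assignment.members(group)
    if not members:
        raise ValueError(f"group {group!r} is empty")
    vals = _member_values(panel, members, indicator, year)
    value = float(vals.sum()) if len(vals) else float("nan")
    return AggregateCell(group, year, indicator, value, AGGREGATE, len(vals))


def aggregate_ratio(
    panel: Panel,
    assignment: GroupAssignment,
    group: str,
    numerator: str,
    denominator: str,
    year: int,
) -> AggregateCell:
    """Aggregate (expenditure-weighted) ratio: Σ numerator / Σ denominator.

    Complete-pairs rule: only members reporting *both* indicators contribute
    to either sum, keeping the two sums over an identical country set.
    Per-capita values are this operation with denominator ``population``.
    """
    members = assignment.members(group)
    num = _member_values(panel, members, numerator, year)
    den = _member_values(panel, members, denominator, year)
    common = num.index.intersection(den.index)
    if len(common) == 0:
        raise ValueError(
            f"no member of {group!r} has both {numerator} and {denominator} in {year}")
    den_sum = float(den.loc[common].sum())
    if den_sum == 0.0:
        raise ZeroDivisionError(
            f"denominator {denominator} sums to zero for {group!r} in {year}")
    value = float(num.loc[common].sum()) / den_sum
    return AggregateCell(
        group, year, f"{numerator}/{denominator}", value, AGGREGATE, len(common))


def per_capita(
    panel: Panel, assignment: GroupAssignment, group: str, indicator: str, year: int
) -> AggregateCell:
    """Group per-capita value (panel units per person)."""
    return aggregate_ratio(panel, assignment, group, indicator, "population", year)


def composition_shares(
    panel: Panel,
    assignment: GroupAssignment,
    group: str,
    year: int,
    components: tuple[str, ...] = CHE_COMPONENTS,
) -> CompositionShares:
    """Shares of aggregate CHE held by each financing source.

    Each share is (Σ component)/(Σ CHE) over members reporting CHE; a member
    missing a component contributes 0 to that component's sum, and the
    component is listed in ``missing_components``. Shares therefore sum to 1
    only up to the panel's additivity residual and missing-data gaps.
    """
    members = assignment.members(group)
    che = _member_values(panel, members, "che", year)
    che_sum = float(che.sum()) if len(che) else 0.0
    if not len(che) or che_sum <= 0:
        raise ValueError(f"group {group!r} CHE sum not positive in {year}")
    shares: dict[str, float] = {}
    flagged: list[str] = []
    for comp in components:
        vals = _member_values(panel, members, comp, year)
        vals = vals.reindex(che.index)
        if vals.isna().any():
            flagged.append(comp)
        shares[comp] = float(vals.fillna(0.0).sum()) / che_sum
    return CompositionShares(group, year, shares, tuple(flagged), len(che))


def country_weighted_average(
    panel: Panel,
    assignment: GroupAssignment,
    group: str,
    numerator: str,
    denominator: str,
    year: int,
) -> AggregateCell:
    """Unweighted mean of member-level ratios (each country counts once).

    This is the WHO-style alternative to :func:`aggregate_ratio`; pairing the
    two exposes how much large members move the aggregate.
    """
    members = assignment.members(group)
    num = _member_values(panel, members, numerator, year)
    den = _member_values(panel, members, denominator, year)
    common = num.index.intersection(den.index)
    den_common = den.loc[common]
    common = den_common.index[den_common != 0.0]
    if len(common) == 0:
        raise ValueError(
            f"no member of {group!r} has complete {numerator}/{denominator} in {year}")
    ratios = num.loc[common] / den.loc[common]
    return AggregateCell(
        group, year, f"{numerator}/{denominator}", float(ratios.mean()),
        COUNTRY_WEIGHTED, len(common))


def weighting_divergence(
    panel: Panel,
    assignment: GroupAssignment,
    group: str,
    numerator: str,
    denominator: str,
    year: int,
) -> dict[str, float]:
    """Aggregate vs country-weighted ratio side by side, plus their gap."""
    agg = aggregate_ratio(panel, assignment, group, numerator, denominator, year)
    cw = country_weighted_average(panel, assignment, group, numerator, denominator, year)
    return {
        "aggregate": agg.value,
        "country_weighted": cw.value,
        "divergence": agg.value - cw.value,
    }
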