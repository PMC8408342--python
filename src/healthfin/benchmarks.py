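"""Spending-target benchmarks and outlier screening.

Two international reference points are tracked:

* the Abuja target — government health spending of at least 15% of the
  total government budget (GGHE/GGE). The default numerator includes
  externally financed government health spending (GGHE-D + EXT); a
  domestic-only variant is selectable;
* the UHC band — public spending on health of 5–6% of GDP; a group or
  country meets the band at the 5% lower edge (the 6% upper edge is
  reported, not used as pass/fail).

Outlier screening flags countries whose indicator levels, or whose changes
over the study window, fall outside configurable percentile (nearest-rank)
or absolute bounds. Published analyses list such countries without stating
a selection rule, so the rule here is explicit, configurable, and embedded
in the report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aggregate import _member_values
from .cohort import GroupAssignment
from .panel import Panel

GGHE_D_ONLY = "gghe_d"
GGHE_D_PLUS_EXT = "gghe_d_plus_ext"

ABUJA_THRESHOLD = 0.15
GDP_BAND = (0.05, 0.06)


@dataclass(frozen=True)
class BenchmarkRecord:
    """Benchmark status of one entity (group or country) in one year."""

    entity: str
    year: int
    gghe_gge_share: float
    abuja_met: bool
    abuja_gap_pp: float  # signed gap to the Abuja threshold, percentage points
    gghe_gdp_share: float
    gdp_band_met: bool
    gdp_gap_pp: float
    numerator_variant: str
    abuja_threshold: float
    gdp_threshold: float


def _entity_shares(
    panel: Panel, members: tuple[str, ...], year: int, variant: str
) -> tuple[float, float]:
    """(GGHE/GGE, GGHE/GDP) for one entity; EXT missing counts as zero."""
    gghe = _member_values(panel, members, "gghe_d", year)
    gge = _member_values(panel, members, "gge", year)
    gdp = _member_values(panel, members, "gdp", year)
    if variant == GGHE_D_PLUS_EXT:
        ext = _member_values(panel, members, "ext", year)
        gghe = gghe.add(ext.reindex(gghe.index).fillna(0.0))
    elif variant != GGHE_D_ONLY:
        raise ValueError(f"unknown numerator variant {variant!r}")
    common_gge = gghe.index.intersection(gge.index)
    common_gdp = gghe.index.intersection(gdp.index)
    if len(common_gge) == 0 or len(common_gdp) == 0:
        raise ValueError(f"benchmark shares not computable in {year}")
    share_gge = float(gghe.loc[common_gge].sum()) / float(gge.loc[common_gge].sum())
    share_gdp = float(gghe.loc[common_gdp].sum()) / float(gdp.loc[common_gdp].sum())
    return share_gge, share_gdp


def benchmark_flags(
    panel: Panel,
    assignment: GroupAssignment,
    years: tuple[int, ...],
    numerator_variant: str = GGHE_D_PLUS_EXT,
    abuja_threshold: float = ABUJA_THRESHOLD,
    gdp_threshold: float = GDP_BAND[0],
    include_countries: bool = False,
) -> list[BenchmarkRecord]:
    """Benchmark every reporting group (and optionally every country) per year.

    Flags are pure threshold comparisons on the shares (met when share ≥
    threshold), so they can be recomputed from the record; the thresholds
    travel with the result.
    """
    entities: list[tuple[str, tuple[str, ...]]] = [
        (label, assignment.members(label)) for label in assignment.labels
        if assignment.members(label)
    ]
    if include_countries:
        entities += [(iso3, (iso3,)) for iso3 in assignment.included]
    records: list[BenchmarkRecord] = []
    for entity, members in entities:
        for year in years:
            s_gge, s_gdp = _entity_shares(panel, members, year, numerator_variant)
            records.append(BenchmarkRecord(
                entity=entity, year=year,
                gghe_gge_share=s_gge,
                abuja_met=s_gge >= abuja_threshold,
                abuja_gap_pp=(s_gge - abuja_threshold) * 100.0,
                gghe_gdp_share=s_gdp,
                gdp_band_met=s_gdp >= gdp_threshold,
                gdp_gap_pp=(s_gdp - gdp_threshold) * 100.0,
                numerator_variant=numerator_variant,
                abuja_threshold=abuja_threshold,
                gdp_threshold=gdp_threshold,
            ))
    return records


def benchmarks_to_frame(records: list[BenchmarkRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


# ---------------------------------------------------------------------------
# outlier screening


@dataclass(frozen=True)
class PercentileRule:
    """Flag values strictly outside the [lower, upper] nearest-rank percentiles."""

    lower_pct: float = 1.0
    upper_pct: float = 99.0
    min_countries: int = 10

    @property
    def rule_id(self) -> str:
        return f"percentile[{self.lower_pct:g},{self.upper_pct:g}]"


@dataclass(frozen=True)
class AbsoluteRule:
    """Flag values strictly outside fixed absolute bounds."""

    lower: float
    upper: float

    @property
    def rule_id(self) -> str:
        return f"absolute[{self.lower:g},{self.upper:g}]"


@dataclass(frozen=True)
class OutlierFlag:
    iso3: str
    indicator: str
    window: str  # a year ("2000") or a change window ("2000-2015")
    value: float
    rule_id: str


@dataclass
class OutlierReport:
    flagged: tuple[OutlierFlag, ...]
    indicator: str
    rule_id: str
    n_countries: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [f.__dict__ for f in self.flagged],
            columns=["iso3", "indicator", "window", "value", "rule_id"])


def nearest_rank_percentile(values: np.ndarray, pct: float) -> float:
    """Nearest-rank percentile: the value at rank ⌈p/100 × n⌉ of the sorted
    sample (rank at least 1). For small samples the extreme percentiles
    coincide with the sample minimum/maximum."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    if n == 0:
        raise ValueError("empty sample")
    k = max(1, math.ceil(pct / 100.0 * n))
    return float(v[min(k, n) - 1])


def _bounds(values: np.ndarray, rule) -> tuple[float, float]:
    if isinstance(rule, AbsoluteRule):
        return rule.lower, rule.upper
    return (nearest_rank_percentile(values, rule.lower_pct),
            nearest_rank_percentile(values, rule.upper_pct))


def flag_outliers(
    panel: Panel,
    countries: tuple[str, ...],
    numerator: str,
    denominator: str,
    years: tuple[int, int] = (2000, 2015),
    rule: PercentileRule | AbsoluteRule = PercentileRule(),
) -> OutlierReport:
    """Screen a country-level ratio for outlying levels and outlying changes.

    For each of the two years, countries whose ratio lies strictly outside
    the rule's bounds are flagged; countries whose change in the ratio
    (end − start, in ratio units) lies outside the same bounds computed on
    the changes are flagged under the change window. Ordering of the output
    is deterministic: sorted by (window, value, iso3).
    """
    series: dict[int, pd.Series] = {}
    for year in years:
        num = _member_values(panel, countries, numerator, year)
        den = _member_values(panel, countries, denominator, year)
        common = num.index.intersection(den.index)
        den_c = den.loc[common]
        common = den_c.index[den_c != 0.0]
        series[year] = (num.loc[common] / den.loc[common]).sort_index()
    indicator = f"{numerator}/{denominator}"
    if isinstance(rule, PercentileRule):
        n_min = min(len(s) for s in series.values())
        if n_min < rule.min_countries:
            raise ValueError(
                f"percentile rule needs at least {rule.min_countries} countries, "
                f"got {n_min}")
    flags: list[OutlierFlag] = []

    def scan(values: pd.Series, window: str) -> None:
        lo, hi = _bounds(values.to_numpy(), rule)
        for iso3, v in sorted(values.items(), key=lambda kv: (kv[1], kv[0])):
            if v < lo or v > hi:
                flags.append(OutlierFlag(iso3, indicator, window, float(v),
                                         rule.rule_id))

    for year in years:
        scan(series[year], str(year))
    start, end = years
    common = series[start].index.intersection(series[end].index)
    changes = (series[end].loc[common] - series[start].loc[common])
    if len(changes):
        scan(changes, f"{start}-{end}")
    flags.sort(key=lambda f: (f.window, f.value, f.iso3))
    return OutlierReport(
        flagged=tuple(flags), indicator=indicator, rule_id=rule.rule_id,
        n_countries=len(series[start]))
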