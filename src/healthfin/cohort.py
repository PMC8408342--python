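"""Cohort selection and fixed start-of-period income grouping.

Two deterministic steps precede any aggregation:

1. inclusion filtering — keep countries that (i) had at least a minimum
   population in a reference year and (ii) report every required indicator
   in both anchor years;
2. income grouping — assign each included country to the World Bank
   analytical income group it held at the *start* of the study period
   (classification is an input table, not computed) and hold that group
   fixed across all years. Designated large "focus" countries additionally
   get a singleton reporting group and a complement group
   (e.g. ``"LIC excluding XND"``) so their weight in the group aggregate
   can be inspected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import NUMERIC_COLUMNS, Panel

INCOME_GROUPS: tuple[str, ...] = ("LIC", "LMIC", "UMIC", "HIC")
UNCLASSIFIED = "UNCLASSIFIED"
VALID_GROUPS: tuple[str, ...] = INCOME_GROUPS + (UNCLASSIFIED,)

INCLUDED = "included"
EXCLUDED_SMALL_POP = "excluded_small_population"
EXCLUDED_MISSING = "excluded_missing_data"


@dataclass(frozen=True)
class InclusionCriteria:
    """Cohort filter parameters.

    Defaults follow the common GHED-analysis convention: population of at
    least 600,000 persons in 2015, and the five core indicators present in
    both anchor years 2000 and 2015. A country sitting exactly on the
    population threshold is included (the rule is ≥).
    """

    pop_threshold: float = 600_000.0
    pop_reference_year: int = 2015
    required_indicators: tuple[str, ...] = ("gdp", "gge", "gghe_d", "che", "oop")
    anchor_years: tuple[int, ...] = (2000, 2015)

    def __post_init__(self) -> None:
        if self.pop_threshold <= 0:
            raise ValueError("pop_threshold must be positive")
        unknown = set(self.required_indicators) - set(NUMERIC_COLUMNS)
        if unknown:
            raise ValueError(f"unknown indicators in criteria: {sorted(unknown)}")


@dataclass(frozen=True)
class CountryDecision:
    iso3: str
    status: str  # INCLUDED | EXCLUDED_SMALL_POP | EXCLUDED_MISSING
    missing: tuple[tuple[str, int], ...] = ()
    note: str = ""


@dataclass
class ExclusionReport:
    """Per-country inclusion decisions plus the criteria that produced them."""

    decisions: dict[str, CountryDecision]
    criteria: InclusionCriteria

    @property
    def included(self) -> tuple[str, ...]:
        return tuple(sorted(c for c, d in self.decisions.items()
                            if d.status == INCLUDED))

    def counts(self) -> dict[str, int]:
        out = {INCLUDED: 0, EXCLUDED_SMALL_POP: 0, EXCLUDED_MISSING: 0}
        for d in self.decisions.values():
            out[d.status] += 1
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"iso3": d.iso3, "status": d.status,
             "missing": ";".join(f"{ind}:{yr}" for ind, yr in d.missing),
             "note": d.note}
            for d in (self.decisions[k] for k in sorted(self.decisions))
        ]
        return pd.DataFrame(rows, columns=["iso3", "status", "missing", "note"])

    def to_json(self) -> str:
        payload = {
            "counts": self.counts(),
            "criteria": {
                "pop_threshold": self.criteria.pop_threshold,
                "pop_reference_year": self.criteria.pop_reference_year,
                "required_indicators": list(self.criteria.required_indicators),
                "anchor_years": list(self.criteria.anchor_years),
            },
            "decisions": {
                iso3: {"status": d.status,
                       "missing": [list(m) for m in d.missing],
                       "note": d.note}
                for iso3, d in sorted(self.decisions.items())
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def apply_inclusion_filters(
    panel: Panel, criteria: InclusionCriteria = InclusionCriteria()
) -> ExclusionReport:
    """Apply the two inclusion criteria to every country in the panel.

    The population check runs first: a country below the threshold — or with
    its population missing in the reference year — is recorded under
    ``excluded_small_population`` and its data completeness is not examined.
    Decisions depend only on the panel content and the criteria, never on
    row order.
    """
    if panel.data.empty:
        raise ValueError("cannot filter an empty panel")
    if panel.year_span is not None:
        lo, hi = panel.year_span
        bad = [y for y in criteria.anchor_years if not lo <= y <= hi]
        if bad:
            raise ValueError(f"anchor years {bad} outside panel span {lo}–{hi}")
    cells = panel.data.set_index(["iso3", "year"])
    decisions: dict[str, CountryDecision] = {}
    for iso3 in sorted(panel.data["iso3"].unique()):
        pop = np.nan
        key = (iso3, criteria.pop_reference_year)
        if key in cells.index:
            pop = float(cells.loc[key, "population"])
        if not np.isfinite(pop):
            decisions[iso3] = CountryDecision(
                iso3, EXCLUDED_SMALL_POP,
                note=f"population missing in {criteria.pop_reference_year}")
            continue
        if pop < criteria.pop_threshold:
            decisions[iso3] = CountryDecision(
                iso3, EXCLUDED_SMALL_POP,
                note=f"population {pop:.0f} < {criteria.pop_threshold:.0f}")
            continue
        missing: list[tuple[str, int]] = []
        for indicator in criteria.required_indicators:
            for year in criteria.anchor_years:
                k = (iso3, year)
                v = float(cells.loc[k, indicator]) if k in cells.index else np.nan
                if not np.isfinite(v):
                    missing.append((indicator, year))
        if missing:
            decisions[iso3] = CountryDecision(
                iso3, EXCLUDED_MISSING, missing=tuple(missing))
        else:
            decisions[iso3] = CountryDecision(iso3, INCLUDED)
    return ExclusionReport(decisions=decisions, criteria=criteria)


# ---------------------------------------------------------------------------
# income grouping


@dataclass
class GroupAssignment:
    """Fixed income-group partition plus derived reporting groups.

    ``base_groups`` partitions the included countries by their start-of-period
    income class; ``reporting_groups`` adds, per focus country, a singleton
    group and the complement group "<base> excluding <iso3>". Groups are
    immutable across analysis years.
    """

    base_groups: dict[str, tuple[str, ...]]
    classification_year: int
    focus_countries: tuple[str, ...] = ()
    reporting_groups: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def members(self, label: str) -> tuple[str, ...]:
        if label in self.reporting_groups:
            return self.reporting_groups[label]
        raise KeyError(f"unknown reporting group {label!r}")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.reporting_groups)

    @property
    def included(self) -> tuple[str, ...]:
        out: set[str] = set()
        for members in self.base_groups.values():
            out.update(members)
        return tuple(sorted(out))

    def group_of(self, iso3: str) -> str:
        for group, members in self.base_groups.items():
            if iso3 in members:
                return group
        raise KeyError(f"{iso3} not in any base group")


def read_classification(path) -> tuple[dict[str, str], int]:
    """Read an iso3 → income-group table (columns iso3, group[, classification_year])."""
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    if not {"iso3", "group"} <= set(df.columns):
        raise ValueError("classification CSV needs columns iso3, group")
    year = 2000
    if "classification_year" in df.columns and len(df):
        year = int(df["classification_year"].iloc[0])
    mapping = dict(zip(df["iso3"], df["group"].str.upper()))
    bad = sorted(set(mapping.values()) - set(VALID_GROUPS))
    if bad:
        raise ValueError(f"unknown income groups in classification: {bad}")
    return mapping, year


def assign_income_groups(
    report: ExclusionReport,
    classification: dict[str, str],
    focus_countries: tuple[str, ...] = (),
    classification_year: int = 2000,
) -> GroupAssignment:
    """Partition the included countries into fixed income groups.

    Every included country must appear in ``classification`` (no silent
    default); countries tagged UNCLASSIFIED form their own group and are kept
    out of the four income-group aggregates. Each focus country must be a
    member of one of the four income groups.
    """
    included = report.included
    missing = [c for c in included if c not in classification]
    if missing:
        raise ValueError(
            f"included countries absent from classification table: {missing}")
    bad = sorted({classification[c] for c in included} - set(VALID_GROUPS))
    if bad:
        raise ValueError(f"unknown income groups: {bad}")

    base: dict[str, tuple[str, ...]] = {}
    for group in VALID_GROUPS:
        members = tuple(sorted(c for c in included if classification[c] == group))
        if members or group in INCOME_GROUPS:
            base[group] = members

    reporting: dict[str, tuple[str, ...]] = {}
    for group in INCOME_GROUPS:
        members = base.get(group, ())
        reporting[group] = members
        for iso3 in focus_countries:
            if classification.get(iso3) != group:
                continue
            if iso3 not in members:
                raise ValueError(
                    f"focus country {iso3} not among included {group} members")
            reporting[f"{group} excluding {iso3}"] = tuple(
                c for c in members if c != iso3)
            reporting[iso3] = (iso3,)
    for iso3 in focus_countries:
        if iso3 not in reporting:
            group = classification.get(iso3, "absent")
            raise ValueError(
                f"focus country {iso3} is not in an income group (got {group!r})")
    if base.get(UNCLASSIFIED):
        reporting[UNCLASSIFIED] = base[UNCLASSIFIED]
    return GroupAssignment(
        base_groups=base,
        classification_year=classification_year,
        focus_countries=tuple(focus_countries),
        reporting_groups=reporting,
    )
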