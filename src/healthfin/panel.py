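"""Country–year health-financing panel: data model, CSV I/O, and validation.

The panel is a long-format table with one row per (iso3, year) holding the
SHA-2011-style financing-source indicators in a single constant-dollar unit
scale (declared once at panel level):

====================  =========================================================
column                meaning
====================  =========================================================
iso3                  3-letter country code
name                  country name (optional)
year                  calendar year
population            persons
gdp                   gross domestic product
gge                   general government expenditure
gghe_d                domestic general government health expenditure
che                   current health expenditure
oop                   out-of-pocket expenditure
ext                   health expenditure from external (donor) sources
vpp                   voluntary prepayment (private)
pvt_other             other domestic private health expenditure
====================  =========================================================

The accounting identity CHE = GGHE-D + EXT + OOP + VPP + PVT-other is checked
by :func:`validate_panel`, never enforced silently. Missing values are empty
CSV cells (the tokens ``N/A``/``NA`` are also accepted on read) and NaN in
memory — never zeros.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: monetary level columns, in canonical order
MONETARY_COLUMNS: tuple[str, ...] = (
    "gdp", "gge", "gghe_d", "che", "oop", "ext", "vpp", "pvt_other",
)
#: components whose sum should reproduce CHE
CHE_COMPONENTS: tuple[str, ...] = ("gghe_d", "ext", "oop", "vpp", "pvt_other")
#: columns a panel CSV must provide
REQUIRED_COLUMNS: tuple[str, ...] = (
    "iso3", "year", "population", "gdp", "gge", "gghe_d", "che", "oop",
)
OPTIONAL_COLUMNS: tuple[str, ...] = ("name", "ext", "vpp", "pvt_other")
#: canonical column order of Panel.data
ALL_COLUMNS: tuple[str, ...] = ("iso3", "name", "year", "population") + MONETARY_COLUMNS
#: tokens read as missing (GHED-style tables print "N/A")
NA_TOKENS: tuple[str, ...] = ("", "N/A", "NA", "n/a", "na")

NUMERIC_COLUMNS: tuple[str, ...] = ("population",) + MONETARY_COLUMNS


class PanelError(ValueError):
    """Raised for malformed panel inputs (unreadable, duplicated, non-numeric)."""


@dataclass
class Panel:
    """In-memory panel: a typed DataFrame plus unit-scale and provenance tags.

    ``data`` always carries the columns of :data:`ALL_COLUMNS` in order, with
    ``iso3``/``name`` as strings, ``year`` as int and everything else as float
    (NaN = missing).
    """

    data: pd.DataFrame
    unit_scale: str = "constant 2010 US$"
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = _canonicalize(self.data)

    @property
    def year_span(self) -> tuple[int, int] | None:
        if self.data.empty:
            return None
        return int(self.data["year"].min()), int(self.data["year"].max())

    @property
    def countries(self) -> tuple[str, ...]:
        return tuple(sorted(self.data["iso3"].unique()))

    def __len__(self) -> int:
        return len(self.data)

    def value(self, iso3: str, year: int, indicator: str) -> float:
        """Single cell lookup; returns NaN when absent or missing."""
        rows = self.data[(self.data["iso3"] == iso3) & (self.data["year"] == year)]
        if rows.empty:
            return float("nan")
        return float(rows.iloc[0][indicator])

    def wide(self, indicator: str) -> pd.DataFrame:
        """Pivot one indicator to a countries × years table."""
        return self.data.pivot(index="iso3", columns="year", values=indicator)

    def copy(self) -> "Panel":
        return replace(self, data=self.data.copy())


def _canonicalize(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    if "name" not in df.columns:
        df["name"] = ""
    for col in MONETARY_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[list(ALL_COLUMNS)]
    df["iso3"] = df["iso3"].astype(str)
    df["name"] = df["name"].fillna("").astype(str)
    df["year"] = df["year"].astype(int)
    for col in NUMERIC_COLUMNS:
        # astype, not to_numeric: the latter parses strings imprecisely
        df[col] = df[col].astype(float)
    dup = df.duplicated(subset=["iso3", "year"], keep=False)
    if dup.any():
        keys = sorted(set(map(tuple, df.loc[dup, ["iso3", "year"]].values)))
        raise PanelError(f"duplicate (iso3, year) pairs: {keys}")
    return df.reset_index(drop=True)


def read_panel(
    path,
    column_map: dict[str, str] | None = None,
    unit_scale: str = "constant 2010 US$",
    provenance: str = "",
) -> Panel:
    """Read a long-format panel CSV into a :class:`Panel`.

    ``column_map`` maps CSV header names to canonical names for files using a
    different dialect (e.g. ``{"country_code": "iso3"}``). Blank cells and
    N/A tokens become missing values, never zeros; row order is preserved.
    """
    try:
        raw = pd.read_csv(
            path, dtype=str, keep_default_na=False, na_values=list(NA_TOKENS),
            skipinitialspace=True,
        )
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise PanelError(f"cannot read panel CSV {path!r}: {exc}") from exc
    if column_map:
        raw = raw.rename(columns=column_map)
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise PanelError(f"panel CSV {path!r} lacks required columns: {missing}")
    for col in NUMERIC_COLUMNS + ("year",):
        if col not in raw.columns:
            continue
        try:
            # astype, not to_numeric: the latter parses strings imprecisely
            raw[col] = raw[col].astype(float)
        except (TypeError, ValueError) as exc:
            raise PanelError(f"non-numeric value in column {col!r}: {exc}") from exc
    if raw["year"].isna().any():
        raise PanelError("missing year in panel CSV")
    return Panel(raw, unit_scale=unit_scale, provenance=provenance or str(path))


def write_panel(panel: Panel, path) -> None:
    """Write the panel back to CSV; missing values become empty cells.

    Values are written at full float precision so a write→read round trip
    reproduces every present value exactly.
    """
    df = panel.data.copy()
    df["year"] = df["year"].astype(int)
    # shortest round-trip float repr (pandas' default formatting drops digits)
    df.to_csv(path, index=False, na_rep="",
              float_format=lambda v: repr(float(v)))


# ---------------------------------------------------------------------------
# validation


@dataclass(frozen=True)
class Finding:
    iso3: str
    year: int
    rule: str
    severity: str  # "warning" | "error"
    detail: str


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_panel`: per-record findings plus counts."""

    findings: list[Finding] = field(default_factory=list)
    n_records: int = 0

    @property
    def errors(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "error"]

    @property
    def warnings(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "warning"]

    @property
    def ok(self) -> bool:
        """True iff the panel is accepted for analysis (zero errors)."""
        return not self.errors

    def counts_by_rule(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for f in self.findings:
            out[f.rule] = out.get(f.rule, 0) + 1
        return dict(sorted(out.items()))

    def to_json(self) -> str:
        payload = {
            "n_records": self.n_records,
            "n_errors": len(self.errors),
            "n_warnings": len(self.warnings),
            "counts_by_rule": self.counts_by_rule(),
            "findings": [
                {"iso3": f.iso3, "year": f.year, "rule": f.rule,
                 "severity": f.severity, "detail": f.detail}
                for f in self.findings
            ],
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def to_text(self) -> str:
        lines = [
            f"validated {self.n_records} records: "
            f"{len(self.errors)} errors, {len(self.warnings)} warnings"
        ]
        for f in self.findings:
            lines.append(f"  [{f.severity}] {f.iso3} {f.year} {f.rule}: {f.detail}")
        return "\n".join(lines)


def validate_panel(
    panel: Panel,
    identity_tolerance: float = 0.01,
    hard_tolerance: float = 0.05,
    gge_gdp_cap: float | None = None,
) -> ValidationReport:
    """Check every record against the panel invariants; never mutates.

    Rules (rule ids in parentheses):

    * present monetary values must be ≥ 0 (``negative_value``, error);
    * population must be > 0 when present (``nonpositive_population``, error);
    * when GGHE-D, EXT, OOP, VPP and other-private are all present, the CHE
      additivity residual |CHE − Σ components|/CHE must stay within
      ``identity_tolerance`` (``che_identity``, warning) and within
      ``hard_tolerance`` (``che_identity``, error);
    * OOP ≤ CHE and GGHE-D ≤ GGE (``oop_exceeds_che`` / ``gghe_exceeds_gge``,
      warnings — GHED-style data occasionally breach these at the margin);
    * GGE ≤ GDP × ``gge_gdp_cap`` when a cap is given (``gge_exceeds_cap``,
      warning).

    The defaults (1% warn / 5% error) reflect that published expenditure
    tables carry rounding slack of unknown size.
    """
    if panel.data.empty:
        raise PanelError("cannot validate an empty panel")
    if not 0 < identity_tolerance < 1:
        raise ValueError("identity_tolerance must be in (0, 1)")
    findings: list[Finding] = []
    for row in panel.data.itertuples(index=False):
        iso3, year = row.iso3, int(row.year)

        def add(rule: str, severity: str, detail: str) -> None:
            findings.append(Finding(iso3, year, rule, severity, detail))

        for col in MONETARY_COLUMNS:
            v = getattr(row, col)
            if np.isfinite(v) and v < 0:
                add("negative_value", "error", f"{col} = {v}")
        if np.isfinite(row.population) and row.population <= 0:
            add("nonpositive_population", "error", f"population = {row.population}")
        comps = [getattr(row, c) for c in CHE_COMPONENTS]
        if np.isfinite(row.che) and row.che > 0 and all(np.isfinite(c) for c in comps):
            rel = abs(row.che - sum(comps)) / row.che
            if rel > hard_tolerance:
                add("che_identity", "error",
                    f"CHE residual {rel:.4%} exceeds hard tolerance")
            elif rel > identity_tolerance:
                add("che_identity", "warning", f"CHE residual {rel:.4%}")
        if np.isfinite(row.oop) and np.isfinite(row.che) and row.oop > row.che:
            add("oop_exceeds_che", "warning", f"oop {row.oop} > che {row.che}")
        if np.isfinite(row.gghe_d) and np.isfinite(row.gge) and row.gghe_d > row.gge:
            add("gghe_exceeds_gge", "warning", f"gghe_d {row.gghe_d} > gge {row.gge}")
        if (gge_gdp_cap is not None and np.isfinite(row.gge)
                and np.isfinite(row.gdp) and row.gge > row.gdp * gge_gdp_cap):
            add("gge_exceeds_cap", "warning",
                f"gge {row.gge} > {gge_gdp_cap} × gdp {row.gdp}")
    return ValidationReport(findings=findings, n_records=len(panel.data))
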