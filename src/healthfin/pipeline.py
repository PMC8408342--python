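"""Single-command pipeline: validate → filter → classify → aggregate →
growth → decompose → benchmark/outliers, with a reproducible output bundle.

The bundle mirrors the standard presentation of group-level health-financing
analyses: a CHE-composition table, a per-capita level/percent-change table,
annualized-growth tables for levels and for ratios/per-capita values, a
decomposition table (g, y, e, h and driver shares), benchmark and outlier
reports, an attrition log, and a verbatim echo of the run configuration.

Output is deterministic: identical inputs and configuration produce a
byte-identical bundle (fixed column order, fixed float formatting, no wall
clock in any file). Progress timestamps go to the ``healthfin`` logger only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import aggregate as agg
from .benchmarks import (GGHE_D_PLUS_EXT, OutlierReport, PercentileRule,
                         benchmark_flags, benchmarks_to_frame, flag_outliers)
from .cohort import (ExclusionReport, GroupAssignment, InclusionCriteria,
                     apply_inclusion_filters, assign_income_groups,
                     read_classification)
from .decompose import decompose_gghed
from .growth import annualized_growth, percent_change, round_half_away
from .panel import Panel, ValidationReport, read_panel, validate_panel

logger = logging.getLogger("healthfin")

FLOAT_FORMAT = "%.10g"

LEVEL_INDICATORS = ("population", "gdp", "gge", "che", "oop", "gghe_d")
RATIO_SPECS = (
    ("gghe_d", "gdp"), ("gghe_d", "gge"), ("gghe_d", "che"), ("oop", "che"),
    ("gdp", "population"), ("gge", "population"),
    ("gghe_d", "population"), ("che", "population"),
)
PER_CAPITA_INDICATORS = ("che", "gghe_d", "ext", "oop", "vpp", "pvt_other")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run depends on; echoed verbatim into the bundle."""

    panel_path: str = ""
    classification_path: str = ""
    out_dir: str = ""
    base_year: int = 2000
    end_year: int = 2015
    min_population: float = 600_000.0
    pop_reference_year: int = 2015
    required_indicators: tuple[str, ...] = ("gdp", "gge", "gghe_d", "che", "oop")
    focus_countries: tuple[str, ...] = ()
    weighting_modes: tuple[str, ...] = ("aggregate", "country_weighted")
    abuja_threshold: float = 0.15
    gdp_threshold: float = 0.05
    numerator_variant: str = GGHE_D_PLUS_EXT
    outlier_lower_pct: float = 1.0
    outlier_upper_pct: float = 99.0
    identity_tolerance: float = 0.01
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True, default=list)

    def criteria(self) -> InclusionCriteria:
        return InclusionCriteria(
            pop_threshold=self.min_population,
            pop_reference_year=self.pop_reference_year,
            required_indicators=tuple(self.required_indicators),
            anchor_years=(self.base_year, self.end_year),
        )


@dataclass
class ReportBundle:
    """All pipeline outputs, in memory; `write` lays them out as CSV/JSON."""

    config: RunConfig
    validation: ValidationReport
    exclusions: ExclusionReport
    assignment: GroupAssignment
    composition: pd.DataFrame
    per_capita: pd.DataFrame
    growth_levels: pd.DataFrame
    growth_ratios: pd.DataFrame
    decomposition: pd.DataFrame
    benchmarks: pd.DataFrame
    outliers: OutlierReport
    weighting_comparison: pd.DataFrame
    log_lines: list[str] = field(default_factory=list)

    def write(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.json").write_text(self.config.to_json() + "\n")
        (out / "validation.json").write_text(self.validation.to_json() + "\n")
        (out / "exclusions.json").write_text(self.exclusions.to_json() + "\n")
        self.exclusions.to_frame().to_csv(out / "exclusions.csv", index=False)
        for name, df in (
            ("composition.csv", self.composition),
            ("per_capita.csv", self.per_capita),
            ("growth_levels.csv", self.growth_levels),
            ("growth_ratios.csv", self.growth_ratios),
            ("decomposition.csv", self.decomposition),
            ("benchmarks.csv", self.benchmarks),
            ("weighting_comparison.csv", self.weighting_comparison),
            ("outliers.csv", self.outliers.to_frame()),
        ):
            df.to_csv(out / name, index=False, float_format=FLOAT_FORMAT)
        (out / "run_log.txt").write_text("\n".join(self.log_lines) + "\n")
        return out


def _income_reporting_labels(assignment: GroupAssignment) -> tuple[str, ...]:
    """Reporting groups for the output tables (unclassified countries are kept
    out of the four income-group aggregates; empty groups are skipped)."""
    return tuple(lbl for lbl in assignment.labels
                 if lbl != "UNCLASSIFIED" and assignment.members(lbl))


def build_composition_table(
    panel: Panel, assignment: GroupAssignment, years: tuple[int, ...]
) -> pd.DataFrame:
    rows = []
    for label in _income_reporting_labels(assignment):
        for year in years:
            shares = agg.composition_shares(panel, assignment, label, year)
            for comp, share in shares.shares.items():
                rows.append({
                    "group": label, "year": year, "component": comp,
                    "share": share,
                    "share_pct": int(round_half_away(share * 100.0, 0)),
                    "component_missing_for_some": comp in shares.missing_components,
                    "n_countries": shares.n_countries,
                })
    return pd.DataFrame(rows)


def build_per_capita_table(
    panel: Panel, assignment: GroupAssignment, base_year: int, end_year: int
) -> pd.DataFrame:
    rows = []
    for label in _income_reporting_labels(assignment):
        for indicator in PER_CAPITA_INDICATORS:
            try:
                v0 = agg.per_capita(panel, assignment, label, indicator, base_year)
                v1 = agg.per_capita(panel, assignment, label, indicator, end_year)
            except ValueError:
                continue  # component absent for the whole group
            row = {
                "group": label, "indicator": f"{indicator}_per_capita",
                "value_base": v0.value, "value_end": v1.value,
                "n_countries": min(v0.n_countries, v1.n_countries),
            }
            if v0.value > 0:
                pct = percent_change(v0.value, v1.value)
                row["pct_change"] = pct
                row["pct_change_1dp"] = round_half_away(pct, 1)
            else:
                row["pct_change"] = float("nan")
                row["pct_change_1dp"] = float("nan")
            rows.append(row)
    cols = ["group", "indicator", "value_base", "value_end",
            "pct_change", "pct_change_1dp", "n_countries"]
    return pd.DataFrame(rows, columns=cols)


def build_growth_tables(
    panel: Panel, assignment: GroupAssignment, base_year: int, end_year: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Annualized growth of level aggregates, and of ratios/per-capita values."""
    level_rows, ratio_rows = [], []
    for label in _income_reporting_labels(assignment):
        n = len(assignment.members(label))
        lrow: dict = {"group": label, "n_countries": n}
        for indicator in LEVEL_INDICATORS:
            c0 = agg.aggregate_level(panel, assignment, label, indicator, base_year)
            c1 = agg.aggregate_level(panel, assignment, label, indicator, end_year)
            lrow[indicator] = round_half_away(
                annualized_growth(c0.value, c1.value, base_year, end_year), 1)
        level_rows.append(lrow)
        rrow: dict = {"group": label, "n_countries": n}
        for num, den in RATIO_SPECS:
            r0 = agg.aggregate_ratio(panel, assignment, label, num, den, base_year)
            r1 = agg.aggregate_ratio(panel, assignment, label, num, den, end_year)
            key = f"{num}_per_capita" if den == "population" else f"{num}/{den}"
            rrow[key] = round_half_away(
                annualized_growth(r0.value, r1.value, base_year, end_year), 1)
        ratio_rows.append(rrow)
    return pd.DataFrame(level_rows), pd.DataFrame(ratio_rows)


def build_decomposition_table(
    panel: Panel, assignment: GroupAssignment, base_year: int, end_year: int
) -> pd.DataFrame:
    """Group-level decomposition of GGHE-D growth from aggregate levels."""
    rows = []
    for label in _income_reporting_labels(assignment):
        levels = {}
        for indicator in ("gdp", "gge", "gghe_d"):
            for year in (base_year, end_year):
                cell = agg.aggregate_level(panel, assignment, label, indicator, year)
                levels[(indicator, year)] = cell.value
        res = decompose_gghed(
            levels[("gdp", base_year)], levels[("gdp", end_year)],
            levels[("gge", base_year)], levels[("gge", end_year)],
            levels[("gghe_d", base_year)], levels[("gghe_d", end_year)],
        )
        rows.append({
            "group": label,
            "g_pct": round_half_away(res.g * 100, 1),
            "y_pct": round_half_away(res.y * 100, 1),
            "e_pct": round_half_away(res.e * 100, 1),
            "h_pct": round_half_away(res.h * 100, 1),
            "share_y": res.share_y, "share_e": res.share_e, "share_h": res.share_h,
            "share_y_pct": round_half_away(res.share_y * 100, 1),
            "share_e_pct": round_half_away(res.share_e * 100, 1),
            "share_h_pct": round_half_away(res.share_h * 100, 1),
            "residual_nats": res.residual,
        })
    return pd.DataFrame(rows)


def build_weighting_comparison(
    panel: Panel, assignment: GroupAssignment, years: tuple[int, ...]
) -> pd.DataFrame:
    rows = []
    for label in _income_reporting_labels(assignment):
        for year in years:
            for num, den in (("che", "population"), ("gghe_d", "population"),
                             ("oop", "che"), ("gghe_d", "che")):
                d = agg.weighting_divergence(panel, assignment, label, num, den, year)
                rows.append({"group": label, "year": year,
                             "indicator": f"{num}/{den}", **d})
    return pd.DataFrame(rows)


def run_pipeline(
    config: RunConfig,
    panel: Panel | None = None,
    classification: dict[str, str] | None = None,
) -> ReportBundle:
    """Execute the full analysis and return the bundle (not yet written).

    ``panel`` and ``classification`` may be passed directly for library use;
    otherwise they are read from the paths in ``config``. Any stage failure
    raises :class:`PipelineError` naming the stage; nothing is written until
    every stage has succeeded, so a failed run leaves no partial bundle. If
    ``config.out_dir`` is set the bundle is also written there.
    """
    log: list[str] = []
    current_stage = "read"

    def stage(name: str):
        nonlocal current_stage
        current_stage = name
        logger.info("stage %s", name)
        log.append(f"stage: {name}")

    try:
        stage("read")
        if panel is None:
            panel = read_panel(config.panel_path)
        if classification is None:
            classification, _ = read_classification(config.classification_path)
        log.append(f"  records: {len(panel)}; countries: {len(panel.countries)}")

        stage("validate")
        validation = validate_panel(panel, identity_tolerance=config.identity_tolerance)
        log.append(f"  errors: {len(validation.errors)}; "
                   f"warnings: {len(validation.warnings)}")
        if not validation.ok:
            raise ValueError(
                f"panel rejected: {len(validation.errors)} validation errors")

        stage("filter")
        exclusions = apply_inclusion_filters(panel, config.criteria())
        counts = exclusions.counts()
        total = len(panel.countries)
        after_pop = total - counts["excluded_small_population"]
        log.append(f"  countries: {total} -> {after_pop} after population "
                   f"filter -> {counts['included']} after completeness filter")

        stage("classify")
        assignment = assign_income_groups(
            exclusions, classification, tuple(config.focus_countries))
        for label in assignment.labels:
            log.append(f"  group {label}: {len(assignment.members(label))} countries")

        years = (config.base_year, config.end_year)
        stage("aggregate")
        composition = build_composition_table(panel, assignment, years)
        per_capita = build_per_capita_table(
            panel, assignment, config.base_year, config.end_year)
        log.append(f"  composition cells: {len(composition)}; "
                   f"per-capita rows: {len(per_capita)}")

        stage("growth")
        growth_levels, growth_ratios = build_growth_tables(
            panel, assignment, config.base_year, config.end_year)
        log.append(f"  growth rows: {len(growth_levels)} + {len(growth_ratios)}")

        stage("decompose")
        decomposition = build_decomposition_table(
            panel, assignment, config.base_year, config.end_year)
        log.append(f"  decomposition rows: {len(decomposition)}")

        stage("benchmark")
        bench = benchmarks_to_frame(benchmark_flags(
            panel, assignment, years,
            numerator_variant=config.numerator_variant,
            abuja_threshold=config.abuja_threshold,
            gdp_threshold=config.gdp_threshold))
        log.append(f"  benchmark rows: {len(bench)}")

        stage("outliers")
        rule = PercentileRule(config.outlier_lower_pct, config.outlier_upper_pct)
        try:
            outliers = flag_outliers(
                panel, assignment.included, "gghe_d", "gdp", years, rule)
        except ValueError as exc:
            # too few countries for the percentile rule: report empty, note why
            outliers = OutlierReport((), "gghe_d/gdp", rule.rule_id, 0)
            log.append(f"  outlier rule skipped: {exc}")
        log.append(f"  outliers flagged: {len(outliers.flagged)}")

        stage("weighting comparison")
        weighting = build_weighting_comparison(panel, assignment, years)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(current_stage, exc) from exc

    bundle = ReportBundle(
        config=config, validation=validation, exclusions=exclusions,
        assignment=assignment, composition=composition, per_capita=per_capita,
        growth_levels=growth_levels, growth_ratios=growth_ratios,
        decomposition=decomposition, benchmarks=bench, outliers=outliers,
        weighting_comparison=weighting, log_lines=log,
    )
    if config.out_dir:
        bundle.write(config.out_dir)
    return bundle
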