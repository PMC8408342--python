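"""Synthetic GHED-like panel generator with recorded ground truth.

Every pipeline stage is testable without the (non-redistributable) source
database because this module builds country–year panels whose generative
parameters are known exactly:

* each country gets base-year levels drawn from group-specific ranges
  (population, GDP per capita, GGE/GDP, GGHE-D/GGE, and CHE composition
  shares);
* trajectories are multiplicative: a group's total-period growth parameters
  (y for GDP, e for GGE/GDP, h for GGHE-D/GGE, plus population growth) are
  applied as constant per-year compound factors, so the endpoint growth of
  every generated series equals the configured parameter exactly, whatever
  the intermediate years show;
* CHE is constructed additively from its financing-source components, so the
  accounting identity holds to machine precision before any noise;
* optional lognormal multiplicative noise is applied per level, after which
  CHE is re-summed from the noised components (additivity survives noise);
* optional missingness blanks cells independently per (indicator, year)
  rate, with the mask returned.

A fixed seed fully determines the output. Synthetic ISO3 codes use reserved
letter ranges (Z-prefix members, X-prefix focus countries) so they cannot
collide with real country codes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .panel import Panel

YEARS_DEFAULT = (2000, 2015)

_COMPONENT_SHARES = ("oop_che", "ext_che", "vpp_che", "other_che")


@dataclass(frozen=True)
class GroupSpec:
    """Generative parameters for one income group.

    Ranges are uniform sampling intervals for base-year (start-of-period)
    values; growth parameters are total-period fractional changes (e.g.
    ``growth_y = 1.5`` means GDP rises 150% over the whole window).
    """

    n_countries: int
    pop_range: tuple[float, float]          # persons
    gdp_pc_range: tuple[float, float]       # US$ per person
    gge_gdp_range: tuple[float, float]      # fraction of GDP
    gghe_gge_range: tuple[float, float]     # fraction of GGE
    oop_che_range: tuple[float, float]      # fraction of CHE
    ext_che_range: tuple[float, float]
    vpp_che_range: tuple[float, float]
    other_che_range: tuple[float, float]
    growth_y: float
    growth_e: float
    growth_h: float
    pop_growth: float


@dataclass(frozen=True)
class FocusSpec:
    """A single dominant country (its own growth path, fixed base levels)."""

    iso3: str
    name: str
    group: str
    population: float
    gdp_pc: float
    gge_gdp: float
    gghe_gge: float
    oop_che: float
    ext_che: float
    vpp_che: float
    other_che: float
    growth_y: float
    growth_e: float
    growth_h: float
    pop_growth: float


@dataclass(frozen=True)
class SyntheticConfig:
    groups: dict[str, GroupSpec]
    focus: tuple[FocusSpec, ...] = ()
    base_year: int = YEARS_DEFAULT[0]
    end_year: int = YEARS_DEFAULT[1]
    noise_sigma: float = 0.0
    #: {(indicator, year): blanking probability}
    missingness: dict[tuple[str, int], float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.end_year <= self.base_year:
            raise ValueError("end_year must exceed base_year")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        for rate in self.missingness.values():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"missingness rate {rate} outside [0, 1]")
        for label, spec in self.groups.items():
            for lo, hi in (spec.pop_range, spec.gdp_pc_range, spec.gge_gdp_range,
                           spec.gghe_gge_range):
                if not 0 < lo <= hi:
                    raise ValueError(f"{label}: base range [{lo}, {hi}] invalid")
            max_sum = sum(getattr(spec, s + "_range")[1] for s in _COMPONENT_SHARES)
            if max_sum >= 1.0:
                raise ValueError(
                    f"{label}: CHE component share ranges can sum to {max_sum:.3f} "
                    "≥ 1; GGHE-D share of CHE would be non-positive")
            for rate in (spec.growth_y, spec.growth_e, spec.growth_h,
                         spec.pop_growth):
                if 1.0 + rate <= 0.0:
                    raise ValueError(f"{label}: growth rate {rate} ≤ −100%")
        for f in self.focus:
            if f.group not in self.groups:
                raise ValueError(f"focus country {f.iso3} group {f.group!r} unknown")
            if f.oop_che + f.ext_che + f.vpp_che + f.other_che >= 1.0:
                raise ValueError(f"focus country {f.iso3}: shares sum ≥ 1")

    def to_json(self) -> str:
        payload = asdict(self)
        payload["missingness"] = [
            {"indicator": k[0], "year": k[1], "rate": v}
            for k, v in sorted(self.missingness.items())
        ]
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticConfig":
        raw = json.loads(text)
        raw["groups"] = {
            k: GroupSpec(**{f: tuple(v) if isinstance(v, list) else v
                            for f, v in g.items()})
            for k, g in raw["groups"].items()
        }
        raw["focus"] = tuple(FocusSpec(**f) for f in raw.get("focus", ()))
        raw["missingness"] = {
            (m["indicator"], int(m["year"])): float(m["rate"])
            for m in raw.get("missingness", [])
        }
        return cls(**raw)


@dataclass
class GroundTruth:
    """Exact generative parameters behind a synthetic panel."""

    group_rates: dict[str, dict[str, float]]    # label → {y, e, h, g, pop_growth}
    country_rates: dict[str, dict[str, float]]  # iso3 → same keys
    classification: dict[str, str]              # iso3 → income group
    focus_countries: tuple[str, ...]
    missing_mask: tuple[tuple[str, int, str], ...] = ()  # (iso3, year, indicator)


def _country_rows(
    iso3: str, name: str, base: dict[str, float], growth: dict[str, float],
    years: range, base_year: int, period: int,
) -> list[dict[str, float | str | int]]:
    rows = []
    s_sum = base["oop_che"] + base["ext_che"] + base["vpp_che"] + base["other_che"]
    s_gghe = 1.0 - s_sum  # GGHE-D share of CHE, fixed over time per country
    for year in years:
        frac = (year - base_year) / period
        pop = base["population"] * (1.0 + growth["pop_growth"]) ** frac
        gdp = base["gdp"] * (1.0 + growth["y"]) ** frac
        gge = gdp * base["gge_gdp"] * (1.0 + growth["e"]) ** frac
        gghe = gge * base["gghe_gge"] * (1.0 + growth["h"]) ** frac
        che = gghe / s_gghe
        oop = base["oop_che"] * che
        ext = base["ext_che"] * che
        vpp = base["vpp_che"] * che
        other = base["other_che"] * che
        rows.append({
            "iso3": iso3, "name": name, "year": year,
            "population": pop, "gdp": gdp, "gge": gge, "gghe_d": gghe,
            "che": gghe + ext + oop + vpp + other,
            "oop": oop, "ext": ext, "vpp": vpp, "pvt_other": other,
        })
    return rows


def generate_panel(config: SyntheticConfig) -> tuple[Panel, GroundTruth]:
    """Build a panel and its ground truth from a :class:`SyntheticConfig`.

    Deterministic for a fixed seed. In the noise-free case the generated
    panel passes CHE-additivity validation at 1e-9 and group-aggregate
    decomposition recovers the configured (y, e, h) exactly, because every
    member of a group shares the group's compound factors.
    """
    rng = np.random.default_rng(config.seed)
    period = config.end_year - config.base_year
    years = range(config.base_year, config.end_year + 1)
    rows: list[dict] = []
    classification: dict[str, str] = {}
    group_rates: dict[str, dict[str, float]] = {}
    country_rates: dict[str, dict[str, float]] = {}
    counter = 0
    for label in sorted(config.groups):
        spec = config.groups[label]
        growth = {
            "y": spec.growth_y, "e": spec.growth_e, "h": spec.growth_h,
            "g": (1 + spec.growth_y) * (1 + spec.growth_e) * (1 + spec.growth_h) - 1,
            "pop_growth": spec.pop_growth,
        }
        group_rates[label] = growth
        for _ in range(spec.n_countries):
            iso3 = "Z" + chr(ord("A") + counter // 26) + chr(ord("A") + counter % 26)
            counter += 1
            pop = rng.uniform(*spec.pop_range)
            base = {
                "population": pop,
                "gdp": pop * rng.uniform(*spec.gdp_pc_range),
                "gge_gdp": rng.uniform(*spec.gge_gdp_range),
                "gghe_gge": rng.uniform(*spec.gghe_gge_range),
                "oop_che": rng.uniform(*spec.oop_che_range),
                "ext_che": rng.uniform(*spec.ext_che_range),
                "vpp_che": rng.uniform(*spec.vpp_che_range),
                "other_che": rng.uniform(*spec.other_che_range),
            }
            rows.extend(_country_rows(iso3, f"Synthland {iso3}", base, growth,
                                      years, config.base_year, period))
            classification[iso3] = label
            country_rates[iso3] = dict(growth)
    for f in config.focus:
        growth = {
            "y": f.growth_y, "e": f.growth_e, "h": f.growth_h,
            "g": (1 + f.growth_y) * (1 + f.growth_e) * (1 + f.growth_h) - 1,
            "pop_growth": f.pop_growth,
        }
        base = {
            "population": f.population, "gdp": f.population * f.gdp_pc,
            "gge_gdp": f.gge_gdp, "gghe_gge": f.gghe_gge,
            "oop_che": f.oop_che, "ext_che": f.ext_che,
            "vpp_che": f.vpp_che, "other_che": f.other_che,
        }
        rows.extend(_country_rows(f.iso3, f.name, base, growth,
                                  years, config.base_year, period))
        classification[f.iso3] = f.group
        country_rates[f.iso3] = dict(growth)

    df = pd.DataFrame(rows)
    if config.noise_sigma > 0:
        noise_cols = ["population", "gdp", "gge", "gghe_d", "ext", "oop",
                      "vpp", "pvt_other"]
        factors = rng.lognormal(0.0, config.noise_sigma,
                                size=(len(df), len(noise_cols)))
        df[noise_cols] = df[noise_cols].to_numpy() * factors
        # CHE re-summed from the noised components: additivity survives noise
        df["che"] = df[["gghe_d", "ext", "oop", "vpp", "pvt_other"]].sum(axis=1)
    panel = Panel(df, unit_scale="constant 2010 US$",
                  provenance=f"synthetic panel, seed={config.seed}")
    truth = GroundTruth(
        group_rates=group_rates, country_rates=country_rates,
        classification=classification,
        focus_countries=tuple(f.iso3 for f in config.focus),
    )
    if config.missingness:
        panel, mask = inject_missingness(
            panel, config.missingness, seed=config.seed + 1)
        truth.missing_mask = mask
    return panel, truth


def inject_missingness(
    panel: Panel, rates: dict[tuple[str, int], float], seed: int
) -> tuple[Panel, tuple[tuple[str, int, str], ...]]:
    """Blank cells independently at the given per-(indicator, year) rates.

    Returns a new panel plus the mask of blanked (iso3, year, indicator)
    cells. Blanking anchor-year cells of required indicators makes the
    affected countries fail the downstream inclusion filter, exactly as
    real-world gaps would.
    """
    for (indicator, year), rate in rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"rate {rate} for ({indicator}, {year}) outside [0, 1]")
        if indicator not in panel.data.columns:
            raise KeyError(f"unknown indicator {indicator!r}")
    rng = np.random.default_rng(seed)
    df = panel.data.copy()
    mask: list[tuple[str, int, str]] = []
    for (indicator, year), rate in sorted(rates.items()):
        if rate == 0.0:
            continue
        idx = df.index[df["year"] == year]
        hit = idx[rng.random(len(idx)) < rate]
        df.loc[hit, indicator] = np.nan
        mask.extend((df.loc[i, "iso3"], year, indicator) for i in hit)
    out = replace(panel, data=df)
    return out, tuple(sorted(mask))


def _total(annual_pct: float, years: int = 15) -> float:
    """Total-period fractional change implied by an annualized percent rate."""
    return (1.0 + annual_pct / 100.0) ** years - 1.0


def default_config(seed: int = 0, noise_sigma: float = 0.0,
                   missingness: dict[tuple[str, int], float] | None = None
                   ) -> SyntheticConfig:
    """Standard fixture: four income groups × 15 countries plus two dominant
    focus countries (one LIC-resident, one LMIC-resident), 2000–2015.

    Group growth parameters are total-period changes implied by realistic
    annualized rates for the era (LIC/LMIC rapid growth, UMIC moderate, HIC
    slow growth with high baseline government spending); the focus countries
    are very large fast growers so that group aggregates visibly diverge
    from country-weighted averages.
    """
    groups = {
        "LIC": GroupSpec(
            n_countries=15, pop_range=(2e6, 5e7), gdp_pc_range=(250, 900),
            gge_gdp_range=(0.15, 0.25), gghe_gge_range=(0.03, 0.08),
            oop_che_range=(0.50, 0.62), ext_che_range=(0.04, 0.10),
            vpp_che_range=(0.01, 0.04), other_che_range=(0.03, 0.08),
            growth_y=_total(5.5), growth_e=_total(0.1), growth_h=_total(1.4),
            pop_growth=_total(2.1)),
        "LMIC": GroupSpec(
            n_countries=15, pop_range=(2e6, 8e7), gdp_pc_range=(800, 3500),
            gge_gdp_range=(0.18, 0.30), gghe_gge_range=(0.05, 0.10),
            oop_che_range=(0.40, 0.55), ext_che_range=(0.005, 0.02),
            vpp_che_range=(0.03, 0.08), other_che_range=(0.05, 0.12),
            growth_y=_total(4.1), growth_e=_total(0.9), growth_h=_total(0.4),
            pop_growth=_total(1.1)),
        "UMIC": GroupSpec(
            n_countries=15, pop_range=(1e6, 5e7), gdp_pc_range=(3000, 10000),
            gge_gdp_range=(0.20, 0.35), gghe_gge_range=(0.06, 0.12),
            oop_che_range=(0.25, 0.40), ext_che_range=(0.002, 0.01),
            vpp_che_range=(0.05, 0.15), other_che_range=(0.10, 0.30),
            growth_y=_total(3.3), growth_e=_total(1.5), growth_h=_total(0.5),
            pop_growth=_total(1.2)),
        "HIC": GroupSpec(
            n_countries=15, pop_range=(1e6, 8e7), gdp_pc_range=(20000, 50000),
            gge_gdp_range=(0.30, 0.45), gghe_gge_range=(0.10, 0.18),
            oop_che_range=(0.12, 0.20), ext_che_range=(0.0001, 0.001),
            vpp_che_range=(0.04, 0.10), other_che_range=(0.25, 0.40),
            growth_y=_total(1.5), growth_e=_total(0.4), growth_h=_total(1.5),
            pop_growth=_total(0.7)),
    }
    focus = (
        FocusSpec(iso3="XIN", name="Bigland", group="LIC",
                  population=1.05e9, gdp_pc=450,
                  gge_gdp=0.23, gghe_gge=0.045,
                  oop_che=0.70, ext_che=0.025, vpp_che=0.01, other_che=0.05,
                  growth_y=_total(7.4), growth_e=_total(0.85),
                  growth_h=_total(0.1), pop_growth=_total(1.5)),
        FocusSpec(iso3="XCN", name="Growland", group="LMIC",
                  population=1.27e9, gdp_pc=950,
                  gge_gdp=0.16, gghe_gge=0.11,
                  oop_che=0.60, ext_che=0.002, vpp_che=0.05, other_che=0.15,
                  growth_y=_total(9.7), growth_e=_total(4.4),
                  growth_h=_total(3.3), pop_growth=_total(0.6)),
    )
    return SyntheticConfig(groups=groups, focus=focus, seed=seed,
                           noise_sigma=noise_sigma,
                           missingness=missingness or {})
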