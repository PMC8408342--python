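# Methods

## The model

The package analyses a long-format country–year panel of health-financing
indicators expressed in a single constant-dollar unit scale. Two accounting
identities organise everything:

1. **Financing-source additivity.** Current health expenditure is the sum
   of its financing sources: `CHE = GGHE-D + EXT + OOP + VPP + PVT-other`
   (government-domestic, external, out-of-pocket, voluntary prepayment,
   other private). Validation checks this identity per record; it is never
   silently repaired.
2. **The multiplicative factorisation of government health spending.**
   `GGHE-D = GDP × (GGE/GDP) × (GGHE-D/GGE)`. Taking endpoint growth rates
   of each factor, `1+g = (1+y)(1+e)(1+h)` and hence
   `ln(1+g) = ln(1+y)+ln(1+e)+ln(1+h)`. Driver shares are log terms over
   `ln(1+g)`.

The decomposition has two entry points with deliberately different
numerical behaviour. `decompose_gghed` takes six levels and derives the
rates from them, so the log identity holds to machine precision — this is
the analysis route. `decompose_from_rates` takes pre-computed (possibly
independently rounded) rates and reports the identity residual in nats —
this is the route for reproducing published tables, where residuals of a
few 10⁻³ nats are normal because published rates are rounded after being
computed from unrounded data. The residual is always reported, never
redistributed into a component.

Shares are stored as fractions and only rendered as percent (one decimal,
half away from zero) at presentation. When GGHE-D is unchanged
(`ln(1+g)=0`) shares are undefined and flagged rather than forced. Growth
rates at or below −100% are rejected as mathematically undefined in log
space.

## Aggregation convention

Group values are *expenditure-weighted*: levels are sums over members with
present values, ratios are `Σ numerator / Σ denominator`. This generalises
to the group's population — a very large economy dominates its group, which
is the point of the convention. The unweighted mean of country ratios
(each country counted once) is computed alongside for methodology
comparison, never mixed into the aggregates.

Missing data rules, since the upstream database leaves the convention
unstated:

- ratios use **complete pairs**: a member missing either side is dropped
  from both sums, keeping the numerator and denominator over an identical
  country set;
- CHE composition shares treat a missing component as a zero contribution
  and flag the component, because published composition tables still report
  groups containing countries with a missing external-financing cell;
- every aggregate cell records `n_countries`, the members actually
  contributing.

## Cohort and grouping

Inclusion defaults: population ≥ 600,000 persons in 2015 (the boundary
value is included — the exclusion rule is "less than"), and the five core
indicators (GDP, GGE, GGHE-D, CHE, OOP) present in both anchor years 2000
and 2015. GGE is required even though it is only needed by the
decomposition, so that every reported group has a decomposable aggregate.
The population check runs first; a country failing both criteria is
reported once, under small population, and a country with population
missing in the reference year is treated as failing the population
criterion (with a note), since its size cannot be established.

Income groups are an *input* table (ISO3 → LIC/LMIC/UMIC/HIC/UNCLASSIFIED
at a stated classification year), not computed: GNI per capita is not part
of the data model, and start-of-period grouping exists precisely to use a
historical classification. Groups are held fixed across all analysis
years. Unclassified countries form their own reporting group and stay out
of the four income-group aggregates. Focus countries (dominant economies)
get a singleton group and a complement group ("LIC excluding XIN") so
their weight can be read off directly. An included country absent from the
classification table is an error, never a silent default.

## Benchmarks and outliers

The Abuja flag tests GGHE/GGE ≥ 15%; the default numerator is
GGHE-D + EXT (government health spending from domestic and external
sources), with a domestic-only variant selectable, because both concepts
are in common use. Missing EXT counts as zero, consistent with the
composition rule. The GDP band is met at its 5% lower edge; the 6% upper
edge is informational. Flags carry their thresholds and the signed gap in
percentage points, so they are recomputable from the record.

Outlier screening has no canonical published rule, so the rule here is
explicit and configurable: values (and period changes) of a country-level
ratio strictly outside the [1st, 99th] nearest-rank percentiles, with an
absolute-bounds alternative. Nearest-rank on n < 100 countries makes the
extreme percentiles coincide with the sample extrema, so nothing can be
flagged on small cohorts; the rule refuses to run below 10 countries.
Ordering of flags is deterministic (window, value, ISO3).

## Synthetic data generator

The generator emulates the structure of the real database, not its
marginals: per-country multiplicative trajectories with group-specific
total-period growth parameters (y, e, h, population growth) applied as
constant per-year compound factors, and CHE built additively from
components with fixed per-country composition shares. Because the exponent
at the end year is exactly 1, endpoint growth equals the configured
parameter to machine precision, which is what makes exact parameter
recovery testable. Optional lognormal multiplicative noise is applied per
level after construction, and CHE is then re-summed from the noised
components, so additivity survives noise. Missingness blanks cells
independently per (indicator, year) rate and returns the mask.

The default fixture is four income groups × 15 countries plus two very
large focus countries (a LIC-resident and a LMIC-resident fast grower),
years 2000–2015, with group growth parameters implied by annualized rates
typical of that era (e.g. LIC GDP ≈ 5.5%/yr, HIC ≈ 1.5%/yr; the
LMIC-resident focus country grows near 10%/yr with rapid budget expansion
and health prioritization). Base levels are drawn uniformly from
group-typical ranges (LIC GDP per capita 250–900 US$, HIC 20,000–50,000,
etc.). Synthetic ISO3 codes use reserved letter ranges (Z-prefix members,
X-prefix focus) to avoid colliding with real codes.

What passing tests on this fixture do **not** show: robustness to the
messiness of real expenditure data — revisions, series breaks,
interpolated cells, currency-conversion artefacts, or correlated (rather
than independent) missingness. The generator's panels are structurally
clean by construction; tests on them verify the algebra and the plumbing,
not data quality handling beyond the explicit validation rules.

## Numerical choices

- CHE-identity validation tolerance: 1% relative residual warns, 5%
  errors; both configurable. Published tables do not state their rounding
  slack, so these are package defaults, chosen loose enough for
  printed-table inputs and tight enough to catch unit mistakes.
- CSV round trip uses shortest round-trip float formatting on write and
  exact string→float conversion on read (`astype`, not pandas'
  `to_numeric`, whose fast parser loses the last digit).
- Presentation rounding is half-away-from-zero (so 57.755 → 57.8 and
  −37.75 → −37.8), applied only in report tables; stored values are never
  rounded.
- The annualized-growth exponent denominator is the calendar-year
  difference (15 for 2000→2015).
- Report bundles are deterministic: fixed column order, `%.10g` floats,
  no wall-clock in any bundle file (timestamps go to the logging stream),
  so regeneration from identical inputs is byte-identical.
- Pipeline problem sizes: the standard fixture (62 countries × 16 years)
  keeps the full suite comfortably in the seconds range.

## Known limitations

- Endpoint formulas only; no regression-based growth estimation, so a
  single anomalous anchor-year value moves every downstream statistic.
- No currency deflation or exchange-rate handling: inputs are assumed
  already in constant dollars at one unit scale.
- No time-series gap filling; countries with incomplete anchor years are
  excluded rather than imputed.
- Capital expenditure is outside the data model; budget-share benchmarks
  based on current expenditure alone slightly understate total government
  health effort, which is documented here rather than adjusted for.
- Exact reproduction of published full-database group values requires the
  original database snapshot, which is not redistributable; the package
  pins only the desk-scale cells that reproduce from printed inputs and
  verifies everything else structurally on synthetic panels.
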