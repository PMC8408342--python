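"""Expenditure-weighted aggregation, composition shares, and the
country-weighted alternative."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import healthfin as hf
from conftest import make_panel, record

FULL = dict(population=700_000, gdp=1000.0, gge=200.0, gghe_d=10.0,
            oop=20.0, che=40.0)


def _assignment_for(rows, classification):
    panel = make_panel(rows)
    report = hf.apply_inclusion_filters(panel)
    return panel, hf.assign_income_groups(report, classification)


def test_single_member_group_aggregates_to_its_own_values():
    panel, asg = _assignment_for(
        [record("AAA", y, **FULL) for y in (2000, 2015)], {"AAA": "LIC"})
    assert hf.aggregate_level(panel, asg, "LIC", "gdp", 2000).value == 1000.0
    cell = hf.aggregate_ratio(panel, asg, "LIC", "gghe_d", "gge", 2000)
    assert cell.value == pytest.approx(10.0 / 200.0)


def test_two_member_sum():
    rows = []
    for iso3, gdp in (("AAA", 10.0), ("BBB", 32.0)):
        for y in (2000, 2015):
            rows.append(record(iso3, y, **dict(FULL, gdp=gdp)))
    panel, asg = _assignment_for(rows, {"AAA": "LIC", "BBB": "LIC"})
    assert hf.aggregate_level(panel, asg, "LIC", "gdp", 2000).value == 42.0


def test_fifty_member_sum_matches_brute_force_loop(default_panel, assignment):
    panel, _ = default_panel
    for group in ("LIC", "HIC"):
        cell = hf.aggregate_level(panel, assignment, group, "gghe_d", 2015)
        total = 0.0
        n = 0
        for iso3 in assignment.members(group):
            v = panel.value(iso3, 2015, "gghe_d")
            if np.isfinite(v):
                total += v
                n += 1
        assert cell.value == pytest.approx(total, rel=1e-12)
        assert cell.n_countries == n


def test_missing_members_are_skipped_and_counted():
    rows = [record("AAA", 2000, **FULL),
            record("BBB", 2000, **{k: v for k, v in FULL.items() if k != "gdp"}),
            record("AAA", 2015, **FULL), record("BBB", 2015, **FULL)]
    panel, asg = _assignment_for(rows, {"AAA": "LIC", "BBB": "LIC"})
    cell = hf.aggregate_level(panel, asg, "LIC", "gdp", 2000)
    assert cell.value == 1000.0 and cell.n_countries == 1


def test_aggregate_ratio_is_denominator_weighted_mean():
    rows = []
    for iso3, num in (("AAA", 10.0), ("BBB", 30.0)):
        for y in (2000, 2015):
            rows.append(record(iso3, y, **dict(FULL, gghe_d=num, gge=100.0)))
    panel, asg = _assignment_for(rows, {"AAA": "LIC", "BBB": "LIC"})
    cell = hf.aggregate_ratio(panel, asg, "LIC", "gghe_d", "gge", 2000)
    assert cell.value == pytest.approx(0.20)


def test_ratio_complete_pairs_rule():
    """A member missing either side of the ratio is dropped from BOTH sums."""
    rows = [record("AAA", 2000, **FULL),
            record("BBB", 2000, **{k: v for k, v in FULL.items() if k != "gge"}),
            record("AAA", 2015, **FULL), record("BBB", 2015, **FULL)]
    panel, asg = _assignment_for(rows, {"AAA": "LIC", "BBB": "LIC"})
    cell = hf.aggregate_ratio(panel, asg, "LIC", "gghe_d", "gge", 2000)
    assert cell.value == pytest.approx(10.0 / 200.0)
    assert cell.n_countries == 1


@given(st.lists(st.tuples(st.floats(0.1, 1e4), st.floats(0.01, 0.9)),
                min_size=1, max_size=12))
def test_aggregate_ratio_bounded_by_member_ratio_extrema(members):
    rows = []
    for i, (den, ratio) in enumerate(members):
        iso3 = "H" + chr(ord("A") + i // 26) + chr(ord("A") + i % 26)
        for y in (2000, 2015):
            rows.append(record(iso3, y, population=700_000, gdp=1000.0,
                               gge=den, gghe_d=den * ratio, oop=1.0, che=5.0))
    panel, asg = _assignment_for(rows, {r["iso3"]: "LIC" for r in rows})
    cell = hf.aggregate_ratio(panel, asg, "LIC", "gghe_d", "gge", 2000)
    ratios = [r for _, r in members]
    assert min(ratios) - 1e-12 <= cell.value <= max(ratios) + 1e-12


@given(st.floats(0.001, 1e6))
def test_ratios_invariant_under_uniform_rescaling(scale):
    rows = [record("AAA", y, **FULL) for y in (2000, 2015)]
    rows += [record("BBB", y, **dict(FULL, gge=317.0, gghe_d=29.0))
             for y in (2000, 2015)]
    panel, asg = _assignment_for(rows, {"AAA": "LIC", "BBB": "LIC"})
    scaled_rows = []
    for r in rows:
        s = dict(r)
        for k in ("gdp", "gge", "gghe_d", "che", "oop"):
            s[k] = s[k] * scale
        scaled_rows.append(s)
    spanel, sasg = _assignment_for(scaled_rows, {"AAA": "LIC", "BBB": "LIC"})
    for fn in (hf.aggregate_ratio, hf.country_weighted_average):
        base = fn(panel, asg, "LIC", "gghe_d", "gge", 2000).value
        scaled = fn(spanel, sasg, "LIC", "gghe_d", "gge", 2000).value
        assert scaled == pytest.approx(base, rel=1e-9)


def test_zero_denominator_sum_raises():
    rows = [record("AAA", y, **dict(FULL, gge=0.0)) for y in (2000, 2015)]
    panel, asg = _assignment_for(rows, {"AAA": "LIC"})
    with pytest.raises(ZeroDivisionError):
        hf.aggregate_ratio(panel, asg, "LIC", "gghe_d", "gge", 2000)


# --- composition -----------------------------------------------------------


def test_composition_all_oop():
    rows = [record("AAA", y, population=700_000, gdp=1000, gge=200,
                   gghe_d=0.0, ext=0.0, oop=40.0, vpp=0.0, pvt_other=0.0)
            for y in (2000, 2015)]
    panel = make_panel(rows)
    report = hf.apply_inclusion_filters(
        panel, hf.InclusionCriteria(required_indicators=("gdp", "oop")))
    asg = hf.assign_income_groups(report, {"AAA": "LIC"})
    shares = hf.composition_shares(panel, asg, "LIC", 2000)
    assert shares.shares["oop"] == 1.0
    assert all(v == 0.0 for k, v in shares.shares.items() if k != "oop")


def test_composition_shares_sum_to_one_on_additive_panel(default_panel,
                                                         assignment):
    panel, _ = default_panel
    for group in ("LIC", "LMIC", "UMIC", "HIC", "XCN"):
        for year in (2000, 2015):
            shares = hf.composition_shares(panel, assignment, group, year)
            assert shares.total() == pytest.approx(1.0, abs=1e-12)
            assert not shares.missing_components


def test_missing_component_contributes_zero_and_is_flagged():
    rows = [record("AAA", y, population=700_000, gdp=1000, gge=200,
                   gghe_d=10.0, oop=30.0, che=45.0) for y in (2000, 2015)]
    panel, asg = _assignment_for(rows, {"AAA": "LIC"})
    shares = hf.composition_shares(panel, asg, "LIC", 2000)
    assert shares.shares["ext"] == 0.0
    assert {"ext", "vpp", "pvt_other"} <= set(shares.missing_components)


def test_per_capita_times_population_recovers_level_sum(default_panel,
                                                        assignment):
    panel, _ = default_panel
    pc = hf.per_capita(panel, assignment, "UMIC", "che", 2015)
    pop = hf.aggregate_level(panel, assignment, "UMIC", "population", 2015)
    lvl = hf.aggregate_level(panel, assignment, "UMIC", "che", 2015)
    assert pc.value * pop.value == pytest.approx(lvl.value, rel=1e-12)


# --- country-weighted comparison ------------------------------------------


def test_identical_members_make_weightings_agree():
    rows = [record(iso3, y, **FULL) for iso3 in ("AAA", "BBB", "CCC")
            for y in (2000, 2015)]
    panel, asg = _assignment_for(rows, {c: "LIC" for c in ("AAA", "BBB", "CCC")})
    agg = hf.aggregate_ratio(panel, asg, "LIC", "gghe_d", "gge", 2000)
    cw = hf.country_weighted_average(panel, asg, "LIC", "gghe_d", "gge", 2000)
    assert agg.value == pytest.approx(cw.value)


def test_weightings_diverge_with_unequal_denominators():
    """Country-weighted mean of 0.10 (large economy) and 0.30 (small) is
    0.20, while the aggregate ratio is pulled toward the large economy."""
    rows = []
    for iso3, gge, ratio in (("BIG", 1000.0, 0.10), ("SML", 10.0, 0.30)):
        for y in (2000, 2015):
            rows.append(record(iso3, y, **dict(FULL, gge=gge, gghe_d=gge * ratio)))
    panel, asg = _assignment_for(rows, {"BIG": "LIC", "SML": "LIC"})
    cw = hf.country_weighted_average(panel, asg, "LIC", "gghe_d", "gge", 2000)
    agg = hf.aggregate_ratio(panel, asg, "LIC", "gghe_d", "gge", 2000)
    assert cw.value == pytest.approx(0.20)
    assert agg.value < 0.20


def test_dominant_member_drives_aggregate(default_panel, assignment):
    """XCN has ~15× everyone's GGE: the LMIC aggregate tracks it, and the
    divergence sign matches an independent weighted-mean computation."""
    panel, _ = default_panel
    div = hf.weighting_divergence(panel, assignment, "LMIC",
                                  "gghe_d", "gge", 2015)
    num = den = 0.0
    ratios = []
    for iso3 in assignment.members("LMIC"):
        n_v = panel.value(iso3, 2015, "gghe_d")
        d_v = panel.value(iso3, 2015, "gge")
        num += n_v
        den += d_v
        ratios.append(n_v / d_v)
    assert div["aggregate"] == pytest.approx(num / den, rel=1e-12)
    assert div["country_weighted"] == pytest.approx(np.mean(ratios), rel=1e-12)
    xcn = panel.value("XCN", 2015, "gghe_d") / panel.value("XCN", 2015, "gge")
    # aggregate sits closer to the dominant member than the plain mean does
    assert abs(div["aggregate"] - xcn) < abs(div["country_weighted"] - xcn)
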