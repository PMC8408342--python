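import pandas as pd
import pytest
from hypothesis import settings

import healthfin as hf

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_panel(rows, **kwargs):
    """Build a Panel from a list of row dicts; absent indicators stay missing."""
    return hf.Panel(pd.DataFrame(rows), **kwargs)


def record(iso3, year, **values):
    """One country-year row with CHE built additively unless given."""
    row = {"iso3": iso3, "year": year}
    row.update(values)
    comps = ("gghe_d", "ext", "oop", "vpp", "pvt_other")
    if "che" not in row and any(c in row for c in comps):
        row["che"] = sum(row.get(c, 0.0) for c in comps)
    return row


@pytest.fixture(scope="session")
def default_panel():
    """The standard noise-free synthetic fixture (62 countries, 2000–2015)."""
    panel, truth = hf.generate_panel(hf.default_config(seed=7))
    return panel, truth


@pytest.fixture(scope="session")
def assignment(default_panel):
    panel, truth = default_panel
    report = hf.apply_inclusion_filters(panel)
    return hf.assign_income_groups(report, truth.classification,
                                   focus_countries=("XIN", "XCN"))
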