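"""Shared fixtures.

Heavy scenario runs are session-scoped so each steady state is solved once
per test session; everything here runs at desk-scale resolutions.
"""

from __future__ import annotations

import numpy as np
import pytest

from rootflux.geometry import build_geometric_cross_section, rasterize
from rootflux.scenarios import build_template, generate_fixture, get_preset, run_scenario


@pytest.fixture(scope="session")
def geometric_template():
    return build_geometric_cross_section()


@pytest.fixture(scope="session")
def mini_template():
    return build_template("geometric-mini")


@pytest.fixture(scope="session")
def mini_grid(mini_template):
    return rasterize(mini_template, dx=0.5, wall_thickness=1.0)


@pytest.fixture(scope="session")
def tiny_fixture():
    return generate_fixture("tiny-grid")


@pytest.fixture(scope="session")
def two_cell_fixture():
    return generate_fixture("two-cell")


@pytest.fixture(scope="session")
def wt_dynamic_result():
    """Wild-type dynamic steady state on the geometric template (coarse)."""
    return run_scenario(get_preset("fig4f_wildtype_dynamic", desk_scale=True, dx=1.0, wall_thickness=2.0))


def cell_mean_map(result):
    """cell_id -> mean auxin of a ScenarioResult."""
    tab = result.cell_table()
    return dict(zip(tab["cell_id"], tab["mean_auxin"]))
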