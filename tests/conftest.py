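"""Shared fixtures.

Heavy artifacts (solved lead fields, fiber populations) are session-scoped:
the PDE solves and compartmental simulations dominate the suite's runtime,
so every test that can share a solved instance does.
"""

import numpy as np
import pytest

from enm.electrodes import Placement, build_time, place_implants
from enm.fibers import populate_fibers
from enm.geometry import cross_section_from_circles, synthesize_cross_section
from enm.volume_conductor import GridSpec, LeadFieldSolver, build_conductivity_map

TEST_GRID = GridSpec(h_plane=0.25, h_axial=0.4, h_max=2.4, growth=0.5)


@pytest.fixture(scope="session")
def toy_nerve():
    """Five-fascicle toy nerve, small enough for exhaustive computations."""
    return cross_section_from_circles(
        (8.0, 5.0),
        [(-2.4, 0.6, 1.0), (-0.9, -0.8, 0.9), (0.8, 0.7, 1.1), (2.3, -0.5, 0.8), (0.1, -1.6, 0.5)],
        anatomy_label="distal",  # reuse the distal effective ranges
    )


@pytest.fixture(scope="session")
def toy_time_setup(toy_nerve):
    """TIME-12 in the toy nerve with solved lead fields and one population."""
    electrode = build_time(12, "distal")
    placement = Placement(electrode=electrode, insertion_point=(0.0, 0.05))
    cmap = build_conductivity_map(toy_nerve, [placement], TEST_GRID)
    fields = LeadFieldSolver(cmap).solve_all()
    pops = populate_fibers(toy_nerve, seed=3, density=60.0)
    return {"cs": toy_nerve, "placements": [placement], "fields": fields, "pops": pops,
            "cmap": cmap}


@pytest.fixture(scope="session")
def distal_section():
    return synthesize_cross_section("distal", 1)


@pytest.fixture(scope="session")
def proximal_section():
    return synthesize_cross_section("proximal", 1)


@pytest.fixture(scope="session")
def distal_time20(distal_section):
    """Distal TIME-20: solved lead fields + populations (two seeds)."""
    pls = place_implants(distal_section, build_time(20, "distal"), 1)
    cmap = build_conductivity_map(distal_section, pls, TEST_GRID)
    fields = LeadFieldSolver(cmap).solve_all()
    pops = {s: populate_fibers(distal_section, s, density=36.0) for s in (1, 2)}
    return {"cs": distal_section, "placements": pls, "fields": fields, "pops": pops}


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
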