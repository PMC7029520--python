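"""MRG axon model behavior: excitability, thresholds, sweep bookkeeping."""

import numpy as np
import pytest

from enm.biophysics import (
    MRG_DIAMETERS_UM,
    N_COMP,
    BiophysicsError,
    StimulusSweep,
    compartment_z,
    diameter_class,
    find_threshold,
    find_threshold_indices,
    nodes_to_compartments,
    simulate_batch,
    simulate_fiber,
)
from enm.fibers import Fiber

SIGMA_MEDIUM = 0.0826  # S/m, epineurium-like surrounding


def point_source_profile(diameter_um, dist_mm, z_src=0.0):
    """V per ampere at all compartments for a point source ``dist_mm`` away."""
    z = compartment_z(diameter_um)
    r = np.sqrt(dist_mm**2 + (z - z_src) ** 2) * 1e-3
    return 1.0 / (4 * np.pi * SIGMA_MEDIUM * np.maximum(r, 1e-6))


def fiber_at(dist_mm, D=10.0):
    return Fiber(id=0, fascicle_id=0, population_id=0, x=0.0, y=dist_mm,
                 diameter_um=D, z_offset=0.0)


class TestStimulusSweep:
    def test_default_sweep_charge_current_identity(self):
        sw = StimulusSweep()
        q = sw.charges_nc
        assert len(q) == 60 and q[0] == 0.5 and q[-1] == 60.0
        assert np.all(np.diff(q) > 0)
        # I = Q / width: 0.5 nC -> 10 uA and 60 nC -> 1.2 mA at 50 us
        assert sw.currents_a[0] == pytest.approx(10e-6)
        assert sw.currents_a[-1] == pytest.approx(1200e-6)

    def test_halving_pulse_width_halves_charge_at_fixed_current(self):
        full = StimulusSweep(pulse_us=50.0)
        half = StimulusSweep(pulse_us=25.0)
        # same current index-by-index means half the delivered charge
        assert np.allclose(half.charges_nc * 1e-9 / (25e-6), half.currents_a)
        assert np.allclose(full.currents_a * 50e-6, full.charges_nc * 1e-9)

    def test_invalid_sweep_rejected(self):
        with pytest.raises(BiophysicsError):
            StimulusSweep(q_min_nc=-1.0)


class TestSimulateFiber:
    def test_zero_drive_not_recruited(self):
        assert not simulate_fiber(fiber_at(1.0), np.zeros(N_COMP), amplitude=0.0)

    def test_suprathreshold_drive_recruited(self):
        prof = -point_source_profile(10.0, 1.0)
        assert simulate_fiber(fiber_at(1.0), prof, amplitude=1e-3)

    def test_node_profile_interpolated_to_compartments(self):
        prof_nodes = -point_source_profile(10.0, 1.0)[
            np.linspace(0, N_COMP - 1, 21).astype(int)
        ]
        prof21 = nodes_to_compartments(prof_nodes, 10.0)
        assert prof21.shape == (N_COMP,)
        assert simulate_fiber(fiber_at(1.0), prof_nodes, amplitude=1e-3)

    def test_inverse_recruitment_order_big_fiber_first(self):
        sw = StimulusSweep()
        t_small = find_threshold(fiber_at(1.0, 7.3), point_source_profile(7.3, 1.0), sw)
        t_big = find_threshold(fiber_at(1.0, 14.0), point_source_profile(14.0, 1.0), sw)
        assert t_big is not None and t_small is not None
        assert t_big <= t_small


class TestFindThreshold:
    def test_floor_and_cap_cases(self):
        sw = StimulusSweep()
        # scaled-up drive: recruited at the lowest rung -> 0.5 nC
        strong = point_source_profile(12.8, 0.8) * 30.0
        assert find_threshold(fiber_at(0.8, 12.8), strong, sw) == pytest.approx(0.5)
        # far fiber: silent at the 60 nC cap -> None
        weak = point_source_profile(5.7, 6.0)
        assert find_threshold(fiber_at(6.0, 5.7), weak, sw) is None

    def test_bisection_matches_exhaustive_scan(self, rng):
        sw = StimulusSweep()
        dists = rng.uniform(0.4, 2.5, size=12)
        Ds = rng.choice(MRG_DIAMETERS_UM, size=12)
        cls = np.array([diameter_class(D) for D in Ds])
        profs = np.stack([-point_source_profile(D, r) for D, r in zip(Ds, dists)])
        fast = find_threshold_indices(cls, profs, sw)
        slow = find_threshold_indices(cls, profs, sw, exhaustive=True)
        assert np.array_equal(fast, slow)

    def test_recruitment_monotone_in_amplitude(self, rng):
        # within the operating range of distances; fibers nearly touching the
        # site can show cathodal conduction block at extreme charges, which
        # the first-recruiting-charge report (bottom-up scan) absorbs
        sw = StimulusSweep()
        dists = rng.uniform(0.7, 2.0, size=5)
        for r in dists:
            prof = -point_source_profile(10.0, r)[None, :]
            rec = [
                simulate_batch(np.array([3]), prof, np.array([cur]))[0]
                for cur in sw.currents_a[::6]
            ]
            assert np.all(np.diff(np.asarray(rec)) >= 0)

    def test_strength_distance_monotone(self):
        sw = StimulusSweep()
        thr = []
        for r in (0.5, 1.0, 1.5, 2.0):
            thr.append(find_threshold(fiber_at(r, 11.5), point_source_profile(11.5, r), sw))
        assert all(t is not None for t in thr)
        assert np.all(np.diff(np.asarray(thr)) >= 0)


def test_compartment_ladder_structure():
    z = compartment_z(10.0)
    assert z.shape == (N_COMP,)
    assert np.all(np.diff(z) > 0)
    # the 21 nodes are exactly L apart
    node_idx = np.arange(0, N_COMP, 11)
    nodes = z[node_idx]
    assert np.allclose(np.diff(nodes), 1.0, atol=1e-9)  # L = 100 * 10 um = 1 mm
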