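"""Selectivity indexes, criterion logic, range filter and policy evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enm.electrodes import build_time
from enm.fibers import Fiber
from enm.selectivity import (
    SelectivityError,
    SelectivityEvaluator,
    StimConfig,
    effective_range_filter,
    enumerate_bipolar_configs,
    fascicle_threshold_charge,
    functional_selectivity,
    monopolar_configs,
    spatial_selectivity,
)


class TestIndexFormulas:
    @pytest.mark.parametrize(
        "mu,i,expected",
        [([1.0, 0.0, 0.0], 0, 1.0), ([0.5, 0.5], 0, 0.0), ([0.8, 0.1, 0.1], 0, 0.7)],
    )
    def test_spatial_selectivity_examples(self, mu, i, expected):
        assert spatial_selectivity(mu, i) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "n,i,expected", [([10, 0, 0], 0, 1.0), ([9, 1, 0], 0, 0.9)]
    )
    def test_functional_selectivity_examples(self, n, i, expected):
        assert functional_selectivity(n, i) == pytest.approx(expected)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(SelectivityError):
            spatial_selectivity([0.5], 0)
        with pytest.raises(SelectivityError):
            functional_selectivity([0, 0, 0], 0)

    @given(st.lists(st.integers(min_value=0, max_value=50), min_size=2, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_functional_selectivity_normalizes(self, counts):
        if sum(counts) == 0:
            counts[0] = 1
        total = sum(functional_selectivity(counts, i) for i in range(len(counts)))
        assert total == pytest.approx(1.0)

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=8),
        st.data(),
    )
    @settings(max_examples=50, deadline=None)
    def test_spatial_selectivity_bounds(self, mu, data):
        i = data.draw(st.integers(min_value=0, max_value=len(mu) - 1))
        s = spatial_selectivity(mu, i)
        assert -1.0 - 1e-12 <= s <= 1.0 + 1e-12
        assert s <= max(mu) + 1e-12
        if mu[i] == 1.0 and all(m == 0.0 for j, m in enumerate(mu) if j != i):
            assert s == pytest.approx(1.0)


class TestThresholdCharge:
    def test_first_crossing_of_ten_percent(self):
        charges = np.linspace(0.5, 60, 60)
        mu = np.zeros(60)
        mu[6:] = np.linspace(0.1, 1.0, 54)
        assert fascicle_threshold_charge(mu, charges) == pytest.approx(charges[6])

    def test_never_reached_returns_none(self):
        assert fascicle_threshold_charge(np.full(60, 0.05), np.linspace(0.5, 60, 60)) is None

    def test_monotone_curve_unique_crossing(self):
        charges = np.linspace(0.5, 60, 60)
        mu = np.clip(np.linspace(-0.2, 1.2, 60), 0, 1)
        q = fascicle_threshold_charge(mu, charges)
        assert mu[np.searchsorted(charges, q)] >= 0.10
        assert np.all(mu[: np.searchsorted(charges, q)] < 0.10)


def make_fiber(i, fid, x, y):
    return Fiber(id=i, fascicle_id=fid, population_id=0, x=x, y=y,
                 diameter_um=10.0, z_offset=0.0)


class TestEffectiveRange:
    def test_far_fascicle_excluded_near_implicated(self):
        fibers = [
            make_fiber(0, 0, 0.5, 0.0),
            make_fiber(1, 0, 2.5, 0.0),  # same fascicle straddles the boundary
            make_fiber(2, 1, 3.5, 0.0),  # fascicle fully beyond 2 mm
        ]
        kept, implicated = effective_range_filter(fibers, (0.0, 0.0), "TIME", "distal")
        assert implicated == {0}
        assert [f.id for f in kept] == [0, 1]  # whole fascicle 0 retained

    def test_fine_proximal_range_is_4mm(self):
        fibers = [make_fiber(0, 0, 3.5, 0.0)]
        kept, implicated = effective_range_filter(fibers, (0.0, 0.0), "FINE", "proximal")
        assert implicated == {0} and len(kept) == 1
        kept, implicated = effective_range_filter(fibers, (0.0, 0.0), "FINE", "distal")
        assert implicated == set()


class TestBipolarEnumeration:
    def test_time12_yields_48_anchored_configs(self):
        cfgs = enumerate_bipolar_configs(build_time(12, "distal"))
        assert len(cfgs) == 48  # 12 anchors x {opposite-face, same-face} x 2 patterns
        for c in cfgs:
            assert len(c.as_keys) == 2
            assert abs(c.weights[0]) == abs(c.weights[1]) == 1.0

    def test_single_site_has_no_pairs(self):
        el = build_time(12, "distal")
        import dataclasses

        lone = dataclasses.replace(
            el, n_as=1, as_positions=el.as_positions[:1], as_face=el.as_face[:1]
        )
        assert enumerate_bipolar_configs(lone) == []

    def test_dedup_collapses_identical_weight_maps(self):
        el = build_time(12, "distal")
        import dataclasses

        two = dataclasses.replace(
            el, n_as=2, as_positions=el.as_positions[[0, 6]], as_face=el.as_face[[0, 6]]
        )
        full = enumerate_bipolar_configs(two)
        deduped = enumerate_bipolar_configs(two, dedup=True)
        assert len(deduped) < len(full)
        maps = {frozenset(zip(c.as_keys, c.weights)) for c in deduped}
        assert len(maps) == len(deduped)


class TestPolicyEvaluation:
    def test_single_fascicle_nerve_rejected(self, toy_time_setup):
        from enm.geometry import cross_section_from_circles
        from enm.fibers import populate_fibers

        cs = cross_section_from_circles((6.0, 4.0), [(0, 0.8, 1.0)])
        pops = populate_fibers(cs, 1, density=40.0)
        with pytest.raises(SelectivityError, match="two fascicles"):
            SelectivityEvaluator(cs, toy_time_setup["placements"],
                                 toy_time_setup["fields"], pops)

    def test_bipolar_policy_contains_monopolar(self, toy_time_setup):
        ev = SelectivityEvaluator(
            toy_time_setup["cs"], toy_time_setup["placements"],
            toy_time_setup["fields"], toy_time_setup["pops"],
        )
        mono_names = {c.name for c in ev.policy_configs("monopolar")}
        bi_names = {c.name for c in ev.policy_configs("bipolar")}
        assert mono_names < bi_names

    def test_bipolar_score_never_below_monopolar(self, toy_time_setup):
        ev = SelectivityEvaluator(
            toy_time_setup["cs"], toy_time_setup["placements"],
            toy_time_setup["fields"], toy_time_setup["pops"],
        )
        mono = ev.evaluate("monopolar")
        bi = ev.evaluate("bipolar")
        assert bi.score >= mono.score
        assert mono.selective_union <= bi.selective_union

    def test_selective_criterion_strict_at_boundary(self):
        from enm.selectivity import is_selective

        assert not is_selective(0.6, 1.0, 5)  # Sel_i exactly 0.6 fails
        assert is_selective(0.6 + 1e-9, 1.0, 5)
        assert not is_selective(0.8, 0.9, 5)  # Sel_s exactly 0.9 fails
        assert is_selective(0.8, 0.9 + 1e-9, 5)
        assert not is_selective(0.8, 1.0, 0)  # vacuous zero-recruitment case
        # equal split across two fascicles can never pass: Sel_s = 0.5
        assert not is_selective(spatial_selectivity([0.5, 0.5], 0),
                                functional_selectivity([5, 5], 0), 5)

    def test_scores_invariant_to_config_order(self, toy_time_setup):
        ev = SelectivityEvaluator(
            toy_time_setup["cs"], toy_time_setup["placements"],
            toy_time_setup["fields"], toy_time_setup["pops"],
        )
        configs = monopolar_configs(toy_time_setup["placements"])
        u1 = set()
        for c in configs:
            u1 |= ev.config_selective_set(c)
        u2 = set()
        for c in reversed(configs):
            u2 |= ev.config_selective_set(c)
        assert u1 == u2


class TestMultiImplant:
    def test_single_implant_matches_policy_and_union_grows(self):
        from enm.electrodes import build_time
        from enm.geometry import cross_section_from_circles
        from enm.selectivity import evaluate_multi_implant
        from tests.conftest import TEST_GRID

        # wide enough for off-center parallel shafts of the 10 mm electrode
        cs = cross_section_from_circles(
            (10.0, 6.0),
            [(-2.6, 1.0, 1.0), (-0.4, -1.2, 0.9), (2.2, 0.9, 1.1), (2.6, -1.2, 0.7)],
            anatomy_label="distal",
        )
        el = build_time(12, "distal")
        cache = {}
        out = evaluate_multi_implant(
            cs, el, [1, 2], seed=3, grid=TEST_GRID, density=60.0, shaft_cache=cache,
        )
        scores = out["scores"]
        sets = out["selective_sets"]
        # single implant equals the plain monopolar policy on that placement
        assert scores[1] == 100.0 * len(sets[1]) / cs.n_fascicles
        # two parallel shafts union their per-shaft selective sets
        assert 0.0 <= scores[1] <= scores[2] + 50.0
        assert len(cache) == 3  # center + two lateral shafts, each solved once

    def test_multi_implant_rejects_fine(self, toy_nerve):
        from enm.electrodes import build_fine
        from enm.selectivity import SelectivityError, evaluate_multi_implant

        with pytest.raises(SelectivityError, match="TIME"):
            evaluate_multi_implant(toy_nerve, build_fine(12, "distal"), [1, 2], seed=1)
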