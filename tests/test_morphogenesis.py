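"""Morphogenesis tests: placement, diffusion field, growth rules, synapses."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from devwta.morphogenesis import (ELONGATING, RETRACTING, STOPPED,
                                  TABLE_GROWTH_PARAMS, GrowthParams,
                                  GrowthState, Somata, SubstanceField,
                                  brute_force_synapses, concentration_at,
                                  connectivity_stats, cube_side_for_density,
                                  export_swc, form_synapses, grow_network,
                                  place_somata)


@pytest.fixture(scope="module")
def small_net():
    """A grown 20-neuron network shared by the synapse tests."""
    rng = np.random.default_rng(0)
    som = place_somata(16, 4, cube_side_for_density(20), rng)
    gs = grow_network(som, seed=1, max_steps=600)
    return gs


class TestPlacement:
    def test_density_inside_biological_range(self):
        rng = np.random.default_rng(1)
        s = place_somata(200, 50, 160.0, rng)
        assert 40_000 <= s.density_per_mm3() <= 86_900
        assert s.density_per_mm3() == pytest.approx(61_035, rel=1e-3)

    def test_positions_inside_cube(self):
        rng = np.random.default_rng(2)
        s = place_somata(50, 10, 100.0, rng)
        assert s.positions.min() >= 0 and s.positions.max() <= 100.0

    def test_single_soma(self):
        s = place_somata(1, 0, 50.0, np.random.default_rng(3))
        assert s.n == 1

    def test_mean_position_at_cube_center(self):
        rng = np.random.default_rng(4)
        side = 100.0
        s = place_somata(5000, 5000, side, rng)
        se = side / np.sqrt(12 * s.n)
        assert np.all(np.abs(s.positions.mean(0) - side / 2) < 3 * se)

    def test_density_warning_outside_range(self):
        with pytest.warns(UserWarning, match="density"):
            place_somata(2, 1, 160.0, np.random.default_rng(5))


class TestSubstanceField:
    def test_zero_sources_zero_everywhere(self):
        fld = SubstanceField(sources=np.zeros((0, 3)), Q=1.0)
        assert concentration_at(np.array([1.0, 2.0, 3.0]), fld) == 0.0

    def test_single_source_matches_screened_kernel_ratio(self):
        # closed form: C(r) = Q/(4 pi D r) exp(-r sqrt(k/D))
        fld = SubstanceField(sources=np.array([[0.0, 0.0, 0.0]]), Q=100.0)
        c10 = concentration_at(np.array([10.0, 0, 0]), fld)
        c20 = concentration_at(np.array([20.0, 0, 0]), fld)
        lam = np.sqrt(fld.k / fld.D)
        assert c10 / c20 == pytest.approx(2.0 * np.exp(lam * 10.0), rel=1e-9)

    def test_additivity_of_two_sources(self):
        one = SubstanceField(sources=np.array([[0.0, 0, 0]]), Q=5.0)
        two = SubstanceField(sources=np.array([[0.0, 0, 0], [40.0, 0, 0]]), Q=5.0)
        mid = np.array([20.0, 0, 0])
        assert concentration_at(mid, two) == pytest.approx(
            2 * concentration_at(mid, one), rel=1e-9)

    def test_monotone_decay_from_isolated_source(self):
        fld = SubstanceField(sources=np.array([[0.0, 0, 0]]), Q=1.0)
        r = np.linspace(5, 80, 40)
        c = concentration_at(np.column_stack([r, 0 * r, 0 * r]), fld)
        assert np.all(np.diff(c) < 0)


class TestSprouting:
    def test_each_neuron_has_one_axon_three_dendrites(self):
        som = place_somata(10, 3, 80.0, np.random.default_rng(6))
        gs = GrowthState(som, seed=7)
        for i in range(som.n):
            mine = gs.c_neuron == i
            assert (gs.c_kind[mine] == 0).sum() == 1
            assert (gs.c_kind[mine] == 1).sum() == 3

    def test_axons_sense_opposite_class_substance(self):
        som = place_somata(10, 3, 80.0, np.random.default_rng(8))
        gs = GrowthState(som, seed=9)
        # excitatory axons read the field sourced at inhibitory somata
        assert len(gs.field_for_exc_axons.sources) == 3
        assert len(gs.field_for_inh_axons.sources) == 10

    def test_initial_directions_uniform_on_sphere(self):
        # Rayleigh-type test: the resultant of n uniform unit vectors is
        # small; each Cartesian component has mean 0 and variance 1/3
        som = place_somata(2500, 2500, 500.0, np.random.default_rng(10))
        gs = GrowthState(som, seed=11, gridded_field=False)
        dirs = gs.c_dir
        n = len(dirs)
        z = np.abs(dirs.mean(0)) / np.sqrt(1.0 / 3.0 / n)
        assert np.all(z < 3.3)  # ~alpha = 0.01 per component


class TestGrowthRules:
    def _lone_axon_state(self, params, conc_level, seed=0):
        """Single neuron whose axon senses a spatially constant field."""
        som = Somata(positions=np.array([[50.0, 50, 50]]),
                     is_excitatory=np.array([True]), cube_side=100.0)
        gs = GrowthState(som, params=params, seed=seed, gridded_field=False)
        gs._eval_exc = lambda p: np.full(len(np.atleast_2d(p)), conc_level)
        return gs

    def test_high_concentration_never_retracts(self):
        # constant level above the retraction-stop threshold 0.036
        gs = self._lone_axon_state(None, 0.05)
        for _ in range(60):
            gs.step()
        ax = gs.c_kind == 0
        assert not np.any(gs.c_state[ax] == RETRACTING)

    def test_low_concentration_triggers_retraction(self):
        # grow in a high field first, then drop it below e_low = 1e-8
        gs = self._lone_axon_state(None, 0.05)
        for _ in range(10):
            gs.step()
        gs._eval_exc = lambda p: np.full(len(np.atleast_2d(p)), 5e-9)
        gs.step()
        ax = gs.c_kind == 0
        assert np.all(gs.c_state[ax] == RETRACTING)

    def test_zero_random_weight_grows_straight(self):
        params = {k: dataclasses.replace(v, w_prev=1.0, w_rand=0.0)
                  for k, v in TABLE_GROWTH_PARAMS.items()}
        gs = self._lone_axon_state(params, 0.05)
        d0 = gs.c_dir.copy()
        p0 = gs.c_pos.copy()
        gs.step()
        moved = gs.c_pos - p0
        step_len = 100.0 * gs.dt
        # every cone moved exactly one step along its initial direction
        assert np.allclose(moved, step_len * d0, atol=1e-9)

    def test_branch_count_binomial_with_constant_probability(self):
        # dendrites: p_bc = 0, so branching per step is Bernoulli(p_b0)
        p_b0 = 0.04
        som = place_somata(150, 1, 400.0, np.random.default_rng(12))
        params = {k: dataclasses.replace(v, d_init=10.0, dd_move=0.0, dd_bif=0.0)
                  for k, v in TABLE_GROWTH_PARAMS.items()}
        gs = GrowthState(som, params=params, seed=13)
        # freeze axons so only dendritic cones count
        gs.c_state[gs.c_kind == 0] = STOPPED
        n_dend = int((gs.c_kind == 1).sum())
        M = 5
        for _ in range(M):
            gs.step()
        # each dendritic cone lineage branches Binomial(M, p_b0) times;
        # total branch events = new cones created
        events = (gs.c_kind == 1).sum() - n_dend
        lam = n_dend * M * p_b0  # small-p expectation (cone count grows)
        assert abs(events - lam) < 4 * np.sqrt(lam) + 5

    def test_dendrites_stop_at_minimal_diameter(self, small_net):
        gs = small_net
        dend = gs.c_kind == 1
        assert np.all(gs.c_state[dend] == STOPPED)
        # excitatory dendrite stops below 0.3
        seg = gs.segments()
        d_seg = seg["diam"][seg["kind"] == 1]
        assert d_seg.min() >= 0.3 - TABLE_GROWTH_PARAMS[("excitatory", "dendrite")].dd_bif - 0.05

    def test_inhibitory_arbors_smaller_than_excitatory(self):
        rng = np.random.default_rng(14)
        som = place_somata(25, 25, cube_side_for_density(50), rng)
        gs = grow_network(som, seed=15, max_steps=600)
        seg = gs.segments()
        dend = seg["kind"] == 1
        d = np.linalg.norm(seg["dist"] - gs.somata.positions[seg["neuron"]], axis=1)
        exc_seg = gs.somata.is_excitatory[seg["neuron"]]
        assert d[dend & ~exc_seg].mean() < d[dend & exc_seg].mean()

    def test_segments_no_longer_than_discretization(self, small_net):
        seg = small_net.segments()
        lengths = np.linalg.norm(seg["dist"] - seg["prox"], axis=1)
        assert lengths.max() <= 7.0 + 1e-6


class TestSynapses:
    def test_matches_brute_force_all_pairs(self, small_net):
        syn = form_synapses(small_net, record=False)
        got = {(int(a), int(b)) for a, b in zip(syn["pre_seg"], syn["post_seg"])}
        assert got == brute_force_synapses(small_net)

    def test_distance_criterion_and_autapse_exclusion(self):
        # hand-built geometry: two parallel segments at known distances
        som = Somata(positions=np.array([[0.0, 0, 0], [30.0, 0, 0]]),
                     is_excitatory=np.array([True, True]), cube_side=60.0)
        gs = GrowthState(som, seed=16)
        gs.seg.append_batch(
            neuron=np.array([0, 1, 1, 0]),
            kind=np.array([0, 1, 1, 1]),          # axon, dendrite, dendrite, dendrite
            parent=np.array([-1, -1, -1, -1]),
            prox=np.array([[0, 0, 0], [0, 1.9, 0], [0, 2.5, -7], [0.5, 0, 0]], float),
            dist=np.array([[7, 0, 0], [7, 1.9, 0], [7, 2.5, -7], [7.5, 0, 0]], float),
            diam=np.ones(4))
        syn = form_synapses(gs, record=False)
        pairs = {(int(a), int(b)) for a, b in zip(syn["pre_seg"], syn["post_seg"])}
        assert (0, 1) in pairs      # 1.9 um apart, different neurons
        assert (0, 2) not in pairs  # 2.5 um in y and 7 um in z: too far
        assert (0, 3) not in pairs  # same neuron: autapse prohibited

    def test_signs_and_initial_weights(self, small_net):
        syn = form_synapses(small_net, record=False)
        exc = small_net.somata.is_excitatory[syn["pre"]]
        assert np.all(syn["sign"][exc] == 1)
        assert np.all(syn["sign"][~exc] == -1)
        assert np.all(syn["weight"][exc] == pytest.approx(0.001))
        assert np.all(syn["weight"][~exc] == pytest.approx(0.01))

    def test_deterministic_ordering(self, small_net):
        a = form_synapses(small_net, record=False)
        b = form_synapses(small_net, record=False)
        assert np.array_equal(a, b)


class TestConnectivityStats:
    def test_all_excitatory_network(self):
        syn = np.zeros(4, dtype=[("pre", int), ("post", int)])
        syn["pre"] = [0, 1, 2, 0]
        syn["post"] = [1, 2, 0, 2]
        st = connectivity_stats(syn, np.array([True, True, True]))
        assert st["mean_pct_excitatory_inputs"] == 100.0

    def test_proportions_normalized_to_ee(self, small_net):
        syn = form_synapses(small_net, record=False)
        st = connectivity_stats(syn, small_net.somata.is_excitatory)
        assert st["proportions"]["EE"] == 1.0
        total = sum(st["totals"].values())
        assert total == len(syn)

    def test_empty_synapse_list_rejected(self):
        with pytest.raises(ValueError):
            connectivity_stats(np.zeros(0, dtype=[("pre", int), ("post", int)]),
                               np.array([True]))


class TestForestIntegrity:
    def test_segment_forest_connected_to_somata(self, small_net):
        """Every alive segment chains back to the soma (parent -1)."""
        gs = small_net
        n = gs.seg.n
        alive = gs.seg.alive[:n]
        parent = gs.seg.parent[:n]
        for sid in np.flatnonzero(alive):
            hops = 0
            cur = sid
            while parent[cur] >= 0 and hops < n:
                cur = parent[cur]
                assert alive[cur], "orphaned segment after retraction"
                hops += 1

    def test_axon_tips_end_above_retraction_trigger(self, small_net):
        from devwta.morphogenesis import STOP_TAPER

        gs = small_net
        ax = (gs.c_kind == 0) & (gs.c_state == STOPPED)
        exc = gs.somata.is_excitatory[gs.c_neuron]
        e_low = 1e-8
        # axon tips that stopped by tapering out (not by retraction back to
        # an anchor) sit in regions above the retraction trigger
        for ev, mask in ((gs._eval_exc, ax & exc), (gs._eval_inh, ax & ~exc)):
            m = mask & (gs.c_stop_reason == STOP_TAPER)
            if m.any():
                c = ev(gs.c_pos[m])
                # the state check precedes the move, so a tip may overshoot
                # the isosurface by at most one step before stopping
                assert np.mean(c >= e_low) > 0.9
                assert np.all(c >= e_low * 1e-3)


class TestExport:
    def test_swc_round_trip_structure(self, small_net):
        txt = export_swc(small_net, 0)
        lines = [l.split() for l in txt.strip().splitlines()]
        assert lines[0][1] == "1"  # soma record
        ids = {int(l[0]) for l in lines}
        for l in lines[1:]:
            assert int(l[6]) in ids  # parent exists
            assert l[1] in ("2", "3")
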