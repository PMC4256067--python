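"""Gene-regulatory-network and lineage tests."""

import math

import numpy as np
import pytest

from devwta.grn import (FateProbabilities, GRNParams, GeneState, LineageTree,
                        calibrate_alpha1, division_probabilities, grn_step,
                        hill_activation, logic_combine, simulate_lineage)


class TestHill:
    def test_no_ligand_no_bias_gives_zero(self):
        assert hill_activation(0.0, K=0.5, n=2, b=0.0) == 0.0

    def test_saturates_at_one(self):
        assert hill_activation(1e6 * 0.5, K=0.5, n=1, b=0.0) == pytest.approx(1.0, abs=1e-6)

    def test_half_activation_at_affinity_constant(self):
        # symbolic evaluation at c=K, n=1, b=0: K / (K + K) = 1/2
        assert hill_activation(0.5, K=0.5, n=1, b=0.0) == pytest.approx(0.5)

    def test_monotone_in_concentration(self):
        c = np.linspace(0, 5, 100)
        v = hill_activation(c, K=0.7, n=3, b=0.1)
        assert np.all(np.diff(v) >= 0)
        assert np.all((v >= 0) & (v <= 1))

    def test_bias_is_basal_binding(self):
        assert hill_activation(0.0, K=1.0, n=2, b=0.2) == pytest.approx(0.2)

    @pytest.mark.parametrize("K,n", [(-1, 2), (0, 2), (1, 0.5)])
    def test_invalid_parameters_rejected(self, K, n):
        with pytest.raises(ValueError):
            hill_activation(1.0, K=K, n=n)


class TestLogic:
    def test_identities(self):
        assert logic_combine("AND", 1.0, 1.0) == 1.0
        assert logic_combine("NOT", 0.0) == 1.0
        # symbolic evaluation: OR(p,q) = p + q - pq at p=q=0.5 -> 0.75
        assert logic_combine("OR", 0.5, 0.5) == pytest.approx(0.75)

    def test_and_below_min_and_double_negation(self):
        for p, q in [(0.3, 0.8), (0.9, 0.9), (0.1, 0.2)]:
            assert logic_combine("AND", p, q) <= min(p, q)
            assert logic_combine("NOT", logic_combine("NOT", p)) == pytest.approx(p)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            logic_combine("AND", 1.5, 0.5)


class TestGrnStep:
    def test_starter_gene_produced_first(self):
        p = GRNParams()
        s = grn_step(GeneState(), p, dt=1e-3)
        assert s.g0 > 0
        assert s.gE == 0 and s.gI == 0

    def test_exponential_decay_matches_closed_form(self):
        # a gene with zero production decays as c * exp(-beta t)
        p = GRNParams(alpha={"g0": 1e-9, "g2": 1e-9, "gE": 1e-9, "gI": 1e-9},
                      beta={"g0": 1.0, "g1": 1.0, "g2": 1.0, "gE": 1.0, "gI": 1.0},
                      alpha1=0.0)
        s = GeneState(g0=1.0)
        beta = 1.0
        dt = 1e-3 / beta
        for _ in range(1000):  # integrate to beta * t = 1
            s = grn_step(s, p, dt)
        assert s.g0 == pytest.approx(math.exp(-1.0), rel=0.01)

    def test_concentrations_never_negative(self):
        p = GRNParams()
        s = GeneState(g0=5.0, g1=0.5, g2=0.2, gE=0.1, gI=0.1)
        for _ in range(200):
            s = grn_step(s, p, dt=1e-2)
            assert min(s.g0, s.g1, s.g2, s.gE, s.gI) >= 0


class TestCalibrateAlpha1:
    def test_crossing_in_requested_cycle(self):
        p = GRNParams()
        a1 = calibrate_alpha1(6, 1.0, p)
        # forward-simulate and find the crossing cycle
        from dataclasses import replace

        q = replace(p, alpha1=a1)
        s = GeneState()
        t, dt = 0.0, 1e-3
        while s.g1 < q.theta_G1:
            s = grn_step(s, q, dt)
            t += dt
        assert 5.0 < t <= 6.0

    def test_degenerate_single_cycle(self):
        p = GRNParams()
        a1 = calibrate_alpha1(1, 1.0, p)
        assert a1 > 0

    def test_doubling_cycle_time_halves_alpha1(self):
        p = GRNParams()
        a1 = calibrate_alpha1(4, 1.0, p)
        a2 = calibrate_alpha1(4, 2.0, p)
        assert a2 == pytest.approx(a1 / 2, rel=0.05)


class TestDivisionProbabilities:
    def test_power_of_two_needs_no_secondary_cycle(self):
        f = division_probabilities(64)
        assert f.n1 == 6 and f.p_secondary == 0.0

    def test_expectation_identity(self):
        # solve 2^n1 * (1 + P2) = n_target for n_target = 100
        f = division_probabilities(100)
        assert f.n1 == 6
        assert f.p_secondary == pytest.approx(0.5625)

    @pytest.mark.parametrize("n_target", [4, 37, 100, 250, 1024])
    def test_expected_count_matches_target(self, n_target):
        f = division_probabilities(n_target)
        assert 2**f.n1 * (1 + f.p_secondary) == pytest.approx(n_target)
        assert 0.0 <= f.p_secondary < 1.0

    def test_too_small_target_rejected(self):
        with pytest.raises(ValueError):
            division_probabilities(1)


class TestLineage:
    def test_deterministic_under_seed(self):
        p = GRNParams()
        f = division_probabilities(20)
        t1 = simulate_lineage(p, f, seed=42)
        t2 = simulate_lineage(p, f, seed=42)
        assert t1.to_json() == t2.to_json()

    def test_pure_symmetric_division(self):
        p = GRNParams()
        f = FateProbabilities(n_target=16, ei_ratio=0.999999, n1=4, p_secondary=0.0)
        t = simulate_lineage(p, f, seed=0)
        leaves = t.leaves
        assert len(leaves) == 16
        assert all(l.fate == "excitatory" for l in leaves)

    def test_tree_structure_invariants(self):
        p = GRNParams()
        f = division_probabilities(50)
        t = simulate_lineage(p, f, seed=1)
        roots = [n for n in t.nodes if n.parent_id is None]
        assert len(roots) == 1
        ids = {n.cell_id for n in t.nodes}
        assert all(n.parent_id in ids for n in t.nodes if n.parent_id is not None)
        children = {}
        for n in t.nodes:
            if n.parent_id is not None:
                children.setdefault(n.parent_id, []).append(n)
        for n in t.nodes:
            kids = children.get(n.cell_id, [])
            assert len(kids) in (0, 2)
            if not kids:
                assert n.fate in ("excitatory", "inhibitory")

    def test_count_distribution_matches_binomial_mixture(self):
        # total leaves = 2^n1 + Binomial(2^n1, p_secondary)
        p = GRNParams()
        f = division_probabilities(100)
        totals = []
        for s in range(2000):
            ne, ni = simulate_lineage(p, f, seed=s).counts()
            totals.append(ne + ni)
        totals = np.array(totals)
        base = 2**f.n1
        mean_expect = base * (1 + f.p_secondary)
        var_expect = base * f.p_secondary * (1 - f.p_secondary)
        se = math.sqrt(var_expect / len(totals))
        assert abs(totals.mean() - mean_expect) < 3 * se
        assert totals.var() == pytest.approx(var_expect, rel=0.2)

    def test_excitatory_fraction_unbiased(self):
        p = GRNParams()
        f = division_probabilities(64, ei_ratio=0.8)
        n_e = n_tot = 0
        for s in range(300):
            ne, ni = simulate_lineage(p, f, seed=s).counts()
            n_e += ne
            n_tot += ne + ni
        se = math.sqrt(0.8 * 0.2 / n_tot)
        assert abs(n_e / n_tot - 0.8) < 3 * se

    def test_newick_export_parses(self):
        import io

        from Bio import Phylo

        p = GRNParams()
        t = simulate_lineage(p, division_probabilities(16), seed=3)
        tree = Phylo.read(io.StringIO(t.to_newick()), "newick")
        assert tree.count_terminals() == len(t.leaves)
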