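"""Pruning likelihoods under GTR+I+G and the SH topology test."""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from mitoconcord import (
    Alignment,
    SubstitutionModel,
    parse_newick,
    sh_test,
    site_log_likelihoods,
)
from mitoconcord.likelihood import (
    gamma_category_rates,
    optimize_branch_lengths,
    total_log_likelihood,
)

from conftest import random_tree


class TestGammaDiscretization:
    def test_single_class_without_shape(self):
        assert gamma_category_rates(None, 4).tolist() == [1.0]

    @pytest.mark.parametrize("shape,k", [(0.3, 4), (0.7, 4), (2.0, 8)])
    def test_mean_one_and_increasing(self, shape, k):
        rates = gamma_category_rates(shape, k)
        assert len(rates) == k
        assert rates.mean() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(rates) > 0)

    def test_small_shape_is_more_dispersed(self):
        r_small = gamma_category_rates(0.2, 4)
        r_large = gamma_category_rates(5.0, 4)
        assert r_small.std() > r_large.std()


class TestSiteLikelihoods:
    def test_zero_branch_identical_bases_gives_stationary_frequency(self):
        model = SubstitutionModel(base_freqs=(0.4, 0.3, 0.2, 0.1))
        aln = Alignment(taxa=["A", "B"], sequences=["C", "C"])
        tree = parse_newick("(A:0,B:0);")
        lnl = site_log_likelihoods(aln, tree, model)
        assert lnl[0] == pytest.approx(np.log(0.3))

    @pytest.mark.parametrize("t", [0.02, 0.1, 0.5, 2.0])
    def test_jc_two_taxon_closed_form(self, t, jc_model):
        aln = Alignment(taxa=["A", "B"], sequences=["AG", "AC"])
        tree = parse_newick(f"(A:{t / 2},B:{t / 2});")
        lnl = site_log_likelihoods(aln, tree, jc_model)
        p_same = 0.25 + 0.75 * np.exp(-4.0 * t / 3.0)
        p_diff = 0.25 - 0.25 * np.exp(-4.0 * t / 3.0)
        assert lnl[0] == pytest.approx(np.log(0.25 * p_same), abs=1e-10)
        assert lnl[1] == pytest.approx(np.log(0.25 * p_diff), abs=1e-10)

    def test_sites_sum_to_total(self, gtr_model):
        tree = random_tree(6, seed=31, height=0.4)
        from mitoconcord import SimulationConfig, evolve_alignment

        cfg = SimulationConfig(seed=31, n_taxa=6, partition_spec={"g": 200}, tree_height_scale=0.4)
        aln = evolve_alignment(tree, cfg)
        lnl = site_log_likelihoods(aln, tree, gtr_model)
        assert lnl.sum() == pytest.approx(total_log_likelihood(aln, tree, gtr_model))

    def test_matches_exhaustive_state_sum(self, gtr_model):
        # unrooted 4-taxon tree: 6 nodes, 2 internal; brute-force over 16
        # internal state assignments with scipy matrix exponentials
        tree = parse_newick("((A:0.1,B:0.3):0.2,(C:0.15,D:0.4):0.0);")
        aln = Alignment(taxa=list("ABCD"), sequences=["ACGTN", "ACTT-", "GCGTA", "ACGAC"])
        model = gtr_model
        q = model.rate_matrix()
        pi = np.array(model.base_freqs)
        rates = model.category_rates()
        weights = [(1 - model.p_invariant) / len(rates)] * len(rates) + [model.p_invariant]
        all_rates = list(rates) + [0.0]
        from mitoconcord.alignment import IUPAC

        def leaf_ok(ch, state):
            return "ACGT"[state] in IUPAC[ch]

        lnl = site_log_likelihoods(aln, tree, model)
        # topology: ((A,B)x,(C,D)y) with root at x implicitly; enumerate x, y
        bl = {"A": 0.1, "B": 0.3, "C": 0.15, "D": 0.4, "x": 0.2, "y": 0.0}
        for site in range(aln.length):
            chars = {t: aln.sequences[i][site] for i, t in enumerate(aln.taxa)}
            total = 0.0
            for w, r in zip(weights, all_rates):
                p = {k: expm(q * (v * r)) for k, v in bl.items()}
                lik = 0.0
                # sum over states at both internal nodes (x, y) and the seed (z)
                for x, y in itertools.product(range(4), repeat=2):
                    la = sum(p["A"][x, a] for a in range(4) if leaf_ok(chars["A"], a))
                    lb = sum(p["B"][x, b] for b in range(4) if leaf_ok(chars["B"], b))
                    lc = sum(p["C"][y, c] for c in range(4) if leaf_ok(chars["C"], c))
                    ld = sum(p["D"][y, d] for d in range(4) if leaf_ok(chars["D"], d))
                    for z in range(4):
                        lik += pi[z] * p["x"][z, x] * p["y"][z, y] * la * lb * lc * ld
                total += w * lik
            assert lnl[site] == pytest.approx(np.log(total), abs=1e-8)

    def test_invariant_under_rerooting(self, gtr_model):
        from mitoconcord import PhyloTree, SimulationConfig, evolve_alignment

        tree = random_tree(7, seed=33, height=0.4)
        cfg = SimulationConfig(seed=33, n_taxa=7, partition_spec={"g": 150}, tree_height_scale=0.4)
        aln = evolve_alignment(tree, cfg)
        before = total_log_likelihood(aln, tree, gtr_model)
        dt = tree.copy().dendropy_tree
        edge = [lf for lf in dt.leaf_node_iter()][3].edge
        dt.reroot_at_edge(edge, length1=edge.length / 2, length2=edge.length / 2)
        after = total_log_likelihood(aln, PhyloTree(dt), gtr_model)
        assert after == pytest.approx(before, abs=1e-6)

    def test_missing_branch_lengths_error(self, jc_model):
        aln = Alignment(taxa=list("ABCD"), sequences=["A", "A", "C", "C"])
        with pytest.raises(ValueError, match="branch length"):
            site_log_likelihoods(aln, parse_newick("((A,B),(C,D));"), jc_model)

    def test_taxa_mismatch_error(self, jc_model):
        aln = Alignment(taxa=list("ABCE"), sequences=["A", "A", "C", "C"])
        with pytest.raises(ValueError, match="mismatch"):
            site_log_likelihoods(
                aln, parse_newick("((A:1,B:1):1,(C:1,D:1):1);"), jc_model
            )


class TestBranchOptimization:
    def test_monotone_improvement_and_fixed_point(self, jc_model):
        from mitoconcord import SimulationConfig, evolve_alignment

        cfg = SimulationConfig(
            seed=35, n_taxa=5, partition_spec={"g": 500},
            model=SubstitutionModel(), tree_height_scale=0.3,
        )
        rng = np.random.default_rng(35)
        from mitoconcord import simulate_tree

        truth = simulate_tree(cfg, rng)
        aln = evolve_alignment(truth, cfg, rng)
        start = truth.copy()
        for nd in start.dendropy_tree.preorder_node_iter():
            if nd.edge.length is not None:
                nd.edge.length = 0.05  # deliberately wrong start
        before = total_log_likelihood(aln, start, jc_model)
        opt, lnl = optimize_branch_lengths(aln, start, jc_model, tol=1e-4)
        assert lnl >= before
        opt2, lnl2 = optimize_branch_lengths(aln, opt, jc_model, tol=1e-4)
        assert abs(lnl2 - lnl) < 1e-2

    def test_recovers_simulated_branch_lengths(self):
        from mitoconcord import SimulationConfig, evolve_alignment

        model = SubstitutionModel()
        tree = parse_newick("((A:0.12,B:0.3):0.08,(C:0.2,D:0.05):0.0);")
        cfg = SimulationConfig(seed=37, n_taxa=4, partition_spec={"g": 50000}, model=model)
        aln = evolve_alignment(tree, cfg)
        opt, _ = optimize_branch_lengths(aln, tree, model, tol=1e-4)
        true_bl = {"A": 0.12, "B": 0.3, "C": 0.2, "D": 0.05}
        for lf in opt.dendropy_tree.leaf_node_iter():
            label = lf.taxon.label
            assert lf.edge.length == pytest.approx(true_bl[label], rel=0.10, abs=0.01)


class TestSHTest:
    def _fixture(self, seed=41, n_taxa=6, sites=300):
        from mitoconcord import SimulationConfig, evolve_alignment, simulate_tree

        model = SubstitutionModel(gamma_shape=0.7, n_categories=4)
        cfg = SimulationConfig(
            seed=seed, n_taxa=n_taxa, partition_spec={"g": sites},
            model=model, tree_height_scale=0.4,
        )
        rng = np.random.default_rng(seed)
        tree = simulate_tree(cfg, rng)
        aln = evolve_alignment(tree, cfg, rng)
        return tree, aln, model

    def test_identical_topologies_both_p_one(self):
        tree, aln, model = self._fixture()
        res = sh_test(
            aln, {"a": tree, "b": tree.copy()}, model,
            n_replicates=200, seed=3,
        )
        assert np.allclose(res.p_values, 1.0)

    def test_best_tree_has_p_one_and_deterministic(self):
        from mitoconcord import nni_neighbor

        tree, aln, model = self._fixture(seed=43)
        cands = {"true": tree, "alt": nni_neighbor(tree)}
        r1 = sh_test(aln, cands, model, n_replicates=300, seed=9)
        r2 = sh_test(aln, cands, model, n_replicates=300, seed=9)
        assert np.array_equal(r1.p_values, r2.p_values)
        best = int(np.argmax(r1.log_likelihoods))
        assert r1.p_values[best] == 1.0
        assert np.all(np.diff(r1.p_values[np.argsort(r1.deltas)]) <= 1e-12)

    def test_replicate_floor_enforced(self):
        tree, aln, model = self._fixture()
        with pytest.raises(ValueError, match="replicates"):
            sh_test(aln, {"a": tree, "b": tree.copy()}, model, n_replicates=50, seed=1)
        res = sh_test(
            aln, {"a": tree, "b": tree.copy()}, model,
            n_replicates=50, seed=1, allow_few_replicates=True,
        )
        assert res.n_replicates == 50
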