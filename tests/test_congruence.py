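"""RF distances, NJ on distance matrices, and concordance factors."""

import dendropy
import numpy as np
import pytest

from mitoconcord import (
    Alignment,
    Bipartition,
    PhyloTree,
    TreeDistanceMatrix,
    gene_concordance_factor,
    make_concordance_fixture,
    neighbor_joining,
    nontrivial_bipartitions,
    parse_newick,
    rf_distance,
    rf_matrix,
    site_concordance_factor,
    write_newick,
)
from mitoconcord.congruence import annotate_reference

from conftest import random_tree


def dendropy_rf(t1: PhyloTree, t2: PhyloTree) -> int:
    """Independent oracle: dendropy's bipartition-based symmetric difference."""
    ns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(data=write_newick(t1), schema="newick", taxon_namespace=ns)
    b = dendropy.Tree.get(data=write_newick(t2), schema="newick", taxon_namespace=ns)
    a.encode_bipartitions()
    b.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(a, b)


def additive_matrix(tree: PhyloTree) -> TreeDistanceMatrix:
    """Patristic leaf-to-leaf distances of a tree (via dendropy path lengths)."""
    dt = tree.dendropy_tree
    pdm = dt.phylogenetic_distance_matrix()
    labels = sorted(tree.leaf_labels)
    taxa = {t.label: t for t in dt.taxon_namespace}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
    return TreeDistanceMatrix(labels=labels, values=d)


class TestRFDistance:
    def test_self_distance_zero(self):
        t = random_tree(15, seed=4)
        assert rf_distance(t, t.copy()) == 0

    def test_four_taxon_conflict(self):
        a = parse_newick("((A,B),(C,D));")
        b = parse_newick("((A,C),(B,D));")
        assert rf_distance(a, b) == 2

    def test_leaf_set_mismatch_reports_difference(self):
        a = parse_newick("((A,B),(C,D));")
        b = parse_newick("((A,B),(C,E));")
        with pytest.raises(ValueError, match="E"):
            rf_distance(a, b)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_dendropy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        a, b = random_tree(n, seed=seed), random_tree(n, seed=seed + 1000)
        assert rf_distance(a, b) == dendropy_rf(a, b)

    @pytest.mark.parametrize("seed", range(10))
    def test_metric_properties(self, seed):
        n = 4 + seed % 7
        trees = [random_tree(n, seed=seed * 3 + k) for k in range(3)]
        a, b, c = trees
        assert rf_distance(a, b) == rf_distance(b, a)
        assert rf_distance(a, a.copy()) == 0
        assert rf_distance(a, c) <= rf_distance(a, b) + rf_distance(b, c)
        assert rf_distance(a, b) <= 2 * (n - 3)


class TestRFMatrix:
    def test_identical_trees_all_zero(self):
        t = random_tree(8, seed=5)
        m = rf_matrix({"a": t, "b": t.copy(), "c": t.copy()})
        assert np.all(m.values == 0)

    def test_rows_consistent_with_pairwise_calls(self):
        trees = {f"g{k}": random_tree(9, seed=50 + k) for k in range(4)}
        m = rf_matrix(trees)
        names = list(trees)
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                assert m.values[i, j] == rf_distance(trees[a], trees[b])


class TestNeighborJoining:
    def test_additive_four_taxon_exact(self):
        # distances from ((A:1,B:2):1,(C:3,D:4))
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
        )
        tree = neighbor_joining(TreeDistanceMatrix(labels=list("ABCD"), values=d))
        assert nontrivial_bipartitions(tree) == {
            Bipartition(frozenset("AB"), frozenset("CD"))
        }
        lengths = {
            nd.taxon.label: nd.edge.length
            for nd in tree.dendropy_tree.leaf_node_iter()
        }
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}

    def test_three_taxon_base_case(self):
        d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
        tree = neighbor_joining(TreeDistanceMatrix(labels=list("ABC"), values=d))
        assert tree.leaf_set == {"A", "B", "C"}
        total = {
            nd.taxon.label: nd.edge.length
            for nd in tree.dendropy_tree.leaf_node_iter()
        }
        assert total["A"] + total["B"] == pytest.approx(2.0)

    def test_asymmetric_input_rejected(self):
        d = np.array([[0, 1, 2], [1.5, 0, 2], [2, 2, 0]])
        with pytest.raises(ValueError):
            neighbor_joining(TreeDistanceMatrix(labels=list("ABC"), values=d))

    @pytest.mark.parametrize("seed", range(15))
    def test_recovers_generating_topology_from_additive_matrix(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        truth = random_tree(n, seed=seed + 300)
        est = neighbor_joining(additive_matrix(truth))
        assert rf_distance(truth, est) == 0

    def test_agrees_with_scikit_bio_on_generic_matrix(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(77)
        n = 8
        base = rng.uniform(0.5, 2.0, size=(n, n))
        d = (base + base.T) / 2
        np.fill_diagonal(d, 0)
        labels = [f"t{i}" for i in range(n)]
        mine = neighbor_joining(TreeDistanceMatrix(labels=labels, values=d))
        theirs = skbio.tree.nj(skbio.DistanceMatrix(d, ids=labels))
        other = parse_newick(str(theirs).strip())
        assert rf_distance(mine, other) == 0


class TestGeneConcordance:
    def test_worked_fractions(self):
        ref = random_tree(12, seed=7)
        branch = sorted(nontrivial_bipartitions(ref), key=repr)[0]
        for frac, expected in [(5 / 15, 33.3), (8 / 15, 53.3)]:
            trees = make_concordance_fixture(ref, {branch: frac}, n_trees=15, seed=11)
            gcf = {a.branch: a.gcf for a in gene_concordance_factor(ref, trees)}
            assert round(gcf[branch], 1) == expected

    def test_reference_copies_give_100_everywhere(self):
        ref = random_tree(10, seed=8)
        anns = gene_concordance_factor(ref, [ref.copy() for _ in range(6)])
        assert all(a.gcf == 100.0 for a in anns)
        assert all(a.n_decisive_trees == 6 for a in anns)

    def test_no_gene_trees_is_an_error(self):
        with pytest.raises(ValueError):
            gene_concordance_factor(random_tree(6, seed=1), [])

    def test_missing_taxa_restriction(self):
        ref = random_tree(10, seed=13)
        pruned = []
        for k in range(4):
            dt = ref.copy().dendropy_tree
            keep = [t for t in dt.taxon_namespace if t.label != f"t{k + 1}"]
            dt = dt.extract_tree_with_taxa(taxa=keep)
            pruned.append(parse_newick(dt.as_string(schema="newick").strip()))
        anns = gene_concordance_factor(ref, pruned)
        # restricted splits of the reference are present in every pruned copy
        for a in anns:
            if a.n_decisive_trees:
                assert a.gcf == 100.0

    def test_collapsing_one_branch_leaves_others_unchanged(self):
        ref = random_tree(10, seed=21)
        genes = [random_tree(10, seed=400 + k) for k in range(5)]
        before = {a.branch: a.gcf for a in gene_concordance_factor(ref, genes)}
        collapsed = ref.copy()
        victim = sorted(
            collapsed.internal_nodes(exclude_root=True),
            key=lambda nd: sorted(lf.taxon.label for lf in nd.leaf_iter())[0],
        )[0]
        victim.edge.collapse()
        after = {a.branch: a.gcf for a in gene_concordance_factor(collapsed, genes)}
        for branch, value in after.items():
            assert before[branch] == value


class TestSiteConcordance:
    def _quartet_alignment(self, pattern_counts):
        """4-taxon alignment from counts of (AABB, ABAB, ABBA) site patterns."""
        cols = (
            [("A", "A", "C", "C")] * pattern_counts[0]
            + [("A", "C", "A", "C")] * pattern_counts[1]
            + [("A", "C", "C", "A")] * pattern_counts[2]
        )
        seqs = ["".join(col[i] for col in cols) for i in range(4)]
        return Alignment(taxa=["A", "B", "C", "D"], sequences=seqs)

    def test_all_sites_support_reference(self):
        ref = parse_newick("((A,B),(C,D));")
        aln = self._quartet_alignment((50, 0, 0))
        anns = site_concordance_factor(ref, aln, n_quartets=10, seed=1)
        assert anns[0].scf == 100.0

    def test_balanced_patterns_give_one_third(self):
        ref = parse_newick("((A,B),(C,D));")
        aln = self._quartet_alignment((40, 40, 40))
        anns = site_concordance_factor(ref, aln, n_quartets=10, seed=1)
        assert anns[0].scf == pytest.approx(100.0 / 3.0, abs=1e-9)

    def test_fixed_seed_reproducible(self):
        from mitoconcord import SimulationConfig, evolve_alignment, simulate_tree

        cfg = SimulationConfig(seed=14, n_taxa=9, partition_spec={"g": 800}, tree_height_scale=0.5)
        rng = np.random.default_rng(14)
        tree = simulate_tree(cfg, rng)
        aln = evolve_alignment(tree, cfg, rng)
        a = site_concordance_factor(tree, aln, n_quartets=30, seed=5)
        b = site_concordance_factor(tree, aln, n_quartets=30, seed=5)
        assert [x.scf for x in a] == [x.scf for x in b]

    def test_annotated_newick_carries_factors(self):
        ref = random_tree(8, seed=15)
        genes = [ref.copy() for _ in range(3)]
        anns = gene_concordance_factor(ref, genes)
        annotated = annotate_reference(ref, anns)
        text = write_newick(annotated)
        assert "gcf=100.00" in text
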