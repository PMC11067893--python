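"""Topological congruence between gene trees and a reference tree.

Implements the unweighted Robinson–Foulds distance (symmetric difference of
nontrivial splits), pairwise RF matrices over named tree sets, Saitou–Nei
neighbour joining on tree-distance matrices (the dendrogram-of-topologies
construction), and gene / site concordance factors annotated onto the
reference tree's internal branches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
import numpy as np

from .alignment import Alignment
from .treeio import Bipartition, PhyloTree, nontrivial_bipartitions

logger = logging.getLogger(__name__)

__all__ = [
    "TreeDistanceMatrix",
    "ConcordanceAnnotation",
    "rf_distance",
    "rf_matrix",
    "neighbor_joining",
    "gene_concordance_factor",
    "site_concordance_factor",
    "annotate_reference",
]


@dataclass
class TreeDistanceMatrix:
    """Symmetric matrix of pairwise distances between named trees."""

    labels: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for label, row in zip(self.labels, self.values):
                fh.write(f"{label}  " + " ".join(f"{v:g}" for v in row) + "\n")


@dataclass
class ConcordanceAnnotation:
    """Concordance factors for one internal branch of the reference tree.

    gcf: percent of decisive gene trees containing the branch.
    scf: mean percent of decisive sites supporting the branch's quartet
    topology, over sampled quartets (None until computed).
    """

    branch: Bipartition
    gcf: Optional[float] = None
    scf: Optional[float] = None
    n_gene_trees: int = 0
    n_decisive_trees: int = 0
    n_quartets_sampled: int = 0
    n_decisive_quartets: int = 0


def _check_leaf_sets(t1: PhyloTree, t2: PhyloTree) -> None:
    s1, s2 = t1.leaf_set, t2.leaf_set
    if s1 != s2:
        only1, only2 = sorted(s1 - s2), sorted(s2 - s1)
        raise ValueError(
            f"leaf sets differ: only in first {only1}; only in second {only2}"
        )


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> int:
    """Unweighted Robinson–Foulds distance.

    The cardinality of the symmetric difference between the two trees'
    nontrivial bipartition sets after unrooting. Zero iff the unrooted
    topologies agree; at most 2(n-3) for two fully resolved trees.
    """
    _check_leaf_sets(t1, t2)
    return len(nontrivial_bipartitions(t1) ^ nontrivial_bipartitions(t2))


def rf_matrix(trees: Dict[str, PhyloTree]) -> TreeDistanceMatrix:
    """Pairwise RF distances over a named set of trees sharing one leaf set."""
    if len(trees) < 2:
        raise ValueError("need at least two trees")
    labels = list(trees)
    splits = {name: nontrivial_bipartitions(t) for name, t in trees.items()}
    ref = labels[0]
    for name in labels[1:]:
        _check_leaf_sets(trees[ref], trees[name])
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = len(splits[labels[i]] ^ splits[labels[j]])
    return TreeDistanceMatrix(labels=labels, values=d)


def neighbor_joining(dist: TreeDistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbour joining with the Studier–Keppler Q-criterion.

    Exact on additive matrices. Ties in Q are broken at the lowest (row,
    column) index pair, so output is deterministic. Negative estimated branch
    lengths are clamped to zero with the total deficit logged. The result is
    unrooted (trifurcating seed node).
    """
    n = len(dist.labels)
    if n < 3:
        raise ValueError("need at least three labels")
    if not np.all(np.isfinite(dist.values)):
        raise ValueError("distance matrix contains non-finite entries")

    taxa = dendropy.TaxonNamespace(dist.labels)
    nodes = []
    for label in dist.labels:
        nd = dendropy.Node()
        nd.taxon = taxa.get_taxon(label)
        nodes.append(nd)
    d = dist.values.astype(float).copy()
    active = list(range(n))
    clamped = 0.0

    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_, j_ = np.unravel_index(np.argmin(q), q.shape)  # row-major => lowest (i, j) on ties
        if i_ > j_:
            i_, j_ = j_, i_
        gi, gj = active[i_], active[j_]
        dij = sub[i_, j_]
        li = 0.5 * dij + (r[i_] - r[j_]) / (2.0 * (m - 2))
        lj = dij - li
        for val, child in ((li, nodes[gi]), (lj, nodes[gj])):
            if val < 0:
                clamped += -val
                val = 0.0
            child.edge.length = float(val)
        parent = dendropy.Node()
        parent.add_child(nodes[gi])
        parent.add_child(nodes[gj])
        nodes.append(parent)
        gk = len(nodes) - 1
        # grow the matrix with the new cluster's distances
        new_row = np.zeros(gk + 1)
        for other in active:
            if other in (gi, gj):
                continue
            new_row[other] = 0.5 * (d[gi, other] + d[gj, other] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[gk, : gk] = new_row[:gk]
        d[: gk, gk] = new_row[:gk]
        active = [a for a in active if a not in (gi, gj)] + [gk]

    ga, gb = active
    final = max(0.0, d[ga, gb])
    # join the last two clusters on a single edge; make the seed trifurcating
    a, b = nodes[ga], nodes[gb]
    if b.child_nodes():
        a, b = b, a  # prefer an internal node as the seed
    if a.child_nodes():
        a.add_child(b)
        b.edge.length = final
        seed = a
    else:  # n == 3 star fallback: both leaves
        seed = dendropy.Node()
        seed.add_child(a)
        seed.add_child(b)
        a.edge.length = final / 2
        b.edge.length = final / 2
    if clamped > 0:
        logger.info("neighbor_joining clamped %.6g of negative branch length", clamped)
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=seed)
    return PhyloTree(tree, rooted=False)


def gene_concordance_factor(
    reference: PhyloTree, gene_trees: Sequence[PhyloTree]
) -> List[ConcordanceAnnotation]:
    """Percent of gene trees containing each internal branch of the reference.

    A gene tree missing taxa is restricted to its own leaf set: it is decisive
    for a branch only when both sides of the restricted split retain at least
    two leaves, and supports it when that restricted split is among its own
    splits. With complete taxon overlap every gene tree is decisive for every
    branch.
    """
    gene_trees = list(gene_trees)
    if not gene_trees:
        raise ValueError("no gene trees supplied")
    gene_splits = [
        (t.leaf_set, nontrivial_bipartitions(t)) for t in gene_trees
    ]
    annotations = []
    for branch in sorted(nontrivial_bipartitions(reference), key=repr):
        decisive = supporting = 0
        for leaves, splits in gene_splits:
            restricted = branch.restricted(leaves)
            if restricted is None or not restricted.is_nontrivial:
                continue
            decisive += 1
            if restricted in splits:
                supporting += 1
        gcf = 100.0 * supporting / decisive if decisive else None
        annotations.append(
            ConcordanceAnnotation(
                branch=branch,
                gcf=gcf,
                n_gene_trees=len(gene_trees),
                n_decisive_trees=decisive,
            )
        )
    return annotations


def _unrooted_adjacency(tree: PhyloTree) -> Tuple[dict, dict]:
    """Adjacency of the unrooted tree (degree-2 root suppressed) and leaf names."""
    adj: dict = {}
    leaf_name: dict = {}
    for nd in tree.dendropy_tree.preorder_node_iter():
        adj.setdefault(id(nd), set())
        if nd.is_leaf():
            leaf_name[id(nd)] = nd.taxon.label
        for child in nd.child_nodes():
            adj[id(nd)].add(id(child))
            adj.setdefault(id(child), set()).add(id(nd))
    root = tree.dendropy_tree.seed_node
    kids = root.child_nodes()
    if len(kids) == 2:  # suppress the rooting node
        a, b = id(kids[0]), id(kids[1])
        adj[a].discard(id(root))
        adj[b].discard(id(root))
        adj[a].add(b)
        adj[b].add(a)
        del adj[id(root)]
    return adj, leaf_name


def _component_leaves(adj, leaf_name, start, blocked) -> list:
    seen, stack, leaves = {start, blocked}, [start], []
    while stack:
        nd = stack.pop()
        if nd in leaf_name:
            leaves.append(leaf_name[nd])
        for nb in adj[nd]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return leaves


def site_concordance_factor(
    reference: PhyloTree,
    aln: Alignment,
    n_quartets: int = 100,
    seed: int = 0,
) -> List[ConcordanceAnnotation]:
    """Site concordance factors by seeded quartet sampling.

    For each internal branch, ``n_quartets`` quartets are drawn — one leaf
    uniformly from each of the four subtrees surrounding the branch. A column
    is decisive for a quartet when all four leaves carry unambiguous bases
    forming a clean two-state 2+2 pattern; it then supports exactly one of the
    three quartet topologies. sCF is the mean, over decisive quartets, of the
    percentage of decisive sites siding with the reference topology.
    """
    missing = reference.leaf_set - set(aln.taxa)
    if missing:
        raise ValueError(f"alignment lacks taxa {sorted(missing)}")
    rng = np.random.default_rng(seed)
    codes = aln.base_codes()
    row = {t: i for i, t in enumerate(aln.taxa)}
    adj, leaf_name = _unrooted_adjacency(reference)

    annotations = []
    # deterministic branch order: sort internal edges by their split repr
    internal_edges = []
    for u, nbs in adj.items():
        for v in nbs:
            if u < v and u not in leaf_name and v not in leaf_name:
                internal_edges.append((u, v))
    keyed = []
    for u, v in internal_edges:
        below = _component_leaves(adj, leaf_name, u, v)
        rest = _component_leaves(adj, leaf_name, v, u)
        branch = Bipartition(frozenset(below), frozenset(rest))
        keyed.append((repr(branch), u, v, branch))
    keyed.sort()

    global_min = min(leaf_name.values())
    for _, u, v, branch in keyed:
        # orient and order everything by leaf content so runs are reproducible
        if global_min in _component_leaves(adj, leaf_name, v, u):
            u, v = v, u
        u_subtrees = sorted(
            (sorted(_component_leaves(adj, leaf_name, nb, u)) for nb in adj[u] - {v}),
            key=lambda leaves: leaves[0],
        )
        v_subtrees = sorted(
            (sorted(_component_leaves(adj, leaf_name, nb, v)) for nb in adj[v] - {u}),
            key=lambda leaves: leaves[0],
        )
        if len(u_subtrees) < 2 or len(v_subtrees) < 2:
            logger.info("sCF: branch %r skipped (fewer than four surrounding subtrees)", branch)
            annotations.append(
                ConcordanceAnnotation(branch=branch, n_quartets_sampled=0)
            )
            continue
        ratios = []
        for _ in range(n_quartets):
            if len(u_subtrees) > 2:
                ia, ib = rng.choice(len(u_subtrees), size=2, replace=False)
            else:
                ia, ib = 0, 1
            if len(v_subtrees) > 2:
                ja, jb = rng.choice(len(v_subtrees), size=2, replace=False)
            else:
                ja, jb = 0, 1
            quartet = [
                u_subtrees[ia][rng.integers(len(u_subtrees[ia]))],
                u_subtrees[ib][rng.integers(len(u_subtrees[ib]))],
                v_subtrees[ja][rng.integers(len(v_subtrees[ja]))],
                v_subtrees[jb][rng.integers(len(v_subtrees[jb]))],
            ]
            b1, b2, b3, b4 = (codes[row[t]] for t in quartet)
            ok = (b1 != 255) & (b2 != 255) & (b3 != 255) & (b4 != 255)
            c1, c2, c3, c4 = b1[ok], b2[ok], b3[ok], b4[ok]
            ref_sites = int(((c1 == c2) & (c3 == c4) & (c1 != c3)).sum())
            alt1 = int(((c1 == c3) & (c2 == c4) & (c1 != c2)).sum())
            alt2 = int(((c1 == c4) & (c2 == c3) & (c1 != c2)).sum())
            total = ref_sites + alt1 + alt2
            if total > 0:
                ratios.append(100.0 * ref_sites / total)
        annotations.append(
            ConcordanceAnnotation(
                branch=branch,
                scf=float(np.mean(ratios)) if ratios else None,
                n_quartets_sampled=n_quartets,
                n_decisive_quartets=len(ratios),
            )
        )
    return annotations


def annotate_reference(
    reference: PhyloTree, annotations: Sequence[ConcordanceAnnotation]
) -> PhyloTree:
    """Copy of the reference with gCF/sCF attached as node comments."""
    by_branch = {a.branch: a for a in annotations}
    tree = reference.copy()
    all_leaves = tree.leaf_set
    for nd in tree.internal_nodes(exclude_root=True):
        below = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        rest = all_leaves - below
        if len(below) < 2 or len(rest) < 2:
            continue
        ann = by_branch.get(Bipartition(below, rest))
        if ann is None:
            continue
        parts = []
        if ann.gcf is not None:
            parts.append(f"gcf={ann.gcf:.2f}")
        if ann.scf is not None:
            parts.append(f"scf={ann.scf:.2f}")
        if parts:
            nd.comments.append("&" + ",".join(parts))
    return tree
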