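"""Support-annotated phylogenetic trees: parsing, writing and topology metrics.

Trees are thin wrappers around :class:`dendropy.Tree`. Node support values
(posterior probabilities or bootstrap percentages) are kept in the internal
node *label*, the consensus-tree convention of MrBayes and IQ-TREE, so that
they survive cloning and round-trip through Newick unchanged.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Optional

import dendropy

__all__ = [
    "Bipartition",
    "PhyloTree",
    "NewickParseError",
    "NoSupportedNodesError",
    "parse_newick",
    "read_tree",
    "write_newick",
    "nontrivial_bipartitions",
    "count_polytomy_branches",
    "count_bifurcating_nodes",
    "mean_node_support",
]


class NewickParseError(ValueError):
    """Raised when a tree string cannot be parsed under the declared convention."""


class NoSupportedNodesError(ValueError):
    """Raised when a support summary is requested for a tree with no annotated nodes."""


@dataclass(frozen=True)
class Bipartition:
    """A split of the leaf set induced by one internal edge of an unrooted tree.

    ``side_a`` and ``side_b`` are disjoint, non-empty and together cover the
    leaf set. Equality and hashing ignore which side is listed first.
    """

    side_a: frozenset
    side_b: frozenset

    def __post_init__(self):
        if not self.side_a or not self.side_b:
            raise ValueError("both sides of a bipartition must be non-empty")
        if self.side_a & self.side_b:
            raise ValueError("bipartition sides must be disjoint")

    @property
    def canonical_key(self) -> frozenset:
        return frozenset((self.side_a, self.side_b))

    @property
    def is_nontrivial(self) -> bool:
        return len(self.side_a) >= 2 and len(self.side_b) >= 2

    def restricted(self, leaves: frozenset) -> Optional["Bipartition"]:
        """Restrict to a leaf subset; ``None`` if either side empties out."""
        a, b = self.side_a & leaves, self.side_b & leaves
        if not a or not b:
            return None
        return Bipartition(a, b)

    def __eq__(self, other):
        if not isinstance(other, Bipartition):
            return NotImplemented
        return self.canonical_key == other.canonical_key

    def __hash__(self):
        return hash(self.canonical_key)

    def __repr__(self):
        fmt = lambda s: ",".join(sorted(s))
        a, b = sorted((self.side_a, self.side_b), key=lambda s: sorted(s)[0])
        return f"{fmt(a)}|{fmt(b)}"


class PhyloTree:
    """A rooted or unrooted tree with optional branch lengths and node supports."""

    def __init__(self, tree: dendropy.Tree, rooted: bool = True):
        self._tree = tree
        self.rooted = rooted

    # -- structure accessors -------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def leaf_labels(self) -> list:
        return [lf.taxon.label for lf in self._tree.leaf_node_iter()]

    @property
    def leaf_set(self) -> frozenset:
        return frozenset(self.leaf_labels)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def internal_nodes(self, exclude_root: bool = False) -> Iterator[dendropy.Node]:
        root = self._tree.seed_node
        for nd in self._tree.preorder_node_iter():
            if nd.is_leaf():
                continue
            if exclude_root and nd is root:
                continue
            yield nd

    @staticmethod
    def node_support(node: dendropy.Node) -> Optional[float]:
        if node.is_leaf() or node.label is None or node.label == "":
            return None
        try:
            return float(node.label)
        except ValueError:
            return None

    @property
    def support_scale(self) -> Optional[str]:
        """'probability' if all supports lie in [0, 1], else 'bootstrap'; None if unannotated."""
        supports = [s for nd in self.internal_nodes() if (s := self.node_support(nd)) is not None]
        if not supports:
            return None
        return "probability" if max(supports) <= 1.0 else "bootstrap"

    def copy(self) -> "PhyloTree":
        return PhyloTree(self._tree.clone(depth=1), rooted=self.rooted)

    def __repr__(self):
        return f"PhyloTree(n_leaves={self.n_leaves}, rooted={self.rooted})"


_NEWICK_META = re.compile(r"[\s()\[\]{}:;,']")


def _format_label(label: str) -> str:
    if _NEWICK_META.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _node_to_newick(node: dendropy.Node, out: list) -> None:
    if node.is_leaf():
        out.append(_format_label(node.taxon.label))
    else:
        out.append("(")
        for i, child in enumerate(node.child_nodes()):
            if i:
                out.append(",")
            _node_to_newick(child, out)
        out.append(")")
        if node.label not in (None, ""):
            out.append(_format_label(str(node.label)))
    for comment in node.comments or []:
        out.append(f"[{comment}]")
    if node.edge.length is not None:
        out.append(f":{node.edge.length:.10g}")


def write_newick(tree: PhyloTree) -> str:
    """Serialise with supports as internal-node labels; round-trips with parse_newick."""
    out: list = []
    _node_to_newick(tree._tree.seed_node, out)
    out.append(";")
    return "".join(out)


def parse_newick(text: str, support_convention: str = "internal-node-label") -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`.

    Parameters
    ----------
    text:
        A single Newick tree description.
    support_convention:
        ``"internal-node-label"`` reads internal node labels as numeric
        support values (MrBayes/IQ-TREE consensus convention) and rejects
        non-numeric labels; ``"comment"`` reads the first numeric bracketed
        comment attached to each internal node instead.
    """
    if support_convention not in ("internal-node-label", "comment"):
        raise ValueError(f"unknown support convention: {support_convention!r}")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
            extract_comment_metadata=False,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed Newick: {exc}") from exc

    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise NewickParseError(f"duplicate leaf labels: {dupes}")

    for nd in tree.preorder_node_iter():
        if nd.is_leaf():
            continue
        if support_convention == "comment":
            support = None
            for comment in nd.comments or []:
                try:
                    support = float(comment)
                    break
                except ValueError:
                    continue
            nd.label = None if support is None else f"{support:g}"
        elif nd.label not in (None, ""):
            try:
                float(nd.label)
            except ValueError:
                raise NewickParseError(
                    f"non-numeric internal node label {nd.label!r} under "
                    "internal-node-label support convention"
                ) from None
    return PhyloTree(tree, rooted=True)


def read_tree(path, support_convention: str = "internal-node-label") -> PhyloTree:
    """Read a tree from a Newick file, or from the trees block of a NEXUS file."""
    path = Path(path)
    text = path.read_text()
    if text.lstrip()[:6].upper() == "#NEXUS":
        try:
            tree = dendropy.Tree.get(data=text, schema="nexus",
                                     suppress_internal_node_taxa=True,
                                     preserve_underscores=True)
        except Exception as exc:
            raise NewickParseError(f"cannot parse NEXUS tree file {path}: {exc}") from exc
        return parse_newick(tree.as_string(schema="newick").strip(),
                            support_convention=support_convention)
    return parse_newick(text, support_convention=support_convention)


def _leafset_below(node: dendropy.Node) -> frozenset:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def nontrivial_bipartitions(tree: PhyloTree) -> set:
    """All nontrivial splits of the (implicitly unrooted) tree.

    One bipartition per internal edge after unrooting; a fully resolved
    unrooted tree on n leaves yields exactly n - 3.
    """
    all_leaves = tree.leaf_set
    if len(all_leaves) < 4:
        return set()
    splits: set = set()
    for nd in tree._tree.preorder_node_iter():
        if nd is tree._tree.seed_node or nd.is_leaf():
            continue
        below = _leafset_below(nd)
        rest = all_leaves - below
        if len(below) >= 2 and len(rest) >= 2:
            splits.add(Bipartition(below, rest))
    return splits


def count_polytomy_branches(tree: PhyloTree) -> int:
    """Total branches emanating directly from polytomies (rooted orientation as given)."""
    return sum(
        nc for nd in tree.internal_nodes() if (nc := len(nd.child_nodes())) > 2
    )


def count_bifurcating_nodes(tree: PhyloTree) -> int:
    """Internal nodes with exactly two children; equals n - 1 for a fully resolved rooted tree."""
    return sum(1 for nd in tree.internal_nodes() if len(nd.child_nodes()) == 2)


def mean_node_support(tree: PhyloTree) -> float:
    """Arithmetic mean of support over annotated internal nodes only.

    Nodes without an annotation (typically those collapsed into polytomies in
    a consensus tree) are excluded rather than treated as zero.
    """
    supports = [s for nd in tree.internal_nodes() if (s := PhyloTree.node_support(nd)) is not None]
    if not supports:
        raise NoSupportedNodesError("tree carries no node support annotations")
    return sum(supports) / len(supports)
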