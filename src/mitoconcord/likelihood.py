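"""GTR+I+G site likelihoods (Felsenstein pruning) and the SH topology test.

The substitution model is the general time-reversible rate matrix with a
proportion of invariant sites and discrete-gamma rate heterogeneity.
Transition probabilities come from an eigendecomposition of the symmetrised
rate matrix, so they are valid stochastic matrices for any branch length.

The Shimodaira–Hasegawa test compares candidate topologies on one alignment
using RELL resampling: per-site log-likelihood columns are bootstrapped, each
tree's replicate scores are centred on its own replicate mean, and a tree's
p-value is the fraction of replicates in which its centred deficit from the
replicate-best tree is at least its observed deficit. The maximum-likelihood
tree gets p = 1 by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import gamma as gamma_dist

from .alignment import IUPAC, Alignment
from .treeio import PhyloTree

__all__ = [
    "SubstitutionModel",
    "SHTestResult",
    "gamma_category_rates",
    "site_log_likelihoods",
    "total_log_likelihood",
    "optimize_branch_lengths",
    "sh_test",
]

_BASES = "ACGT"
_PARTIALS = {
    code: np.array([1.0 if b in bases else 0.0 for b in _BASES])
    for code, bases in IUPAC.items()
}


@dataclass(frozen=True)
class SubstitutionModel:
    """GTR+I+G parameters.

    exchangeabilities: upper-triangle GTR rates in the order
    (AC, AG, AT, CG, CT, GT); only relative values matter.
    base_freqs: stationary frequencies (A, C, G, T), summing to 1.
    p_invariant: proportion of invariant sites, in [0, 1].
    gamma_shape: shape of the gamma rate distribution; None disables rate
    heterogeneity (single rate class).
    n_categories: number of discrete gamma categories.
    """

    exchangeabilities: Tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    base_freqs: Tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    p_invariant: float = 0.0
    gamma_shape: Optional[float] = None
    n_categories: int = 4

    def __post_init__(self):
        if len(self.exchangeabilities) != 6 or any(x < 0 for x in self.exchangeabilities):
            raise ValueError("need six non-negative exchangeabilities")
        if len(self.base_freqs) != 4 or not np.isclose(sum(self.base_freqs), 1.0):
            raise ValueError("base frequencies must be four values summing to 1")
        if not (0.0 <= self.p_invariant <= 1.0):
            raise ValueError("p_invariant must lie in [0, 1]")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")
        if self.n_categories < 1:
            raise ValueError("need at least one rate category")

    @classmethod
    def jc69(cls, **kw) -> "SubstitutionModel":
        return cls(**kw)

    def rate_matrix(self) -> np.ndarray:
        """GTR rate matrix scaled so the expected substitution rate is 1."""
        pi = np.asarray(self.base_freqs)
        s = np.zeros((4, 4))
        ac, ag, at, cg, ct, gt = self.exchangeabilities
        s[0, 1] = s[1, 0] = ac
        s[0, 2] = s[2, 0] = ag
        s[0, 3] = s[3, 0] = at
        s[1, 2] = s[2, 1] = cg
        s[1, 3] = s[3, 1] = ct
        s[2, 3] = s[3, 2] = gt
        q = s * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -float(np.dot(pi, np.diag(q)))
        return q / mu

    def eigensystem(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(eigenvalues, right-transform, left-transform) of the rate matrix.

        P(t) = right @ diag(exp(lam * t)) @ left, guaranteed stochastic by the
        symmetrisable structure of reversible rate matrices.
        """
        pi = np.asarray(self.base_freqs)
        sqrt_pi = np.sqrt(pi)
        q = self.rate_matrix()
        sym = (sqrt_pi[:, None] * q) / sqrt_pi[None, :]
        lam, u = np.linalg.eigh((sym + sym.T) / 2.0)
        right = u / sqrt_pi[:, None]
        left = u.T * sqrt_pi[None, :]
        return lam, right, left

    def category_rates(self) -> np.ndarray:
        """Rates of the non-invariant classes, rescaled so the overall mean rate is 1."""
        rates = gamma_category_rates(self.gamma_shape, self.n_categories)
        if self.p_invariant >= 1.0:  # degenerate: the variable classes carry no weight
            return rates
        return rates / (1.0 - self.p_invariant)


def gamma_category_rates(shape: Optional[float], n_categories: int) -> np.ndarray:
    """Discrete-gamma rates by the mean-of-quantile-interval rule, mean 1.

    With ``shape`` None a single unit-rate class is returned.
    """
    if shape is None:
        return np.ones(1)
    k = n_categories
    edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), a=shape, scale=1.0 / shape)
    # mean within [lo, hi) of Gamma(a, 1/a) equals CDF difference under Gamma(a+1, 1/a), times k
    cdf_hi = gamma_dist.cdf(edges[1:], a=shape + 1.0, scale=1.0 / shape)
    cdf_lo = gamma_dist.cdf(edges[:-1], a=shape + 1.0, scale=1.0 / shape)
    rates = k * (cdf_hi - cdf_lo)
    return rates / rates.mean()


def _encode_leaves(aln: Alignment, taxa_order: Sequence[str]) -> np.ndarray:
    """(n_taxa, n_sites, 4) partial-likelihood array; ambiguity codes spread over bases."""
    lut = np.zeros((256, 4))
    for code, partial in _PARTIALS.items():
        lut[ord(code)] = partial
    rows = []
    seq_by_taxon = dict(zip(aln.taxa, aln.sequences))
    for taxon in taxa_order:
        arr = np.frombuffer(seq_by_taxon[taxon].encode(), dtype=np.uint8)
        rows.append(lut[arr])
    return np.array(rows)


class _PruningEngine:
    """Reusable pruning workspace for one (alignment, tree, model) triple.

    Branch lengths are read from the tree on every call, so the same engine
    serves branch-length optimisation without re-encoding the data.
    """

    def __init__(self, aln: Alignment, tree: PhyloTree, model: SubstitutionModel):
        missing = tree.leaf_set ^ frozenset(aln.taxa)
        if missing:
            raise ValueError(f"taxa mismatch between tree and alignment: {sorted(missing)}")
        self.tree = tree
        self.model = model
        self.pi = np.asarray(model.base_freqs)
        self.lam, self.right, self.left = model.eigensystem()
        self.postorder = list(tree.dendropy_tree.postorder_node_iter())
        for nd in self.postorder[:-1]:  # all but seed need branch lengths
            if nd.edge.length is None:
                raise ValueError("tree has missing branch lengths")
        leaf_order = [nd.taxon.label for nd in self.postorder if nd.is_leaf()]
        leaf_partials = _encode_leaves(aln, leaf_order)
        self.leaf_partial = {}
        i = 0
        for nd in self.postorder:
            if nd.is_leaf():
                self.leaf_partial[id(nd)] = leaf_partials[i]
                i += 1
        self.n_sites = aln.length
        rates = model.category_rates()
        self.classes: List[Tuple[float, float]] = [
            ((1.0 - model.p_invariant) / len(rates), r) for r in rates
        ]
        if model.p_invariant > 0:
            self.classes.append((model.p_invariant, 0.0))

    def _transition(self, t: float, rate: float) -> np.ndarray:
        p = (self.right * np.exp(self.lam * (t * rate))) @ self.left
        return np.clip(p, 0.0, None)

    def site_likelihoods(self) -> np.ndarray:
        """Per-site likelihoods mixed over rate classes."""
        total = np.zeros(self.n_sites)
        for weight, rate in self.classes:
            partials: Dict[int, np.ndarray] = {}
            for nd in self.postorder:
                if nd.is_leaf():
                    partials[id(nd)] = self.leaf_partial[id(nd)]
                    continue
                acc = None
                for child in nd.child_nodes():
                    down = partials.pop(id(child)) @ self._transition(
                        child.edge.length, rate
                    ).T
                    acc = down if acc is None else acc * down
                partials[id(nd)] = acc
            root = partials[id(self.postorder[-1])]
            total += weight * (root @ self.pi)
        return total

    def site_log_likelihoods(self) -> np.ndarray:
        lik = self.site_likelihoods()
        with np.errstate(divide="ignore"):
            return np.log(lik)


def site_log_likelihoods(
    aln: Alignment, tree: PhyloTree, model: SubstitutionModel
) -> np.ndarray:
    """Per-site log-likelihoods of the alignment on the tree under the model."""
    return _PruningEngine(aln, tree, model).site_log_likelihoods()


def total_log_likelihood(
    aln: Alignment, tree: PhyloTree, model: SubstitutionModel
) -> float:
    return float(site_log_likelihoods(aln, tree, model).sum())


def optimize_branch_lengths(
    aln: Alignment,
    tree: PhyloTree,
    model: SubstitutionModel,
    tol: float = 1e-3,
    max_sweeps: int = 20,
    max_branch_length: float = 20.0,
) -> Tuple[PhyloTree, float]:
    """Coordinate-wise branch-length optimisation on a fixed topology.

    Sweeps over branches, optimising each with a bounded scalar search, until
    the total log-likelihood improves by less than ``tol`` between sweeps.
    Returns the optimised tree copy and its final log-likelihood; warns if the
    sweep budget runs out first.
    """
    work = tree.copy()
    for nd in work.dendropy_tree.preorder_node_iter():
        if nd is work.dendropy_tree.seed_node:
            continue
        if nd.edge.length is None:
            raise ValueError("tree has missing branch lengths")
        nd.edge.length = max(float(nd.edge.length), 1e-8)
    engine = _PruningEngine(aln, work, model)
    edges = [nd for nd in engine.postorder[:-1]]
    current = float(engine.site_log_likelihoods().sum())
    converged = False
    for _ in range(max_sweeps):
        for nd in edges:
            def objective(x: float) -> float:
                nd.edge.length = x
                return -float(engine.site_log_likelihoods().sum())

            res = minimize_scalar(
                objective,
                bounds=(1e-8, max_branch_length),
                method="bounded",
                options={"xatol": 1e-6},
            )
            nd.edge.length = float(res.x)
        new = float(engine.site_log_likelihoods().sum())
        delta, current = new - current, new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"branch-length optimisation stopped after {max_sweeps} sweeps "
            f"(last improvement {delta:.3g} >= tol {tol:g})",
            RuntimeWarning,
        )
    return work, current


@dataclass
class SHTestResult:
    """Per-tree log-likelihoods, deficits from the best tree, and SH p-values."""

    tree_ids: list
    log_likelihoods: np.ndarray
    deltas: np.ndarray
    p_values: np.ndarray
    n_replicates: int
    seed: int

    @property
    def best_tree(self) -> str:
        return self.tree_ids[int(np.argmax(self.log_likelihoods))]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "tree_id": self.tree_ids,
                "log_likelihood": self.log_likelihoods,
                "delta": self.deltas,
                "p_value": self.p_values,
            }
        )


def sh_test(
    aln: Alignment,
    trees: Dict[str, PhyloTree],
    model: SubstitutionModel,
    n_replicates: int = 1000,
    seed: int = 0,
    optimize: bool = True,
    tol: float = 1e-3,
    allow_few_replicates: bool = False,
) -> SHTestResult:
    """Shimodaira–Hasegawa test over candidate topologies with RELL resampling.

    Branch lengths of every candidate are optimised on the test alignment
    (unless ``optimize=False``, in which case the supplied lengths are used).
    Fewer than 100 replicates is refused unless explicitly allowed.
    """
    if len(trees) < 2:
        raise ValueError("need at least two candidate trees")
    if n_replicates < 100 and not allow_few_replicates:
        raise ValueError(
            "fewer than 100 RELL replicates gives an underpowered test; "
            "pass allow_few_replicates=True to override"
        )
    ids = list(trees)
    site_lnl = []
    for name in ids:
        tree = trees[name]
        if optimize:
            tree, _ = optimize_branch_lengths(aln, tree, model, tol=tol)
        site_lnl.append(site_log_likelihoods(aln, tree, model))
    site_lnl = np.array(site_lnl)  # (T, S)
    totals = site_lnl.sum(axis=1)
    deltas = totals.max() - totals

    rng = np.random.default_rng(seed)
    n_sites = site_lnl.shape[1]
    counts = rng.multinomial(n_sites, np.full(n_sites, 1.0 / n_sites), size=n_replicates)
    rep = counts @ site_lnl.T  # (B, T)
    centered = rep - rep.mean(axis=0, keepdims=True)
    rep_deficit = centered.max(axis=1, keepdims=True) - centered  # (B, T)
    p_values = (rep_deficit >= deltas[None, :]).mean(axis=0)
    return SHTestResult(
        tree_ids=ids,
        log_likelihoods=totals,
        deltas=deltas,
        p_values=p_values,
        n_replicates=n_replicates,
        seed=seed,
    )
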