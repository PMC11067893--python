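"""Canned simulation experiments over the pipeline.

Two study-shaped experiments, each fully seeded:

* the marker-length versus topology-recovery experiment: how RF distance from
  the generating tree falls with alignment length, and whether the full
  concatenation beats every single partition;
* the SH type-I-error calibration: how often the SH test rejects the
  generating topology against a one-NNI rearrangement when the data were
  simulated on it.

The fixed conditions (tree depth, model, branch-length floor) are the
package's reference regime for these experiments; see docs/methods.md for
the rationale behind each value.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np
from scipy.stats import spearmanr

from .congruence import rf_distance
from .likelihood import SubstitutionModel
from .simulate import SimulationConfig, estimate_tree_nj, evolve_alignment, nni_neighbor, simulate_tree
from .likelihood import sh_test

__all__ = [
    "RECOVERY_LENGTHS",
    "RECOVERY_MODEL",
    "length_vs_rf_experiment",
    "sh_calibration",
]

# Six partitions spanning the length range of mitochondrial markers, from a
# short-gene scale (150 bp) to a multi-gene concatenation scale (4.8 kb).
RECOVERY_LENGTHS: Dict[str, int] = {
    "p150": 150, "p300": 300, "p600": 600,
    "p1200": 1200, "p2400": 2400, "p4800": 4800,
}

# Mildly transition-biased GTR with strong gamma rate heterogeneity.
RECOVERY_MODEL = SubstitutionModel(
    exchangeabilities=(1, 2, 1, 1, 2, 1),
    base_freqs=(0.28, 0.26, 0.22, 0.24),
    gamma_shape=0.5,
    n_categories=4,
)

_RECOVERY_HEIGHT = 0.7  # root height, substitutions/site
_RECOVERY_FLOOR = 0.03  # minimum branch length: shorter splits are
#                         unidentifiable at these alignment lengths

_CALIBRATION_MODEL = SubstitutionModel(
    exchangeabilities=(1, 2, 1, 1, 2, 1),
    base_freqs=(0.28, 0.26, 0.22, 0.24),
    gamma_shape=0.7,
    n_categories=4,
)


def length_vs_rf_experiment(
    base_seed: int, n_replicates: int = 20, n_taxa: int = 12
) -> Tuple[int, int, List[dict]]:
    """Replicated recovery experiment relating marker length to RF distance.

    Per replicate: simulate a tree and a partitioned alignment, estimate an
    NJ tree per partition and for the full concatenation (gamma-matched JC
    distances), and record RF to the generating tree.

    Returns (number of replicates with negative Spearman rank correlation
    between length and RF, number where the concatenation attains the
    minimum RF, per-replicate records).
    """
    negative = concat_best = 0
    records: List[dict] = []
    shape = RECOVERY_MODEL.gamma_shape
    for rep in range(n_replicates):
        cfg = SimulationConfig(
            seed=base_seed + rep,
            n_taxa=n_taxa,
            partition_spec=dict(RECOVERY_LENGTHS),
            model=RECOVERY_MODEL,
            tree_height_scale=_RECOVERY_HEIGHT,
            min_branch_length=_RECOVERY_FLOOR,
        )
        rng = np.random.default_rng(cfg.seed)
        truth = simulate_tree(cfg, rng)
        aln = evolve_alignment(truth, cfg, rng)
        rfs = {
            name: rf_distance(truth, estimate_tree_nj(aln.partition(name), gamma_shape=shape))
            for name in RECOVERY_LENGTHS
        }
        concat_rf = rf_distance(truth, estimate_tree_nj(aln, gamma_shape=shape))
        rho = spearmanr(
            list(RECOVERY_LENGTHS.values()), [rfs[n] for n in RECOVERY_LENGTHS]
        ).statistic
        is_negative = (not np.isnan(rho)) and rho < 0
        is_best = concat_rf <= min(rfs.values())
        negative += is_negative
        concat_best += is_best
        records.append(
            {"seed": cfg.seed, "rho": rho, "concat_rf": concat_rf, **rfs}
        )
    return int(negative), int(concat_best), records


def sh_calibration(
    base_seed: int,
    n_runs: int = 100,
    alpha: float = 0.05,
    n_taxa: int = 6,
    n_sites: int = 400,
    n_replicates: int = 500,
) -> Tuple[int, List[float]]:
    """Type-I-error calibration of the SH test under the null.

    Data are simulated on tree A; the candidate set is {A, one NNI neighbour
    of A}. Returns (number of runs rejecting A at ``alpha``, the per-run
    p-values of A).
    """
    rejections = 0
    p_values: List[float] = []
    for run in range(n_runs):
        cfg = SimulationConfig(
            seed=base_seed + run,
            n_taxa=n_taxa,
            partition_spec={"g": n_sites},
            model=_CALIBRATION_MODEL,
            tree_height_scale=0.4,
            min_branch_length=_RECOVERY_FLOOR,
        )
        rng = np.random.default_rng(cfg.seed)
        truth = simulate_tree(cfg, rng)
        aln = evolve_alignment(truth, cfg, rng)
        res = sh_test(
            aln,
            {"true": truth, "alt": nni_neighbor(truth)},
            _CALIBRATION_MODEL,
            n_replicates=n_replicates,
            seed=cfg.seed,
        )
        p_true = float(dict(zip(res.tree_ids, res.p_values))["true"])
        p_values.append(p_true)
        rejections += p_true < alpha
    return int(rejections), p_values
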