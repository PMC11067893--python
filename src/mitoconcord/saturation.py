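"""Substitution-saturation assessment by distance regression.

Uncorrected p-distances are regressed on model-corrected distances over all
taxon pairs. A slope near 1 means observed differences track inferred
substitutions (little saturation); the lower the slope, the more multiple
hits are hidden by the correction, i.e. the more saturated the marker.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .alignment import Alignment, corrected_distance_matrix, p_distance_matrix

__all__ = ["SaturationResult", "saturation_regression"]


@dataclass
class SaturationResult:
    gene_id: Optional[str]
    slope: float
    intercept: float
    r_squared: float
    n_pairs: int
    n_excluded_pairs: int
    model: str

    def scatter_data(self):
        """(corrected, uncorrected) arrays of the pairs used — the plot data."""
        return self._x, self._y


def saturation_regression(
    aln: Alignment, model: str = "JC69", gene_id: Optional[str] = None
) -> SaturationResult:
    """OLS of uncorrected p-distance on corrected distance (free intercept).

    Pairs whose corrected distance is undefined (saturated past the model
    bound, or no comparable sites) are excluded and counted.
    """
    if aln.n_taxa < 3:
        raise ValueError("need at least three taxa")
    p = p_distance_matrix(aln).condensed()
    d = corrected_distance_matrix(aln, model=model).condensed()
    defined = np.isfinite(p) & np.isfinite(d)
    n_excluded = int((~defined).sum())
    x, y = d[defined], p[defined]
    if len(x) < 3:
        raise ValueError(f"only {len(x)} defined pairs; need at least 3")
    if np.ptp(x) == 0:
        raise ValueError("corrected distances have zero variance (no divergence)")
    fit = stats.linregress(x, y)
    result = SaturationResult(
        gene_id=gene_id,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n_pairs=int(len(x)),
        n_excluded_pairs=n_excluded,
        model=model,
    )
    result._x, result._y = x, y
    return result
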