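"""Topographic and expression-level comparison of two covariance patterns."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .derive import CovariancePattern
from .scoring import ScoreTable

__all__ = ["VoxelCorrelation", "voxelweight_correlation", "score_correlation"]


@dataclass
class VoxelCorrelation:
    r: float
    r_squared: float
    n_voxels_used: int
    p_value: float
    # Voxel weights are spatially autocorrelated; the nominal p-value
    # treats voxels as independent and is anticonservative.
    p_value_uncorrected_for_autocorrelation: bool = True

    def __iter__(self):
        return iter((self.r, self.r_squared, self.n_voxels_used))


def voxelweight_correlation(
    p1: CovariancePattern,
    p2: CovariancePattern,
    include_single_pattern_voxels: bool = False,
) -> VoxelCorrelation:
    """Pearson correlation of two patterns' voxel weights on a common grid.

    Both patterns must live on masks over the same grid; the comparison
    uses the intersection of their masks, restricted by default to voxels
    non-zero in BOTH patterns. With ``include_single_pattern_voxels`` the
    union-with-zeros variant is used instead (voxels non-zero in at least
    one pattern, the other contributing 0 there).
    """
    if p1.mask.shape != p2.mask.shape or not np.allclose(
        p1.mask.affine, p2.mask.affine, atol=1e-4
    ):
        raise ValueError("patterns must be resampled/aligned to a common grid")
    common = p1.mask.data & p2.mask.data
    if not common.any():
        raise ValueError("common mask is empty")

    def on_common(p: CovariancePattern) -> np.ndarray:
        flat = np.zeros(int(np.prod(p.mask.shape)))
        flat[p.mask.voxel_order] = p.weights
        return flat[np.flatnonzero(common.ravel(order="C"))]

    w1, w2 = on_common(p1), on_common(p2)
    nz1, nz2 = w1 != 0, w2 != 0
    sel = (nz1 | nz2) if include_single_pattern_voxels else (nz1 & nz2)
    n = int(sel.sum())
    if n < 3:
        raise ValueError("fewer than 3 common non-zero voxels")
    a, b = w1[sel], w2[sel]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in a voxel-weight vector")
    res = stats.pearsonr(a, b)
    r = float(res.statistic)
    return VoxelCorrelation(r=r, r_squared=r * r, n_voxels_used=n, p_value=float(res.pvalue))


def score_correlation(scores1: ScoreTable, scores2: ScoreTable) -> tuple[float, float]:
    """Pearson correlation of two patterns' z-scores across the same subjects."""
    if scores1.subject_ids != scores2.subject_ids:
        raise ValueError("score tables must cover the same subjects in the same order")
    if scores1.z_scores is None or scores2.z_scores is None:
        raise ValueError("both tables must be z-transformed first")
    if len(scores1.subject_ids) < 3:
        raise ValueError("need at least 3 subjects")
    res = stats.pearsonr(scores1.z_scores, scores2.z_scores)
    return float(res.statistic), float(res.pvalue)
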