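"""Diversity and community-dissimilarity metrics.

Response variables for the driver analysis: per-site genus richness and
Shannon's diversity, and pairwise Jaccard (incidence-based) and Bray-Curtis
(abundance-based) dissimilarity matrices.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .containers import CommunityMatrix, DistanceMatrix

__all__ = ["richness", "shannon", "jaccard_matrix", "braycurtis_matrix"]


def richness(c: CommunityMatrix) -> np.ndarray:
    """Number of genera with abundance strictly > 0, per site.

    The strict threshold matters because site values may be fractional
    after plot-level counts are averaged.
    """
    return (c.abundance > 0).sum(axis=1).astype(int)


def shannon(c: CommunityMatrix) -> np.ndarray:
    """Shannon's diversity H = -sum(p_i ln p_i) per site, natural log.

    Genera with zero abundance contribute nothing.  Raises if a site total
    is zero (proportions undefined) — which the container already forbids.
    """
    totals = c.abundance.sum(axis=1)
    bad = np.where(totals <= 0)[0]
    if bad.size:
        raise ValueError(f"site {c.sites[bad[0]]!r} has zero total abundance")
    p = c.abundance / totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return -terms.sum(axis=1)


def jaccard_matrix(c: CommunityMatrix) -> DistanceMatrix:
    """Pairwise Jaccard dissimilarity (b + c) / (a + b + c) on incidence.

    ``a`` counts genera present at both sites, ``b`` and ``c`` those unique
    to each.  Presence means abundance > 0.
    """
    incidence = c.abundance > 0
    d = squareform(pdist(incidence, metric="jaccard"))
    return DistanceMatrix(list(c.sites), d, metric="jaccard")


def braycurtis_matrix(c: CommunityMatrix) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity sum|x_ij - x_ik| / sum(x_ij + x_ik).

    A pair of all-zero sites is undefined by the formula; the container
    forbids all-zero sites, but if one slips through via direct array use the
    limit convention d = 1 is applied with a warning.
    """
    totals = c.abundance.sum(axis=1)
    if (totals <= 0).any():
        warnings.warn("all-zero site present; Bray-Curtis uses the d=1 limit convention")
    d = squareform(pdist(c.abundance, metric="braycurtis"))
    d = np.nan_to_num(d, nan=1.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(c.sites), d, metric="braycurtis")
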