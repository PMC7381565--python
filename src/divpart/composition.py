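"""Community-composition analyses.

NMDS ordination of Jaccard / Bray-Curtis dissimilarities, environmental
vector fitting onto the ordination, Mantel tests against spatial distance,
and a distance-based variation partition: community dissimilarity regressed
on per-set environmental distances (Euclidean distance over all principal
components of each standardized predictor set), decomposed into the same
seven fractions as the diversity-side partition.

Permutation p-values are one-sided throughout, and all matrix permutations
reorder site labels (simultaneous row/column shuffles), never individual
distance entries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import smacof

from .containers import DistanceMatrix, PredictorTable
from .elastic_net import adjusted_r2, standardize
from .varpart import (
    COMBINATIONS,
    FRACTIONS,
    PartitionResult,
    _haversine_matrix,
    partition_from_combination_r2,
)

__all__ = [
    "OrdinationResult",
    "nmds",
    "envfit",
    "MantelResult",
    "mantel",
    "geographic_distance",
    "predictor_distance",
    "db_varpart",
]


@dataclass
class OrdinationResult:
    """NMDS scores with Kruskal-type normalized stress."""

    scores: np.ndarray  # (n_sites, k), centered, principal-axis orientation
    stress: float
    k: int
    n_starts: int
    converged: bool
    seed: int | None
    labels: list[str] = field(default_factory=list)


def _principal_orientation(scores: np.ndarray) -> np.ndarray:
    """Center and rotate scores onto their principal axes with fixed signs.

    NMDS solutions are defined only up to rotation/reflection; this makes
    the reported configuration deterministic.
    """
    x = scores - scores.mean(axis=0)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    rot = x @ vt.T
    for j in range(rot.shape[1]):
        i = np.argmax(np.abs(rot[:, j]))
        if rot[i, j] < 0:
            rot[:, j] = -rot[:, j]
    return rot


def nmds(
    d: DistanceMatrix,
    k: int = 2,
    n_starts: int = 50,
    seed: int | None = 0,
    *,
    max_iter: int = 500,
    tol: float = 1e-7,
) -> OrdinationResult:
    """Nonmetric multidimensional scaling by SMACOF with isotonic regression.

    Minimizes normalized stress between ordination distances and a monotone
    transform of the input dissimilarities; keeps the best of ``n_starts``
    random starts and reports scores rotated to principal axes.
    """
    if d.n < k + 2:
        raise ValueError(f"need at least k + 2 = {k + 2} sites for a {k}-D ordination")
    rng = np.random.default_rng(seed)
    # classical-scaling (PCoA) start: deterministic, and on data embeddable in
    # < k dimensions it already contains the exact configuration, which makes
    # stress non-increasing in k in practice
    n = d.n
    J = np.eye(n) - 1.0 / n
    B = -0.5 * J @ (d.d**2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1][:k]
    pcoa = evecs[:, order] * np.sqrt(np.clip(evals[order], 0.0, None))
    inits = [pcoa] + [rng.standard_normal((n, k)) for _ in range(max(n_starts - 1, 0))]

    best_scores, best_stress, best_iter = None, np.inf, 0
    for init in inits:
        scores, stress, n_iter = smacof(
            d.d,
            metric=False,
            n_components=k,
            init=init,
            n_init=1,
            max_iter=max_iter,
            eps=tol,
            normalized_stress=True,
            return_n_iter=True,
        )
        if stress < best_stress:
            best_scores, best_stress, best_iter = scores, float(stress), n_iter
    return OrdinationResult(
        scores=_principal_orientation(best_scores),
        stress=best_stress,
        k=k,
        n_starts=n_starts,
        converged=best_iter < max_iter,
        seed=seed,
        labels=list(d.labels),
    )


def envfit(
    ord: OrdinationResult,
    env: PredictorTable,
    n_perm: int = 999,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Fit each environmental variable as a vector onto the ordination.

    Per variable: least-squares regression of the (centered) variable on the
    ordination scores; r^2 is the regression R^2 and the direction the unit
    coefficient vector.  Significance from permuting the variable across
    sites: p = (1 + #{null r^2 >= observed}) / (1 + n_perm).
    """
    if env.n_sites != ord.scores.shape[0]:
        raise ValueError("environment table and ordination have different site counts")
    X = ord.scores - ord.scores.mean(axis=0)
    pinv = np.linalg.pinv(X)
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    rows = []
    for var in env.values.columns:
        v = env.values[var].to_numpy(float)
        vc = v - v.mean()
        sst = float(vc @ vc)
        if sst == 0:
            warnings.warn(f"variable {var!r} is constant; envfit r^2 set to 0")
            rows.append((var, env.set_labels[var], *np.zeros(ord.k), 0.0, 1.0))
            continue

        def fit_r2(vec):
            b = pinv @ vec
            resid = vec - X @ b
            return b, 1.0 - float(resid @ resid) / float(vec @ vec)

        b, r2 = fit_r2(vc)
        nrm = np.linalg.norm(b)
        direction = b / nrm if nrm > 0 else b
        null = np.empty(n_perm)
        for i in range(n_perm):
            vp = vc[rng.permutation(n)]
            null[i] = fit_r2(vp)[1]
        p = float((1 + np.sum(null >= r2)) / (1 + n_perm))
        rows.append((var, env.set_labels[var], *direction, r2, p))
    cols = ["variable", "set"] + [f"axis{i + 1}" for i in range(ord.k)] + ["r2", "p"]
    return pd.DataFrame(rows, columns=cols).set_index("variable")


@dataclass
class MantelResult:
    r: float
    p: float
    n_permutations: int


def mantel(
    d1: DistanceMatrix, d2: DistanceMatrix, n_perm: int = 999, seed: int | None = 0
) -> MantelResult:
    """Mantel correlation between two distance matrices.

    Pearson r over the strictly-lower triangles; one-sided p from
    simultaneous row/column permutations of the second matrix.
    """
    if d1.labels != d2.labels:
        raise ValueError("distance matrices have different site labels/order")
    n = d1.n
    if n < 4:
        raise ValueError("Mantel test needs at least 4 sites")
    v1 = d1.condensed()
    v2 = d2.condensed()
    if np.ptp(v1) == 0 or np.ptp(v2) == 0:
        raise ValueError("a distance matrix has zero variance off-diagonal")
    v1c = v1 - v1.mean()

    def corr(vec):
        vc = vec - vec.mean()
        return float(v1c @ vc) / np.sqrt(float(v1c @ v1c) * float(vc @ vc))

    r_obs = corr(v2)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    m2 = d2.d
    for b in range(n_perm):
        perm = rng.permutation(n)
        null[b] = corr(squareform(m2[np.ix_(perm, perm)], checks=False))
    p = float((1 + np.sum(null >= r_obs)) / (1 + n_perm))
    return MantelResult(float(r_obs), p, n_perm)


def geographic_distance(coords, labels) -> DistanceMatrix:
    """Great-circle distance matrix (km) from (lon, lat) site coordinates."""
    d = _haversine_matrix(np.asarray(coords, float))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(labels), (d + d.T) / 2.0, metric="greatcircle_km")


def predictor_distance(env: PredictorTable, pset: str) -> DistanceMatrix:
    """Environmental distance for one predictor set.

    Variables are standardized, PCA is computed, and Euclidean distance is
    taken over ALL principal components — which equals Euclidean distance on
    the standardized variables (rotation invariance), so the PCA serves as
    an explicit change of basis, not a reduction.
    """
    cols = env.variables(pset)
    X = env.values[cols].to_numpy(float)
    keep = X.std(axis=0) > 0
    if not keep.all():
        dropped = [c for c, k in zip(cols, keep) if not k]
        warnings.warn(f"constant variables dropped before PCA: {dropped}")
        X = X[:, keep]
    if X.shape[1] < 2:
        raise ValueError(f"predictor set {pset!r} needs at least 2 non-constant variables")
    Z = standardize(X)
    Zc = Z - Z.mean(axis=0)
    u, s, _ = np.linalg.svd(Zc, full_matrices=False)
    pcs = u * s  # scores on all principal components
    d = squareform(pdist(pcs, metric="euclidean"))
    return DistanceMatrix(list(env.sites), d, metric=f"euclid_pcs_{pset}")


def _ols_r2adj(y: np.ndarray, X: np.ndarray) -> float:
    n, p = X.shape
    A = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    yc = y - y.mean()
    sst = float(yc @ yc)
    r2 = 1.0 - float(resid @ resid) / sst if sst > 0 else 0.0
    return adjusted_r2(r2, n, p)


def db_varpart(
    response_d: DistanceMatrix,
    env: PredictorTable,
    n_perm: int = 999,
    seed: int | None = 0,
) -> PartitionResult:
    """Distance-based variation partition of community dissimilarity.

    Unfolds strictly-lower triangles and regresses response distances on the
    per-set environmental distances for each of the seven set combinations
    (ordinary least squares; n = number of site pairs, p = number of
    distance predictors in the adjusted R^2).  Fraction significance from
    row/column permutations of the response matrix.
    """
    if response_d.labels != list(env.sites):
        raise ValueError("response distance labels do not match environment sites")
    set_letter = {"C": "climatic", "S": "soil", "H": "historical"}
    pred = {k: predictor_distance(env, s).condensed() for k, s in set_letter.items()}

    def combos_r2adj(yvec):
        out = {}
        for combo in COMBINATIONS:
            X = np.column_stack([pred[letter] for letter in combo])
            out[combo] = _ols_r2adj(yvec, X)
        return out

    y = response_d.condensed()
    combo_r2 = combos_r2adj(y)
    fractions = partition_from_combination_r2(combo_r2)
    totals = {set_letter[k]: combo_r2[k] for k in ("C", "S", "H")}

    stat_keys = list(FRACTIONS) + [f"total_{set_letter[k]}" for k in ("C", "S", "H")]
    obs_stats = {**fractions, **{f"total_{s}": t for s, t in totals.items()}}
    rng = np.random.default_rng(seed)
    n = response_d.n
    m = response_d.d
    null = np.empty((n_perm, len(stat_keys)))
    for b in range(n_perm):
        perm = rng.permutation(n)
        yp = squareform(m[np.ix_(perm, perm)], checks=False)
        cr = combos_r2adj(yp)
        fr = partition_from_combination_r2(cr)
        null[b, :7] = [fr[k] for k in FRACTIONS]
        null[b, 7:] = [cr[k] for k in ("C", "S", "H")]
    pvalues = {}
    significant = {}
    for j, key in enumerate(stat_keys):
        o = obs_stats[key]
        pvalues[key] = float((1 + np.sum(null[:, j] >= o)) / (1 + n_perm))
        significant[key] = bool(o > np.quantile(null[:, j], 0.95))
    return PartitionResult(
        fractions=fractions,
        totals=totals,
        combination_r2=combo_r2,
        pvalues=pvalues,
        significant=significant,
        n_permutations=n_perm,
        seed=seed,
        meta={"response": response_d.metric, "model": "distance-ols"},
    )
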