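"""Variation partitioning of diversity across three predictor sets.

Adjusted R^2 from elastic-net models of a diversity response on every
combination of the climatic (C), soil (S) and historical (H) predictor sets
is decomposed by inclusion-exclusion into seven fractions: three pure
(independent) effects, three pairwise overlaps, and the triple overlap.
Individual fractions may be negative (they are differences of adjusted
R^2 values) and are reported as-is.

Significance of each fraction and of each set's total effect comes from a
permutation test: the response is randomly reordered, the full
seven-combination partition recomputed, and the observed value compared
against the null distribution (one-sided; a fraction is flagged significant
when it exceeds the 95% null quantile).

A Moran's I check on model residuals guards against unmodelled spatial
autocorrelation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _engine
from ._engine import CD_MAX_ITER, CD_TOL, LAMBDA_MIN_RATIO
from .containers import PredictorTable
from .elastic_net import default_alpha_grid, fold_layouts, standardize

__all__ = [
    "COMBINATIONS",
    "FRACTIONS",
    "PartitionResult",
    "partition_from_combination_r2",
    "partition_three_sets",
    "permutation_test_fractions",
    "MoranResult",
    "morans_i",
    "inverse_distance_weights",
]

#: predictor-set combinations, in canonical order
COMBINATIONS = ("C", "S", "H", "CS", "CH", "SH", "CSH")
#: the seven partition fractions: pure C/S/H, pairwise-only overlaps, triple overlap
FRACTIONS = ("C", "S", "H", "CS", "CH", "SH", "CSH")
_SET_OF = {"C": "climatic", "S": "soil", "H": "historical"}


@dataclass
class PartitionResult:
    """Seven-fraction adjusted-R^2 partition, optionally with permutation p-values."""

    fractions: dict[str, float]
    totals: dict[str, float]
    combination_r2: dict[str, float]
    pvalues: dict[str, float] | None = None
    significant: dict[str, bool] | None = None
    n_permutations: int = 0
    n_repeats: int = 1
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def full_model_r2adj(self) -> float:
        return self.combination_r2["CSH"]


def partition_from_combination_r2(r: dict[str, float]) -> dict[str, float]:
    """Inclusion-exclusion decomposition of the seven combination R^2adj values.

    Returns the fractions {C, S, H, CS, CH, SH, CSH} = pure climatic, pure
    soil, pure historical, the three pairwise-only overlaps, and the triple
    overlap.  Their sum reconstructs r['CSH'] exactly.
    """
    missing = [k for k in COMBINATIONS if k not in r]
    if missing:
        raise KeyError(f"missing combination values: {missing}")
    return {
        "C": r["CSH"] - r["SH"],
        "S": r["CSH"] - r["CH"],
        "H": r["CSH"] - r["CS"],
        "CS": r["CH"] + r["SH"] - r["CSH"] - r["H"],
        "CH": r["CS"] + r["SH"] - r["CSH"] - r["S"],
        "SH": r["CS"] + r["CH"] - r["CSH"] - r["C"],
        "CSH": r["C"] + r["S"] + r["H"] - r["CS"] - r["CH"] - r["SH"] + r["CSH"],
    }


def _combo_layout(env: PredictorTable):
    """Column-index layout of the 7 combinations in the full design matrix."""
    cols = list(env.values.columns)
    set_idx = {s: [i for i, v in enumerate(cols) if env.set_labels[v] == s]
               for s in ("climatic", "soil", "historical")}
    for s, idx in set_idx.items():
        if not idx:
            raise ValueError(f"predictor set {s!r} has no variables")
    combo_lists = []
    for combo in COMBINATIONS:
        idx = []
        for letter in combo:
            idx.extend(set_idx[_SET_OF[letter]])
        combo_lists.append(idx)
    max_p = max(len(ix) for ix in combo_lists)
    combo_cols = np.zeros((len(COMBINATIONS), max_p), dtype=np.int64)
    combo_len = np.zeros(len(COMBINATIONS), dtype=np.int64)
    for c, ix in enumerate(combo_lists):
        combo_cols[c, : len(ix)] = ix
        combo_len[c] = len(ix)
    return combo_cols, combo_len


def _partition_arrays(
    Xs, y, combo_cols, combo_len, folds, repeats, alphas, n_lambda, ratio, rng
) -> np.ndarray:
    fold_ids = fold_layouts(Xs.shape[0], folds, repeats, rng)
    return _engine.partition_combos_core(
        Xs, y, combo_cols, combo_len, fold_ids, folds, alphas, n_lambda, ratio,
        CD_TOL, CD_MAX_ITER,
    )


def _validate_inputs(y, env: PredictorTable):
    y = np.asarray(y, dtype=float).ravel()
    if y.shape[0] != env.n_sites:
        raise ValueError("response length does not match environment table")
    if np.ptp(y) == 0:
        raise ValueError("response is constant; model undefined")
    n, p_full = env.n_sites, env.values.shape[1]
    if n - p_full - 1 <= 0:
        raise ValueError(
            f"full model has n={n}, p={p_full}: adjusted R^2 undefined; offer fewer variables"
        )
    return y


def partition_three_sets(
    y,
    env: PredictorTable,
    repeats: int = 100,
    folds: int = 5,
    alpha_grid=None,
    seed: int | None = 0,
    *,
    n_lambda: int = 50,
    lambda_min_ratio: float = LAMBDA_MIN_RATIO,
    rng: np.random.Generator | None = None,
) -> PartitionResult:
    """Adjusted-R^2 variation partition of ``y`` over the three predictor sets.

    Fits the elastic net (CV-tuned, ``repeats`` reruns averaged) on each of
    the seven set combinations and decomposes by inclusion-exclusion.
    ``totals`` holds each set's total (pure + shared) effect, i.e. the
    single-set model's mean adjusted R^2.
    """
    y = _validate_inputs(y, env)
    alphas = np.asarray(alpha_grid if alpha_grid is not None else default_alpha_grid(), float)
    Xs = standardize(env.values.to_numpy(float))
    combo_cols, combo_len = _combo_layout(env)
    if rng is None:
        rng = np.random.default_rng(seed)
    r = _partition_arrays(
        Xs, y, combo_cols, combo_len, folds, repeats, alphas, n_lambda, lambda_min_ratio, rng
    )
    combo_r2 = dict(zip(COMBINATIONS, map(float, r)))
    fractions = partition_from_combination_r2(combo_r2)
    totals = {_SET_OF[k]: combo_r2[k] for k in ("C", "S", "H")}
    return PartitionResult(
        fractions=fractions,
        totals=totals,
        combination_r2=combo_r2,
        n_repeats=repeats,
        seed=seed,
        meta={"folds": folds, "alpha_grid": alphas.tolist(), "n_lambda": n_lambda},
    )


def permutation_test_fractions(
    y,
    env: PredictorTable,
    n_perm: int = 999,
    repeats_null: int = 10,
    seed: int | None = 0,
    *,
    repeats: int = 100,
    folds: int = 5,
    alpha_grid=None,
    n_lambda: int = 50,
    lambda_min_ratio: float = LAMBDA_MIN_RATIO,
) -> PartitionResult:
    """Partition with permutation p-values for every fraction and set total.

    The response is permuted ``n_perm`` times; each permutation re-tunes
    (alpha, lambda) and recomputes the full seven-combination partition with
    ``repeats_null`` CV reruns (fewer than the observed ``repeats`` to keep
    the null tractable; set equal for full fidelity).  For statistic t,
    p = (1 + #{null >= observed}) / (1 + n_perm), and ``significant`` flags
    observed values exceeding the 95% null quantile.
    """
    if n_perm < 99:
        warnings.warn(f"n_perm={n_perm} < 99: the 95% null quantile is unreliable")
    y = _validate_inputs(y, env)
    alphas = np.asarray(alpha_grid if alpha_grid is not None else default_alpha_grid(), float)
    Xs = standardize(env.values.to_numpy(float))
    combo_cols, combo_len = _combo_layout(env)
    rng = np.random.default_rng(seed)
    obs = partition_three_sets(
        y, env, repeats, folds, alphas, seed=None, n_lambda=n_lambda,
        lambda_min_ratio=lambda_min_ratio, rng=rng,
    )
    stat_keys = list(FRACTIONS) + [f"total_{_SET_OF[k]}" for k in ("C", "S", "H")]
    obs_stats = {**obs.fractions,
                 **{f"total_{s}": v for s, v in obs.totals.items()}}
    null = np.empty((n_perm, len(stat_keys)))
    n = y.shape[0]
    for b in range(n_perm):
        yp = y[rng.permutation(n)]
        r = _partition_arrays(
            Xs, yp, combo_cols, combo_len, folds, repeats_null, alphas, n_lambda,
            lambda_min_ratio, rng,
        )
        combo_r2 = dict(zip(COMBINATIONS, r))
        fr = partition_from_combination_r2(combo_r2)
        null[b, :7] = [fr[k] for k in FRACTIONS]
        null[b, 7:] = [combo_r2[k] for k in ("C", "S", "H")]
    pvalues = {}
    significant = {}
    for j, key in enumerate(stat_keys):
        o = obs_stats[key]
        pvalues[key] = float((1 + np.sum(null[:, j] >= o)) / (1 + n_perm))
        significant[key] = bool(o > np.quantile(null[:, j], 0.95))
    obs.pvalues = pvalues
    obs.significant = significant
    obs.n_permutations = n_perm
    obs.seed = seed
    obs.meta.update({"repeats_null": repeats_null, "retune_per_permutation": True})
    return obs


# ---------------------------------------------------------------------------
# Moran's I residual diagnostics


def _haversine_matrix(coords: np.ndarray) -> np.ndarray:
    """Great-circle distances (km) between (lon, lat) points in degrees."""
    lon = np.radians(coords[:, 0])[:, None]
    lat = np.radians(coords[:, 1])[:, None]
    dlon = lon - lon.T
    dlat = lat - lat.T
    a = np.sin(dlat / 2) ** 2 + np.cos(lat) * np.cos(lat.T) * np.sin(dlon / 2) ** 2
    return 2 * 6371.0 * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def inverse_distance_weights(coords, row_standardize: bool = True) -> np.ndarray:
    """Inverse great-circle-distance spatial weights, zero diagonal."""
    coords = np.asarray(coords, dtype=float)
    d = _haversine_matrix(coords)
    with np.errstate(divide="ignore"):
        w = 1.0 / d
    np.fill_diagonal(w, 0.0)
    if not np.all(np.isfinite(w)):
        raise ValueError("coincident sites give infinite inverse-distance weights")
    if row_standardize:
        w = w / w.sum(axis=1, keepdims=True)
    return w


@dataclass
class MoranResult:
    I: float
    expected: float  # -1/(n-1) under the permutation null
    p: float
    n_permutations: int


def morans_i(
    residuals,
    coords=None,
    weights: np.ndarray | None = None,
    n_perm: int = 999,
    seed: int | None = 0,
    alternative: str = "two-sided",
) -> MoranResult:
    """Moran's I spatial autocorrelation of residuals with a permutation test.

    I = (n / sum w_ij) * (sum_ij w_ij z_i z_j) / (sum_i z_i^2) with z the
    centered residuals.  Weights default to row-standardized inverse
    great-circle distance from ``coords`` (lon, lat in degrees).
    """
    z = np.asarray(residuals, dtype=float).ravel()
    n = z.shape[0]
    if n < 4:
        raise ValueError("Moran's I needs at least 4 sites")
    z = z - z.mean()
    denom = float(z @ z)
    if denom == 0:
        raise ValueError("residuals have zero variance")
    if weights is None:
        if coords is None:
            raise ValueError("provide either coords or an explicit weight matrix")
        weights = inverse_distance_weights(np.asarray(coords, float))
    w = np.asarray(weights, dtype=float)
    if w.shape != (n, n):
        raise ValueError("weight matrix shape does not match residual length")
    s0 = float(w.sum())

    def stat(v):
        return (n / s0) * float(v @ w @ v) / float(v @ v)

    i_obs = stat(z)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = stat(z[rng.permutation(n)])
    if alternative == "greater":
        p = (1 + np.sum(null >= i_obs)) / (1 + n_perm)
    elif alternative == "less":
        p = (1 + np.sum(null <= i_obs)) / (1 + n_perm)
    elif alternative == "two-sided":
        p_hi = (1 + np.sum(null >= i_obs)) / (1 + n_perm)
        p_lo = (1 + np.sum(null <= i_obs)) / (1 + n_perm)
        p = min(1.0, 2.0 * min(p_hi, p_lo))
    else:
        raise ValueError("alternative must be 'two-sided', 'greater' or 'less'")
    return MoranResult(float(i_obs), -1.0 / (n - 1), float(p), n_perm)
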