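"""Numba coordinate-descent kernels for elastic-net cross-validation.

The driver analysis refits penalized models thousands of times (7 predictor
combinations x repeated cross-validation x 999 response permutations), so
the inner solver is a compiled coordinate-descent loop rather than a
per-fit call into scikit-learn.  The objective follows scikit-learn's
convention:

    (1 / 2n) * ||y - Xw||^2  +  lam * alpha * ||w||_1
                             +  lam * (1 - alpha) / 2 * ||w||^2

so coefficients at a given (alpha, lam) agree with
``sklearn.linear_model.ElasticNet(alpha=lam, l1_ratio=alpha)`` — that
agreement is asserted in the test suite.

All kernels expect predictor columns already standardized on the full data;
fold-wise centering (of X columns and y) happens inside so each training
fit carries its own intercept.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: geometric span of the lambda path, lambda_max down to lambda_max * ratio
LAMBDA_MIN_RATIO = 1e-3
CD_TOL = 1e-7
CD_MAX_ITER = 500


@njit(cache=False)
def _cd_gram(G, q, l1, l2, w, tol, max_iter):
    """Elastic-net coordinate descent on sufficient statistics, warm-started.

    ``G = Xc^T Xc / n`` and ``q = Xc^T yc / n`` for centered X and y, so
    each coordinate sweep is O(p^2) regardless of n.
    """
    p = q.shape[0]
    gw = G @ w  # running G @ w, updated incrementally
    for _ in range(max_iter):
        max_change = 0.0
        for j in range(p):
            gjj = G[j, j]
            if gjj <= 0.0:
                w[j] = 0.0
                continue
            wj = w[j]
            rho = q[j] - gw[j] + gjj * wj
            if rho > l1:
                wnew = (rho - l1) / (gjj + l2)
            elif rho < -l1:
                wnew = (rho + l1) / (gjj + l2)
            else:
                wnew = 0.0
            d = wnew - wj
            if d != 0.0:
                for k in range(p):
                    gw[k] += G[k, j] * d
                w[j] = wnew
                ad = abs(d)
                if ad > max_change:
                    max_change = ad
        if max_change < tol:
            break
    return w


@njit(cache=False)
def _cd(X, y, l1, l2, w, tol, max_iter):
    """Elastic-net solve from raw (centered) X and y; thin Gram wrapper."""
    n = X.shape[0]
    G = (X.T @ X) / n
    q = (X.T @ y) / n
    return _cd_gram(G, q, l1, l2, w, tol, max_iter)


@njit(cache=False)
def _center_columns(X):
    n, p = X.shape
    out = np.empty_like(X)
    means = np.empty(p)
    for j in range(p):
        m = 0.0
        for i in range(n):
            m += X[i, j]
        m /= n
        means[j] = m
        for i in range(n):
            out[i, j] = X[i, j] - m
    return out, means


@njit(cache=False)
def _lambda_path(X, y, alpha, n_lambda, ratio):
    """Geometric lambda path from the smallest all-zeroing lambda downward."""
    n, p = X.shape
    Xc, _ = _center_columns(X)
    ym = y.mean()
    lam_max = 0.0
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += Xc[i, j] * (y[i] - ym)
        s = abs(s) / n
        if s > lam_max:
            lam_max = s
    a = alpha if alpha > 1e-3 else 1e-3
    lam_max = lam_max / a
    if lam_max <= 0.0:
        lam_max = 1e-12
    path = np.empty(n_lambda)
    if n_lambda == 1:
        path[0] = lam_max
        return path
    step = ratio ** (1.0 / (n_lambda - 1))
    lam = lam_max
    for k in range(n_lambda):
        path[k] = lam
        lam *= step
    return path


@njit(cache=False)
def _cv_sse(X, y, fold_ids, n_folds, alphas, n_lambda, ratio, tol, max_iter):
    """Summed validation squared error for every (alpha, lambda) grid point."""
    n, p = X.shape
    n_alpha = alphas.shape[0]
    sse = np.zeros((n_alpha, n_lambda))
    paths = np.empty((n_alpha, n_lambda))
    for a in range(n_alpha):
        paths[a] = _lambda_path(X, y, alphas[a], n_lambda, ratio)
    for f in range(n_folds):
        n_te = 0
        for i in range(n):
            if fold_ids[i] == f:
                n_te += 1
        n_tr = n - n_te
        if n_tr == 0 or n_te == 0:
            continue
        Xtr = np.empty((n_tr, p))
        ytr = np.empty(n_tr)
        Xte = np.empty((n_te, p))
        yte = np.empty(n_te)
        it = 0
        ie = 0
        for i in range(n):
            if fold_ids[i] == f:
                Xte[ie] = X[i]
                yte[ie] = y[i]
                ie += 1
            else:
                Xtr[it] = X[i]
                ytr[it] = y[i]
                it += 1
        Xtrc, mx = _center_columns(Xtr)
        my = ytr.mean()
        ytrc = ytr - my
        G = (Xtrc.T @ Xtrc) / n_tr
        q = (Xtrc.T @ ytrc) / n_tr
        Xtec = Xte - mx
        ytec = yte - my
        for a in range(n_alpha):
            alpha = alphas[a]
            w = np.zeros(p)
            for k in range(n_lambda):
                lam = paths[a, k]
                w = _cd_gram(G, q, lam * alpha, lam * (1.0 - alpha), w, tol, max_iter)
                for i in range(n_te):
                    pred = 0.0
                    for j in range(p):
                        pred += Xtec[i, j] * w[j]
                    d = pred - ytec[i]
                    sse[a, k] += d * d
    return sse, paths


@njit(cache=False)
def _refit(X, y, alpha, paths_row, k_best, tol, max_iter):
    """Warm-started refit on all rows down the path to the selected lambda."""
    n, p = X.shape
    Xc, _ = _center_columns(X)
    my = y.mean()
    yc = y - my
    G = (Xc.T @ Xc) / n
    q = (Xc.T @ yc) / n
    w = np.zeros(p)
    for k in range(k_best + 1):
        lam = paths_row[k]
        w = _cd_gram(G, q, lam * alpha, lam * (1.0 - alpha), w, tol, max_iter)
    sse = 0.0
    sst = 0.0
    for i in range(n):
        pred = 0.0
        for j in range(p):
            pred += Xc[i, j] * w[j]
        d = yc[i] - pred
        sse += d * d
        sst += yc[i] * yc[i]
    r2 = 1.0 - sse / sst if sst > 0.0 else 0.0
    return w, my, r2


@njit(cache=False)
def fit_en_cv_core(X, y, fold_ids, n_folds, alphas, n_lambda, ratio, tol, max_iter):
    """Grid-search CV and refit; returns (alpha_idx, lambda, coefs, intercept, r2).

    Ties in validation RMSE break toward the smallest alpha, then the
    largest lambda (the more shrunken, more parsimonious model).
    """
    sse, paths = _cv_sse(X, y, fold_ids, n_folds, alphas, n_lambda, ratio, tol, max_iter)
    best_a = 0
    best_k = 0
    best = np.inf
    for a in range(alphas.shape[0]):
        for k in range(n_lambda):
            # strict < keeps the first (smallest alpha, largest lambda) optimum
            if sse[a, k] < best - 1e-15:
                best = sse[a, k]
                best_a = a
                best_k = k
    w, intercept, r2 = _refit(X, y, alphas[best_a], paths[best_a], best_k, tol, max_iter)
    return best_a, paths[best_a, best_k], w, intercept, r2


@njit(cache=False)
def mean_r2adj_core(X, y, fold_ids_all, n_folds, alphas, n_lambda, ratio, tol, max_iter):
    """Mean adjusted R^2 over repeated CV reruns (one fold layout per row)."""
    n, p = X.shape
    repeats = fold_ids_all.shape[0]
    acc = 0.0
    for r in range(repeats):
        _, _, _, _, r2 = fit_en_cv_core(
            X, y, fold_ids_all[r], n_folds, alphas, n_lambda, ratio, tol, max_iter
        )
        acc += 1.0 - (1.0 - r2) * (n - 1.0) / (n - p - 1.0)
    return acc / repeats


@njit(cache=False)
def partition_combos_core(
    X, y, combo_cols, combo_len, fold_ids_all, n_folds, alphas, n_lambda, ratio, tol, max_iter
):
    """Mean adjusted R^2 for each predictor-set combination.

    ``combo_cols[c, :combo_len[c]]`` holds the column indices of combination
    c in the full standardized design X.
    """
    n_combo = combo_cols.shape[0]
    out = np.empty(n_combo)
    n = X.shape[0]
    for c in range(n_combo):
        pc = combo_len[c]
        Xc = np.empty((n, pc))
        for j in range(pc):
            Xc[:, j] = X[:, combo_cols[c, j]]
        out[c] = mean_r2adj_core(
            Xc, y, fold_ids_all, n_folds, alphas, n_lambda, ratio, tol, max_iter
        )
    return out
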