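"""Elastic-net regression with cross-validated (alpha, lambda) tuning.

The elastic net blends ridge and lasso penalties: ``alpha`` in [0, 1] sets
the blend (1 = lasso) and ``lambda`` the shrinkage strength.  Both are
tuned by k-fold cross-validation minimizing validation RMSE, and the model
is then refit on all rows at the selected pair.  Because a single CV split
is noisy at small n, :func:`mean_r2adj` averages the adjusted R^2 over many
independent CV reruns.

Model performance is summarized by the adjusted R^2,
``1 - (1 - R^2) (n - 1) / (n - p - 1)``, with ``p`` the number of
predictors offered to the model (not the number surviving shrinkage;
``p_adjust="selected"`` switches to the latter).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _engine
from ._engine import CD_MAX_ITER, CD_TOL, LAMBDA_MIN_RATIO

__all__ = ["ENFit", "adjusted_r2", "fit_en", "fit_en_cv", "mean_r2adj", "default_alpha_grid"]


def default_alpha_grid() -> np.ndarray:
    """Alpha grid 0.05, 0.10, ..., 1.00."""
    return np.round(np.arange(1, 21) * 0.05, 2)


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - p - 1); may be negative."""
    if n - p - 1 <= 0:
        raise ValueError(f"adjusted R^2 undefined: n - p - 1 = {n - p - 1} <= 0")
    return 1.0 - (1.0 - r2) * (n - 1.0) / (n - p - 1.0)


@dataclass
class ENFit:
    """A tuned-and-refit elastic-net model."""

    alpha: float
    lam: float
    coefficients: np.ndarray  # slopes on the standardized predictor scale
    intercept: float
    r2: float
    r2adj: float
    n: int
    p: int  # predictors offered

    def predict(self, X_std: np.ndarray) -> np.ndarray:
        """Predict from predictors already on the standardized scale."""
        return self.intercept + X_std @ self.coefficients


def standardize(X: np.ndarray) -> np.ndarray:
    """Column z-scores (population SD).  Penalties are not scale-invariant,
    so all predictors enter on a common scale."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)  # constant columns stay constant (zero) after centering
    return (X - mu) / sd


def _check_response(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float).ravel()
    if np.ptp(y) == 0:
        raise ValueError("response is constant; model undefined")
    return y


def fold_layouts(n: int, folds: int, repeats: int, rng: np.random.Generator) -> np.ndarray:
    """``repeats`` independent random k-fold assignments (rows of fold ids)."""
    base = np.arange(n) % folds
    return rng.permuted(np.tile(base, (repeats, 1)), axis=1)


def fit_en(y, X, alpha: float, lam: float, *, standardized: bool = False) -> ENFit:
    """Single elastic-net fit at a fixed (alpha, lambda) — no tuning.

    Useful for the limiting cases: ``lam=0`` reproduces least squares,
    ``lam`` very large shrinks every slope to zero (intercept-only, R^2 = 0).
    """
    y = _check_response(y)
    X = np.asarray(X, dtype=float)
    Xs = X if standardized else standardize(X)
    n, p = Xs.shape
    Xc = Xs - Xs.mean(axis=0)
    yc = y - y.mean()
    w = _engine._cd(
        Xc, yc, lam * alpha, lam * (1.0 - alpha), np.zeros(p), 1e-12, 100 * CD_MAX_ITER
    )
    resid = yc - Xc @ w
    sst = float(yc @ yc)
    r2 = 1.0 - float(resid @ resid) / sst if sst > 0 else 0.0
    return ENFit(alpha, lam, w, float(y.mean()), r2, adjusted_r2(r2, n, p), n, p)


def fit_en_cv(
    y,
    X,
    folds: int = 5,
    alpha_grid=None,
    seed: int | None = 0,
    *,
    n_lambda: int = 50,
    lambda_min_ratio: float = LAMBDA_MIN_RATIO,
    rng: np.random.Generator | None = None,
    standardized: bool = False,
) -> ENFit:
    """Tune (alpha, lambda) by k-fold CV on RMSE and refit on all rows.

    The lambda path per alpha is geometric over ``n_lambda`` points from the
    smallest lambda that zeroes every slope.  RMSE ties break toward the
    smallest alpha, then the largest lambda.  Fold assignment is
    reproducible from ``seed`` (or an explicit ``rng``).
    """
    y = _check_response(y)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n != y.shape[0]:
        raise ValueError("y and X row counts differ")
    if not (2 <= folds <= n):
        raise ValueError(f"need 2 <= folds <= n rows, got folds={folds}, n={n}")
    Xs = X if standardized else standardize(X)
    alphas = np.asarray(alpha_grid if alpha_grid is not None else default_alpha_grid(), float)
    if rng is None:
        rng = np.random.default_rng(seed)
    fold_ids = fold_layouts(n, folds, 1, rng)[0]
    a_idx, lam, w, intercept, r2 = _engine.fit_en_cv_core(
        Xs, y, fold_ids, folds, alphas, n_lambda, lambda_min_ratio, CD_TOL, CD_MAX_ITER
    )
    return ENFit(float(alphas[a_idx]), float(lam), w, float(intercept), float(r2),
                 adjusted_r2(r2, n, p), n, p)


def mean_r2adj(
    y,
    X,
    repeats: int = 100,
    folds: int = 5,
    alpha_grid=None,
    seed: int | None = 0,
    *,
    n_lambda: int = 50,
    lambda_min_ratio: float = LAMBDA_MIN_RATIO,
    rng: np.random.Generator | None = None,
    p_adjust: str = "offered",
    standardized: bool = False,
) -> float:
    """Mean adjusted R^2 over ``repeats`` independent CV reruns.

    Each rerun reshuffles the fold assignment; the mean damps the
    instability of a single CV split at small sample size.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    y = _check_response(y)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n - p - 1 <= 0:
        raise ValueError(f"adjusted R^2 undefined for n={n}, p={p}; offer fewer predictors")
    Xs = X if standardized else standardize(X)
    alphas = np.asarray(alpha_grid if alpha_grid is not None else default_alpha_grid(), float)
    if rng is None:
        rng = np.random.default_rng(seed)
    fold_ids = fold_layouts(n, folds, repeats, rng)
    if p_adjust == "offered":
        return float(
            _engine.mean_r2adj_core(
                Xs, y, fold_ids, folds, alphas, n_lambda, lambda_min_ratio, CD_TOL, CD_MAX_ITER
            )
        )
    if p_adjust != "selected":
        raise ValueError("p_adjust must be 'offered' or 'selected'")
    acc = 0.0
    for r in range(repeats):
        _, _, w, _, r2 = _engine.fit_en_cv_core(
            Xs, y, fold_ids[r], folds, alphas, n_lambda, lambda_min_ratio, CD_TOL, CD_MAX_ITER
        )
        p_sel = max(int(np.count_nonzero(w)), 0)
        if n - p_sel - 1 <= 0:
            raise ValueError("selected-predictor adjustment undefined: n - p_sel - 1 <= 0")
        acc += adjusted_r2(r2, n, p_sel)
    return acc / repeats
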