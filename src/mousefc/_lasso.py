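"""Multinomial logistic LASSO by partial-Newton coordinate descent.

Minimizes, over class weights W (K x p) and intercepts b,

    F(W, b) = -loglik(W, b; X, y) + lam * sum_jk |W_kj|

with the (unscaled, summed) multinomial log-likelihood.  The algorithm is
the classic penalized-GLM scheme: an outer loop forms, per class, the
quadratic approximation of the log-likelihood at the current probabilities
(working response and weights), and an inner weighted-lasso coordinate
descent solves it with soft-thresholding, iterating over the active set
and finishing with full verification passes.  The parameterization is the
symmetric (over-parameterized) one; the L1 penalty picks the minimal-norm
gauge for the weights and the intercepts are mean-centered.

The model is fit on standardized columns internally; public wrappers in
:mod:`mousefc.netclass` return coefficients on the original feature scale.
"""
from __future__ import annotations

import numpy as np
from numba import njit

_WEIGHT_FLOOR = 1e-5  # glmnet-style floor on p(1-p)


@njit(cache=True)
def _cd_pass(X, v, w, b, lam, r, only_active):
    """One coordinate-descent sweep; returns (b, max parameter change)."""
    n, p = X.shape
    delta = 0.0
    sv = v.sum()
    db = (v * r).sum() / sv
    b += db
    for i in range(n):
        r[i] -= db
    if abs(db) > delta:
        delta = abs(db)
    for j in range(p):
        if only_active and w[j] == 0.0:
            continue
        denom = 0.0
        rho = 0.0
        for i in range(n):
            vx = v[i] * X[i, j]
            denom += vx * X[i, j]
            rho += vx * r[i]
        if denom <= 0.0:
            continue
        rho += denom * w[j]
        if rho > lam:
            wj = (rho - lam) / denom
        elif rho < -lam:
            wj = (rho + lam) / denom
        else:
            wj = 0.0
        d = wj - w[j]
        if d != 0.0:
            for i in range(n):
                r[i] -= d * X[i, j]
            w[j] = wj
            if abs(d) > delta:
                delta = abs(d)
    return b, delta


@njit(cache=True)
def _cd_weighted_lasso(X, v, z, w, b, lam, tol, max_sweeps):
    """Solve min 0.5*sum v_i (z_i - b - x_i.w)^2 + lam*|w|_1 by CD."""
    r = z - b - X @ w
    b, _ = _cd_pass(X, v, w, b, lam, r, False)
    for _ in range(max_sweeps):
        b, delta = _cd_pass(X, v, w, b, lam, r, True)
        if delta < tol:
            b, delta = _cd_pass(X, v, w, b, lam, r, False)
            if delta < tol:
                break
    return b


def _softmax(eta: np.ndarray) -> np.ndarray:
    m = eta.max(axis=1, keepdims=True)
    p = np.exp(eta - m)
    p /= p.sum(axis=1, keepdims=True)
    return p


def fit_multinomial_cd(X: np.ndarray, y_onehot: np.ndarray, lam: float,
                       tol: float = 1e-6, max_outer: int = 500,
                       warm: tuple | None = None):
    """Fit the penalized multinomial model; returns ``(W, b, n_outer)``.

    ``warm`` optionally carries ``(W, b)`` from a nearby lambda to warm-start
    a regularization path.  ``tol`` bounds the maximum change of any linear
    predictor between outer iterations (and, scaled by 0.1, the inner
    coordinate moves), which bounds the KKT residual at the optimum.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    Y = np.asarray(y_onehot, dtype=np.float64)
    n, p = X.shape
    K = Y.shape[1]
    if warm is not None:
        W = warm[0].copy()
        b = warm[1].copy()
    else:
        W = np.zeros((K, p))
        b = np.log(Y.mean(axis=0) + 1e-12)
        b -= b.mean()
    eta = b[None, :] + X @ W.T
    n_outer = 0
    for n_outer in range(1, max_outer + 1):
        eta_old = eta.copy()
        for k in range(K):
            P = _softmax(eta)
            v = np.clip(P[:, k] * (1.0 - P[:, k]), _WEIGHT_FLOOR, None)
            z = eta[:, k] + (Y[:, k] - P[:, k]) / v
            b[k] = _cd_weighted_lasso(X, v, z, W[k], b[k], lam,
                                      tol * 0.1, 1000)
            eta[:, k] = b[k] + X @ W[k]
        if np.abs(eta - eta_old).max() < tol:
            break
    b = b - b.mean()
    return W, b, n_outer


def penalized_objective(X, y_onehot, W, b, lam: float) -> float:
    """F(W, b) = negative multinomial log-likelihood + lam * |W|_1."""
    eta = np.asarray(b)[None, :] + np.asarray(X) @ np.asarray(W).T
    m = eta.max(axis=1, keepdims=True)
    log_z = m[:, 0] + np.log(np.exp(eta - m).sum(axis=1))
    ll = float((eta * y_onehot).sum() - log_z.sum())
    return -ll + lam * float(np.abs(W).sum())


def lambda_max(X: np.ndarray, y_onehot: np.ndarray) -> float:
    """Smallest lambda at which all weights are zero (KKT bound at the
    intercept-only solution)."""
    pbar = y_onehot.mean(axis=0, keepdims=True)
    g = X.T @ (y_onehot - pbar)          # (p, K) score at null model
    return float(np.abs(g).max())
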