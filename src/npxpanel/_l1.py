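"""L1-penalized logistic regression with per-feature penalty factors.

The stability-selection loop needs a lasso logistic fit in which the core
clinical covariates (HE4, CA125, age) are carried unpenalized while the
candidate markers compete under the L1 penalty. That per-feature penalty
weighting is the one thing the scikit-learn lasso does not expose, so the
solver lives here: penalized iteratively-reweighted least squares with
cyclic coordinate descent and soft-thresholding, warm-started down a
geometric lambda path (the standard algorithm for this problem class).
Inner loops are numba-compiled; all fits are on internally standardized
predictors, so coefficients come back in per-SD units.

The objective, for labels y in {0,1} and penalty factors w_j >= 0, is

    (1/n) * sum_i [log(1 + exp(eta_i)) - y_i * eta_i]
        + lambda * sum_j w_j * |beta_j| ,      eta = b0 + X beta.

Forced (unpenalized) features have w_j = 0; the intercept is never
penalized.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_EPS_W = 1e-5  # floor on IRLS weights, guards against p*(1-p) underflow


@njit(cache=True)
def _soft(z: float, g: float) -> float:
    if z > g:
        return z - g
    if z < -g:
        return z + g
    return 0.0


@njit(cache=True)
def _sweep(X, w, r, beta, den, lam, pf, n, idx):
    """One coordinate-descent pass over ``idx``; returns max |update|."""

    dmax = 0.0
    for jj in range(idx.shape[0]):
        j = idx[jj]
        if den[j] <= 0.0:
            continue
        bj = beta[j]
        num = 0.0
        for i in range(n):
            num += w[i] * X[i, j] * r[i]
        num = num / n + den[j] * bj
        bnew = _soft(num, lam * pf[j]) / den[j]
        d = bnew - bj
        if d != 0.0:
            for i in range(n):
                r[i] -= X[i, j] * d
            beta[j] = bnew
            if abs(d) > dmax:
                dmax = abs(d)
    # intercept (never penalized)
    sw = 0.0
    sr = 0.0
    for i in range(n):
        sw += w[i]
        sr += w[i] * r[i]
    d0 = sr / sw
    if d0 != 0.0:
        for i in range(n):
            r[i] -= d0
        if abs(d0) > dmax:
            dmax = abs(d0)
    return dmax, d0


@njit(cache=True)
def _cd_path(X, y, lambdas, pf, max_outer, max_inner, tol):
    """Coordinate-descent path, warm-started across ``lambdas``.

    Returns (intercepts, coefficient matrix) with one row per lambda.
    ``X`` must already be standardized; ``pf`` is the per-feature penalty
    factor vector (0 = unpenalized). Each inner solve alternates full
    passes with passes over the active set (nonzero or unpenalized
    coordinates), the usual speed trick for sparse paths.
    """

    n, p = X.shape
    nlam = lambdas.shape[0]
    b0s = np.zeros(nlam)
    betas = np.zeros((nlam, p))

    beta = np.zeros(p)
    ybar = y.mean()
    if ybar <= 0.0 or ybar >= 1.0:
        raise ValueError("labels are single-class")
    b0 = np.log(ybar / (1.0 - ybar))
    all_idx = np.arange(p)
    w = np.empty(n)
    r = np.empty(n)
    den = np.empty(p)
    active = np.empty(p, dtype=np.int64)

    for li in range(nlam):
        lam = lambdas[li]
        for _outer in range(max_outer):
            eta = b0 + X @ beta
            for i in range(n):
                e = eta[i]
                if e > 30.0:
                    pi = 1.0
                elif e < -30.0:
                    pi = 0.0
                else:
                    pi = 1.0 / (1.0 + np.exp(-e))
                wi = pi * (1.0 - pi)
                if wi < _EPS_W:
                    wi = _EPS_W
                w[i] = wi
                r[i] = (y[i] - pi) / wi  # z - eta
            for j in range(p):
                s = 0.0
                for i in range(n):
                    s += w[i] * X[i, j] * X[i, j]
                den[j] = s / n
            for _inner in range(max_inner):
                dmax, d0 = _sweep(X, w, r, beta, den, lam, pf, n, all_idx)
                b0 += d0
                if dmax < tol:
                    break
                for _ac in range(max_inner):
                    na = 0
                    for j in range(p):
                        if beta[j] != 0.0 or pf[j] == 0.0:
                            active[na] = j
                            na += 1
                    dmax_a, d0a = _sweep(X, w, r, beta, den, lam, pf, n, active[:na])
                    b0 += d0a
                    if dmax_a < tol:
                        break
            eta_new = b0 + X @ beta
            dd = 0.0
            for i in range(n):
                a = abs(eta_new[i] - eta[i])
                if a > dd:
                    dd = a
            if dd < tol:
                break
        b0s[li] = b0
        betas[li] = beta
    return b0s, betas


def standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center/scale columns; constant columns get scale 1 (coef stays 0)."""

    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    return (X - mean) / sd, mean, sd


def lambda_grid(
    Z: np.ndarray,
    y: np.ndarray,
    pf: np.ndarray,
    n_lambda: int = 30,
    min_ratio: float = 0.01,
) -> np.ndarray:
    """Geometric lambda path from the smallest lambda that zeroes every
    penalized coefficient down to ``min_ratio`` times it."""

    n = len(y)
    resid = y - y.mean()
    grad = np.abs(Z.T @ resid) / n
    pen = pf > 0
    if not pen.any():
        raise ValueError("no penalized features")
    lam_max = float(grad[pen].max())
    if lam_max <= 0:
        lam_max = 1e-3
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


def fit_l1_path(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray,
    pf: np.ndarray,
    max_outer: int = 25,
    max_inner: int = 200,
    tol: float = 1e-7,
):
    """Fit the penalized path; returns standardized-scale coefficients.

    Output: ``(b0s, betas, mean, sd)`` where ``betas[k]`` are the per-SD
    coefficients at ``lambdas[k]`` and predictions on new data use
    ``b0 + ((Xnew - mean) / sd) @ beta``.
    """

    Z, mean, sd = standardize(X)
    y = np.asarray(y, dtype=float)
    b0s, betas = _cd_path(
        Z,
        y,
        np.asarray(lambdas, dtype=float),
        np.asarray(pf, dtype=float),
        max_outer,
        max_inner,
        tol,
    )
    return b0s, betas, mean, sd


def binomial_deviance(y: np.ndarray, eta: np.ndarray) -> float:
    """Mean binomial deviance (-2 * average log-likelihood)."""

    y = np.asarray(y, dtype=float)
    eta = np.clip(np.asarray(eta, dtype=float), -30.0, 30.0)
    ll = y * eta - np.log1p(np.exp(eta))
    return float(-2.0 * ll.mean())


def fit_at_lambda(
    X: np.ndarray, y: np.ndarray, lam: float, pf: np.ndarray, n_path: int = 20
):
    """Fit at a single lambda, warm-starting from the null end of a short
    path (lambda larger than this data's lambda_max selects nothing
    penalized, which is the correct degenerate answer)."""

    Z, mean, sd = standardize(X)
    y = np.asarray(y, dtype=float)
    resid = y - y.mean()
    grad = np.abs(Z.T @ resid) / len(y)
    lam_max = float(grad[np.asarray(pf) > 0].max()) if (np.asarray(pf) > 0).any() else lam
    if lam >= lam_max:
        path = np.array([lam])
    else:
        path = np.append(np.geomspace(lam_max, lam, n_path)[:-1], lam)
    b0s, betas = _cd_path(
        Z, y, path, np.asarray(pf, dtype=float), 50, 200, 1e-7
    )
    return float(b0s[-1]), betas[-1], mean, sd
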