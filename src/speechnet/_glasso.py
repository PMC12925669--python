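"""Graphical-lasso solver and EBIC path kernels.

Block coordinate descent in the covariance parameterization (Friedman et
al. style): cycle over variables, solve an L1-penalized regression of each
variable on the rest against the current working covariance, and update
the corresponding row/column. The diagonal is unpenalized, so the working
covariance keeps the sample variances on its diagonal. The precision
matrix is recovered from the final regression coefficients, which makes
zero patterns exact (an excluded predictor gives an exactly zero
precision entry).

The kernels are numba-jitted because bootstrap and permutation loops
re-estimate the whole penalty path tens of thousands of times.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["glasso_single", "ebic_glasso_path", "make_lambda_grid"]


@njit(cache=True)
def _glasso_cd(S, lam, tol, max_iter, W, B):
    """One glasso solve, warm-started from (W, B). Modifies W, B in place.

    Returns (n_iter, converged flag). Convergence is mean absolute change
    of the off-diagonal working covariance below ``tol * mean |S_offdiag|``
    (absolute ``tol`` when S is diagonal).
    """
    p = S.shape[0]
    # scale for the convergence threshold
    s_off = 0.0
    for i in range(p):
        for j in range(p):
            if i != j:
                s_off += abs(S[i, j])
    denom = p * (p - 1)
    mean_off = s_off / denom if denom > 0 else 0.0
    thresh = tol * mean_off if mean_off > 0 else tol

    for i in range(p):
        W[i, i] = S[i, i]

    if p == 1:
        return 1, True

    beta = np.empty(p - 1)
    idx = np.empty(p - 1, dtype=np.int64)

    for it in range(max_iter):
        max_delta = 0.0
        total_delta = 0.0
        for col in range(p):
            k = 0
            for j in range(p):
                if j != col:
                    idx[k] = j
                    k += 1
            for k in range(p - 1):
                beta[k] = B[idx[k], col]
            # inner lasso coordinate descent on:
            #   0.5 b' W11 b - s12' b + lam |b|_1
            for _inner in range(200):
                inner_delta = 0.0
                for k in range(p - 1):
                    jk = idx[k]
                    r = S[jk, col]
                    for m in range(p - 1):
                        if m != k:
                            r -= W[jk, idx[m]] * beta[m]
                    old = beta[k]
                    if r > lam:
                        new = (r - lam) / W[jk, jk]
                    elif r < -lam:
                        new = (r + lam) / W[jk, jk]
                    else:
                        new = 0.0
                    beta[k] = new
                    d = abs(new - old)
                    if d > inner_delta:
                        inner_delta = d
                if inner_delta < 1e-10:
                    break
            # update working covariance column: w12 = W11 beta
            for k in range(p - 1):
                jk = idx[k]
                new_w = 0.0
                for m in range(p - 1):
                    new_w += W[jk, idx[m]] * beta[m]
                d = abs(new_w - W[jk, col])
                total_delta += d
                if d > max_delta:
                    max_delta = d
                W[jk, col] = new_w
                W[col, jk] = new_w
                B[jk, col] = beta[k]
        mean_delta = total_delta / denom
        if mean_delta < thresh:
            return it + 1, True
    return max_iter, False


@njit(cache=True)
def _precision_from_wb(W, B):
    """Recover Theta from the working covariance and regression coefficients."""
    p = W.shape[0]
    Theta = np.zeros((p, p))
    for col in range(p):
        # theta_col,col = 1 / (w_col,col - w12' beta)
        dot = 0.0
        for j in range(p):
            if j != col:
                dot += W[j, col] * B[j, col]
        tcc = 1.0 / (W[col, col] - dot)
        Theta[col, col] = tcc
        for j in range(p):
            if j != col and B[j, col] != 0.0:
                Theta[j, col] = -B[j, col] * tcc
    # symmetrize, preserving exact zeros
    for i in range(p):
        for j in range(i + 1, p):
            if Theta[i, j] == 0.0 or Theta[j, i] == 0.0:
                v = 0.0
            else:
                v = 0.5 * (Theta[i, j] + Theta[j, i])
            Theta[i, j] = v
            Theta[j, i] = v
    return Theta


def glasso_single(S, lam, tol=1e-4, max_iter=10000):
    """Solve one graphical lasso problem from a cold start.

    Returns (Theta, n_iter, converged).
    """
    S = np.ascontiguousarray(S, dtype=np.float64)
    p = S.shape[0]
    W = S.copy()
    B = np.zeros((p, p))
    n_iter, ok = _glasso_cd(S, float(lam), float(tol), int(max_iter), W, B)
    return _precision_from_wb(W, B), int(n_iter), bool(ok)


@njit(cache=True)
def _ebic_of(Theta, S, n, gamma):
    """EBIC = -2L + E log n + 4 E gamma log p, L = (n/2)(logdet - tr(S Theta))."""
    p = Theta.shape[0]
    L_chol = np.linalg.cholesky(Theta)
    logdet = 0.0
    for i in range(p):
        logdet += 2.0 * np.log(L_chol[i, i])
    tr = 0.0
    for i in range(p):
        for j in range(p):
            tr += S[i, j] * Theta[j, i]
    E = 0
    for i in range(p):
        for j in range(i + 1, p):
            if Theta[i, j] != 0.0:
                E += 1
    loglik = 0.5 * n * (logdet - tr)
    return -2.0 * loglik + E * np.log(n) + 4.0 * E * gamma * np.log(p)


@njit(cache=True)
def ebic_glasso_path(S, n, gamma, lambdas, tol, max_iter):
    """Fit the full penalty path (lambdas descending) with warm starts.

    Returns (thetas: (nlam, p, p), ebics, converged flags). Ties in EBIC
    are broken by the caller toward the larger penalty (sparser model).
    """
    p = S.shape[0]
    nlam = lambdas.shape[0]
    thetas = np.empty((nlam, p, p))
    ebics = np.empty(nlam)
    converged = np.zeros(nlam, dtype=np.bool_)
    W = S.copy()
    B = np.zeros((p, p))
    for li in range(nlam):
        _, ok = _glasso_cd(S, lambdas[li], tol, max_iter, W, B)
        converged[li] = ok
        Theta = _precision_from_wb(W, B)
        thetas[li] = Theta
        if ok:
            ebics[li] = _ebic_of(Theta, S, n, gamma)
        else:
            ebics[li] = np.inf
    return thetas, ebics, converged


def make_lambda_grid(S, nlambda=100, lambda_min_ratio=0.01):
    """Log-spaced penalty grid from lambda_max = max off-diagonal |S| down
    to lambda_max * lambda_min_ratio, descending."""
    p = S.shape[0]
    off = np.abs(S - np.diag(np.diag(S)))
    lam_max = float(off.max()) if p > 1 else 0.0
    if lam_max <= 0:
        # perfectly diagonal input: any penalty gives the empty model
        return np.array([0.0])
    return np.logspace(np.log10(lam_max), np.log10(lam_max * lambda_min_ratio),
                       int(nlambda))
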