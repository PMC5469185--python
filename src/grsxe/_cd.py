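"""Elastic-net penalized logistic regression by cyclic coordinate descent.

Outer loop: iteratively reweighted least squares (quadratic
approximation of the binomial log-likelihood at the current linear
predictor).  Inner loop: cyclic coordinate descent on the penalized
weighted least-squares problem, using precomputed weighted Gram
("covariance") updates so a full sweep costs O(p^2) independent of n.
Solutions are computed along a descending lambda path with warm
starts.  The per-observation objective minimized is

    (1/n) sum_i nll_i(b0, w) + lam * sum_j (alpha |w_j|
                                            + (1 - alpha)/2 w_j^2)

with an unpenalized intercept, matching the conventions of
coordinate-descent elastic-net software, so lambda values are directly
comparable to glmnet's.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, logit

__all__ = ["enet_logistic_path"]

_PMIN = 1e-5  # probability clamp in the IRLS weights


def _soft(x: float, t: float) -> float:
    if x > t:
        return x - t
    if x < -t:
        return x + t
    return 0.0


def _solve_one(
    Z: np.ndarray,
    y: np.ndarray,
    lam: float,
    alpha: float,
    w: np.ndarray,
    b0: float,
    tol: float,
    outer_tol: float,
    max_inner: int,
    max_outer: int,
) -> tuple[np.ndarray, float, bool]:
    n, p = Z.shape
    converged = False
    obj_prev = np.inf
    for _outer in range(max_outer):
        eta = b0 + Z @ w
        # outer (IRLS) convergence: relative change of the penalized
        # objective (the quantity the algorithm actually minimizes)
        nll = float(np.sum(np.logaddexp(0.0, eta) - y * eta))
        pen = n * lam * float(np.sum(alpha * np.abs(w) + 0.5 * (1 - alpha) * w**2))
        obj = nll + pen
        if abs(obj_prev - obj) < outer_tol * (abs(obj) + 0.1):
            converged = True
            break
        obj_prev = obj
        pr = np.clip(expit(eta), _PMIN, 1 - _PMIN)
        W = pr * (1 - pr)
        z = eta + (y - pr) / W
        # weighted sufficient statistics for the quadratic subproblem
        ZW = Z * W[:, None]
        A = (ZW.T @ Z) / n
        c = Z.T @ (W * z) / n
        u = ZW.sum(axis=0) / n
        s0 = W.mean()
        t0 = (W * z).mean()
        diag = np.diag(A).copy()
        denom = diag + lam * (1.0 - alpha)
        thr = lam * alpha

        Aw = A @ w
        for _it in range(max_inner):
            dmax = 0.0
            for j in range(p):
                if denom[j] <= 1e-12:
                    continue
                g = c[j] - b0 * u[j] - (Aw[j] - diag[j] * w[j])
                wj = _soft(g, thr) / denom[j]
                d = wj - w[j]
                if d != 0.0:
                    Aw += A[:, j] * d
                    w[j] = wj
                    dd = diag[j] * d * d
                    if dd > dmax:
                        dmax = dd
            b0_new = (t0 - float(u @ w)) / s0
            db = b0_new - b0
            if s0 * db * db > dmax:
                dmax = s0 * db * db
            b0 = b0_new
            if dmax < tol:
                break
    w[np.abs(w) < 1e-10] = 0.0  # clear float drift from incremental updates
    return w, b0, converged


def enet_logistic_path(
    Z: np.ndarray,
    y: np.ndarray,
    lams: np.ndarray,
    alpha: float,
    tol: float = 1e-10,
    outer_tol: float = 1e-9,
    max_inner: int = 400,
    max_outer: int = 30,
):
    """Yield (coef, intercept, converged) along a descending lambda path."""
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    p = Z.shape[1]
    w = np.zeros(p)
    b0 = float(logit(np.clip(y.mean(), _PMIN, 1 - _PMIN)))
    for lam in lams:
        w, b0, ok = _solve_one(
            Z, y, float(lam), float(alpha), w, b0, tol, outer_tol, max_inner, max_outer
        )
        yield w.copy(), b0, ok
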