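"""Cyclic coordinate-descent kernel for penalized weighted least squares.

Solves, for fixed observation weights ``w`` and working response ``z``,

    min_{b0, beta}  (1/2n) sum_i w_i (z_i - b0 - x_i beta)^2
                    + lam * sum_j pf_j * P(beta_j)

with P either |.| (soft-thresholding) or (.)^2.  ``pf_j = 0`` leaves a
coefficient unpenalized, ``pf_j = inf`` pins it at zero.  The kernel is the
inner loop of the IRLS solvers and is JIT-compiled; it mutates ``beta`` and
the residual in place and returns the intercept and sweep count.
"""

import numpy as np
from numba import njit


@njit(cache=True, fastmath=False)
def _sweep(X, w, z, beta, b0, lam, pf, l1, use_intercept, xv, r, sw, n, active_only):
    """One pass over the coordinates (optionally only currently-nonzero ones);
    returns (b0, maxdelta)."""
    p = X.shape[1]
    maxdelta = 0.0
    if use_intercept and sw > 0.0:
        num = 0.0
        for i in range(n):
            num += w[i] * r[i]
        db0 = num / sw
        b0 += db0
        for i in range(n):
            r[i] -= db0
        if abs(db0) > maxdelta:
            maxdelta = abs(db0)
    for j in range(p):
        if active_only and beta[j] == 0.0:
            continue
        if not np.isfinite(pf[j]) or xv[j] <= 0.0:
            continue
        rho = 0.0
        for i in range(n):
            rho += w[i] * X[i, j] * r[i]
        rho = rho / n + xv[j] * beta[j]
        if l1:
            thr = lam * pf[j]
            if rho > thr:
                new = (rho - thr) / xv[j]
            elif rho < -thr:
                new = (rho + thr) / xv[j]
            else:
                new = 0.0
        else:
            new = rho / (xv[j] + 2.0 * lam * pf[j])
        d = new - beta[j]
        if d != 0.0:
            for i in range(n):
                r[i] -= d * X[i, j]
            beta[j] = new
            if abs(d) > maxdelta:
                maxdelta = abs(d)
    return b0, maxdelta


@njit(cache=True, fastmath=False)
def cd_solve(X, w, z, beta, b0, lam, pf, l1, use_intercept, tol, max_sweeps):
    n, p = X.shape
    # (1/n) sum_i w_i x_ij^2, fixed while w is fixed
    xv = np.zeros(p)
    for j in range(p):
        acc = 0.0
        for i in range(n):
            acc += w[i] * X[i, j] * X[i, j]
        xv[j] = acc / n

    r = z.copy()
    for i in range(n):
        r[i] -= b0
    for j in range(p):
        if beta[j] != 0.0:
            for i in range(n):
                r[i] -= X[i, j] * beta[j]

    sw = 0.0
    for i in range(n):
        sw += w[i]

    # glmnet-style: full sweep to find the active set, then cycle on the
    # active set to convergence, then re-check with another full sweep.
    sweeps = 0
    while sweeps < max_sweeps:
        b0, maxdelta = _sweep(
            X, w, z, beta, b0, lam, pf, l1, use_intercept, xv, r, sw, n, False
        )
        sweeps += 1
        if maxdelta < tol:
            break
        while sweeps < max_sweeps:
            b0, maxdelta = _sweep(
                X, w, z, beta, b0, lam, pf, l1, use_intercept, xv, r, sw, n, True
            )
            sweeps += 1
            if maxdelta < tol:
                break
    return b0, sweeps
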