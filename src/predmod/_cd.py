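"""Numba coordinate-descent kernels for the penalized working least squares.

These kernels operate on the quadratic approximation of the Cox (or Poisson)
log-likelihood built by the outer IRLS loop.  They maintain the working
residual `r = z - X @ coef` in place.  Sweeps are restricted to a candidate
index set (sequential strong-rule screening); the outer loop verifies the
full Karush-Kuhn-Tucker conditions on the exact gradient and re-enters any
violating column.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_INF_WEIGHT = 1e18  # lam*weight at or above this marks a frozen (excluded) column


@njit(cache=True)
def _sweep(X, w, r, coef, lam_w, xwx, cand, only_active):
    """One coordinate-descent sweep over `cand`; returns max scaled change."""
    n = X.shape[0]
    maxd = 0.0
    for idx in range(cand.shape[0]):
        j = cand[idx]
        if lam_w[j] >= _INF_WEIGHT:
            continue
        cj = coef[j]
        if only_active and cj == 0.0:
            continue
        if xwx[j] <= 0.0:
            continue
        rho = cj * xwx[j]
        for i in range(n):
            rho += w[i] * r[i] * X[i, j]
        lw = lam_w[j]
        if lw > 0.0:
            if rho > lw:
                newc = (rho - lw) / xwx[j]
            elif rho < -lw:
                newc = (rho + lw) / xwx[j]
            else:
                newc = 0.0
        else:
            newc = rho / xwx[j]
        delta = newc - cj
        if delta != 0.0:
            for i in range(n):
                r[i] -= delta * X[i, j]
            coef[j] = newc
            d = abs(delta) * np.sqrt(xwx[j] / n)
            if d > maxd:
                maxd = d
    return maxd


@njit(cache=True)
def cd_solve(X, w, r, coef, lam_w, xwx, cand, tol, max_cycles):
    """Cyclic coordinate descent with soft-thresholding over `cand`.

    Minimizes 0.5 * sum_i w_i (z_i - x_i'c)^2 + sum_j lam_w_j |c_j| given the
    residual r = z - X @ coef (updated in place along with coef).
    Returns the number of sweeps performed.
    """
    cycles = 0
    while cycles < max_cycles:
        maxd = _sweep(X, w, r, coef, lam_w, xwx, cand, False)
        cycles += 1
        if maxd < tol:
            break
        # iterate on the current active subset until stable
        while cycles < max_cycles:
            maxd = _sweep(X, w, r, coef, lam_w, xwx, cand, True)
            cycles += 1
            if maxd < tol:
                break
    return cycles


@njit(cache=True)
def group_sweep(X, resid, M, eta, coef, grp_a, grp_b, lam, lip_safety, only_active):
    """One block-coordinate sweep for the paired group-lasso (Poisson IRLS).

    X        : patient-level design (n x q), columns addressed via grp_a/grp_b
    resid    : events - expected counts per patient (updated in place)
    M        : expected counts per patient (updated in place)
    eta      : covariate part of the linear predictor (updated in place)
    coef     : full coefficient vector (updated in place)
    grp_a/b  : column indices of (main, interaction) per group
    lam      : group penalty level
    Returns max scaled step over the sweep.
    """
    n = X.shape[0]
    G = grp_a.shape[0]
    maxd = 0.0
    for g in range(G):
        ja = grp_a[g]
        jb = grp_b[g]
        ca = coef[ja]
        cb = coef[jb]
        if only_active and ca == 0.0 and cb == 0.0:
            continue
        # gradient of the Poisson loglik wrt the pair, and a curvature bound
        # (largest eigenvalue of the 2x2 block of the current Hessian)
        ga = 0.0
        gb = 0.0
        saa = 0.0
        sbb = 0.0
        sab = 0.0
        for i in range(n):
            ga += resid[i] * X[i, ja]
            gb += resid[i] * X[i, jb]
            saa += M[i] * X[i, ja] * X[i, ja]
            sbb += M[i] * X[i, jb] * X[i, jb]
            sab += M[i] * X[i, ja] * X[i, jb]
        half = 0.5 * (saa + sbb)
        L = half + np.sqrt(0.25 * (saa - sbb) ** 2 + sab * sab)
        L = L * lip_safety + 1e-12
        ua = ca + ga / L
        ub = cb + gb / L
        norm = np.sqrt(ua * ua + ub * ub)
        if norm <= lam / L:
            na, nb = 0.0, 0.0
        else:
            shrink = 1.0 - lam / (L * norm)
            na = shrink * ua
            nb = shrink * ub
        da = na - ca
        db = nb - cb
        if da != 0.0 or db != 0.0:
            coef[ja] = na
            coef[jb] = nb
            for i in range(n):
                de = da * X[i, ja] + db * X[i, jb]
                if de != 0.0:
                    eta[i] += de
                    newm = M[i] * np.exp(de)
                    resid[i] += M[i] - newm
                    M[i] = newm
            d = np.sqrt((da * da + db * db) * L / n)
            if d > maxd:
                maxd = d
    return maxd
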