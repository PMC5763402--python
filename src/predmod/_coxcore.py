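"""Cox partial-likelihood primitives shared by all solvers.

Everything here works on a fixed (time, event) pair whose sort order and tie
structure are precomputed once (`CoxData`).  Ties are handled with the Breslow
convention throughout: tied event times share a single risk-set denominator.
"""

from __future__ import annotations

import numpy as np

__all__ = ["CoxData", "newton_cox"]


class CoxData:
    """Precomputed sort/tie structure for repeated partial-likelihood work.

    Parameters
    ----------
    time : array-like of positive floats
    event : array-like of {0,1}
    """

    def __init__(self, time, event):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=float)
        if time.ndim != 1 or event.shape != time.shape:
            raise ValueError("time and event must be 1-d arrays of equal length")
        if np.any(time <= 0):
            raise ValueError("all times must be positive")
        if event.sum() < 1:
            raise ValueError("at least one event is required")
        self.n = time.size
        order = np.argsort(time, kind="mergesort")
        self.order = order
        self.t_sorted = time[order]
        self.d_sorted = event[order]
        # tie groups on the sorted time axis; grp is nondecreasing
        uniq, grp = np.unique(self.t_sorted, return_inverse=True)
        self.grp = grp
        self.n_groups = uniq.size
        self.dg = np.bincount(grp, weights=self.d_sorted, minlength=self.n_groups)
        self.first_idx = np.searchsorted(grp, np.arange(self.n_groups))
        self.n_events = float(self.d_sorted.sum())

    # -- core quantities ---------------------------------------------------
    def _risk(self, eta):
        """exp(eta) in sorted order and Breslow denominators per tie group."""
        es = np.exp(eta[self.order])
        suffix = np.cumsum(es[::-1])[::-1]
        s0 = suffix[self.first_idx]
        return es, s0

    def loglik(self, eta):
        """Breslow partial log-likelihood at linear predictor `eta`."""
        es, s0 = self._risk(eta)
        ev = self.d_sorted > 0
        return float(np.sum(eta[self.order][ev] * self.d_sorted[ev])
                     - np.sum(self.dg[self.dg > 0] * np.log(s0[self.dg > 0])))

    def grad_eta(self, eta):
        """d loglik / d eta, returned in the original subject order."""
        es, s0 = self._risk(eta)
        a_g = np.cumsum(self.dg / s0)
        g_sorted = self.d_sorted - es * a_g[self.grp]
        g = np.empty(self.n)
        g[self.order] = g_sorted
        return g

    def loglik_grad_weights(self, eta):
        """(loglik, gradient, diagonal curvature) in one pass.

        The curvature is the diagonal of the negative Hessian of the partial
        log-likelihood with respect to eta (the glmnet working weight); it is
        nonnegative by construction and clipped at 0.
        """
        es, s0 = self._risk(eta)
        ev = self.dg > 0
        ll = float(np.sum(eta[self.order] * self.d_sorted)
                   - np.sum(self.dg[ev] * np.log(s0[ev])))
        a_g = np.cumsum(self.dg / s0)
        b_g = np.cumsum(self.dg / s0**2)
        a = a_g[self.grp]
        b = b_g[self.grp]
        g_sorted = self.d_sorted - es * a
        w_sorted = np.maximum(es * a - es**2 * b, 0.0)
        g = np.empty(self.n)
        w = np.empty(self.n)
        g[self.order] = g_sorted
        w[self.order] = w_sorted
        return ll, g, w

    def hessian(self, X, eta):
        """Negative Hessian of the partial log-likelihood wrt coefficients.

        H = X' diag(exp(eta) * A) X  -  M' diag(d_g) M   with  m_g = S1_g/S0_g.
        Intended for small/medium column counts (univariate fits, ridge
        Newton in the reduced space).
        """
        X = np.asarray(X, dtype=float)
        es, s0 = self._risk(eta)
        a_g = np.cumsum(self.dg / s0)
        Xs = X[self.order]
        w1 = es * a_g[self.grp]
        term1 = Xs.T @ (w1[:, None] * Xs)
        # S1 per group: suffix sums of exp(eta)*x at group starts
        sx = np.cumsum((es[:, None] * Xs)[::-1], axis=0)[::-1]
        m = sx[self.first_idx] / s0[:, None]
        ev = self.dg > 0
        term2 = (m[ev] * self.dg[ev, None]).T @ m[ev]
        return term1 - term2


def newton_cox(X, cox: CoxData, offset=None, ridge_diag=None, init=None,
               tol=1e-8, max_iter=50):
    """Newton–Raphson (with step halving) for a Cox model of modest dimension.

    Maximizes  l(c) - 0.5 * sum_j ridge_diag_j * c_j**2  where l is the
    Breslow partial log-likelihood with `offset` added to the linear
    predictor.  Returns (coef, loglik, converged, n_iter, inv_hessian).
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    off = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)
    pen = np.zeros(p) if ridge_diag is None else np.asarray(ridge_diag, dtype=float)
    coef = np.zeros(p) if init is None else np.array(init, dtype=float)

    def objective(c):
        return cox.loglik(X @ c + off) - 0.5 * float(pen @ c**2)

    obj = objective(coef)
    hinv = None
    converged = False
    for it in range(1, max_iter + 1):
        eta = X @ coef + off
        g = X.T @ cox.grad_eta(eta) - pen * coef
        if np.linalg.norm(g, ord=np.inf) < tol:
            converged = True
            break
        h = cox.hessian(X, eta) + np.diag(pen)
        try:
            step = np.linalg.solve(h, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(h, g, rcond=None)[0]
        # damped update
        alpha = 1.0
        for _ in range(30):
            cand = coef + alpha * step
            new_obj = objective(cand)
            if np.isfinite(new_obj) and new_obj >= obj - 1e-12:
                break
            alpha *= 0.5
        coef = coef + alpha * step
        obj = objective(coef)
    eta = X @ coef + off
    h = cox.hessian(X, eta) + np.diag(pen)
    try:
        hinv = np.linalg.inv(h)
    except np.linalg.LinAlgError:
        hinv = np.linalg.pinv(h)
    return coef, cox.loglik(eta), converged, it, hinv
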