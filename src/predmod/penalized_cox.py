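"""Penalized Cox regression: ridge and per-coefficient-weighted lasso.

The lasso solver follows the glmnet recipe: an outer iteratively-reweighted
least-squares loop builds a diagonal quadratic approximation of the Breslow
partial log-likelihood, and an inner cyclic coordinate descent with
soft-thresholding solves the penalized working problem (numba kernels in
``_cd``).  The ridge solver is an exact Newton method; when the number of
penalized columns exceeds the sample size the problem is first reduced to an
equivalent one of rank <= n via an SVD of the penalized block.

Conventions
-----------
* The objective is the *full* partial log-likelihood (not scaled by 1/n)
  minus ``lam * sum_j w_j |c_j|`` (lasso) or ``lambda2/2 * sum_j w_j c_j**2``
  (ridge).  Columns with weight 0 are unpenalized; weights at or above
  ``WEIGHT_CAP`` freeze the column at exactly zero.
* Penalized columns are internally rescaled to unit sample standard
  deviation before solving and the coefficients are transformed back
  (``standardize=True``, the default).  Because interaction columns X*T with
  T = +/-0.5 have sd ~ 0.5*sd(X), this rescaling changes their effective
  penalty relative to the main effects — mirroring the default behaviour of
  the mainstream penalized-regression software this solver family follows.
  Unpenalized columns are never rescaled.
* Ties: Breslow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._cd import _INF_WEIGHT, cd_solve
from ._coxcore import CoxData, newton_cox

WEIGHT_CAP = 1e10

__all__ = [
    "PenaltySpec", "FitResult", "PathResult", "cox_partial_loglik",
    "fit_ridge_cox", "fit_weighted_lasso_cox", "lasso_path",
    "LassoProblem", "RidgeProblem", "WEIGHT_CAP",
]


@dataclass
class PenaltySpec:
    """Per-coefficient penalty description.

    weights : per-column nonnegative penalty factors (0 = unpenalized,
        >= WEIGHT_CAP = frozen at zero); scalar 1.0 broadcasts.
    kind : "lasso" or "ridge".
    lam / lambda2 : the tuning parameter for the respective kind.
    offset : optional per-subject addition to the linear predictor with
        fixed coefficient 1.
    """

    kind: str = "lasso"
    lam: float | None = None
    lambda2: float | None = None
    weights: np.ndarray | float = 1.0
    offset: np.ndarray | None = None

    def resolve_weights(self, p: int) -> np.ndarray:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim == 0:
            w = np.full(p, float(w))
        if w.shape != (p,):
            raise ValueError(f"penalty weights have shape {w.shape}, expected ({p},)")
        if np.any(w < 0):
            raise ValueError("penalty weights must be nonnegative")
        return np.minimum(np.nan_to_num(w, nan=WEIGHT_CAP, posinf=WEIGHT_CAP), WEIGHT_CAP)


@dataclass
class PathResult:
    lambdas: np.ndarray
    coefs: np.ndarray          # (n_lambda, p) in the original column scale
    loglik: np.ndarray
    first_entry: np.ndarray    # per column: path index of first activation, -1 if never
    n_active: np.ndarray


@dataclass
class FitResult:
    coef: np.ndarray
    loglik: float
    lam: float | None = None
    lambda2: float | None = None
    alpha: float | None = None
    beta: np.ndarray | None = None
    gamma: np.ndarray | None = None
    path: PathResult | None = None
    converged: bool = True
    n_iter: int = 0
    diagnostics: dict = field(default_factory=dict)


def cox_partial_loglik(design, coefs, time, event, offset=None):
    """Breslow partial log-likelihood of `coefs` for the given design."""
    Z = np.atleast_2d(np.asarray(design, dtype=float))
    coefs = np.asarray(coefs, dtype=float)
    if coefs.shape[0] != Z.shape[1]:
        raise ValueError("coefficient length does not match design columns")
    eta = Z @ coefs
    if offset is not None:
        eta = eta + np.asarray(offset, dtype=float)
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite linear predictor")
    return CoxData(time, event).loglik(eta)


# ---------------------------------------------------------------------------
# weighted lasso
# ---------------------------------------------------------------------------

class LassoProblem:
    """Reusable state for weighted-lasso fits on one (design, survival) pair.

    Construction standardizes the penalized columns once; `fit` and `path`
    then share warm starts and the precomputed sort structure.
    """

    def __init__(self, design, time, event, weights=1.0, offset=None,
                 standardize=True, cox: CoxData | None = None,
                 kkt_tol=1e-4, max_outer=40):
        # kkt_tol is the solver's working stopping rule; single fits through
        # fit_weighted_lasso_cox tighten it to the 1e-6 contract.
        self.kkt_tol = kkt_tol
        self.max_outer = max_outer
        Z = np.ascontiguousarray(np.asarray(design, dtype=float))
        if Z.ndim != 2:
            raise ValueError("design must be 2-d")
        self.n, self.p = Z.shape
        self.cox = cox if cox is not None else CoxData(time, event)
        pw = PenaltySpec(weights=weights).resolve_weights(self.p)
        self.offset = (np.zeros(self.n) if offset is None
                       else np.asarray(offset, dtype=float))
        scales = np.ones(self.p)
        if standardize:
            pen = pw > 0
            sd = Z.std(axis=0, ddof=1)
            zero_sd = pen & (sd <= 0)
            if np.any(zero_sd):
                warnings.warn(
                    f"{int(zero_sd.sum())} constant penalized column(s); "
                    "treated as infinitely penalized")
                pw = pw.copy()
                pw[zero_sd] = WEIGHT_CAP
            ok = pen & (sd > 0)
            scales[ok] = sd[ok]
        self.scales = scales
        self.pw = pw
        self.Zs = np.ascontiguousarray(Z / scales)
        self.Zs2 = self.Zs**2
        self.unpen = pw == 0
        self.pen_mask = (pw > 0) & (pw < WEIGHT_CAP)

    # -- helpers -----------------------------------------------------------
    def _penalty(self, lam, coef_s):
        act = self.pw < WEIGHT_CAP
        return lam * float(np.sum(self.pw[act] * np.abs(coef_s[act])))

    def null_fit(self):
        """Fit only the unpenalized columns (the lasso 'null' model)."""
        coef_s = np.zeros(self.p)
        if np.any(self.unpen):
            idx = np.where(self.unpen)[0]
            c, _, _, _, _ = newton_cox(self.Zs[:, idx], self.cox, offset=self.offset)
            coef_s[idx] = c
        return coef_s

    def lambda_max(self, coef_null_s=None):
        if coef_null_s is None:
            coef_null_s = self.null_fit()
        eta = self.Zs @ coef_null_s + self.offset
        grad = self.Zs.T @ self.cox.grad_eta(eta)
        act = (self.pw > 0) & (self.pw < WEIGHT_CAP)
        if not np.any(act):
            raise ValueError("no penalized columns")
        return float(np.max(np.abs(grad[act]) / self.pw[act]))

    def _kkt_from_grad(self, lam, coef_s, grad):
        act = self.pw < WEIGHT_CAP
        lam_w = lam * self.pw
        zero = act & (coef_s == 0)
        nz = act & (coef_s != 0)
        res = 0.0
        if np.any(zero):
            res = max(res, float(np.max(np.abs(grad[zero]) - lam_w[zero])))
        if np.any(nz):
            res = max(res, float(np.max(np.abs(
                grad[nz] - lam_w[nz] * np.sign(coef_s[nz])))))
        return max(res, 0.0)

    def _irls(self, lam, coef_s, lam_prev=None, max_outer=None, kkt_tol=None,
              cd_tol=1e-6, max_cycles=300):
        """IRLS + screened coordinate descent for one penalty level.

        Candidate columns come from the sequential strong rule at the warm
        start; every outer iteration verifies the KKT conditions on the
        exact partial-likelihood gradient and re-enters violating columns,
        so screening never changes the solution.
        """
        if max_outer is None:
            max_outer = self.max_outer
        if kkt_tol is None:
            kkt_tol = self.kkt_tol
        lam_w = lam * self.pw
        lam_w[self.pw >= WEIGHT_CAP] = _INF_WEIGHT
        obj_prev = None
        prev_coef = coef_s.copy()
        cand_mask = None
        it = 0
        for it in range(1, max_outer + 1):
            eta = self.Zs @ coef_s + self.offset
            if not np.all(np.isfinite(np.exp(eta))):
                raise FloatingPointError("diverging linear predictor in lasso fit")
            ll, g, w = self.cox.loglik_grad_weights(eta)
            obj = ll - self._penalty(lam, coef_s)
            if obj_prev is not None and obj < obj_prev - 1e-9 * (abs(obj_prev) + 1.0):
                # quadratic step overshot: bisect back toward the previous iterate
                coef_s = 0.5 * (coef_s + prev_coef)
                continue
            grad = self.Zs.T @ g
            if cand_mask is None:
                thresh = (2.0 * lam - (lam_prev if lam_prev is not None else lam))
                cand_mask = (self.unpen | (coef_s != 0)
                             | (self.pen_mask
                                & (np.abs(grad) >= self.pw * thresh)))
            if self._kkt_from_grad(lam, coef_s, grad) <= kkt_tol:
                break
            # re-enter any screened-out column violating its subgradient bound
            viol = self.pen_mask & ~cand_mask & (np.abs(grad) > lam * self.pw)
            cand_mask |= viol
            obj_prev = obj
            prev_coef = coef_s.copy()
            w = np.maximum(w, 1e-10)
            r = g / w
            xwx = w @ self.Zs2
            cand = np.flatnonzero(cand_mask).astype(np.int64)
            cd_solve(self.Zs, w, r, coef_s, lam_w, xwx, cand, cd_tol,
                     max_cycles)
        return coef_s, it

    def fit(self, lam, coef_init_s=None, kkt_tol=None, max_outer=None) -> FitResult:
        if lam < 0:
            raise ValueError("lam must be nonnegative")
        coef_s = (self.null_fit() if coef_init_s is None
                  else np.array(coef_init_s, dtype=float))
        coef_s, it = self._irls(lam, coef_s, kkt_tol=kkt_tol,
                                max_outer=max_outer)
        ll = self.cox.loglik(self.Zs @ coef_s + self.offset)
        return FitResult(coef=coef_s / self.scales, loglik=ll, lam=lam,
                         n_iter=it, diagnostics={"scales": self.scales})

    def kkt_residual(self, lam, coef):
        """Max violation of the subgradient conditions (in the solver scale)."""
        coef_s = np.asarray(coef, dtype=float) * self.scales
        eta = self.Zs @ coef_s + self.offset
        grad = self.Zs.T @ self.cox.grad_eta(eta)
        res = 0.0
        for j in range(self.p):
            if self.pw[j] >= WEIGHT_CAP:
                continue
            lw = lam * self.pw[j]
            if coef_s[j] == 0.0:
                res = max(res, max(0.0, abs(grad[j]) - lw))
            else:
                res = max(res, abs(grad[j] - lw * np.sign(coef_s[j])))
        return res

    def lambda_grid(self, n_lambda=100, lambda_min_ratio=0.01):
        lmax = self.lambda_max()
        return np.exp(np.linspace(np.log(lmax), np.log(lmax * lambda_min_ratio),
                                  n_lambda))

    def path(self, lambdas=None, n_lambda=100, lambda_min_ratio=0.01,
             dfmax=None) -> PathResult:
        """Warm-started path over a descending lambda grid.

        The path stops early once more than `dfmax` penalized columns are
        active (default: 90% of the event count) — beyond that point the
        working problem is rank-deficient and of no use for tuning.
        """
        if lambdas is None:
            lambdas = self.lambda_grid(n_lambda, lambda_min_ratio)
        lambdas = np.asarray(lambdas, dtype=float)
        if lambdas.size < 1:
            raise ValueError("empty lambda grid")
        if np.any(np.diff(lambdas) > 0):
            lambdas = np.sort(lambdas)[::-1]
        if dfmax is None:
            dfmax = max(10, int(0.9 * self.cox.n_events))
        L = lambdas.size
        coefs = np.zeros((L, self.p))
        loglik = np.zeros(L)
        first_entry = np.full(self.p, -1, dtype=int)
        coef_s = self.null_fit()
        lam_prev = None
        stop = L
        for k, lam in enumerate(lambdas):
            coef_s, _ = self._irls(lam, coef_s, lam_prev=lam_prev)
            lam_prev = lam
            loglik[k] = self.cox.loglik(self.Zs @ coef_s + self.offset)
            coefs[k] = coef_s / self.scales
            newly = (first_entry < 0) & (coef_s != 0) & (self.pw > 0)
            first_entry[newly] = k
            if np.count_nonzero(coef_s[self.pw > 0]) > dfmax:
                stop = k + 1
                break
        lambdas, coefs, loglik = lambdas[:stop], coefs[:stop], loglik[:stop]
        n_active = np.count_nonzero(coefs[:, self.pw > 0], axis=1)
        return PathResult(lambdas=lambdas, coefs=coefs, loglik=loglik,
                          first_entry=first_entry, n_active=n_active)


def fit_weighted_lasso_cox(design, penalty: PenaltySpec, time, event,
                           offset=None, standardize=True) -> FitResult:
    """Maximize l(c) - lam * sum_j w_j |c_j| (Breslow partial likelihood)."""
    if penalty.lam is None or penalty.lam < 0:
        raise ValueError("PenaltySpec.lam must be a nonnegative real")
    off = offset if offset is not None else penalty.offset
    prob = LassoProblem(design, time, event, weights=penalty.weights,
                        offset=off, standardize=standardize)
    fit = prob.fit(penalty.lam, kkt_tol=1e-6, max_outer=200)
    fit.diagnostics["kkt_residual"] = prob.kkt_residual(penalty.lam, fit.coef)
    return fit


def lasso_path(design, weights, time, event, offset=None, n_lambda=100,
               lambda_min_ratio=0.01, standardize=True) -> FitResult:
    """Weighted-lasso regularization path with warm starts.

    Returns a FitResult whose `coef` is the final (smallest-lambda) solution
    and whose `path` records per-column first-entry indices, used downstream
    for tuning-free rankings.
    """
    prob = LassoProblem(design, time, event, weights=weights, offset=offset,
                        standardize=standardize)
    pr = prob.path(n_lambda=n_lambda, lambda_min_ratio=lambda_min_ratio)
    return FitResult(coef=pr.coefs[-1], loglik=float(pr.loglik[-1]),
                     lam=float(pr.lambdas[-1]), path=pr)


# ---------------------------------------------------------------------------
# ridge
# ---------------------------------------------------------------------------

class RidgeProblem:
    """Ridge Cox fits with a reusable SVD reduction of the penalized block.

    With uniform (after column rescaling) ridge weights the penalized
    coefficients live, at the optimum, in the row space of the penalized
    design block, so a problem with p >> n columns reduces exactly to one of
    rank <= n.  The SVD is computed once and shared across a lambda2 grid.
    """

    def __init__(self, design, time, event, weights=1.0, offset=None,
                 standardize=True, cox: CoxData | None = None):
        Z = np.asarray(design, dtype=float)
        self.n, self.p = Z.shape
        self.cox = cox if cox is not None else CoxData(time, event)
        self.offset = (np.zeros(self.n) if offset is None
                       else np.asarray(offset, dtype=float))
        pw = PenaltySpec(weights=weights).resolve_weights(self.p)
        self.pw = pw
        self.pen_idx = np.where(pw > 0)[0]
        self.unpen_idx = np.where(pw == 0)[0]
        # transform penalized columns so the penalty becomes lambda2/2 ||u||^2
        scales = np.ones(self.p)
        if standardize and self.pen_idx.size:
            sd = Z[:, self.pen_idx].std(axis=0, ddof=1)
            if np.any(sd <= 0):
                raise ValueError("constant penalized column in ridge design")
            scales[self.pen_idx] = sd
        self.colfac = scales * np.sqrt(np.maximum(pw, 0.0))  # c = u / colfac on pen cols
        P = Z[:, self.pen_idx] / self.colfac[self.pen_idx]
        self.reduce = self.pen_idx.size > self.n
        if self.reduce:
            U, s, Vt = np.linalg.svd(P, full_matrices=False)
            keep = s > s[0] * 1e-12 if s.size else np.zeros(0, bool)
            self.B = U[:, keep] * s[keep]      # n x r reduced penalized design
            self.Vt = Vt[keep]
        else:
            self.B = P
            self.Vt = None
        self.X = np.hstack([Z[:, self.unpen_idx], self.B])
        self.r = self.B.shape[1]
        self._warm = None

    def fit(self, lambda2, tol=1e-7, max_iter=200, warm=True) -> FitResult:
        if lambda2 < 0:
            raise ValueError("lambda2 must be nonnegative")
        q = self.unpen_idx.size
        pen_diag = np.concatenate([np.zeros(q), np.full(self.r, lambda2)])
        init = self._warm if (warm and self._warm is not None) else None
        c, ll, converged, it, _ = newton_cox(self.X, self.cox, offset=self.offset,
                                             ridge_diag=pen_diag, init=init,
                                             tol=tol, max_iter=max_iter)
        if not converged:
            grad = (self.X.T @ self.cox.grad_eta(self.X @ c + self.offset)
                    - pen_diag * c)
            raise RuntimeError(
                "ridge Cox did not converge: "
                f"lambda2={lambda2:g}, iterations={it}, "
                f"grad_norm={np.linalg.norm(grad, np.inf):.3e}")
        self._warm = c.copy()
        coef = np.zeros(self.p)
        coef[self.unpen_idx] = c[:q]
        u = c[q:]
        b = self.Vt.T @ u if self.reduce else u
        coef[self.pen_idx] = b / self.colfac[self.pen_idx]
        return FitResult(coef=coef, loglik=ll, lambda2=lambda2, n_iter=it)


def fit_ridge_cox(design, penalty: PenaltySpec, time, event, offset=None,
                  standardize=True, tol=1e-7, max_iter=200) -> FitResult:
    """Maximize l(c) - lambda2/2 * sum_j w_j c_j**2 by Newton iterations."""
    if penalty.lambda2 is None or penalty.lambda2 < 0:
        raise ValueError("PenaltySpec.lambda2 must be a nonnegative real")
    off = offset if offset is not None else penalty.offset
    prob = RidgeProblem(design, time, event, weights=penalty.weights,
                        offset=off, standardize=standardize)
    return prob.fit(penalty.lambda2, tol=tol, max_iter=max_iter)
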