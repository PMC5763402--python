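"""Cross-validated partial likelihood (Verweij & van Houwelingen) tuning.

The criterion for a tuning value theta is

    CVL(theta) = sum_k [ l_full(c_{-k}(theta)) - l_{-k}(c_{-k}(theta)) ]

where c_{-k} is the estimate with fold k left out, l_full the partial
log-likelihood on all subjects and l_{-k} the one excluding fold k.  Larger
is better; ties are broken toward the stronger penalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._coxcore import CoxData
from .penalized_cox import LassoProblem, RidgeProblem

__all__ = ["CVResult", "make_folds", "cvl", "cv_lasso_path", "cv_ridge"]


@dataclass
class CVResult:
    grid: np.ndarray
    cvl: np.ndarray
    best_index: int
    folds: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    @property
    def best(self):
        return self.grid[self.best_index]


def make_folds(n, k=5, event=None, seed=0) -> np.ndarray:
    """Fold labels in {0..k-1}, balanced (+-1) and stratified by event status."""
    if k < 2:
        raise ValueError("need at least 2 folds")
    if k > n:
        raise ValueError("more folds than subjects")
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=int)
    if event is None:
        strata = [np.arange(n)]
    else:
        event = np.asarray(event)
        strata = [np.where(event == v)[0] for v in (1, 0)]
    offset = 0
    for idx in strata:
        perm = rng.permutation(idx)
        # continue the round-robin across strata to keep overall sizes balanced
        labels = (np.arange(offset, offset + perm.size)) % k
        folds[perm] = labels
        offset += perm.size
    return folds


def _pick_best(grid, scores, smaller_is_stronger=False):
    """Argmax with ties toward stronger penalization.

    `grid` must be ordered from the strongest penalty (largest lambda /
    fewest components or iterations) to the weakest; the first strict
    maximum then wins.
    """
    best = 0
    for i in range(1, len(scores)):
        if scores[i] > scores[best] + 1e-12:
            best = i
    return best


def cvl(fit_fn, time, event, folds, grid):
    """Generic VVH criterion.

    fit_fn(train_mask, value) must return a linear-predictor vector for all
    n subjects (offset included) fitted using only the masked-in subjects.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, float)
    folds = np.asarray(folds)
    k = int(folds.max()) + 1
    if k < 2:
        raise ValueError("CVL needs at least 2 folds")
    cox_full = CoxData(time, event)
    out = np.zeros(len(grid))
    for ki in range(k):
        mask = folds != ki
        cox_train = CoxData(time[mask], event[mask])
        for gi, val in enumerate(grid):
            try:
                eta = np.asarray(fit_fn(mask, val), float)
                out[gi] += cox_full.loglik(eta) - cox_train.loglik(eta[mask])
            except Exception:
                out[gi] = -np.inf
    best = _pick_best(grid, out)
    return CVResult(grid=np.asarray(grid, float), cvl=out, best_index=best,
                    folds=folds)


def cv_lasso_path(design, time, event, weights=1.0, offset=None, folds=None,
                  k=5, seed=0, n_lambda=100, lambda_min_ratio=0.01,
                  standardize=True, stop_patience=15, stop_margin=25.0,
                  dfmax=None):
    """Fivefold-CVL selection of the lasso penalty along a shared grid.

    The lambda grid comes from the full-data lambda_max; the full-data path
    and all fold paths advance in lockstep with warm starts.  The grid is
    abandoned early once the criterion has clearly peaked (`stop_patience`
    points past the running argmax and at least `stop_margin` log-likelihood
    units below it) or once the full-data fit saturates — regions where
    continuing cannot change the selected lambda.  Returns
    (CVResult, full-data PathResult over the visited grid).
    """
    from .penalized_cox import PathResult

    Z = np.asarray(design, float)
    time = np.asarray(time, float)
    event = np.asarray(event, float)
    n = Z.shape[0]
    off = np.zeros(n) if offset is None else np.asarray(offset, float)
    if folds is None:
        folds = make_folds(n, k=k, event=event, seed=seed)
    full = LassoProblem(Z, time, event, weights=weights, offset=off,
                        standardize=standardize)
    lambdas = full.lambda_grid(n_lambda, lambda_min_ratio)
    if dfmax is None:
        dfmax = max(10, int(0.9 * full.cox.n_events))
    nfold = int(folds.max()) + 1
    subs = []
    for ki in range(nfold):
        mask = folds != ki
        subs.append((mask, LassoProblem(Z[mask], time[mask], event[mask],
                                        weights=weights, offset=off[mask],
                                        standardize=standardize)))
    coef_full = full.null_fit()
    coef_subs = [sub.null_fit() for _, sub in subs]
    L = lambdas.size
    scores = np.zeros(L)
    coefs = np.zeros((L, full.p))
    loglik = np.zeros(L)
    first_entry = np.full(full.p, -1, dtype=int)
    lam_prev = None
    best = 0
    stop = L
    for gi, lam in enumerate(lambdas):
        coef_full, _ = full._irls(lam, coef_full, lam_prev=lam_prev)
        coefs[gi] = coef_full / full.scales
        loglik[gi] = full.cox.loglik(full.Zs @ coef_full + full.offset)
        newly = (first_entry < 0) & (coef_full != 0) & (full.pw > 0)
        first_entry[newly] = gi
        for fi, (mask, sub) in enumerate(subs):
            # the per-observation penalty convention: a fold with n_k
            # subjects is fitted at lam * n_k/n, mirroring solvers that
            # normalize the log-likelihood by the sample size
            frac = sub.n / n
            try:
                coef_subs[fi], _ = sub._irls(lam * frac, coef_subs[fi],
                                             lam_prev=None if lam_prev is None
                                             else lam_prev * frac)
                coef = coef_subs[fi] / sub.scales
                eta = Z @ coef + off
                scores[gi] += full.cox.loglik(eta) - sub.cox.loglik(eta[mask])
            except Exception:
                scores[gi] = -np.inf
        lam_prev = lam
        if scores[gi] > scores[best] + 1e-12:
            best = gi
        n_act = int(np.count_nonzero(coef_full[full.pw > 0]))
        if ((gi - best >= stop_patience and scores[gi] <= scores[best] - stop_margin)
                or n_act > dfmax):
            stop = gi + 1
            break
    lambdas, scores = lambdas[:stop], scores[:stop]
    coefs, loglik = coefs[:stop], loglik[:stop]
    n_active = np.count_nonzero(coefs[:, full.pw > 0], axis=1)
    path = PathResult(lambdas=lambdas, coefs=coefs, loglik=loglik,
                      first_entry=first_entry, n_active=n_active)
    cv = CVResult(grid=lambdas, cvl=scores, best_index=best, folds=folds)
    return cv, path


def cv_ridge(design, time, event, weights=1.0, offset=None, folds=None, k=5,
             seed=0, lambda2_grid=None, standardize=True):
    """Fivefold-CVL selection of the ridge penalty lambda2.

    The per-fold SVD reduction is reused across the grid; the default grid is
    log-spaced and deliberately coarse (rough selection of lambda2).
    Returns (CVResult, full-data FitResult at the selected lambda2).
    """
    Z = np.asarray(design, float)
    time = np.asarray(time, float)
    event = np.asarray(event, float)
    n = Z.shape[0]
    off = np.zeros(n) if offset is None else np.asarray(offset, float)
    if lambda2_grid is None:
        lambda2_grid = np.geomspace(2000.0, 2.0, 7)
    lambda2_grid = np.sort(np.asarray(lambda2_grid, float))[::-1]
    if folds is None:
        folds = make_folds(n, k=k, event=event, seed=seed)
    cox_full = CoxData(time, event)
    nfold = int(folds.max()) + 1
    scores = np.zeros(lambda2_grid.size)
    for ki in range(nfold):
        mask = folds != ki
        sub = RidgeProblem(Z[mask], time[mask], event[mask], weights=weights,
                           offset=off[mask], standardize=standardize)
        for gi, lam2 in enumerate(lambda2_grid):
            try:
                fit = sub.fit(lam2)
                eta = Z @ fit.coef + off
                scores[gi] += cox_full.loglik(eta) - sub.cox.loglik(eta[mask])
            except Exception:
                scores[gi] = -np.inf
    best = _pick_best(lambda2_grid, scores)
    full = RidgeProblem(Z, time, event, weights=weights, offset=off,
                        standardize=standardize)
    fit = full.fit(lambda2_grid[best])
    cv = CVResult(grid=lambda2_grid, cvl=scores, best_index=best, folds=folds)
    return cv, fit
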