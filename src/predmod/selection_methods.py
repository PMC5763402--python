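"""The twelve treatment-effect-modifier selection strategies.

Each strategy maps a standardized training `TrialDataset` to a
`SelectionResult`: the set H of biomarkers whose treatment interaction is
retained, their interaction coefficients (used downstream for the
biomarker-treatment score), and — where the strategy admits one — a
tuning-free ranking of all p candidates for precision-recall evaluation.

Strategy families
-----------------
* penalties on the full interaction model [T | X | X*T]: full_lasso (one
  shared lasso penalty), three adaptive lassos with ridge-derived weights
  (biomarker-specific Sw, grouped Gw, arm-specific-prognostic Aspw),
  ridge+lasso (ridge main effects fixed as an offset, lasso on the
  interactions), and the group-lasso on (beta_i, gamma_i) pairs;
* modified covariates: lasso on M_i = X_i*T alone, no main effects;
* dimension reduction of the main-effect space: PCA+lasso and PLS+lasso;
* arm-specific prognostic effects: the two-I model (lasso on per-arm
  biomarker effects; selected when exactly one arm effect survives);
* componentwise gradient boosting with the treatment effect as an offset;
* univariate interaction Wald tests with Benjamini-Hochberg control.

All tuning parameters are chosen by fivefold cross-validated partial
likelihood (`tuning.cvl` family); the treatment main effect is never
penalized.

Penalty scale convention: the strategies apply the penalties to the
coefficients of the design columns exactly as the formulas are written —
standardized biomarkers and their raw products with T (sd ~ 0.5) — without
re-scaling columns inside the solver (``STANDARDIZE_INTERNALLY = False``).
Interactions are therefore penalized somewhat more strongly than main
effects per unit of effect, which is what keeps the selected interaction
sets sparse.  Flip the module constant to study the alternative convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from ._coxcore import CoxData, newton_cox
from .penalized_cox import WEIGHT_CAP, LassoProblem
from .poisson_grouplasso import cv_group_lasso
from .trial_data import TrialDataset, build_design
from .tuning import cv_lasso_path, cv_ridge, make_folds

STANDARDIZE_INTERNALLY = False

__all__ = ["SelectionResult", "WeightSpec", "estimate_ridge_weights",
           "full_lasso", "alasso_sw", "alasso_gw", "alasso_aspw",
           "ridge_lasso", "modified_covariates", "pca_lasso", "pls_lasso",
           "two_I_model", "group_lasso", "gradient_boosting", "univariate_bh",
           "METHOD_REGISTRY", "run_method"]


@dataclass
class SelectionResult:
    method: str
    H: np.ndarray                      # sorted biomarker indices
    gamma_hat: dict                    # biomarker index -> interaction coef
    ranking: np.ndarray | None         # permutation of 0..p-1, best first
    tuning: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        self.H = np.asarray(sorted(self.H), dtype=int)


@dataclass
class WeightSpec:
    main_weights: np.ndarray
    interaction_weights: np.ndarray
    source: str


def _inv_abs(x):
    """1/|x| with near-zero coefficients capped (column effectively frozen)."""
    x = np.abs(np.asarray(x, float))
    return np.minimum(1.0 / np.maximum(x, 1.0 / WEIGHT_CAP), WEIGHT_CAP)


def estimate_ridge_weights(train: TrialDataset, source="ridge_full", seed=0,
                           lambda2_grid=None) -> WeightSpec:
    """Adaptive-lasso weights from a preliminary CVL-tuned ridge model.

    source="ridge_full": w_beta_i = 1/|betaR_i|, w_gamma_i = 1/|gammaR_i|.
    source="grouped":    one common weight per block, 1/mean|betaR| and
                         1/mean|gammaR|.
    source="ridge_two_I": from the ridge two-I model's arm-specific effects,
        w_gamma_i = 1/|gR+_i - gR-_i| and
        w_beta_i = 1/(|gR+_i + gR-_i| + |gR+_i - gR-_i|), so interactions
        with a large between-arm difference are penalized least.
    """
    p = train.p
    if source in ("ridge_full", "grouped"):
        design = build_design(train, "full")
        w = np.r_[0.0, np.ones(2 * p)]
        _, fit = cv_ridge(design.Z, train.time, train.event, weights=w,
                          seed=seed, lambda2_grid=lambda2_grid,
                          standardize=STANDARDIZE_INTERNALLY)
        beta_r = fit.coef[1:1 + p]
        gamma_r = fit.coef[1 + p:]
        if np.all(beta_r == 0) and np.all(gamma_r == 0):
            raise ValueError("degenerate all-zero ridge fit")
        if source == "ridge_full":
            return WeightSpec(_inv_abs(beta_r), _inv_abs(gamma_r), source)
        return WeightSpec(
            np.full(p, float(_inv_abs(np.mean(np.abs(beta_r))))),
            np.full(p, float(_inv_abs(np.mean(np.abs(gamma_r))))), source)
    if source == "ridge_two_I":
        design = build_design(train, "two_I")
        w = np.r_[0.0, np.ones(2 * p)]
        _, fit = cv_ridge(design.Z, train.time, train.event, weights=w,
                          seed=seed, lambda2_grid=lambda2_grid,
                          standardize=STANDARDIZE_INTERNALLY)
        g_plus = fit.coef[1:1 + p]
        g_minus = fit.coef[1 + p:]
        diff = np.abs(g_plus - g_minus)
        summ = np.abs(g_plus + g_minus)
        return WeightSpec(_inv_abs(summ + diff), _inv_abs(diff), source)
    raise ValueError(f"unknown weight source {source!r}")


# ---------------------------------------------------------------------------
# ranking helpers
# ---------------------------------------------------------------------------

def _path_ranking(path, design, inter_cols, p, tie_score):
    """Order biomarkers by first entry of their interaction on the path.

    Columns that never enter are ranked afterwards by `tie_score`
    (descending) — a gradient-based proxy for how close they are to entering.
    """
    entry = path.first_entry[inter_cols].astype(float)
    entry[entry < 0] = path.lambdas.size + 1
    order = np.lexsort((-np.asarray(tie_score, float), entry))
    ranking = np.empty(p, dtype=int)
    parents = design.parent_biomarker[inter_cols]
    ranking[:] = parents[order]
    return ranking


def _lasso_selection(name, train, design, weights, seed, offset=None,
                     n_lambda=100, folds=None):
    """Shared CVL-tuned weighted-lasso backbone for the lasso-family methods."""
    cv, path = cv_lasso_path(design.Z, train.time, train.event,
                             weights=weights, offset=offset, folds=folds,
                             seed=seed, n_lambda=n_lambda,
                             standardize=STANDARDIZE_INTERNALLY)
    coef = path.coefs[cv.best_index]
    inter = design.interaction_cols
    parents = design.parent_biomarker[inter]
    nz = coef[inter] != 0
    H = parents[nz]
    gamma_hat = {int(b): float(c) for b, c in zip(parents[nz], coef[inter][nz])}
    # tie scores: score-statistic proximity at the end of the path
    prob = LassoProblem(design.Z, train.time, train.event, weights=weights,
                        offset=offset, standardize=STANDARDIZE_INTERNALLY)
    eta = design.Z @ path.coefs[-1] + (0 if offset is None else offset)
    grad = np.abs(design.Z.T @ prob.cox.grad_eta(eta))
    pw = np.asarray(weights, float)[inter] if np.ndim(weights) else np.ones(inter.size)
    tie = grad[inter] / np.maximum(pw, 1e-12)
    ranking = _path_ranking(path, design, inter, train.p, tie)
    return SelectionResult(
        method=name, H=H, gamma_hat=gamma_hat, ranking=ranking,
        tuning={"lambda": float(cv.best), "cvl": cv.cvl, "grid": cv.grid},
        diagnostics={"coef": coef, "n_active_path": path.n_active})


# ---------------------------------------------------------------------------
# the methods
# ---------------------------------------------------------------------------

def full_lasso(train: TrialDataset, seed=0, n_lambda=100) -> SelectionResult:
    """One shared lasso penalty on all main effects and interactions."""
    design = build_design(train, "full")
    weights = np.r_[0.0, np.ones(2 * train.p)]
    return _lasso_selection("full_lasso", train, design, weights, seed,
                            n_lambda=n_lambda)


def _alasso(name, source, train, seed, n_lambda=100, lambda2_grid=None):
    ws = estimate_ridge_weights(train, source=source, seed=seed,
                                lambda2_grid=lambda2_grid)
    design = build_design(train, "full")
    weights = np.r_[0.0, ws.main_weights, ws.interaction_weights]
    res = _lasso_selection(name, train, design, weights, seed,
                           n_lambda=n_lambda)
    res.diagnostics["weights"] = ws
    return res


def alasso_sw(train: TrialDataset, seed=0, **kw) -> SelectionResult:
    """Adaptive lasso, biomarker-specific inverse-ridge weights."""
    return _alasso("alasso_sw", "ridge_full", train, seed, **kw)


def alasso_gw(train: TrialDataset, seed=0, **kw) -> SelectionResult:
    """Adaptive lasso with one grouped weight for mains, one for interactions."""
    return _alasso("alasso_gw", "grouped", train, seed, **kw)


def alasso_aspw(train: TrialDataset, seed=0, **kw) -> SelectionResult:
    """Adaptive lasso with arm-specific prognostic weights (ridge two-I fit)."""
    return _alasso("alasso_aspw", "ridge_two_I", train, seed, **kw)


def ridge_lasso(train: TrialDataset, seed=0, n_lambda=100,
                lambda2_grid=None) -> SelectionResult:
    """Ridge on the main effects (fixed as an offset), lasso on interactions.

    Step 1 fits a CVL-tuned ridge Cox on [T | X] (treatment unpenalized);
    the biomarker part of its linear predictor becomes an offset with fixed
    coefficient 1 in step 2, a lasso on [T | X*T] re-estimating the treatment
    effect unpenalized.
    """
    p = train.p
    Z1 = np.hstack([train.treatment[:, None], train.X])
    w1 = np.r_[0.0, np.ones(p)]
    cv2, ridge_fit = cv_ridge(Z1, train.time, train.event, weights=w1,
                              seed=seed, lambda2_grid=lambda2_grid,
                              standardize=STANDARDIZE_INTERNALLY)
    offset = train.X @ ridge_fit.coef[1:]
    # [T | X*T] is the K=0 case of the reduced-main-effect layout
    design = build_design(train, "pca", components=np.zeros((train.n, 0)))
    weights = np.r_[0.0, np.ones(p)]
    res = _lasso_selection("ridge_lasso", train, design, weights, seed,
                           offset=offset, n_lambda=n_lambda)
    res.tuning["lambda2"] = float(cv2.best)
    return res


def modified_covariates(train: TrialDataset, seed=0, n_lambda=100
                        ) -> SelectionResult:
    """Lasso on the modified covariates M_i = X_i * T alone (no main effects)."""
    design = build_design(train, "interactions_only")
    weights = np.ones(train.p)
    return _lasso_selection("modified_covariates", train, design, weights,
                            seed, n_lambda=n_lambda)


def pca_lasso(train: TrialDataset, seed=0, n_lambda=100, k_grid=None
              ) -> SelectionResult:
    """PCA of the main-effect space; lasso on the interactions.

    The number of components K and lambda are chosen jointly by maximizing
    CVL over a K grid (default 1..20), with ties toward smaller K.  The
    component effects and the treatment are unpenalized.
    """
    p, n = train.p, train.n
    kmax = min(20, n - 2, p)
    if k_grid is None:
        k_grid = range(1, kmax + 1)
    pca = PCA(n_components=max(k_grid)).fit(train.X)
    scores = pca.transform(train.X)
    folds = make_folds(n, k=5, event=train.event, seed=seed)
    best = None
    for K in k_grid:
        design = build_design(train, "pca", components=scores[:, :K])
        weights = np.r_[0.0, np.zeros(K), np.ones(p)]
        cv, path = cv_lasso_path(design.Z, train.time, train.event,
                                 weights=weights, folds=folds, seed=seed,
                                 n_lambda=n_lambda,
                                 standardize=STANDARDIZE_INTERNALLY)
        if best is None or cv.cvl[cv.best_index] > best[0] + 1e-12:
            best = (cv.cvl[cv.best_index], K, cv, path, design, weights)
    _, K, cv, path, design, weights = best
    res = _lasso_selection("pca_lasso", train, design, weights, seed,
                           folds=folds, n_lambda=n_lambda)
    res.tuning["K"] = int(K)
    return res


def _pls_component(train: TrialDataset) -> np.ndarray:
    """First supervised component: weights proportional to the univariate Cox
    score statistics of each biomarker at the null model, unit-normalized."""
    cox = CoxData(train.time, train.event)
    g0 = cox.grad_eta(np.zeros(train.n))
    u = train.X.T @ g0
    norm = np.linalg.norm(u)
    if norm <= 0:
        raise ValueError("degenerate component: all score statistics zero")
    return (train.X @ (u / norm))[:, None]


def pls_lasso(train: TrialDataset, seed=0, n_lambda=100) -> SelectionResult:
    """Single supervised (PLS-style) main-effect component; lasso interactions."""
    comp = _pls_component(train)
    design = build_design(train, "pls", components=comp)
    weights = np.r_[0.0, 0.0, np.ones(train.p)]
    res = _lasso_selection("pls_lasso", train, design, weights, seed,
                           n_lambda=n_lambda)
    res.tuning["K"] = 1
    return res


def two_I_model(train: TrialDataset, seed=0, n_lambda=100) -> SelectionResult:
    """Lasso on arm-specific biomarker effects [T | X*1(T+) | X*1(T-)].

    A biomarker is a treatment-effect modifier when exactly one of its two
    arm effects is retained; its score coefficient is gamma+ - gamma-.
    No tuning-free ranking is defined for this strategy.
    """
    p = train.p
    design = build_design(train, "two_I")
    weights = np.r_[0.0, np.ones(2 * p)]
    cv, path = cv_lasso_path(design.Z, train.time, train.event,
                             weights=weights, seed=seed, n_lambda=n_lambda,
                             standardize=STANDARDIZE_INTERNALLY)
    coef = path.coefs[cv.best_index]
    g_plus = coef[1:1 + p]
    g_minus = coef[1 + p:]
    sel = (g_plus != 0) ^ (g_minus != 0)
    H = np.where(sel)[0]
    gamma_hat = {int(i): float(g_plus[i] - g_minus[i]) for i in H}
    return SelectionResult(
        method="two_I", H=H, gamma_hat=gamma_hat, ranking=None,
        tuning={"lambda": float(cv.best), "cvl": cv.cvl, "grid": cv.grid},
        diagnostics={"gamma_plus": g_plus, "gamma_minus": g_minus})


def group_lasso(train: TrialDataset, seed=0, n_lambda=20) -> SelectionResult:
    """Group-lasso on (beta_i, gamma_i) pairs via the piecewise-exponential
    Poisson model; a biomarker is selected as interaction when its group is
    active with a nonzero gamma."""
    p = train.p
    design = build_design(train, "full")
    groups = [(1 + i, 1 + p + i) for i in range(p)]
    cv, fit = cv_group_lasso(design.Z, train.time, train.event, groups,
                             unpenalized=(0,), seed=seed, n_lambda=n_lambda)
    gamma = fit.coef[1 + p:]
    H = np.where(np.abs(gamma) > 1e-8)[0]
    gamma_hat = {int(i): float(gamma[i]) for i in H}
    entry = cv.diagnostics["first_entry"].astype(float)
    entry[entry < 0] = cv.grid.size + 1
    tie = cv.diagnostics["group_grad_null"]
    ranking = np.lexsort((-tie, entry))
    return SelectionResult(
        method="group_lasso", H=H, gamma_hat=gamma_hat, ranking=ranking,
        tuning={"lambda": float(cv.best), "cvl": cv.cvl, "grid": cv.grid},
        diagnostics={"coef": fit.coef, "kkt": fit.diagnostics.get("kkt")})


def gradient_boosting(train: TrialDataset, seed=0, nu=0.1, mstop_grid=None
                      ) -> SelectionResult:
    """Componentwise L2 gradient boosting on main and interaction columns.

    The treatment effect is fitted first and fixed as an offset.  At each
    iteration the least-squares update to the partial-likelihood gradient is
    computed for every candidate column, the best (largest decrease of the
    working loss, ties to the lowest index) is retained, and its coefficient
    moves by nu times the fitted step.  The stopping iteration is chosen by
    fivefold CVL over `mstop_grid` (default 0..500, ties toward fewer
    iterations).
    """
    if mstop_grid is None:
        mstop_grid = np.arange(0, 501)
    mstop_grid = np.asarray(mstop_grid, dtype=int)
    if mstop_grid.size == 0:
        raise ValueError("empty mstop grid")
    mmax = int(mstop_grid.max())
    p, n = train.p, train.n
    C = np.hstack([train.X, train.X * train.treatment[:, None]])
    colnorm2 = (C**2).sum(axis=0)
    T1 = train.treatment[:, None]

    def boost(idx, eval_times):
        """Run boosting on subjects `idx`; record coef snapshots at eval_times."""
        cox = CoxData(train.time[idx], train.event[idx])
        a, _, _, _, _ = newton_cox(T1[idx], cox)
        offset = (T1[idx] @ a).ravel()
        Ci = C[idx]
        cn2 = (Ci**2).sum(axis=0)
        cn2 = np.where(cn2 > 0, cn2, np.inf)
        coef = np.zeros(2 * p)
        eta = offset.copy()
        snaps = {}
        first_update = np.full(2 * p, -1, dtype=int)
        want = set(int(m) for m in eval_times)
        if 0 in want:
            snaps[0] = coef.copy()
        for m in range(1, mmax + 1):
            g = cox.grad_eta(eta)
            proj = Ci.T @ g
            gain = proj**2 / cn2
            j = int(np.argmax(gain))           # argmax takes the lowest index on ties
            step = nu * proj[j] / cn2[j]
            coef[j] += step
            eta = eta + step * Ci[:, j]
            if first_update[j] < 0:
                first_update[j] = m
            if m in want:
                snaps[m] = coef.copy()
        return float(a[0]), coef, snaps, first_update

    folds = make_folds(n, k=5, event=train.event, seed=seed)
    cox_full = CoxData(train.time, train.event)
    scores = np.zeros(mstop_grid.size)
    for ki in range(int(folds.max()) + 1):
        mask = folds != ki
        idx = np.where(mask)[0]
        a_k, _, snaps, _ = boost(idx, mstop_grid)
        cox_train = CoxData(train.time[idx], train.event[idx])
        for gi, m in enumerate(mstop_grid):
            coef = snaps[int(m)]
            eta_all = train.treatment * a_k + C @ coef
            scores[gi] += cox_full.loglik(eta_all) - cox_train.loglik(eta_all[idx])
    best = 0
    for i in range(1, scores.size):
        if scores[i] > scores[best] + 1e-12:
            best = i
    mstar = int(mstop_grid[best])
    # H and ranking from the m* prefix of the full-data run
    coef_star, first_star, a0 = _boost_prefix(train, C, T1, nu, mstar)
    inter_first = first_star[p:]
    H = np.where(inter_first > 0)[0]
    gamma = coef_star[p:]
    gamma_hat = {int(i): float(gamma[i]) for i in H}
    entry = inter_first.astype(float)
    entry[entry <= 0] = mmax + 2
    cox = CoxData(train.time, train.event)
    g_final = np.abs(C.T @ cox.grad_eta(train.treatment * a0 + C @ coef_star))
    ranking = np.lexsort((-g_final[p:], entry))
    return SelectionResult(
        method="boosting", H=H, gamma_hat=gamma_hat, ranking=ranking,
        tuning={"mstop": mstar, "cvl": scores, "grid": mstop_grid, "nu": nu},
        diagnostics={"coef": coef_star, "alpha": a0})


def _boost_prefix(train, C, T1, nu, mstar):
    """Full-data boosting for exactly mstar iterations."""
    cox = CoxData(train.time, train.event)
    a, _, _, _, _ = newton_cox(T1, cox)
    eta = (T1 @ a).ravel()
    cn2 = (C**2).sum(axis=0)
    cn2 = np.where(cn2 > 0, cn2, np.inf)
    coef = np.zeros(C.shape[1])
    first = np.zeros(C.shape[1], dtype=int)
    for m in range(1, mstar + 1):
        g = cox.grad_eta(eta)
        proj = C.T @ g
        j = int(np.argmax(proj**2 / cn2))
        step = nu * proj[j] / cn2[j]
        coef[j] += step
        eta = eta + step * C[:, j]
        if first[j] == 0:
            first[j] = m
    return coef, first, float(a[0])


def univariate_bh(train: TrialDataset, alpha=0.05, seed=0) -> SelectionResult:
    """Per-biomarker interaction Wald tests with Benjamini-Hochberg control.

    Each biomarker gets a three-covariate Cox fit [T, X_i, X_i*T]; the
    interaction Wald p-values are BH-adjusted and biomarkers with adjusted
    p < alpha are kept.  Non-converged fits get p = 1 (logged).  The ranking
    is by raw p-value.
    """
    p = train.p
    cox = CoxData(train.time, train.event)
    pvals = np.ones(p)
    gammas = np.zeros(p)
    failures = []
    T = train.treatment
    for i in range(p):
        Z = np.column_stack([T, train.X[:, i], train.X[:, i] * T])
        try:
            coef, _, converged, _, hinv = newton_cox(Z, cox, max_iter=40)
            if not converged:
                raise RuntimeError("no convergence")
            se = np.sqrt(hinv[2, 2])
            z = coef[2] / se
            pvals[i] = 2.0 * stats.norm.sf(abs(z))
            gammas[i] = coef[2]
        except Exception:
            failures.append(i)
            pvals[i] = 1.0
    reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    H = np.where(p_adj < alpha)[0]
    gamma_hat = {int(i): float(gammas[i]) for i in H}
    ranking = np.lexsort((np.arange(p), pvals))
    return SelectionResult(
        method="univariate", H=H, gamma_hat=gamma_hat, ranking=ranking,
        tuning={"alpha": alpha},
        diagnostics={"pvalues": pvals, "p_adjusted": p_adj,
                     "failed_fits": failures})


METHOD_REGISTRY = {
    "univariate": univariate_bh,
    "modified_covariates": modified_covariates,
    "pca_lasso": pca_lasso,
    "pls_lasso": pls_lasso,
    "ridge_lasso": ridge_lasso,
    "group_lasso": group_lasso,
    "two_I": two_I_model,
    "full_lasso": full_lasso,
    "alasso_sw": alasso_sw,
    "alasso_gw": alasso_gw,
    "alasso_aspw": alasso_aspw,
    "boosting": gradient_boosting,
}


def run_method(name: str, train: TrialDataset, seed=0, **kw) -> SelectionResult:
    if name not in METHOD_REGISTRY:
        raise KeyError(f"unknown method {name!r}; choose from "
                       f"{sorted(METHOD_REGISTRY)}")
    return METHOD_REGISTRY[name](train, seed=seed, **kw)
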