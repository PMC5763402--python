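import numpy as np
import pytest

from predmod._coxcore import CoxData
from predmod.penalized_cox import (LassoProblem, PenaltySpec, RidgeProblem,
                                   cox_partial_loglik, fit_ridge_cox,
                                   fit_weighted_lasso_cox, lasso_path)


def brute_force_partial_loglik(X, coefs, time, event, offset=None):
    """Independent oracle: explicit loop over event times and risk sets."""
    eta = X @ coefs + (0 if offset is None else offset)
    ll = 0.0
    for t in np.unique(time[event > 0]):
        risk = time >= t
        for i in np.where((time == t) & (event > 0))[0]:
            ll += eta[i] - np.log(np.exp(eta[risk]).sum())
    return ll


class TestPartialLoglik:
    def test_two_events_at_null(self):
        Z = np.zeros((2, 1))
        ll = cox_partial_loglik(Z, np.zeros(1), [1.0, 2.0], [1, 1])
        assert np.isclose(ll, -np.log(2))

    def test_matches_brute_force_enumeration(self, rng):
        n, p = 9, 3
        X = rng.standard_normal((n, p))
        time = rng.exponential(1, n)
        time[3] = time[5]                       # force a tie
        event = rng.integers(0, 2, n).astype(float)
        event[[0, 3, 5]] = 1
        coefs = rng.normal(0, 0.5, p)
        off = rng.normal(0, 0.3, n)
        ours = cox_partial_loglik(X, coefs, time, event, offset=off)
        assert np.isclose(ours, brute_force_partial_loglik(X, coefs, time,
                                                           event, off),
                          atol=1e-10)

    def test_offset_location_invariance(self, small_surv):
        X, time, event = small_surv
        c = np.array([0.3, -0.2, 0.1, 0.0])
        l0 = cox_partial_loglik(X, c, time, event, offset=np.zeros(len(time)))
        l1 = cox_partial_loglik(X, c, time, event,
                                offset=np.full(len(time), 5.0))
        assert np.isclose(l0, l1, atol=1e-9)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="event"):
            cox_partial_loglik(np.zeros((3, 1)), np.zeros(1),
                               [1.0, 2.0, 3.0], [0, 0, 0])


class TestRidge:
    def test_infinite_shrinkage_limit(self, small_surv):
        X, time, event = small_surv
        fit = fit_ridge_cox(X, PenaltySpec("ridge", lambda2=1e9), time, event)
        assert np.max(np.abs(fit.coef)) < 1e-6

    def test_lambda2_zero_matches_unpenalized_mle(self, small_surv):
        # oracle: lifelines' Newton-Raphson Cox fit
        import pandas as pd
        from lifelines import CoxPHFitter
        X, time, event = small_surv
        fit = fit_ridge_cox(X, PenaltySpec("ridge", lambda2=0.0), time, event)
        df = pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])
        df["t"], df["e"] = time, event
        cph = CoxPHFitter().fit(df, "t", "e")
        # lifelines' own stopping rule leaves a ~5e-4 score residual; our
        # Newton solution has gradient below 1e-7, so compare at that level
        assert np.allclose(fit.coef, cph.params_.values, atol=5e-4)
        grad = X.T @ CoxData(time, event).grad_eta(X @ fit.coef)
        assert np.linalg.norm(grad, np.inf) < 1e-6

    def test_optimality_probe(self, small_surv):
        X, time, event = small_surv
        lam2 = 3.0
        fit = fit_ridge_cox(X[:, :2], PenaltySpec("ridge", lambda2=lam2),
                            time, event, standardize=False)
        cox = CoxData(time, event)

        def obj(c):
            return cox.loglik(X[:, :2] @ c) - 0.5 * lam2 * (c @ c)

        base = obj(fit.coef)
        rng = np.random.default_rng(0)
        perturbed = [obj(fit.coef + rng.normal(0, 0.05, 2)) for _ in range(1000)]
        assert base >= max(perturbed)

    def test_unpenalized_column_unshrunk(self, small_surv):
        X, time, event = small_surv
        w = np.array([0.0, 1.0, 1.0, 1.0])
        fit = fit_ridge_cox(X, PenaltySpec("ridge", lambda2=1e9, weights=w),
                            time, event)
        assert abs(fit.coef[0]) > 0.1          # the true strong effect stays
        assert np.max(np.abs(fit.coef[1:])) < 1e-6

    def test_svd_reduction_agrees_with_direct_newton(self, rng):
        # p > n triggers the reduced-space path; compare to the direct fit
        n, p = 30, 45
        X = rng.standard_normal((n, p))
        t = rng.exponential(np.exp(-0.6 * X[:, 0]))
        c = rng.uniform(0.3, 3, n)
        time, event = np.minimum(t, c), (t <= c).astype(float)
        lam2 = 4.0
        red = fit_ridge_cox(X, PenaltySpec("ridge", lambda2=lam2), time, event,
                            standardize=False)
        from predmod._coxcore import newton_cox
        direct, _, conv, _, _ = newton_cox(X, CoxData(time, event),
                                           ridge_diag=np.full(p, lam2))
        assert conv
        assert np.allclose(red.coef, direct, atol=1e-6)

    def test_gradient_norm_at_solution(self, rng):
        n, p = 40, 120
        X = rng.standard_normal((n, p))
        t = rng.exponential(np.exp(-0.5 * X[:, 0]))
        c = rng.uniform(0.3, 3, n)
        time, event = np.minimum(t, c), (t <= c).astype(float)
        fit = fit_ridge_cox(X, PenaltySpec("ridge", lambda2=5.0), time, event,
                            standardize=False)
        grad = X.T @ CoxData(time, event).grad_eta(X @ fit.coef) - 5.0 * fit.coef
        assert np.linalg.norm(grad, np.inf) < 1e-6


def proximal_gradient_lasso(X, time, event, lam, weights=None, offset=None,
                            step=1e-3, iters=400_000, tol=1e-13):
    """Independent slow solver: ISTA on the exact partial likelihood."""
    n, p = X.shape
    w = np.ones(p) if weights is None else np.asarray(weights, float)
    off = np.zeros(n) if offset is None else offset
    cox = CoxData(time, event)
    c = np.zeros(p)
    for _ in range(iters):
        g = X.T @ cox.grad_eta(X @ c + off)
        new = c + step * g
        thr = step * lam * w
        free = w == 0
        new = np.where(free, new, np.sign(new) * np.maximum(np.abs(new) - thr, 0))
        if np.max(np.abs(new - c)) < tol:
            return new
        c = new
    return c


class TestWeightedLasso:
    def test_lambda_max_gives_null_model(self, small_surv):
        X, time, event = small_surv
        prob = LassoProblem(X, time, event)
        fit = prob.fit(prob.lambda_max() * 1.000001)
        assert np.all(fit.coef == 0)

    def test_matches_proximal_gradient_oracle(self, rng):
        n, p = 30, 4
        X = rng.standard_normal((n, p))
        t = rng.exponential(np.exp(-(0.9 * X[:, 0] - 0.6 * X[:, 2])))
        c = rng.uniform(0.3, 3, n)
        time, event = np.minimum(t, c), (t <= c).astype(float)
        w = np.array([1.0, 2.0, 1.0, 0.5])
        prob = LassoProblem(X, time, event, weights=w, standardize=False)
        lam = prob.lambda_max() * 0.4
        fit = fit_weighted_lasso_cox(X, PenaltySpec(lam=lam, weights=w),
                                     time, event, standardize=False)
        oracle = proximal_gradient_lasso(X, time, event, lam, weights=w)
        assert np.allclose(fit.coef, oracle, atol=1e-4)

    def test_kkt_conditions_hold(self, rng):
        n, p = 80, 12
        X = rng.standard_normal((n, p))
        t = rng.exponential(np.exp(-(0.8 * X[:, 0] - 0.8 * X[:, 5])))
        c = rng.uniform(0.3, 4, n)
        time, event = np.minimum(t, c), (t <= c).astype(float)
        w = np.r_[0.0, np.ones(p - 1)]
        prob = LassoProblem(X, time, event, weights=w)
        lam = prob.lambda_max() * 0.3
        fit = fit_weighted_lasso_cox(X, PenaltySpec(lam=lam, weights=w),
                                     time, event)
        assert fit.diagnostics["kkt_residual"] <= 1e-6

    def test_weight_lambda_rescaling_invariance(self, small_surv):
        # multiplying all weights by c and dividing lambda by c leaves the
        # optimization problem, hence the solution, unchanged
        X, time, event = small_surv
        prob = LassoProblem(X, time, event, standardize=False)
        lam = prob.lambda_max() * 0.4
        f1 = fit_weighted_lasso_cox(X, PenaltySpec(lam=lam, weights=1.0),
                                    time, event, standardize=False)
        f2 = fit_weighted_lasso_cox(
            X, PenaltySpec(lam=lam / 2, weights=np.full(4, 2.0)),
            time, event, standardize=False)
        assert np.allclose(f1.coef, f2.coef, atol=1e-6)

    def test_frozen_weight_column_exactly_zero(self, small_surv):
        X, time, event = small_surv
        w = np.array([1.0, 1e12, 1.0, 1.0])
        prob = LassoProblem(X, time, event, weights=w)
        fit = prob.fit(prob.lambda_max() * 0.05)
        assert fit.coef[1] == 0.0

    def test_negative_lambda_rejected(self, small_surv):
        X, time, event = small_surv
        with pytest.raises(ValueError):
            fit_weighted_lasso_cox(X, PenaltySpec(lam=-1.0), time, event)

    def test_permutation_equivariance(self, small_surv, rng):
        X, time, event = small_surv
        prob = LassoProblem(X, time, event)
        lam = prob.lambda_max() * 0.3
        f1 = prob.fit(lam, kkt_tol=1e-8)
        perm = rng.permutation(len(time))
        prob2 = LassoProblem(X[perm], time[perm], event[perm])
        f2 = prob2.fit(lam, kkt_tol=1e-8)
        assert np.allclose(f1.coef, f2.coef, atol=1e-6)


class TestLassoPath:
    def test_first_point_has_no_active_penalized(self, small_surv):
        X, time, event = small_surv
        res = lasso_path(X, 1.0, time, event, n_lambda=30)
        assert res.path.n_active[0] == 0

    def test_warm_start_consistency_with_direct_fit(self, small_surv):
        X, time, event = small_surv
        prob = LassoProblem(X, time, event, kkt_tol=1e-9)
        pr = prob.path(n_lambda=30)
        direct = prob.fit(pr.lambdas[-1], kkt_tol=1e-9)
        assert np.allclose(direct.coef, pr.coefs[-1], atol=1e-6)

    def test_path_mostly_monotone_in_active_count(self, rng):
        n, p = 100, 15
        X = rng.standard_normal((n, p))
        t = rng.exponential(np.exp(-(X[:, 0] - 0.5 * X[:, 3])))
        c = rng.uniform(0.3, 4, n)
        time, event = np.minimum(t, c), (t <= c).astype(float)
        res = lasso_path(X, 1.0, time, event, n_lambda=60)
        steps = np.diff(res.path.n_active)
        assert (steps >= 0).mean() >= 0.9

    def test_first_entry_recorded(self, small_surv):
        X, time, event = small_surv
        res = lasso_path(X, 1.0, time, event, n_lambda=40)
        fe = res.path.first_entry
        active_end = res.coef != 0
        assert np.all(fe[active_end] >= 0)

    def test_constant_column_warns_and_freezes(self, small_surv):
        X, time, event = small_surv
        X2 = np.column_stack([X, np.zeros(len(time))])
        with pytest.warns(UserWarning, match="constant"):
            res = lasso_path(X2, 1.0, time, event, n_lambda=20)
        assert np.all(res.path.coefs[:, -1] == 0)
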