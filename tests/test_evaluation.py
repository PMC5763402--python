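import numpy as np
import pytest

from predmod.evaluation import (auprc, biomarker_treatment_score, delta_c,
                                selection_metrics, uno_c)
from predmod.selection_methods import SelectionResult
from predmod.simulator import make_scenario, simulate_pair
from predmod.trial_data import TrialDataset, TruthLabels, standardize


def _truth(p, modifiers=(), prognostic=()):
    g = np.zeros(p)
    b = np.zeros(p)
    g[list(modifiers)] = -0.7
    b[list(prognostic)] = -0.7
    return TruthLabels(modifiers=np.array(modifiers, int),
                       prognostic_only=np.array(prognostic, int),
                       true_gamma=g, true_beta=b)


def _sel(H, p, gamma=None, ranking=None):
    return SelectionResult(method="test", H=np.array(H, int),
                           gamma_hat={int(i): (gamma or {}).get(i, -0.5)
                                      for i in H},
                           ranking=ranking)


class TestSelectionMetrics:
    def test_tp_fp_fdr(self):
        truth = _truth(500, modifiers=[3], prognostic=[7])
        m = selection_metrics(_sel([3, 10, 11, 12], 500), truth)
        assert (m.TP, m.FP, m.pFP, m.FN) == (1, 3, 0, 0)
        assert np.isclose(m.FDR, 0.75)
        assert m.rejected

    def test_prognostic_false_positive_counted(self):
        truth = _truth(100, modifiers=[3], prognostic=[7, 8])
        m = selection_metrics(_sel([7, 8], 100), truth)
        assert (m.TP, m.FP, m.pFP) == (0, 2, 2)

    def test_empty_selection_conventions(self):
        truth = _truth(100, modifiers=list(range(10)))
        m = selection_metrics(_sel([], 100), truth)
        assert m.FNR == 1.0 and m.FDR == 0.0 and not m.rejected

    def test_exact_recovery(self):
        truth = _truth(50, modifiers=[1, 2])
        m = selection_metrics(_sel([1, 2], 50), truth)
        assert m.FDR == 0.0 and m.FNR == 0.0

    def test_null_truth_zero_over_zero(self):
        truth = _truth(50)
        m = selection_metrics(_sel([], 50), truth)
        assert m.FDR == 0.0 and m.FNR == 0.0 and m.AUPRC is None


class TestAUPRC:
    def test_modifier_ranked_first_gives_one(self):
        truth = _truth(500, modifiers=[42])
        ranking = np.r_[42, np.delete(np.arange(500), 42)]
        assert auprc(ranking, truth) == 1.0

    def test_modifier_ranked_second_gives_half(self):
        truth = _truth(500, modifiers=[42])
        ranking = np.r_[0, 42, np.delete(np.arange(500), [0, 42])]
        assert np.isclose(auprc(ranking, truth), 0.5)

    def test_one_iff_all_actives_first(self):
        truth = _truth(20, modifiers=[0, 1, 2])
        perfect = np.arange(20)
        assert auprc(perfect, truth) == 1.0
        swapped = perfect.copy()
        swapped[[2, 3]] = swapped[[3, 2]]
        assert auprc(swapped, truth) < 1.0

    def test_matches_sklearn_average_precision(self, rng):
        from sklearn.metrics import average_precision_score
        truth = _truth(80, modifiers=[4, 17, 33])
        y = np.zeros(80)
        y[[4, 17, 33]] = 1
        for _ in range(10):
            ranking = rng.permutation(80)
            scores = np.empty(80)
            scores[ranking] = -np.arange(80)
            assert np.isclose(auprc(ranking, truth),
                              average_precision_score(y, scores), atol=1e-12)

    def test_random_ranking_mean_near_prevalence(self, rng):
        # 10 actives among 500: an uninformative ranking scores close to the
        # prevalence 0.02 (the exact mean, ~0.031, sits slightly above it
        # because average precision is skewed upward at small active counts)
        # and far below any informative ranking
        truth = _truth(500, modifiers=list(range(10)))
        vals = []
        base = np.arange(500)
        for _ in range(2000):
            vals.append(auprc(rng.permutation(base), truth))
        assert 0.02 < np.mean(vals) < 0.045

    def test_errors(self):
        truth = _truth(10, modifiers=[1])
        with pytest.raises(ValueError, match="permutation"):
            auprc(np.zeros(10, int), truth)
        with pytest.raises(ValueError, match="modifiers"):
            auprc(np.arange(10), _truth(10))


class TestScore:
    def _ds(self, X):
        n = X.shape[0]
        return TrialDataset(X=X, treatment=np.resize([0.5, -0.5], n),
                            time=np.arange(1.0, n + 1),
                            event=np.resize([1.0, 0.0], n))

    def test_cross_product_arithmetic(self):
        ds = self._ds(np.array([[0.0, 0, 2.0], [1.0, 0, -1.0]]))
        res = _sel([2], 3, gamma={2: -0.5})
        assert np.allclose(biomarker_treatment_score(res, ds), [-1.0, 0.5])

    def test_empty_signature_scores_zero(self):
        ds = self._ds(np.eye(4))
        assert np.all(biomarker_treatment_score(_sel([], 4), ds) == 0)

    def test_linearity_in_gamma(self):
        ds = self._ds(np.arange(12.0).reshape(4, 3))
        s1 = biomarker_treatment_score(_sel([0, 2], 3, {0: -0.3, 2: 0.4}), ds)
        s2 = biomarker_treatment_score(_sel([0, 2], 3, {0: -0.6, 2: 0.8}), ds)
        assert np.allclose(s2, 2 * s1)

    def test_missing_biomarker_rejected(self):
        ds = self._ds(np.eye(3))
        with pytest.raises(ValueError, match="missing"):
            biomarker_treatment_score(_sel([7], 8), ds)


def uno_c_brute_force(score, time, event, tau):
    """Independent double-loop IPCW oracle (same-sample censoring KM)."""
    n = len(time)
    order = np.argsort(time)
    # Kaplan-Meier of censoring, left-continuous evaluation
    def G_left(t):
        g = 1.0
        for u in np.unique(time):
            if u >= t:
                break
            at_risk = (time >= u).sum()
            d_c = ((time == u) & (event == 0)).sum()
            g *= 1 - d_c / at_risk
        return g

    num = den = 0.0
    for i in range(n):
        if event[i] != 1 or time[i] >= tau:
            continue
        w = 1.0 / G_left(time[i]) ** 2
        for j in range(n):
            if time[i] < time[j]:
                den += w
                if score[i] > score[j]:
                    num += w
                elif score[i] == score[j]:
                    num += 0.5 * w
    return num / den


class TestUnoC:
    def test_perfect_concordance_without_censoring(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.ones(4)
        score = np.array([4.0, 3.0, 2.0, 1.0])   # higher = earlier event
        assert uno_c(score, time, event, tau=5.0) == 1.0

    def test_constant_score_is_half(self, rng):
        time = rng.exponential(1, 30)
        event = rng.integers(0, 2, 30).astype(float)
        event[0] = 1
        assert np.isclose(uno_c(np.ones(30), time, event, tau=2.0), 0.5)

    def test_matches_brute_force_oracle(self, rng):
        n = 20
        t = rng.exponential(1, n)
        c = rng.uniform(0.2, 2.5, n)
        time, event = np.minimum(t, c), (t <= c).astype(float)
        score = rng.normal(0, 1, n)
        tau = float(np.quantile(time, 0.9))
        assert np.isclose(uno_c(score, time, event, tau),
                          uno_c_brute_force(score, time, event, tau),
                          atol=1e-10)

    def test_matches_scikit_survival(self, rng):
        from sksurv.metrics import concordance_index_ipcw
        from sksurv.util import Surv
        n = 120
        t = rng.exponential(1, n)
        c = rng.uniform(0.2, 3.0, n)
        time, event = np.minimum(t, c), (t <= c).astype(bool)
        score = 0.5 * t + rng.normal(0, 1, n)
        y = Surv.from_arrays(event, time)
        tau = float(np.quantile(time, 0.9))
        theirs = concordance_index_ipcw(y, y, -score, tau=tau)[0]
        # our convention: higher score = earlier event, so flip the sign
        ours = uno_c(-score, time, event.astype(float), tau)
        assert np.isclose(ours, theirs, atol=1e-8)

    def test_monotone_transform_invariance(self, rng):
        n = 40
        t = rng.exponential(1, n)
        c = rng.uniform(0.2, 2.5, n)
        time, event = np.minimum(t, c), (t <= c).astype(float)
        score = rng.normal(0, 1, n)
        tau = float(np.quantile(time, 0.9))
        a = uno_c(score, time, event, tau)
        b = uno_c(np.exp(3 * score), time, event, tau)
        assert np.isclose(a, b, atol=1e-12)

    def test_no_events_before_tau_rejected(self):
        with pytest.raises(ValueError, match="tau"):
            uno_c(np.arange(4.0), np.arange(1.0, 5.0), np.ones(4), tau=0.5)


class TestDeltaC:
    def _pair(self, seed, n=300, p=12, modifiers=(0, 1, 2), gamma=-0.9):
        spec = make_scenario("5a", p=p, block_size=p, n=n,
                             modifier_idx=np.array(modifiers, int),
                             hr_plus=np.full(len(modifiers), np.exp(gamma)),
                             hr_minus=np.ones(len(modifiers)),
                             n_modifiers=len(modifiers), seed=seed)
        tr, va = simulate_pair(spec)
        trs, sc = standardize(tr)
        vas, _ = standardize(va, scaler=sc)
        return trs, vas

    def test_empty_signature_gives_zero(self):
        trs, vas = self._pair(0)
        res = _sel([], trs.p)
        out = delta_c(res, vas)
        assert out.delta_c == 0.0 and out.c_plus == 0.5

    def test_oracle_signature_positive_on_validation(self):
        hits = 0
        for seed in range(12):
            trs, vas = self._pair(seed)
            res = _sel([0, 1, 2], trs.p, gamma={i: -0.9 for i in (0, 1, 2)})
            if delta_c(res, vas).delta_c > 0:
                hits += 1
        assert hits >= 10

    def test_null_data_signature_centred_at_zero(self):
        vals = []
        for seed in range(20):
            spec = make_scenario("1a", p=10, block_size=5, n=300, seed=seed)
            tr, va = simulate_pair(spec)
            trs, sc = standardize(tr)
            vas, _ = standardize(va, scaler=sc)
            res = _sel([2, 5], 10, gamma={2: -0.4, 5: 0.3})
            vals.append(delta_c(res, vas).delta_c)
        assert abs(np.mean(vals)) < 0.04

    def test_one_arm_only_rejected(self):
        ds = TrialDataset(X=np.eye(4), treatment=np.full(4, 0.5),
                          time=np.arange(1.0, 5.0), event=np.ones(4))
        with pytest.raises(ValueError, match="arm"):
            delta_c(_sel([1], 4), ds)
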