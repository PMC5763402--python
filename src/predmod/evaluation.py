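"""Evaluation of selected interaction sets and of signature strength.

Selection quality is scored against simulation truth (TP/FP/FDR/FNR, plus a
tuning-free AUPRC of each method's biomarker ranking).  Signature strength
uses the biomarker-treatment score eta_hat — the cross-product of retained
interaction coefficients with a patient's biomarker values; lower score =
larger predicted treatment benefit — and measures, separately per arm, the
IPCW (Uno) concordance between eta_hat and survival.  The difference of the
two arm-specific concordances (Delta C = C_plus - C_minus) quantifies how
much of the score's discrimination is treatment-specific: it is the
interaction-strength of the signature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trial_data import TrialDataset, TruthLabels

__all__ = ["MetricsRow", "StrengthResult", "selection_metrics", "auprc",
           "biomarker_treatment_score", "uno_c", "delta_c"]


@dataclass
class MetricsRow:
    method: str
    TP: int
    FP: int
    pFP: int
    FN: int
    FDR: float
    FNR: float
    AUPRC: float | None
    rejected: bool
    n_selected: int


@dataclass
class StrengthResult:
    score: np.ndarray
    c_plus: float
    c_minus: float
    delta_c: float
    set: str = "validation"


def selection_metrics(result, truth: TruthLabels) -> MetricsRow:
    """TP/FP/FDR/FNR of a selection against simulation truth.

    Conventions: FDR = FP/(TP+FP) and FNR = FN/(TP+FN) with 0/0 -> 0;
    `rejected` is True when at least one interaction was selected (the
    global-test reading: type-I error under null scenarios, power otherwise).
    """
    H = np.asarray(sorted(result.H), dtype=int)
    modifiers = np.asarray(truth.modifiers, dtype=int)
    prog = np.asarray(truth.prognostic_only, dtype=int)
    tp = int(np.intersect1d(H, modifiers).size)
    fp = int(H.size - tp)
    pfp = int(np.intersect1d(H, prog).size)
    fn = int(modifiers.size - tp)
    fdr = fp / (tp + fp) if (tp + fp) else 0.0
    fnr = fn / (tp + fn) if (tp + fn) else 0.0
    au = None
    if result.ranking is not None and modifiers.size:
        au = auprc(result.ranking, truth)
    return MetricsRow(method=result.method, TP=tp, FP=fp, pFP=pfp, FN=fn,
                      FDR=fdr, FNR=fnr, AUPRC=au, rejected=H.size > 0,
                      n_selected=int(H.size))


def auprc(ranking, truth: TruthLabels) -> float:
    """Average precision of a biomarker ranking against the true modifiers.

    `ranking` is a permutation of {0..p-1}, best candidate first.  The
    precision-recall curve is integrated as a step function (average
    precision), avoiding the optimism of linear interpolation.
    """
    ranking = np.asarray(ranking, dtype=int)
    p = ranking.size
    if np.unique(ranking).size != p:
        raise ValueError("ranking must be a permutation of all biomarkers")
    actives = np.zeros(p, dtype=bool)
    modifiers = np.asarray(truth.modifiers, dtype=int)
    if modifiers.size == 0:
        raise ValueError("AUPRC undefined without true modifiers")
    actives[modifiers] = True
    hits = actives[ranking]
    cum_tp = np.cumsum(hits)
    precision = cum_tp / np.arange(1, p + 1)
    return float(precision[hits].sum() / modifiers.size)


def biomarker_treatment_score(result, dataset: TrialDataset) -> np.ndarray:
    """eta_hat_j = sum_{s in H} gamma_hat_s * X_{j,s}; zeros when H is empty.

    The dataset must be on the training scale (validation data standardized
    with the training scalers).
    """
    H = np.asarray(sorted(result.H), dtype=int)
    if H.size == 0:
        return np.zeros(dataset.n)
    if H.max() >= dataset.p:
        raise ValueError("selected biomarker missing from dataset")
    gamma = np.asarray([result.gamma_hat[s] for s in H], dtype=float)
    return dataset.X[:, H] @ gamma


def _censor_km_left(time, event, t_query):
    """Kaplan-Meier of the censoring distribution, evaluated at t_query-."""
    order = np.argsort(time, kind="mergesort")
    ts = time[order]
    cens = 1.0 - event[order]
    uniq, inv = np.unique(ts, return_inverse=True)
    at_risk = time.size - np.searchsorted(ts, uniq, side="left")
    c_events = np.bincount(inv, weights=cens)
    factors = 1.0 - c_events / at_risk
    surv = np.cumprod(factors)
    # G(t-) : product over censoring times strictly below t
    idx = np.searchsorted(uniq, t_query, side="left") - 1
    out = np.ones_like(np.asarray(t_query, float))
    pos = idx >= 0
    out[pos] = surv[idx[pos]]
    return out


def uno_c(score, time, event, tau) -> float:
    """Uno's IPCW concordance of `score` with survival, truncated at tau.

    Pairs (i,j) with t_i < t_j, t_i < tau and event_i = 1 are usable; each is
    weighted 1/G(t_i-)^2 with G the same-sample Kaplan-Meier estimate of the
    censoring distribution.  A higher score must predict an earlier event;
    score ties count 1/2 (a constant score gives 0.5).
    """
    score = np.asarray(score, float)
    time = np.asarray(time, float)
    event = np.asarray(event, float)
    n = time.size
    if n < 2:
        raise ValueError("need at least two subjects")
    g = _censor_km_left(time, event, time)
    g = np.maximum(g, 1e-12)
    w = 1.0 / g**2
    usable_i = (event > 0) & (time < tau)
    if not np.any(usable_i):
        raise ValueError("no events before tau")
    ti = time[usable_i][:, None]
    si = score[usable_i][:, None]
    wi = w[usable_i][:, None]
    comp = ti < time[None, :]
    conc = np.where(si > score[None, :], 1.0,
                    np.where(si == score[None, :], 0.5, 0.0))
    num = float(np.sum(wi * comp * conc))
    den = float(np.sum(wi * comp))
    if den == 0:
        raise ValueError("no usable pairs")
    return num / den


def delta_c(result, dataset: TrialDataset, tau_quantile=0.95,
            which="validation") -> StrengthResult:
    """Arm-specific Uno concordances of the biomarker-treatment score.

    C_plus is computed among experimental-arm patients, C_minus among
    controls, each with its own censoring KM and truncation at the arm's
    `tau_quantile` observed-time quantile.  delta_c = C_plus - C_minus,
    reported signed; an empty signature scores 0 by convention.
    """
    score = biomarker_treatment_score(result, dataset)
    if np.all(score == score[0]):
        return StrengthResult(score=score, c_plus=0.5, c_minus=0.5,
                              delta_c=0.0, set=which)
    cs = []
    for arm in (0.5, -0.5):
        m = dataset.treatment == arm
        if m.sum() < 2 or dataset.event[m].sum() < 1:
            raise ValueError("each arm needs patients with events")
        tau = float(np.quantile(dataset.time[m], tau_quantile))
        cs.append(uno_c(score[m], dataset.time[m], dataset.event[m], tau))
    return StrengthResult(score=score, c_plus=cs[0], c_minus=cs[1],
                          delta_c=cs[0] - cs[1], set=which)
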