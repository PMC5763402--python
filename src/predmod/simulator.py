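"""Seeded scenario simulator for randomized trials with correlated biomarkers.

Emulates the study conditions used throughout the package: unit-variance
Gaussian biomarkers with within-block autoregressive correlation rho^|i-j|,
exact 1:1 randomization (arm codes +/-0.5), exponential (or Weibull)
proportional-hazards event times parameterized through per-arm median
survival, and administrative censoring from U(2,5) years (a trial with
three-year accrual and two-year follow-up).  Six scenario families cover the
complete null, a treatment-only effect, purely prognostic biomarkers, and
one/many treatment-effect modifiers with or without prognostic markers; "c"
variants draw smaller effects at random and add heavier censoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .trial_data import TrialDataset, TruthLabels

__all__ = [
    "CensoringSpec", "ScenarioSpec", "ResolvedEffects", "gen_biomarkers",
    "linear_predictor", "gen_times", "make_scenario", "simulate_pair",
    "apply_correlation_sensitivity", "resolve_effects",
    "analytic_censoring_probability", "SCENARIO_NAMES",
]

LOG2 = float(np.log(2.0))


@dataclass
class CensoringSpec:
    """Censoring time distribution: U(a,b), optionally min-ed with Exp(rate)."""

    kind: str = "uniform"          # "uniform" | "uniform_plus_exponential"
    a: float = 2.0
    b: float = 5.0
    rate: float = 0.0

    def __post_init__(self):
        if not self.a < self.b:
            raise ValueError("require a < b")
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        if self.kind not in ("uniform", "uniform_plus_exponential"):
            raise ValueError(f"unknown censoring kind {self.kind!r}")

    def draw(self, n, rng):
        c = rng.uniform(self.a, self.b, size=n)
        if self.kind == "uniform_plus_exponential" and self.rate > 0:
            c = np.minimum(c, rng.exponential(1.0 / self.rate, size=n))
        return c


def analytic_censoring_probability(median: float, censoring: CensoringSpec) -> float:
    """P(censored) for an Exp event time with the given median, closed form."""
    theta = LOG2 / median
    r = censoring.rate if censoring.kind == "uniform_plus_exponential" else 0.0
    a, b = censoring.a, censoring.b
    s = theta + r
    p_event = (theta / s) * (1.0 - np.exp(-a * s))
    p_event += (theta / (b - a)) * ((b - a) * np.exp(-a * s) / s
                                    - (np.exp(-a * s) - np.exp(-b * s)) / s**2)
    return float(1.0 - p_event)


def _calibrate_exp_censoring(target=0.65, a=2.0, b=5.0):
    """Extra-exponential censoring rate giving `target` censoring under the
    complete null (baseline median 1 year)."""
    def f(r):
        return analytic_censoring_probability(
            1.0, CensoringSpec("uniform_plus_exponential", a, b, r)) - target
    return brentq(f, 1e-6, 10.0, xtol=1e-10)


@dataclass
class ScenarioSpec:
    """Full parameterization of one simulation scenario."""

    name: str
    p: int = 500
    n: int = 500
    block_size: int = 25
    rho: float = 0.7
    m0: float = 1.0                      # control-arm median survival at X=0 (years)
    treatment_median_ratio: float = 1.0  # experimental/control median at X=0
    modifier_idx: np.ndarray | None = None   # None => drawn at simulation time
    hr_plus: np.ndarray = field(default_factory=lambda: np.array([]))
    hr_minus: np.ndarray = field(default_factory=lambda: np.array([]))
    prognostic_idx: np.ndarray | None = None
    hr_prog: np.ndarray = field(default_factory=lambda: np.array([]))
    n_modifiers: int = 0
    n_prognostic: int = 0
    effect_draw: dict | None = None      # {"main": (lo,hi), "interaction": (lo,hi)}
    time_dist: str = "exponential"       # "exponential" | "weibull"
    weibull_shape: float = 1.0
    censoring: CensoringSpec = field(default_factory=CensoringSpec)
    seed: int = 0

    def __post_init__(self):
        if self.p % self.block_size != 0:
            raise ValueError("block_size must divide p")
        if self.modifier_idx is not None:
            self.modifier_idx = np.asarray(self.modifier_idx, dtype=int)
            if self.prognostic_idx is not None and np.intersect1d(
                    self.modifier_idx, self.prognostic_idx).size:
                raise ValueError("modifier and prognostic indices must be disjoint")
        if self.prognostic_idx is not None:
            self.prognostic_idx = np.asarray(self.prognostic_idx, dtype=int)
        for hr in (self.hr_plus, self.hr_minus, self.hr_prog):
            if np.any(np.asarray(hr) <= 0):
                raise ValueError("hazard ratios must be positive")

    @property
    def alpha(self) -> float:
        """Treatment log-hazard ratio implied by the per-arm medians."""
        return -float(np.log(self.treatment_median_ratio))


@dataclass
class ResolvedEffects:
    alpha: float
    beta: np.ndarray
    gamma: np.ndarray
    truth: TruthLabels


def gen_biomarkers(p, n, block_size, rho, rng) -> np.ndarray:
    """n x p standard-normal biomarkers, AR(1) correlation rho within blocks."""
    if p % block_size != 0:
        raise ValueError("block_size must divide p")
    if not -1 < rho < 1:
        raise ValueError("rho must be in (-1, 1)")
    X = rng.standard_normal((n, p))
    scale = np.sqrt(1.0 - rho * rho)
    for start in range(0, p, block_size):
        for j in range(start + 1, start + block_size):
            X[:, j] = rho * X[:, j - 1] + scale * X[:, j]
    return X


def resolve_effects(spec: ScenarioSpec, rng) -> ResolvedEffects:
    """Turn a scenario recipe into concrete (alpha, beta, gamma) vectors.

    The generating model is lp = alpha*T + X beta + (X*T) gamma with
    T = +/-0.5, so an active biomarker's per-unit log-hazard ratio is
    beta - gamma/2 in the control arm and beta + gamma/2 in the experimental
    arm.  The scenarios prescribe those arm-specific ratios (HR-, HR+),
    hence beta_i = (log HR+ + log HR-)/2 and gamma_i = log HR+ - log HR-:
    a pure modifier (HR- = 1) has no effect in the control arm.

    For fixed scenarios beta_i = log HR-, gamma_i = log HR+ - log HR-, so the
    per-unit hazard ratio is HR- in the control arm and HR+ in the
    experimental arm.  Draw-based ("c") scenarios sample effects and block
    positions at random.
    """
    p = spec.p
    beta = np.zeros(p)
    gamma = np.zeros(p)
    if spec.effect_draw is None:
        mod = spec.modifier_idx if spec.modifier_idx is not None else np.array([], int)
        prog = (spec.prognostic_idx if spec.prognostic_idx is not None
                else np.array([], int))
        if mod.size:
            lhr_plus = np.log(spec.hr_plus)
            lhr_minus = np.log(spec.hr_minus)
            beta[mod] = 0.5 * (lhr_plus + lhr_minus)
            gamma[mod] = lhr_plus - lhr_minus
        if prog.size:
            beta[prog] = np.log(spec.hr_prog)
    else:
        k, m = spec.n_modifiers, spec.n_prognostic
        idx = rng.choice(p, size=k + m, replace=False)
        mod, prog = idx[:k], idx[k:]
        lo, hi = spec.effect_draw["interaction"]
        draw = rng.uniform(lo, hi, size=k)   # log HR+ with HR- = 1
        gamma[mod] = draw
        beta[mod] = 0.5 * draw
        lo, hi = spec.effect_draw["main"]
        beta[prog] = rng.uniform(lo, hi, size=m)
    modifiers = np.sort(np.where(gamma != 0)[0])
    prognostic_only = np.sort(np.where((beta != 0) & (gamma == 0))[0])
    truth = TruthLabels(modifiers=modifiers, prognostic_only=prognostic_only,
                        true_gamma=gamma, true_beta=beta)
    return ResolvedEffects(alpha=spec.alpha, beta=beta, gamma=gamma, truth=truth)


def linear_predictor(spec: ScenarioSpec, X, T,
                     effects: ResolvedEffects | None = None) -> np.ndarray:
    """lp = alpha*T + X beta + (X*T) gamma for the scenario's effects."""
    if effects is None:
        if spec.effect_draw is not None:
            raise ValueError("draw-based scenario: pass resolved effects")
        effects = resolve_effects(spec, np.random.default_rng(0))
    X = np.asarray(X, dtype=float)
    T = np.asarray(T, dtype=float)
    if X.shape[1] != spec.p:
        raise ValueError("X width does not match spec.p")
    return (effects.alpha * T + X @ effects.beta + (X @ effects.gamma) * T)


def gen_times(spec: ScenarioSpec, lp, rng):
    """Draw (observed time, event flag) given the linear predictor.

    The baseline hazard is anchored so the control arm at X=0 has median
    survival spec.m0: the hazard multiplier is exp(lp + alpha/2), equal to 1
    for a control-arm patient at X=0.  Weibull uses the proportional-hazards
    parameterization with baseline median m0; shape 1 is exponential.
    """
    lp = np.asarray(lp, dtype=float)
    if not np.all(np.isfinite(lp)):
        raise ValueError("non-finite linear predictor")
    if spec.m0 <= 0:
        raise ValueError("m0 must be positive")
    mult = np.exp(lp + spec.alpha / 2.0)
    e = rng.exponential(1.0, size=lp.size)
    k = spec.weibull_shape if spec.time_dist == "weibull" else 1.0
    t_event = spec.m0 * (e / (LOG2 * mult)) ** (1.0 / k)
    c = spec.censoring.draw(lp.size, rng)
    time = np.minimum(t_event, c)
    event = (t_event <= c).astype(float)
    return time, event


SCENARIO_NAMES = tuple(f"{i}{s}" for s in "abc" for i in range(1, 7))

_C_CENSOR_RATE = None


def _c_censoring() -> CensoringSpec:
    global _C_CENSOR_RATE
    if _C_CENSOR_RATE is None:
        _C_CENSOR_RATE = _calibrate_exp_censoring()
    return CensoringSpec("uniform_plus_exponential", 2.0, 5.0, _C_CENSOR_RATE)


def _block_centers(n_active, block_size, start_block=0):
    """Deterministic default placement: one active per block, at block center."""
    return np.array([(start_block + b) * block_size + block_size // 2
                     for b in range(n_active)], dtype=int)


def make_scenario(name: str, seed: int = 0, **overrides) -> ScenarioSpec:
    """Table of study scenarios, keyed '1a'..'6c'.

    Families: 1 complete null; 2 treatment effect only (experimental-arm
    median 2.0); 3 strongly prognostic markers (HR 0.5 both arms); 4 one
    treatment-effect modifier (HR+ 0.5, HR- 1); 5 ten/twenty modifiers;
    6 modifiers plus prognostic markers.  Suffix a: p=500; b: p=1000;
    c: p=500 with effects drawn from U(-0.5,-0.1) (main) and U(-0.7,-0.1)
    (interaction), random block allocation, and heavier censoring.
    """
    if name not in SCENARIO_NAMES:
        raise ValueError(f"unknown scenario {name!r}; expected one of {SCENARIO_NAMES}")
    fam, variant = int(name[0]), name[1]
    p, bs = (1000, 50) if variant == "b" else (500, 25)
    n_active = 20 if variant == "b" else 10
    spec = ScenarioSpec(name=name, p=p, block_size=bs, seed=seed)

    if fam == 2:
        spec = replace(spec, treatment_median_ratio=2.0)

    if variant == "c":
        draw = {"main": (-0.5, -0.1), "interaction": (-0.7, -0.1)}
        spec = replace(spec, censoring=_c_censoring())
        if fam == 3:
            spec = replace(spec, effect_draw=draw, n_prognostic=n_active)
        elif fam == 4:
            spec = replace(spec, effect_draw=draw, n_modifiers=1)
        elif fam == 5:
            spec = replace(spec, effect_draw=draw, n_modifiers=n_active)
        elif fam == 6:
            spec = replace(spec, effect_draw=draw, n_modifiers=n_active,
                           n_prognostic=n_active)
    else:
        if fam == 3:
            idx = _block_centers(n_active, bs)
            spec = replace(spec, prognostic_idx=idx,
                           hr_prog=np.full(n_active, 0.5),
                           n_prognostic=n_active)
        elif fam == 4:
            idx = _block_centers(1, bs)
            spec = replace(spec, modifier_idx=idx, hr_plus=np.array([0.5]),
                           hr_minus=np.array([1.0]), n_modifiers=1)
        elif fam == 5:
            idx = _block_centers(n_active, bs)
            spec = replace(spec, modifier_idx=idx,
                           hr_plus=np.full(n_active, 0.5),
                           hr_minus=np.ones(n_active), n_modifiers=n_active)
        elif fam == 6:
            mod = _block_centers(n_active, bs)
            prog = _block_centers(n_active, bs, start_block=n_active)
            spec = replace(spec, modifier_idx=mod,
                           hr_plus=np.full(n_active, 0.5),
                           hr_minus=np.ones(n_active), n_modifiers=n_active,
                           prognostic_idx=prog, hr_prog=np.full(n_active, 0.5),
                           n_prognostic=n_active)
    if overrides:
        spec = replace(spec, **overrides)
    return spec


def apply_correlation_sensitivity(spec: ScenarioSpec, mode: str | None = None
                                  ) -> ScenarioSpec:
    """Move active biomarkers to adjacent within-block positions.

    mode "pred_pred": modifiers packed contiguously into the first block so
    adjacent modifiers have correlation rho; "pred_prog": modifiers and
    prognostic markers interleaved in the first block(s).  Without a mode
    the spec is returned unchanged.
    """
    if mode is None:
        return spec
    if spec.modifier_idx is None or spec.modifier_idx.size == 0:
        raise ValueError("scenario has no fixed modifier indices")
    k = spec.modifier_idx.size
    if mode == "pred_pred":
        if k > spec.block_size:
            raise ValueError("more modifiers than one block holds")
        return replace(spec, modifier_idx=np.arange(k))
    if mode == "pred_prog":
        if spec.prognostic_idx is None or spec.prognostic_idx.size == 0:
            raise ValueError("pred_prog mode needs prognostic markers")
        m = spec.prognostic_idx.size
        if k + m > spec.block_size:
            raise ValueError("more active markers than one block holds")
        pos = np.arange(k + m)
        return replace(spec, modifier_idx=pos[0::2][:k],
                       prognostic_idx=pos[1::2][:m])
    raise ValueError(f"unknown mode {mode!r}")


def simulate_pair(spec: ScenarioSpec, rng=None):
    """Generate an independent (training, validation) dataset pair.

    Both datasets share the same resolved effects (and hence truth labels);
    randomization is exactly 1:1 via a permuted half/half arm assignment.
    """
    if spec.n % 2:
        raise ValueError("n must be even for exact 1:1 randomization")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    effects = resolve_effects(spec, rng)
    out = []
    arms = np.repeat([0.5, -0.5], spec.n // 2)
    for _ in range(2):
        X = gen_biomarkers(spec.p, spec.n, spec.block_size, spec.rho, rng)
        T = rng.permutation(arms)
        lp = linear_predictor(spec, X, T, effects)
        time, event = gen_times(spec, lp, rng)
        out.append(TrialDataset(X=X, treatment=T, time=time, event=event,
                                truth=effects.truth))
    return out[0], out[1]
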