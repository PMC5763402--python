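# Methods

## Model

All strategies operate on the proportional-hazards interaction model

    h(t | T, X) = h0(t) · exp( α·T + Σi βi·Xi + Σi γi·Xi·T ),

with treatment coded T = ±0.5 (+0.5 experimental), biomarkers Xi
standardized on the training set (sample sd, ddof = 1; validation data are
transformed with the training means/sds), and Breslow handling of tied
event times throughout.  The treatment coefficient α is never penalized.
A biomarker is declared a treatment-effect modifier when its interaction
coefficient is retained (the two-I model instead compares arm-specific
effects and declares a modifier when exactly one of γi+, γi− survives).

## Synthetic trial generator

`simulator` emulates a two-arm randomized trial with high-dimensional
biomarkers:

* **Biomarkers.** Unit-variance Gaussians; within blocks of 25 (p = 500)
  or 50 (p = 1000) consecutive columns the correlation is AR(1),
  corr(Xi, Xj) = 0.7^|i−j|; blocks are independent.
* **Randomization.** Exactly n/2 patients per arm via a permuted
  half-and-half assignment; n defaults to 500.
* **Event times.** Exponential, parameterized through per-arm median
  survival at X = 0: the baseline hazard is anchored so the control arm
  has median m0 = 1 year; the treatment log-hazard ratio is
  α = −log(median ratio).  A Weibull option (shapes 0.5 and 2 in the
  sensitivity analyses) keeps the same baseline median and multiplies the
  baseline hazard by exp(lp).
* **Effects.** Scenarios prescribe *arm-specific* per-unit hazard ratios
  (HR−, HR+) for each active biomarker.  Under ±0.5 coding this maps to
  βi = (log HR+ + log HR−)/2 and γi = log HR+ − log HR−, so a pure
  modifier (HR− = 1, HR+ = 0.5) truly has no effect in the control arm.
  (The alternative convention βi = log HR− would leak a spurious
  control-arm effect of −γi/2; it also contradicts the asymmetric per-arm
  censoring fractions of the study design, which this parameterization
  reproduces: 0.105/0.156 for the one-modifier scenario.)
* **Censoring.** Administrative, U(2, 5) years (three-year accrual plus
  two-year follow-up).  The closed form
  P(censored) = 1 − ∫ f_T S_U e^{−rt} dt is used for analytic checks
  (e.g. 0.311 for a median of 2 years).  The "c" scenario family needs
  60–80% censoring, which U(2, 5) cannot produce; the generator adds an
  independent exponential censoring component whose rate is calibrated by
  root-finding so the complete-null censoring probability is 0.65.  This
  is an explicit approximation — the original mechanism is not documented
  — so c-scenario censoring fractions are not treated as reproduction
  targets.
* **Active-index placement.** For the a/b scenarios actives sit at the
  centers of distinct blocks (deterministic); `apply_correlation_sensitivity`
  moves them to adjacent within-block positions ("pred_pred") or
  interleaves modifiers with prognostic markers ("pred_prog").  The "c"
  scenarios draw effects (main log-HR ~ U(−0.5, −0.1), interaction
  ~ U(−0.7, −0.1)) and allocate indices at random per replication.

What the generator does **not** emulate: non-proportional hazards,
covariate-dependent or informative censoring, measurement error,
non-Gaussian expression distributions, batch effects, and accrual beyond
the uniform window.  Passing tests therefore demonstrate correctness of
the algorithms under the stated generative model, not robustness to real
transcriptomic data pathologies.

## Penalized Cox solvers

The weighted lasso maximizes `l(c) − λ Σj wj |cj|` (full partial
log-likelihood, not scaled by 1/n) by iteratively reweighted least squares
with cyclic coordinate descent on the diagonal-curvature working problem
(numba kernels).  Sequential strong-rule screening restricts each sweep to
candidate columns; every outer iteration verifies the
Karush–Kuhn–Tucker conditions on the exact gradient and re-admits any
violator, so screening never changes the solution.  Defaults: working KKT
tolerance 1e−4 (single fits through `fit_weighted_lasso_cox` tighten to
1e−6), inner step tolerance 1e−6, at most 300 sweeps per working problem
and 40 outer iterations, with an objective-decrease safeguard that bisects
overshooting quadratic steps.  λ grids are log-spaced over 100 points down
to 0.01·λmax, with λmax computed from the score at the null model (only
unpenalized columns fitted).  Paths stop early once more than 90% of the
event count of penalized columns are active — beyond that the working
problem is rank-deficient and useless for tuning.

The ridge solver is an exact damped Newton method (gradient norm ≤ 1e−7 at
convergence).  When penalized columns outnumber subjects the problem is
first reduced by an SVD of the penalized block to an equivalent one of
rank ≤ n; the reduction is exact for the ridge penalty and is reused
across a λ₂ grid.

**Penalty scale convention.**  The solver can rescale penalized columns to
unit sd internally (glmnet-style, `standardize=True`), but the selection
strategies deliberately do not use it: the penalties apply to the
coefficients of the design columns exactly as the formulas are written —
standardized biomarkers and their raw products with T, whose sd is about
0.5.  Interactions are therefore penalized more strongly per unit of
effect, which keeps selected interaction sets sparse (single-modifier
scenario: mean ≈ 1–2 selected for the full-lasso, matching the reference
behaviour; with internal rescaling the mean rises to ≈ 4–5).  The
trade-off is documented: in the strongly-prognostic null scenario the
full-lasso's leakage of interactions is lower under this convention than
the reference tables suggest.  `selection_methods.STANDARDIZE_INTERNALLY`
flips the convention package-wide.

## Cross-validated partial likelihood (CVL)

All tuning uses fivefold cross-validation with the criterion

    CVL(θ) = Σk [ l_full(ĉ(−k)(θ)) − l(−k)(ĉ(−k)(θ)) ],

maximized over the grid; ties break toward stronger penalization (larger
λ, smaller K, fewer boosting iterations).  Folds are balanced ±1 and
stratified by event status, drawn once per method fit and shared across
the grid.  Fold-level fits scale the penalty by n_fold/n (the
per-observation convention of solvers that normalize the likelihood by n);
with matched folds the resulting λ choice reproduces the mainstream
penalized-Cox CV implementation exactly.  For lasso-family methods the
full-data and fold paths advance in lockstep over the λ grid, and the grid
is abandoned 15 points past the running CVL maximum once the criterion has
dropped 25 log-likelihood units below it (5 points / 25 units for the
group-lasso) — regions that cannot change the argmax.  The CVL curve is
kept in `SelectionResult.tuning` for inspection; the criterion is known to
run conservative for the grouped-weight adaptive lasso and lenient for the
group-lasso, and the package reproduces that behaviour rather than
correcting it.

## Group-lasso via piecewise-exponential Poisson

Follow-up is split into 1/6-year (two-month) intervals; each patient
contributes one Poisson observation per interval at risk with log-exposure
offset, and one free intercept per interval (≤ 30 at the 5-year maximum)
plays the role of the baseline hazard — on null data the per-interval
rates reproduce the Breslow cumulative-hazard increments within 5%.  The
intercepts are profiled in closed form between block-coordinate sweeps;
blocks are the (βi, γi) pairs with penalty λ Σ √(βi² + γi²) — no
group-size rescaling, and no internal column rescaling.  Block updates are
proximal steps with the exact largest eigenvalue of the 2×2 block Hessian
as curvature bound, with a step-damping safeguard on objective decrease.
A biomarker counts as a selected interaction when its group is active and
|γi| > 1e−8 (solver tolerance).  Events are assigned to the interval
containing the event time; a vanishing-rate floor protects the CVL
evaluation when a held-out event falls in an interval where the training
fold saw none.

## Gradient boosting

Componentwise L2 boosting on the partial-likelihood gradient: the
treatment effect is fitted first and fixed as an offset; candidates are
all main-effect and interaction columns (not the treatment); at each
iteration the least-squares fit to the current gradient is computed for
every candidate, the largest improvement (ties to the lowest column
index) is retained, and the winning coefficient moves by ν = 0.1 times the
fitted step.  The stopping iteration m* is chosen by fivefold CVL over
0..500; H is the set of biomarkers whose interaction column was updated at
least once within m*.

## Evaluation

* **Selection metrics.** TP/FP/pFP/FN against simulation truth;
  FDR = FP/(TP+FP) and FNR = FN/(TP+FN) with the 0/0 → 0 convention; a
  replication "rejects" when at least one interaction is selected (type-I
  error in null scenarios, power otherwise).
* **AUPRC.** Average precision (step-function integral, no linear
  interpolation) of each method's tuning-free biomarker ranking: lasso
  family — order of first entry along the regularization path, never-
  entered columns ranked by their weighted score statistic; univariate —
  raw p-value; boosting — iteration of first selection; group-lasso —
  group entry order along the λ grid.  The two-I model has no ranking.
  Under a random ranking with 10 actives among 500 the mean AUPRC is
  ≈ 0.031 (slightly above the 0.02 prevalence — average precision is
  upward-skewed at small active counts).
* **Uno's C and ΔC.** The biomarker-treatment score η̂j = Σ_{s∈H} γ̂s Xjs
  is evaluated per arm with the IPCW concordance: pairs (i, j) with
  ti < tj, ti < τ, eventi = 1 weighted 1/Ĝ(ti−)², Ĝ the same-sample
  Kaplan–Meier estimate of the censoring distribution; score ties count
  1/2.  τ is the 95th percentile of the arm's observed times (stabilizes
  the IPCW tail; a free choice documented here).  ΔC = C₊ − C₋, reported
  signed: positive when the score discriminates survival more in the
  experimental arm, the expected direction when interactions act there.
  An empty signature scores ΔC = 0 by convention.  Both training and
  validation ΔC are reported; the training value is optimistically biased
  for every data-driven selection.

## Problem sizes and reproduction scale

The replication engine defaults to 50 replications per scenario (the full
study used 250); `scripts/acceptance.py` uses 50 replications for the
univariate, grouped-weight adaptive lasso and full-lasso cells and 10 for
the group-lasso, two-I and boosting cells, and the test suite scales two
of the 50-replication checks to 30 so the default run stays comfortably
within a desk-scale budget.  Monte-Carlo standard errors are attached to
every summary cell.

## Known limitations

* The c-scenario censoring mechanism is a calibrated approximation (see
  above).
* The PLS variant is a score-statistic supervised component (weights
  proportional to each biomarker's univariate Cox score at the null
  model, unit-normalized, single component); other PLS-for-Cox variants
  exist and differ in detail.
* Clinical-covariate adjustment is supported only through the generic
  unpenalized-offset hook; competitive selection of clinical factors is
  out of scope, as are post-selection inference and contrast tests
  between arm-specific effects in the two-I model.
* Parallel replication execution (joblib) is replication-level and
  seed-stable, but the default is serial.
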