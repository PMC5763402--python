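# predmod

Selection of biomarker-by-treatment interactions (treatment-effect
modifiers) in high-dimensional survival data from randomized controlled
trials.

## The problem

A randomized trial measures an *average* treatment effect, but with
genomic covariates the question is increasingly *who* benefits.  A
biomarker that changes the treatment effect — a **treatment-effect
modifier**, or predictive biomarker — appears as a nonzero
biomarker-by-treatment interaction in the Cox model

```
h(t | T, X) = h0(t) · exp( α·T + Σᵢ βᵢ·Xᵢ + Σᵢ γᵢ·Xᵢ·T ),    T ∈ {−0.5, +0.5}
```

with `T = +0.5` the experimental arm, `Xᵢ` standardized biomarkers, `βᵢ`
prognostic main effects and `γᵢ` the interactions of interest.  With
`2p + 1 ≫ n` the model is not identifiable, so sparse selection of the
`γᵢ` is required.  `predmod` implements twelve selection strategies for
this problem, a seeded trial simulator to evaluate them, and an
interaction-strength metric for the resulting gene signatures:

| registry name | strategy |
|---|---|
| `full_lasso` | one lasso penalty on all `βᵢ, γᵢ` (α never penalized) |
| `alasso_sw` | adaptive lasso, weights `1/\|βᵢᴿ\|, 1/\|γᵢᴿ\|` from a preliminary ridge fit |
| `alasso_gw` | adaptive lasso, one grouped weight for mains and one for interactions |
| `alasso_aspw` | adaptive lasso, weights from ridge arm-specific prognostic effects |
| `ridge_lasso` | ridge on main effects (fixed as an offset), lasso on interactions |
| `group_lasso` | group penalty `λ Σᵢ √(βᵢ² + γᵢ²)` via a piecewise-exponential Poisson model |
| `modified_covariates` | lasso on `Mᵢ = Xᵢ·T` only, no main effects |
| `pca_lasso` / `pls_lasso` | main-effect space reduced to K components, lasso on interactions |
| `two_I` | lasso on arm-specific effects `γᵢ⁺, γᵢ⁻`; modifier iff exactly one is retained |
| `boosting` | componentwise L2 gradient boosting (ν = 0.1), treatment fixed as offset |
| `univariate` | per-biomarker interaction Wald tests with Benjamini–Hochberg control |

All tuning parameters (λ, λ₂, K, boosting iterations) are chosen by
fivefold cross-validated partial likelihood (the Verweij–van Houwelingen
criterion).

A selected signature `H = {s : γ̂ₛ ≠ 0}` is scored on new patients by the
biomarker-treatment score `η̂ⱼ = Σ_{s∈H} γ̂ₛ·Xⱼₛ` (lower = more predicted
benefit), and its **interaction strength** is the difference of arm-specific
IPCW concordances (Uno's C) between `η̂` and survival:
`ΔC = C₊ − C₋`, computed on both the training and an external validation
set to expose overfitting.

## Worked example

```python
import predmod as pm

spec = pm.make_scenario("4a", seed=7)          # one true modifier, p=500, n=500
train, valid = pm.simulate_pair(spec)
train_std, scaler = pm.standardize(train)
valid_std, _ = pm.standardize(valid, scaler=scaler)

sel = pm.run_method("univariate", train_std, seed=7)
m = pm.selection_metrics(sel, train.truth)
dc = pm.delta_c(sel, valid_std)
```

prints, for this seed:

```
true modifier : [12]
selected      : [10 11 12 13 14]
TP=1 FP=4 FDR=0.80 AUPRC=1.00
C+=0.651 C-=0.471 deltaC=0.180
full_lasso selected: [12] gamma_hat: {12: -0.319}
```

The univariate screen finds the true modifier (biomarker 12) but drags in
its four correlated block neighbours (within-block correlation decays as
0.7^|i−j|), while the full-lasso retains exactly the true modifier with a
shrunken coefficient.  The positive validation ΔC = 0.18 says the selected
signature separates survival in the experimental arm (C₊ = 0.65) but not in
the control arm (C₋ ≈ 0.5) — the signature is predictive, not merely
prognostic.

The same machinery runs from the shell:

```bash
predmod simulate --scenario 5a --seed 1 --out data/
predmod select --method alasso_sw --train data/5a_train.csv --out sel.json
predmod experiment --scenario 4a --method univariate --method full_lasso \
    --replications 50 --seed 1 --out results/
```

`predmod experiment` writes `replications.csv`, `summary.csv` (means with
Monte-Carlo standard errors for rejection probability, TP/FP counts, FDR,
FNR, AUPRC, training/validation ΔC) and the FDR–FNR and ΔC plots.

## Simulated study conditions

`make_scenario` reproduces the six scenario families used throughout:
complete null (1), treatment effect only (2, experimental-arm median 2.0
years), strongly prognostic biomarkers (3), one (4) or ten/twenty (5)
treatment-effect modifiers with experimental-arm hazard ratio 0.5, and
modifiers plus prognostic markers (6) — each with p = 500 (`a`), p = 1000
(`b`), or smaller random effects with heavy censoring (`c`).  Biomarkers
are unit-variance Gaussians with AR(0.7) correlation inside blocks of
25/50; event times are exponential (baseline median 1 year) with U(2, 5)
administrative censoring; arms are randomized exactly 1:1.  See
`docs/methods.md` for the full parameterization and its assumptions.

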