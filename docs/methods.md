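# Methods

## Model and estimands

The package targets natural-effect decomposition of a three-level exposure
(family history of T1D: affected mother, affected father or sibling, none)
on a rare binary outcome through a continuous mediator (CpG methylation on
the M-value scale), conditioning on the high-risk HLA-DR3/4 genotype.
Exposure is dummy-coded with "none" as reference, and each contrast is
decomposed with the other dummy held at 0, so "mother vs none" and
"father/sib vs none" are reported side by side.

With mediator model `M = β₀ + β₁·A + β₂·C + ε, ε ~ N(0, σ²)` and outcome
model `logit P(Y=1) = θ₀ + θ₁·A + θ₂·M + θ₃·A·M + θ₄·C`, the pure natural
indirect effect (PNIE) and total natural direct effect (TNDE) for a = 1 vs
a\* = 0 at covariate level c are, on the odds-ratio scale under the
rare-outcome approximation,

```
log PNIE = (θ₂ + θ₃·a*) · β₁ · (a − a*) = θ₂·β₁
log TNDE = [θ₁ + θ₃(β₀ + β₁·a + β₂·c + θ₂σ²)](a − a*) + ½θ₃²σ²(a² − a*²)
```

and multiply exactly to the total effect (an identity the test suite
asserts to 1e-9 on every fit).  Key structural facts used by the design:

* θ₀ appears in neither formula, so the case-control bias of the logistic
  intercept is irrelevant; the outcome model is therefore fit unweighted
  on the case-control sample (all non-intercept logistic coefficients are
  sampling-consistent under outcome-dependent sampling).
* The mediator model *is* weighted (cases π/q, controls (1−π)/(1−q)),
  because its coefficients are not case-control invariant whenever
  methylation differs by case status; a simulation test shows the weighted
  estimator tracks the source-population coefficient while the unweighted
  one is biased.
* σ² is the weighted residual variance with denominator Σw − p.  Its
  sampling variance enters the delta method via the normal-theory
  approximation Var(σ̂²) ≈ 2σ⁴/(Σw − p).

### Monte-Carlo counterfactual oracle

An independent check of the closed forms draws the mediator under each
exposure level (common random numbers) and averages outcome probabilities
to form P(Y(a\*, M(a\*))), P(Y(a\*, M(a))), P(Y(a, M(a))); then
PNIE = P(Y(a\*, M(a)))/P(Y(a\*, M(a\*))) and
TNDE = P(Y(a, M(a)))/P(Y(a\*, M(a))).  The oracle reports risk ratios by
default, or odds ratios (`scale="or"`), which removes the OR-vs-RR part of
the approximation error.  Measured agreement with the closed forms at
n_mc = 10⁶: within ~0.6% (RR) / 0.2% (OR) at 0.3% prevalence, ~2% (RR) /
1% (OR) around 1–2%, growing roughly linearly with risk to ~3–5% as the
exposed-group risk approaches 6–8%, and far beyond that at 30% prevalence
(the deliberate stress test).  "Rare" should therefore be read as a few
percent, not as a sharp 6% threshold, when interpreting odds-ratio output
for the more common exposure strata.

### Confidence intervals

Default is the multivariate delta method on the log-effect scale over the
block-diagonal covariance of (β̂, σ̂², θ̂) — mediator sandwich block,
scalar σ² block, model-based logistic block — which is deterministic and
collapses to the classic two-term product formula for log PNIE when
θ₃ = 0.  A stratified nonparametric bootstrap (resampling subjects within
case and control strata, refitting both models per replicate, percentile
intervals) is the cross-check; its refit kernels are plain WLS/Newton
solvers verified against statsmodels to machine precision.  Both methods
cover the true PNIE in 93–97% of 500 simulated 500/500 case-control
replicates in the calibration test.

## Longitudinal summarization

Per CpG, `m ~ age_c + platform + sex + (1 | subject)` is fit by REML, with
age mean-centered so the intercept (and hence the summary, fixed intercept
plus subject BLUP) is the subject's predicted mean methylation at the
reference platform (450K) and sex (female).  For the random-intercept
model the restricted likelihood is profiled down to the variance ratio
ρ = τ²/σ² and maximized by bounded scalar search with per-subject rank-one
updates, so a 50,000-subject population fits in well under a second; the
fit is verified against statsmodels MixedLM, which also powers the
optional random-age-slope variant (`random_slope=True`).  A fit whose
between-subject variance collapses to zero warns and falls back to
fixed-effect predictions; a zero-variance CpG is an error.

**A property worth knowing:** because the fixed effects deliberately
exclude the exposure (matching the published procedure), exposure-related
between-subject differences sit in the random intercepts and are shrunk by
λ = τ²/(τ² + σ²/k) for k visits.  The downstream mediator-model exposure
coefficient — and hence PNIE — is attenuated by the same factor, while the
outcome-model slope on the BLUP is not (the BLUP is the posterior mean of
the latent level).  With the default variance components (below) λ ≈ 0.96,
so the pipeline's PNIE estimand is ~1.97 when the latent-scale truth is
2.0.  Users applying the method to low-reliability probes (small λ) should
expect proportionally larger attenuation; this is inherent to the
two-stage design, not an implementation artifact.

## Synthetic cohort: what it emulates and the default conditions

Per subject: exposure from a categorical mixture, HLA Bernoulli per
exposure group, latent methylation mean β₀ + β₁·A + β₂·HLA + b,
b ~ N(0, τ²); per visit, M-value = latent + platform offset (EPIC) +
N(0, σ²_visit); outcome Bernoulli from the logistic model evaluated at the
latent mean, with θ₀ calibrated by bisection so the realized prevalence
hits the target; frequency-matched case-control subsampling allocates
controls across whole-year age bins in proportion to the sampled cases
(largest-remainder rounding).  Defaults and the reasoning behind them:

| Parameter | Default | Why |
| --- | --- | --- |
| incidence π | 0.06 | cohort T1D incidence used in the weights |
| exposure mix | 0.18 / 0.36 / 0.46 | control-arm family-history distribution (controls ≈ source population for a rare outcome) |
| β₁ₘ, β₁f | 0.46, 0.05 | maternal methylation shift of the strongest replicated probe; null-ish paternal shift |
| τ² | 0.5 | implied by the reported coefficient SE (~0.14) at the weighted case-control n |
| σ²_visit | 0.1 | longitudinal ICC ≈ 0.83; candidate probes were pre-filtered for reproducibility, so within-subject noise is small relative to between-subject spread |
| θ₂ | 1.5069 (≈ ln 2 / 0.46) | makes the true maternal PNIE 2.0 |
| θ₃ₘ | −2.2 | flips the methylation-risk slope to negative in the affected-mother group, the qualitative interaction pattern under study |
| θ₁ₘ, θ₁f | 1.96, 1.21 | give true maternal TNDE ≈ 1.65 and father/sib TNDE ≈ 3.35 |
| visits | 0.75, 1.25, 2, 4, 7 y | early-childhood clinic schedule, up to five measurements |
| platform offset | 0.2 | additive EPIC-vs-450K shift, removed by the fixed effect |
| HLA prob. | 0.3 / 0.3 / 0.2 | modest enrichment in exposed groups |

Because the outcome is generated from the latent mean, the residual
variance the mediator model sees is τ², and that is the σ² entering the
closed-form truth (`true_effects`).  Expression, when simulated, is linear
in a fresh single-visit M-value with age and sex effects and Gaussian
noise — adequate for testing the eQTM estimator, but real RNA-seq
count-derived values are heavier-tailed and batch-structured.

What the generator does **not** emulate: probe-level array artifacts,
cell-composition shifts, age trends in methylation, autoantibody
trajectories, attrition, or correlated multi-CpG regional structure
(additional CpGs are independent nulls).  Passing recovery tests therefore
demonstrate estimator correctness under the stated model, not robustness
to those real-data features.

## eQTM conventions

TSS = gene start on +, gene end on − strand; the ±1 Mb window is closed at
the boundary; regional predictors use the DMR midpoint (floor).  The DMR
summary is the first principal component of column-standardized M-values,
sign-anchored to correlate non-negatively with mean methylation so results
are reproducible across runs and subject subsets.  Fold change per SD is
2^slope from OLS of log2 expression on methylation standardized across all
included subjects (sample SD), adjusting age and sex; values below 1
encode negative association.  Nominal p < 0.05, no multiplicity
adjustment, mirroring the targeted candidate-region design; a null
calibration test confirms uniform p-values at n = 55.

## Descriptive statistics

The case/control characteristics table uses the uncorrected Pearson
chi-square (this reproduces all four published descriptive p-values from
the printed counts: 0.023, 6.2E-5, 0.171, 0.816); Fisher's exact test is
available by flag for 2×2 blocks.  Diagnosis age is summarized for cases
only, with no test.  P-values display with 3 decimals above 0.001 and in
scientific notation below.

## Numerical and significance conventions

* REML search over log ρ ∈ [−14, 14], tolerance 1e-10; ρ below 1e-6 is
  treated as a singular (zero-variance) fit.
* Logistic fits: statsmodels Newton, 100-iteration cap; perfect separation
  and non-convergence are hard errors, as are rank-deficient designs
  (aliased columns are named).
* Interaction screening at p < 0.1, main effects at p < 0.05, no
  multiple-testing correction — the analysis is a targeted follow-up of a
  small candidate set.
* Report tables round ORs and CIs to 2 decimals; E-values are computed
  from unrounded estimates.
* Bisection for θ₀ over [−60, 60], 100-iteration cap.
* Seeds: every stochastic operation takes an explicit integer seed;
  identical configuration + seed reproduces byte-identical outputs.

## Problem sizes used by the test suite

Parameter-recovery tests run the full pipeline on populations of 50,000
subjects (averaging three populations for the headline PNIE recovery
check); interval calibration uses 500 replicates of 500/500 case-control
samples with a 200-resample bootstrap arm; the oracle uses 10⁶ draws;
eQTM null calibration uses 1,000 genes at n = 55.  These sizes keep every
Monte-Carlo standard error well inside the asserted tolerance.

## Known limitations

* Single mediator per decomposition; no multiple-mediator or four-way
  decomposition, and no exposure-induced mediator-outcome confounders.
* Odds-ratio effect measures rely on the rare-outcome approximation; see
  the oracle error profile above.
* The BLUP-shrinkage attenuation described under summarization.
* Delta-method intervals treat the mediator and outcome fits as
  independent blocks; the two models share subjects, and the ignored
  cross-covariance is second-order but not exactly zero.
* E-values inherit the OR ≈ RR approximation and address only unmeasured
  mediator-outcome confounding.
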