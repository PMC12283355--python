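# Methods

`trialgen` implements a genetics-augmented target-trial-emulation workflow
on synthetic biobank cohorts. This note records the models, the defaults and
the design choices that were genuinely open, in enough detail to reproduce
or criticize any number the package produces.

## Why synthetic cohorts

Registry-linked biobank data of the kind these methods are designed for are
access-restricted. Every stage of the package therefore runs against a
synthetic cohort whose generative process is fully known, which turns each
downstream method into a testable estimator: the true treatment hazard
ratio, the confounding structure and each PGS–trait r² are configuration
inputs, so recovery, calibration and diagnostic-trajectory claims can be
checked against ground truth rather than against published estimates.

## The cohort generator

One row per individual, with all dates as integer days from an epoch and a
hard administrative censoring day (`registry_end`, default 3,650).

- **PGS panel.** 20 cardiometabolic trait scores, each drawn standard normal
  and then standardized exactly (mean 0, sd 1, ddof 0) over the full cohort.
- **Latent traits.** `C_k = √(r²_k)·PGS_k + √(1−r²_k)·ε`, so the squared
  PGS–trait correlation is `r²_k` by construction. Defaults cycle through
  {0.01, 0.05, 0.1, 0.2, 0.3, 0.5} — the realistic range for polygenic
  predictors of complex traits; per-trait values are configurable.
- **Treatment assignment.** Two logistic stages over the latent traits:
  initiation of any study drug (intercept −1.5, ≈18% initiators at null log
  odds), then choice of target drug versus active comparator (intercept 0).
  Nonzero log-odds coefficients create confounding by indication: the same
  traits that drive prescribing can also enter the outcome hazard.
- **Events.** Exponential event times with hazard
  `baseline_hazard · exp(Σ_k b_k·C_k)` from day 0, multiplied by
  `exp(true_treatment_log_hr)` from the initiation day onward for
  target-drug users. The switch is implemented piecewise via the memoryless
  property, so the post-initiation hazard is exact, and a correctly
  specified Cox model is the true model. Death is an independent exponential
  (default 0.005/year); events and deaths beyond `registry_end` are
  censored.
- **Diagnosis flags.** A trait's flag fires when `C_k` exceeds its cohort
  quantile (default 0.75). For initiators the onset day is drawn before
  initiation — the indication is on record when the prescribing decision is
  made, which is the premise of confounding by indication and what makes
  eligibility look-back windows meaningful; for noninitiators onset is
  uniform over the registry period.
- **Purchases.** One package per `package_days` (default 90) from
  initiation, stopping at the event, death, registry end, or by a
  per-refill discontinuation probability (default 0.08). Every initiator
  has at least one purchase.
- **Genotypes** (used to exercise PGS scoring and LD clumping, not cohort
  construction): biallelic dosages from thresholded Gaussians in
  block-exchangeable LD blocks. The latent Gaussian correlation is
  calibrated by inverting the tetrachoric transform so the *dosage*
  correlation, not the latent one, hits the requested within-block value.
  Mafs are drawn per block.
- **Summary statistics.** Per-variant exposure effects are inputs; outcome
  effects are `β_Y = θ·β_X + α + noise` with pleiotropic intercepts
  `α ~ N(0, pleiotropy_sd²)`. Standard errors follow
  `1/√(2·n·eaf·(1−eaf))` (standardized-phenotype GWAS scaling) and
  p-values the normal approximation, so `p` is always consistent with
  `β/se`.

What the generator does *not* emulate: age structure and calendar drift,
ICD-coded outcome misclassification, time-varying adherence or dosing,
family relatedness, and genuine genome-wide genetic architecture (PGS are
latent scores unless built from the dosage module). Passing tests therefore
demonstrate correctness of the estimators under the stated model, not
robustness to these real-data complications.

## Emulation

Eligibility rules are predicates on flag onsets relative to the individual
initiation day, applied in protocol order with a per-rule attrition log.
The plain observational stage reflects the original trial design: for
placebo-controlled designs, target initiators versus everyone who did not
initiate the target drug; for active-comparator designs, target versus
comparator initiators. Reading the placebo-design control side as
"non-initiators of the target drug" makes the three stages strictly nested
by individual id, which the code asserts after every run.

The propensity score is a main-effects logistic regression (statsmodels) of
arm on the protocol covariates evaluated at initiation. Covariates that are
constant in the eligible cohort — typically flags that eligibility itself
required — are dropped with a warning; complete separation and residual
collinearity raise errors naming the covariates. Matching is greedy 1:1
nearest-neighbor without replacement within a caliper (default 0.1; when
the arm-wise PS histograms overlap by more than 0.98, the tighter 0.01 is
chosen), treated individuals processed in a seeded random permutation and
distance ties broken by lowest comparator id.

On-treatment follow-up runs from first purchase to the earliest of event,
death, switch (first purchase of the opposing drug), supply exhaustion, or
registry end. Supply exhaustion is first purchase day + total packages ×
days-per-package; there is no grace period. Individuals without purchases
or with nonpositive follow-up (event on/before first purchase) are excluded
with a logged warning.

Cox fits use lifelines' partial likelihood with Efron tie handling; the CI
is Wald, `exp(log HR ± 1.96·se)`. Constant adjustment covariates are
dropped (a constant term of interest is an error). Estimate agreement is
the closed-interval test: emulated HR inside the reference RCT CI.

## Balance diagnostics

SMD is the pooled-sd standardized mean difference with the standard
large-sample variance `(n₁+n₀)/(n₁n₀) + d²/(2(n₁+n₀))`; p-values come from
a two-sided Welch t-test and significance is called at alpha divided by the
number of scores (0.05/20 = 2.5×10⁻³ for the default panel). The stage
trajectory reports mean |SMD| per stage and a strict-decrease flag. On a
confounded synthetic cohort the trajectory decreases because each stage
removes part of the indication signal that the PGS partially proxy; on an
exchangeable cohort the Bonferroni call keeps the family-wise error at or
below alpha (its exact level with 20 independent tests is
1−(1−0.0025)²⁰ ≈ 0.049, so empirical estimates hover just under 0.05).

## Proxy-confounding simulations

Model 1: `PGS~N(0,1)`, `C = r·PGS + √(1−r²)ε_C`,
`X = b_CX·C + √(1−b_CX²)ε_X`, `Y = X + b_CY·C`. Model 2 replaces the direct
PGS→C arrow with a shared cause G\* plus a PGS-only component G′ that may
also hit X and Y (`b_G*C = r/b_G*PGS`; the X-equation noise term is an
independent ε_X — reusing ε_C there would break the unit-variance
calibration). All variables are unit variance by construction and the true
X→Y effect is 1; the estimand is the X coefficient in OLS of Y on (X, PGS),
reported as percent bias `100·(β̂_X − 1)` (since the true effect is 1,
percent and absolute bias coincide).

Because everything is jointly Gaussian, the expected OLS coefficients are a
deterministic function of the 3×3 covariance of (X, PGS, Y); the package
ships that closed form for both models as the oracle, and the Monte-Carlo
grid (defaults mirror r² ∈ {0.01,…,0.5} × confounding fraction
∈ {0.1, 0.2, 0.3, 0.5}, 100 iterations of n = 100,000) must agree with it
within Monte-Carlo error. Confounding strength is parameterized by variance
fractions: `b_CX = √f` and `b_CY` solves the quadratic
`(1−f)b²_CY − 2f·b_CX·b_CY − f = 0` so that `Var(b_CY·C)/Var(Y) = f` too.
Key consequences, all reproduced by the oracle: bias is zero iff either
confounder arrow is zero, decreasing in r², equal to the fully unadjusted
bias `100·b_CX·b_CY` at r = 0, and strictly positive even at r² = 0.5 —
i.e. adjusting for a realistic PGS proxy cannot remove confounding.

The acceptance test runs the grid at 10 iterations × n = 100,000 (a 10×
reduction of the full budget; the 3-standard-error agreement margin scales
accordingly).

## MR confounder detection

Harmonization joins exposure and outcome tables on variant id, flipping the
outcome beta when the allele pair is swapped and dropping (with a log)
pairs that cannot be reconciled. Instrument selection is threshold
(p < 5×10⁻⁸) → greedy clumping (keep smallest exposure p; drop variants
within 10,000 kb on the same chromosome with LD r² ≥ 0.001; p-ties broken
by position then id) → exclusion of outcome-associated variants
(p < 5×10⁻⁸), in that order. LD is supplied as a block structure matching
the genotype generator; cross-chromosome pairs never clump.

The fixed-effect IVW estimate is
`β = Σ β_Xj β_Yj/se²_Yj / Σ β²_Xj/se²_Yj` with `se = (Σ β²_Xj/se²_Yj)^−½`;
a multiplicative random-effects flag inflates the se by `max(1, √(Q/(J−1)))`.
One instrument degenerates to the Wald ratio with first-order delta se,
flagged. Note the fixed-effect se ignores exposure-side sampling error: with
exposure and outcome samples of equal size the true sampling sd is inflated
by `√(1+θ²)` and nominal 95% coverage drops to ≈93%. CI calibration is
therefore validated in the estimator's intended regime — a large exposure
GWAS (n = 10⁶) against a smaller outcome sample — where coverage is ≈94.5%;
the attenuation of |β̂| as instruments weaken (regression dilution) is
tested separately as a monotone property.

A trait is a putative confounder when both MRs (on treatment, on outcome)
are significant (strict `p < alpha`; both the nominal 5×10⁻² and a
Bonferroni threshold are reported). The mediation check subtracts the
outcome-mediated path: `direct_CX = total_CX − β_CY·β_YX` with delta-method
se under independence of the three inputs; the Y→X (outcome-influences-
prescribing) estimate is user-supplied or comes from a second MR.

## Enrichment

Prognostic association is the PGS term of
`h(t|T,PGS) = h₀(t)·exp(β₁T + β₂PGS)` on on-treatment records; the
population analogue follows the whole cohort from day 0 (age timescale,
no left truncation by default — a flag exists). Sample-size arithmetic uses
the equal-expected-events criterion
`n_required = n_original · rate_all / rate_top-q` (the top-q cut uses the
full-population PGS distribution, default q = 0.25); a Schoenfeld log-rank
alternative is available behind a flag and yields the same *relative*
reduction. Predictive enrichment is the Wald p of the T×PGS product term.
Because eligibility can restrict to high-liability individuals where the
liability→hazard map saturates, the trial-cohort HR can attenuate relative
to the population HR; the test suite reproduces this mechanism.

## Numerical and reproducibility choices

All randomness flows from one seed through keyed `SeedSequence` streams
(`child_rng(seed, *path)`), so every stage and every Monte-Carlo iteration
has an independent, reproducible stream and pipeline manifests are
identical across reruns modulo timestamps. Standardization uses population
sd and rejects zero variance explicitly. OLS in the bias estimator solves
the normal equations and rejects condition numbers above 10¹². Matching
order, clump tie-breaks and flag quantiles are all deterministic given the
seed. Test problem sizes (cohorts of 4,000–40,000; 10-iteration proxy
grids; 100-replicate recovery suites; 1,000-replicate calibration suites)
were chosen as the smallest sizes at which the checked quantities are
well-resolved relative to their Monte-Carlo noise.

## Known limitations

- The spec-level wording "discontinuation = last purchase date + total
  packages × package size" double-counts consumed supply when purchases are
  spaced; the implementation uses supply exhaustion from first purchase,
  which matches the worked examples and the registry semantics.
- No intention-to-treat weighting, censoring weights, or imputation; the
  on-treatment analysis is the only estimator.
- Binary-trait MR results are reported on the presence-versus-absence
  scale without per-sd rescaling.
- The caliper auto-rule (0.01 when PS-density overlap > 0.98) is a
  heuristic; the quantitative rule behind "0.1 or 0.01 depending on the
  initial overlap" is not established practice, so the caliper is always
  configurable.
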