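# Methods

This note documents the statistical models, the synthetic-data
generator, the numerical choices, and the known limitations of
`lipidprs`.

## Mixed-model engine

All longitudinal fits use a random-intercept linear mixed model: for the
stacked visit vector, `V = s2_u Z Z' + s2_e I` is block diagonal by
subject, each block `s2_e (I + g J)` with `g = s2_u / s2_e`.  Fixed
effects are generalized least squares at the variance optimum,
`B̃ = (X'V⁻¹X)⁻¹ X'V⁻¹Y`.  Fitting profiles the likelihood down to a
bounded 1-D optimization over `log g` (Brent, window `e⁻²³…e¹⁶`,
tolerance 1e-8), using the rank-one Woodbury identity per block —
`(I + gJ)⁻¹ = I − g/(1+gk) J`, `log|I+gJ| = log(1+gk)` — so cost is
linear in the number of observations and no K×K matrix is ever built
outside the test oracles.  ML and REML are both available; AIC uses ML
log-likelihoods (`AIC = 2(p+2) − 2·loglik`, counting the two variance
components) so that models differing only in fixed terms are
comparable.  When the profiled likelihood at `g = 0` is within 1e-7 of
the optimum the fit is flagged as a boundary (zero subject variance)
solution and collapses to OLS, which also covers the
one-observation-per-subject degenerate case.  Coefficient tests are
Wald z-tests (`p = 2Φ(−|est/se|)`): deterministic, cheap inside
cross-validation, and adequate at the sample sizes involved.

Predictions for unseen subjects are fixed-effects-only: a never-observed
subject's random intercept has expectation zero.

## Age transform

`f(age) = sin((π/2)(2·age − a_max − a_min)/(a_max − a_min))` maps the
observed age span onto [−1, 1], capturing the sigmoidal lifetime trend
of lipid levels within a linear model.  The anchors `(a_min, a_max)` are
always estimated from the training split inside cross-validation, never
from the full data; test ages outside the training span are clamped to
the boundary with a warning.  `compare_age_models` fits the non-genetic
model with a linear age term and with `f(age)` (equal model dimension)
and reports both ML AICs.

## Risk scores

**NCBI.**  Entries for the target trait are deduplicated to the
largest-study estimate per marker (ties keep the first occurrence, with
a warning), then `score_i = Σ_j dosage_ij w_j`.  Weights are accepted in
mg/dL only; the catalog reader rejects any other declared unit rather
than attempting conversion, because published lipid estimates mix mg/dL,
mmol/L and variance-standardized scales and silent conversion is the
main corruption risk for this kind of catalog.

**BHS.**  The single-marker model is
`Y₋ᵢ = x₋ᵢ,ⱼ β₋ᵢ,ⱼ + W₋ᵢ θ + Z₋ᵢ V + e₋ᵢ` with the same covariates as
the non-genetic model.  Exact mode refits this by REML for every
(subject, marker) pair.  Fast mode (default) estimates the variance
ratio once per fold from the training-only covariate model — a single
marker moves the variance components negligibly — and then solves every
marker's GLS coefficient at that ratio in one batched
Frisch–Waugh–Lovell pass over subject-level sufficient statistics
(dosages are constant within subject).  Fast mode deliberately does
*not* reuse full-data variance components: that would let the held-out
subject's phenotypes influence their own predictions.  Exact and fast
agree to well under 10% relative error on test cohorts.  Markers
monomorphic in a training split contribute a zero effect, with a
warning.

In cross-validation folds, *every* subject in fold −i (training rows and
the held-out subject) is scored with the fold's weights `β̂₋ᵢ`.  Scoring
training subjects with their own personal weights `β̂₋ⱼ` instead would
leak subject *i*'s phenotypes into the training covariates, since
`β̂₋ⱼ` is estimated on data that includes subject *i*.  The published
per-subject score `Φᵢ = Σⱼ xᵢⱼ β̂₋ᵢ,ⱼ` is still what `bhs_score` and the
full-cohort significance test report.

## Bayesian whole-genome regression

The Gibbs sampler (numba kernel) updates, per sweep: fixed effects
jointly (flat prior, Cholesky solve), marker effects one at a time via
per-subject residual sums (O(n·m) instead of O(K·m) per sweep), the
lasso scale hierarchy (`1/τ²ⱼ` inverse-Gaussian, `λ²` Gamma), or the
ridge common marker variance (scaled-inverse-χ²), subject intercepts,
and the residual and subject variances (scaled-inverse-χ²; in the lasso
the marker effects contribute `Σβ²ⱼ/τ²ⱼ` and m degrees of freedom to the
residual-variance update, since the lasso ties the marker prior scale to
`varE` as in the standard scale-mixture formulation).

Prior elicitation (`default_priors`) uses the training phenotypic
variance `V(y)`, an assumed heritability `h² = 0.5`, and
`MSx = Σⱼ meanᵢ(x²ᵢⱼ)`: every variance prior mean `S/(df−2)` then equals
its natural variance-partition target (`(1−h²)V(y)` for varE, `h²V(y)`
for varU, `h²V(y)/MSx` for the ridge marker variance), and the lasso
rate `λ² = 2(1−h²)MSx/h²` is the value at which the expected penalized
genetic variance matches `h²V(y)`; `λ²` carries a Gamma(2, rate) prior
with its mode at that value, a deliberately flat choice.  Degrees of
freedom are fixed at 5 so all variance priors have finite mean and
variance and little influence on inference.

Validation hooks (`fix_varE`, `fix_varU`, `fix_lambda2`, `fix_varB`,
`include_random=False`) freeze parts of the model so the sampler can be
checked against conjugate closed forms and 1-D quadrature; these are
used by the test suite and are not part of the analysis path.

Standalone fits default to 20 000 iterations, 5 000 burn-in, thinning 5.
Inside cross-validation the package uses 600 iterations with 200
burn-in: a posterior *mean* under ≤ a few hundred markers stabilizes
within a few hundred sweeps of this conjugate-update sampler, and the
CV loop performs one fit per subject per model family.  Chains of all
scalar parameters (and all marker effects) are retained thinned;
effective sample sizes and Monte-Carlo standard errors come from arviz,
and a Geweke-style early/late drift statistic is provided.

## Cross-validation and accuracy

`loso_cv` removes each subject's visits en bloc, refits the model
builder on the remainder, and predicts the subject from fixed effects
only.  R² is the squared Pearson correlation over all pooled held-out
predictions; it is undefined (an error, reported as degenerate) for
constant inputs.  Confidence intervals are subject-level percentile
bootstrap (default 1 000 resamples): observations within a subject are
dependent, so subjects are resampled with replacement and their visit
blocks pooled.  The ΔR² significance reported for the scalar-score
models is the Wald p of the score coefficient in the full-cohort mixed
model — a test on the coefficient, not on the R² difference itself; the
Bayesian families have no scalar score and get no p-value.

Fold seeds for the stochastic (MCMC) builders derive from the base seed
and the fold index only, never from data, so reruns are bit-identical
and mutating a held-out subject's phenotypes cannot alter their own
predictions through the random stream.  Per-fold genotype imputation
uses training-side marker means via an exclusion of the held-out
subject's rows.

**Age windows.**  For a target age (10/20/30/40), each subject
contributes the single observation closest to the target within ±2.5
years.  With one observation per subject the random intercept is
unidentifiable, so the models are ordinary linear regressions; ΔR² is
the difference in leave-one-out CV R² with and without the score, and
the p-value is the full-data Wald test of the score term.  The optional
"previous measurement" covariate is the subject's most recent
measurement strictly before the selected visit, at any age (a literal
reading — the previous visit need not fall in the window); subjects
with no earlier measurement are dropped with a logged count, and
windows with fewer than 30 subjects raise an error.

## Synthetic cohort generator

The generator emulates the longitudinal structure of the study cohort:
523 subjects by default, visit counts `4 + Binomial(9, 0.411)` (mean
7.7), first visits uniform on ages 4–17, inter-visit gaps Gamma with
mean 3.0 and SD 3.5 years redrawn to fit under age 48, sex ~
Bernoulli(0.455), and a BMI trajectory linear in age with subject-level
random intercept and slope.  These calibration constants were chosen
analytically from the published cohort summary statistics before any
testing; a discrete-uniform visit count was rejected at design time
because its mean (8.5) and SD (2.7) are both inconsistent with the
reported 7.7 (1.9).

Phenotypes follow
`y = μ + a·f(age) + s·sex + b·bmi + Σⱼ xᵢⱼβⱼ + uᵢ + εᵢₜ` with
independent binomial dosages (MAF uniform on a configured range — no
linkage disequilibrium), causal effects
`βⱼ = ±c/√(2·MAFⱼ(1−MAFⱼ))` (equal expected variance per causal marker)
scaled so the genetic fraction of the non-covariate variance hits
`heritability_target` (default 0.5, the conventional lipid
heritability), and defaults `μ=85`, `a=15`, `s=−5`, `b=1` mg/dL,
`subject_sd = residual_sd = 18` mg/dL, chosen so the total phenotypic
SD (~36 mg/dL) matches a realistic LDL-C distribution.  The emitted
catalog gives causal markers their true β plus Gaussian estimation
noise (default SD 1 mg/dL) and the cohort's trait label — the **R**
set — while null markers carry the other trait labels, so the full
catalog is the **A** set.

What the generator does *not* emulate: linkage disequilibrium between
markers, gene–gene and gene–environment interactions, cross-trait
correlation (one trait per run), ancestry structure, relatedness, and
genotyping/imputation artefacts.  Passing tests therefore demonstrate
correctness of the estimators and the leakage-free evaluation design
under the assumed generative model, not real-data effect sizes: with
h² = 0.5 and perfectly tagged causal markers, synthetic ΔR² values are
an order of magnitude larger than anything observable with published
GWAS weights on a real cohort.

A separate deterministic stand-in catalog
(`published_catalog_standin`) reproduces the *composition* of the
published marker extract — 207 distinct markers, 244 marker–trait
associations (77 HDL, 62 LDL, 65 TC, 40 TG) — with synthetic
identifiers and weights, for exercising the catalog-handling path.

## Problem sizes

The test suite and the acceptance script run the full roster at 200
subjects and 60 markers (30 causal, 30 null) with 20 replicates for the
directional comparisons, the sampler-recovery checks at 300 subjects and
30 markers with 10 000 iterations, and variance-component recovery at
500 subjects — sizes at which every qualitative property of the method
is stable across seeds while a complete run stays comfortably
interactive on one CPU.

## Known limitations

* Fast-mode BHS weights share one variance ratio per fold across
  markers; exact per-(subject, marker) REML is available but quadratic
  in cohort×marker count.
* The Wald normal approximation is used throughout; no small-sample
  (Satterthwaite/Kenward–Roger) correction.
* The sequential "clinic-updating" variant in which only a subject's
  later observations are excluded is not implemented; exclusion is
  always of the whole subject.
* VCF input supports biallelic markers with GT or DS fields only;
  multiallelic sites are skipped with a warning.
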