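# Methods

This note documents the statistical procedures implemented in `glycocc`,
the choices made where the design was genuinely open, and what the
synthetic-data benchmarks do and do not demonstrate.

## Data model

A cohort table holds one row per sample: identifier, cohort, plate, age
(years), sex (normalized to F/M; dummy-coded F = 0 in regressions),
case/control status, optional clinical flags (ANA positivity,
pericarditis, proteinuria; absent values are recorded as missing, never as
zero), disease duration in years, and 24 raw peak areas GP1–GP24.

The panel annotation assigns each peak an Oxford-notation structure and
the features that drive trait algebra: galactose count (0–2), sialic-acid
count (0–2), core fucose, bisecting GlcNAc, oligomannose.  Twenty-one
peaks have standard structure assignments; **GP3, GP13 and GP20 are
convention defaults** (A2B, A2BG2, FA2BG1S1) inherited from the
measurement method's panel definition and can be overridden by loading a
custom annotation table.  The oligomannose peak M5 (GP5) counts as
agalactosylated, so agalactosylation traits span GP1–GP6; a library switch
(`default_trait_library(include_oligomannose_in_g0=False)`) excludes it.

## Preprocessing

1. *Total-area normalization*: each peak area divided by the sample's
   total, ×100.  Scale-invariant per sample; zero totals are errors.
2. *Log transform*: natural log.  Zeros indicate failed upstream peak
   integration, so the default policy is a hard error; an opt-in
   pseudo-count policy substitutes a configurable ε (default 10⁻³) and
   reports the substitution count.
3. *Batch correction*: parametric empirical-Bayes location/scale
   adjustment with the plate as batch and no biological covariates in the
   batch model.  Per feature g: weighted grand mean α̂_g and pooled
   variance σ̂²_g define standardized data Z; per batch i, location γ̂_ig
   and scale δ̂²_ig (unbiased within-batch variance) are shrunk toward
   method-of-moments hyperpriors (γ̄_i, τ̄²_i; inverse-gamma a_i, b_i) by
   the standard iterative posterior equations (relative-change tolerance
   10⁻¹⁰, ≤ 500 iterations); adjusted data are
   (Z − γ*)/√δ²* · σ̂ + α̂.  A `mean_only` mode subtracts only γ*, for the
   literal reading of "batch effects were subtracted"; the default removes
   location and scale.  As a final step each feature is re-centred so its
   grand mean is exactly preserved (`preserve_grand_mean=True`); the
   standard adjustment preserves it only approximately, and exact
   preservation makes downstream summaries independent of the batch
   layout.  Single-batch input is returned unchanged; batches of size 1
   and zero-variance features are errors.
4. *Back-transform*: elementwise exponential to proportions.  Row
   renormalization to 100 is available but off by default (the derived
   traits are ratios, so it is immaterial to them).

## Association

- *Inverse-normal transform (INT)*: value = Φ⁻¹((r − ½)/n) with average
  ranks for ties (Blom offset (r − 3/8)/(n + ¼) available).  Constant
  vectors are rejected.
- *Case-control model*: logistic regression of status on one INT variable
  plus age and sex, fitted by Newton/IRLS (convergence: max |score| <
  10⁻⁸ or deviance change < 10⁻¹⁰, ≤ 50 iterations, step-halving line
  search).  Wald SEs come from the observed information; ORs are per 1 SD.
  Coefficients diverging past |β| > 15 raise a separation error.  The
  solver is cross-checked against an independent maximum-likelihood
  implementation in the test suite.
- *Intracase models*: OLS of the INT glycan on a clinical trait plus age
  and sex, cases only; binary-trait coefficients are between-class
  differences in SDs.  Disease duration is dichotomized at > 8 years
  (parameterized).
- *Symptom burden*: the per-case count of {ANA, pericarditis, proteinuria,
  duration > 8 y} (missing flags counted as absent by default, or samples
  missing all four excluded); a linear trend of the INT trait on the count
  (0–4), adjusted for age and sex, with per-group quartile summaries for
  plotting.  A linear trend is an assumption; no ordinal alternative is
  fitted.
- *Meta-analysis*: fixed-effect inverse-variance weighting; Cochran's Q
  is always reported but not tested by default (a random-effects option is
  out of scope; heterogeneity across cohorts is visible through Q).
- *Multiplicity*: Benjamini–Hochberg step-up within each analysis family —
  all variables × one contrast (the case-control meta family, each
  intracase contrast family, the trend family).  Per-cohort tables are
  additionally adjusted within cohort.

## Classification

The penalized objective is `(1/n)·NLL + λ[(1−α)/2‖β‖² + α‖β‖₁]` over
non-intercept coefficients with predictors standardized internally, making
λ portable across implementations; λ = 0.1, α = 0 (pure ridge) is the
default configuration.  α = 0 is solved by the in-package Newton
iteration (the same IRLS core as the association model, with the penalty
in score and information); α > 0 delegates to a coordinate (saga) solver.
Age and sex are penalized along with the glycans in the full model (an
unpenalized-covariates flag exists via the `penalize` mask).

Evaluation is always by merged out-of-fold prediction: seeded stratified
k-fold (default 10), standardization statistics computed on training folds
only, one ROC/AUC over the concatenated held-out predictions per model
(base = age + sex; full = age + sex + 24 peaks).  AUC is the Mann–Whitney
statistic with ties counted ½.  Hyperparameter tuning is a seeded grid
search by internal cross-validated AUC with ties broken toward more
regularization.  The paired bootstrap AUC test resamples within classes
(B = 2000 default) and reports the two-sided sign-agreement p-value.
PCA of GP6/GP9/GP10/GP14 standardizes columns and fixes component signs by
making each loading vector's largest-magnitude entry positive.  The
severity classifier reuses the same machinery with the binary target
"≥ 2 of 4 complications" within pooled cases.

## Synthetic-data generator

Latent per-sample log-abundances are Gaussian with exchangeable
correlation (ρ = 0.10, per-peak log-SD 0.25) around a baseline reflecting
a typical adult IgG glycome; age slopes, sex effects, per-plate
location shifts (SD 0.15 log units) and scale multipliers (log-SD 0.08)
and, for cases, a planted disease shift and a latent severity loading are
added before softmax closure to percent-of-total and multiplication by a
random chromatogram total.  Status is drawn first (matched design: age and
sex distributions are shared between arms), so each peak's marginal
single-glycan logistic model is exactly linear.

**Effect calibration.**  The generator's contract is that a planted value
is the log-OR per 1 SD that the pipeline estimates.  Because the pipeline
measures log *percentages* y_g = x_g − log Σ exp(x), the latent shift d_g
is solved by fixed point so that (d_g − κ)·sd_marg(y_g)/var(y_g) equals
the target, where κ is the first-order common closure shift (null peaks
receive exactly κ, so their measured effect is zero), var(y_g) is the
linearized closure-scale within-class variance, and sd_marg adds the
case/control mixture and age/sex variance components.  Residual bias from
the neglected higher-order terms is ≲ 0.02 at |β| = 0.7 in the recovery
benchmark.

Clinical flags are thresholded mixtures of the latent severity and noise
(target prevalences ≈ 0.70 ANA, 0.25 pericarditis, 0.35 proteinuria);
disease duration is log-normal with severity loading 0.3.  The default
severity-to-glycan loadings (±0.08 log units on nine peaks) were chosen so
the symptom-burden classifier operates near the reported AUC ≈ 0.68 for
this design; the default disease pattern mirrors the published direction
of findings (agalactosylated/bisected analogues up in cases,
digalactosylated/sialylated down) and is illustrative, never a
replication.

**What the generator does not emulate**: chromatographic co-elution and
integration error, instrument drift within plates, non-Gaussian latent
structure, realistic inter-peak covariance (unpublished), ancestry
structure, or treatment effects.  Passing recovery tests therefore shows
the pipeline is calibrated for logistic-normal compositional data with
plate effects — not that real-cohort effect sizes would be reproduced.

## Benchmarks and problem sizes

The repeated-simulation benchmarks use: recovery — 3 cohorts × 500
samples, planted log-ORs {0, ±0.3, ±0.7} in ±-pairs on
comparable-abundance peaks, 200 replicates (tests) / 100 (script); null
FDR — one cohort of 500, 24 peaks + 16 summary traits, 200/100
replicates; batch confounding — one cohort of 200 on two plates with
status-coupled plating (location-shift SD 0.30), 200/100 replicates.
Under confounded plating the corrected type-I error is conservative
(well below nominal) because the batch means absorb part of the
case/control contrast; the benchmark claims control, not exactness.

## Known limitations

- The trait library ships the summary traits and per-peak neutral shares
  used in the analyses it supports (32 definitions); the full historical
  catalogue of 57 derived traits can be reproduced by extending the
  trait-library TSV with the same predicate grammar.
- Some published trait descriptions are internally inconsistent about
  bisecting GlcNAc ("without" vs the FB symbol); the library follows the
  symbol (FB = fucosylated AND bisected).
- Fab- vs Fc-glycan deconvolution is impossible at the peak level and is
  out of scope, as are random-intercept family models and conditional
  logistic matching.
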