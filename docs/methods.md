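# Methods

## Scope and design

`placmed` models a two-group (full-term low birth weight vs normal weight)
mother–baby study in which placental CpG methylation is the exposure,
placental surface area the mediator, and FT-LBW the binary outcome. The
package has five layers — synthetic cohort/assay generation, β-value QC,
association models, mediation, and pipeline orchestration — each usable on
its own. The central fit-shaped methods are additionally exposed as
scikit-learn-style estimators (`NaturalEffectsMediator`,
`CorrelationBlockGrouper`, `Standardizer`) so they compose with sklearn
tooling; the module-level functions are thin equivalents.

## Generative model

All structural coefficients act on standardized scales.

* **Latent methylation.** Five CpG units (`CpG 2`, `CpG 3.4`, `CpG 5`,
  `CpG 7`, `CpG 11`) are drawn as a multivariate normal z-score vector with
  a block-exchangeable correlation matrix: r = 0.66 inside the
  {CpG 2, CpG 3.4} block, r = 0.45 inside {CpG 5, CpG 7, CpG 11}, r = 0.10
  across blocks. The matrix is checked for positive semi-definiteness at
  parameter construction. β fractions are affine transforms of the
  z-scores with per-CpG means/SDs (defaults around 0.19–0.48 / 0.08–0.21,
  typical of placental amplicon methylation). The latent fractions are left
  Gaussian — values straying past [0, 1] in the far tails are clipped only
  at *measurement* time, where detection limits genuinely act; clipping the
  latent scale would bias the marginal mean/SD calibration the generator
  guarantees (sample moments within Monte-Carlo error of the configured
  values).
* **Covariates.** Maternal age ~ truncated N(28, 5²) on [18, 45];
  gestational age ~ truncated N(38.0, 0.97²) on [37, 42] (the full-term
  window); college education Bernoulli(0.41); low family income
  Bernoulli(0.55); ETS exposure Bernoulli(0.30); alcohol use
  Bernoulli(0.04); primiparity Bernoulli(0.73); female Bernoulli(0.588).
  Structural equations consume internally standardized covariates so all
  nuisance coefficients are per-SD effects.
* **Mediator.** `z_area = β₁·z_meth(causal CpG) + γᵀC + ε`. By default the
  residual SD completes the structural variance to exactly 1, so the
  generated standardized area has unit marginal variance and analysis-side
  re-standardization does not rescale the path coefficients. Default
  nuisance effects: gestational age +0.15 SD, female −0.05 SD.
* **Outcome.** Bernoulli with
  `logit p = θ₀ + θ₁′·z_meth + θ₂·z_area + δᵀC`. Defaults are the
  calibrated truths θ₁′ = 0.3436 (= ln 1.41), θ₂ = −0.8440 (= ln 0.43),
  β₁ = −0.3816, making NIE = exp(β₁θ₂) = 1.38 and the log-scale proportion
  mediated 48.4%. The intercept default (−3.46) was calibrated once by
  Monte-Carlo (n = 400 000) to a ~5% marginal prevalence — the rare-outcome
  regime in which odds-ratio mediation formulas are interpretable — and is
  fixed. `true_effects` refuses to report closed forms when the baseline
  prevalence implied by the intercept exceeds 10%.
* **Geometry.** Area in cm² is `274.8 + 58.0·z_area` (floored at 60 cm²),
  decomposed into elliptical axes by drawing an aspect ratio ~ truncated
  N(1.08, 0.04²) on [1.0, 1.3] and inverting area = major·minor·π/4; axes
  are rounded to 0.01 cm and the stored area is recomputed from the rounded
  axes so the ellipse identity holds exactly. Placental weight is a noisy
  linear function of area. The paper-gap choice here is deliberate: the
  ellipse formula defines area from axes, not the reverse, so the inverse
  decomposition (aspect-ratio model) is the package's own construction.
* **Draw order.** One `default_rng(seed)` stream consumed in a documented
  fixed order (covariates → CpG z-scores → mediator residual → outcome
  uniforms → aspect ratios → weight noise), making seeds portable across
  re-implementations of the same algorithm and runs bit-reproducible.
* **Case-control imitation.** The cohort is generated prospectively;
  `subsample_case_control` draws e.g. an 86:79 sample and records the
  regime. Matched-pair recruitment is *not* simulated: the analysis models
  are unconditional regressions with covariate adjustment, so matching
  would add structure the estimators never exploit.

## Assay model

Plates hold 24 samples, interleaved case/control (exactly half/half when
counts allow). Readouts are latent β plus N(0, 0.01²) noise clipped to
[0, 1]; the noise default is chosen so technical repeat pairs satisfy
|Δβ| < 0.05 essentially always, consistent with a well-run plate assay.
Per plate: one random sample is re-measured as a repeat and one conversion
control is drawn uniformly in [0.985, 0.999]. Missingness (default 3%)
models poor readouts; a small injection rate (default 2%) forces values into
the detection-limit tails. Every corruption is recorded in an injection
ledger, against which QC recovery is tested event-by-event. The composite
unit `CpG 3.4` can be emitted as two fragments that QC averages back.

## Quality control semantics

* "Lower than 5% / higher than 95%" are strict inequalities: β = 0.05 and
  β = 0.95 are retained.
* "Poor readout" is operationalized as a missing β (no spectrum-level
  information exists here).
* A CpG is retained when valid/assayed ≥ 0.75, the denominator being the
  samples assayed *for that CpG* (per-CpG counts legitimately differ).
* Statuses partition entries exactly (input = missing + censored + valid),
  the filter is idempotent, and removal order (missing vs censored) cannot
  change the final valid set because the two conditions are disjoint.
* Repeat failure (any pair |Δβ| ≥ 0.05) or conversion ≤ 0.98 flags the
  batch in the report; default mode keeps flagged batches (a sound assay is
  expected to pass), `strict=True` drops them before filtering.

## Association layer

* Standardization uses the sample SD (ddof = 1), preserves missing values,
  and by default computes μ, σ over all QC-valid samples for a variable
  *before* model-specific complete-case restriction (configurable to
  per-model scope), matching per-model n's that differ across CpGs.
* Logistic fits are binomial GLMs by IRLS (relative deviance tolerance
  1e-8, max 100 iterations) with Wald CIs and p-values — the symmetric
  log-OR-scale intervals that adjusted odds-ratio tables print.
  A |coefficient| > 15 heuristic (intercept excluded) flags complete
  separation. Fractional outcomes in [0, 1] are accepted, which the
  natural-effects imputation fit requires.
* Group descriptives use the pooled-variance two-sample t test and the
  chi-squared test without continuity correction.
* Correlation blocks: pairwise-complete Pearson r, single-linkage grouping
  at |r| ≥ 0.30 (transitive chains merge blocks), α divided by the block
  count. Single linkage mirrors the transitive "block" reading of grouped
  CpGs; the cutoff applies to |r|.

## Mediation engine

* Conditions (a)–(c) are significance tests (default α = 0.05) of β₁, θ₁
  and θ₂; condition (d) is *strict* attenuation |θ₁′| < |θ₁| with the
  attenuation percentage reported — loss of significance alone does not
  qualify. The discovery scan uses the block-corrected threshold (0.025
  with two blocks); the mediation conditions use their own α = 0.05. Both
  are configurable.
* The natural-effects estimator uses exposure grid offsets {0, −1} SD so
  NDE/NIE are per-one-SD effects, matching the per-SD association models;
  the grid is configurable. Imputation feeds *expected* outcome
  probabilities (not resampled binaries) into the natural-effect model,
  all expanded replicas weighted equally, so point estimates are
  deterministic.
* TE = NDE × NIE holds exactly by construction (log-scale coefficients
  add); proportion mediated = 100·ln(NIE)/ln(TE) and is undefined at
  TE = 1.
* Uncertainty: nonparametric bootstrap of subjects (never expanded
  replicas), percentile 95% CIs, deterministic under a fixed seed; failed
  replicates are counted and > 10% failures raise an error. A sandwich
  variance is a noted alternative, not implemented.
* Estimates from case-control samples or non-rare outcomes carry a caveat
  in the result object: OR-scale NDE/NIE are interpretable only under the
  rare-outcome assumption. Calibration checks therefore use cohort
  sampling at ~5% prevalence, where a small conservative bias remains
  visible (estimated NDE ≈ 1.37–1.39 against a closed-form 1.41): the
  logistic odds ratio is not collapsible over the mediator residual, and
  the closed form is exact only as prevalence → 0.

## Problem sizes

Unit and property tests run at n = 400–50 000 subjects. Estimator
calibration uses 20 cohorts of n = 100 000 (natural-effects recovery,
medians), 20 × n = 20 000 (mediator-path recovery), and bootstrap coverage
under the null at 250:250 case-control with 60 replicates per simulation —
sizes at which Monte-Carlo error is small relative to the tolerances while
the full suite stays in the minutes range on one CPU.

## What the generator does not emulate

Mass-spectrum peak calling and fragment chemistry; genotype-driven (mQTL)
methylation structure; matched-pair sampling and any residual correlation
matching might induce; sex-specific path coefficients (stratified analyses
are exercised, but the default truth is common to boys and girls);
gestational-age dating error. Passing tests therefore demonstrate
correctness of the estimators under the stated structural model, not
robustness to these real-data features.

## Known limitations

* The OR-scale decomposition inherits the rare-outcome approximation; at
  5% prevalence recovered ORs sit ~0.02–0.04 below the closed forms.
* No exposure–mediator interaction term (NDE and NIE share one working
  model); multiple mediators and weighting-based natural-effect estimation
  are out of scope.
* Wald inference throughout; profile-likelihood or LR-based intervals are
  not provided.
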