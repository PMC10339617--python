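# Methods

This note documents the statistical models behind `aprs`, the defaults and
conventions that were genuinely open choices, and what the synthetic
validation does and does not establish about real data.

## Synthetic cohort model

### Population structure

Genotypes follow the Balding–Nichols F-model. Each variant draws an
ancestral allele frequency p₀ ~ Uniform(0.05, 0.95) (the range avoids
monomorphic variants at desk-scale sample sizes). Each population then draws
its own frequency from Beta(p₀(1−F)/F, (1−p₀)(1−F)/F), which has mean p₀ and
variance F·p₀(1−p₀); F = 0 is handled as the degenerate case (frequency
equals p₀ exactly). Genotypes are Binomial(2, p) within population
(Hardy–Weinberg) and variants are unlinked. The default F = 0.1 produces
clean but not trivial PC separation between two populations at ~1,000
variants; F is per-population and tunable. Reference panel and study cohort
share one set of population frequencies under the same seed but are
independent genotype draws — mimicking projection onto an external reference
drawn from the same populations.

### Scoring file

Per-variant weights are Normal(0, 0.1) by default. Two representational
perturbations exercise the harmonizer: a fraction of variants (default 10%)
carries strand-ambiguous A/T or C/G allele pairs, and a fraction (default
10%) is written with effect/other alleles swapped relative to the genotype
alt/ref orientation. Both counts are deterministic
(round(fraction·n_variants)) under the seed. The optional
`weight_freq_coupling` parameter adds `coupling × Δ(effect-allele
frequency)` to each weight; this is the mechanism that creates a
structure-driven mean shift of the raw score between populations — the
portability failure the PC adjustment is designed to remove. It defaults to
0 (a portable score); the distribution-shift validation study sets it to
0.1, which at F = 0.1 and 1,000 variants separates the two populations'
raw-score distributions almost completely.

### Disease, family history, onset

Disease is a liability-threshold model: L = β_prs·G + β_sex·(sex−½) +
β_age·age_std + c + e, with G the standardized true score (defined over the
non-ambiguous variants only, so the estimable PRS equals the generative
score exactly), c a family-shared environment term (variance
`fh_shared_env`, default 0.05), and e independent Gaussian noise scaled so
Var(L) = 1. Covariates are centered inside the liability so the case
threshold Φ⁻¹(1−prevalence) calibrates prevalence exactly; configurations
whose fixed effects leave non-positive residual variance are rejected. Age
is Uniform(40, 69) (recruitment-age range of large volunteer biobanks) and
standardized as (age − 54.5)/8.4 so β_age is per-SD. Defaults: prevalence
0.1, β_prs 0.5, β_sex 0.3, β_age 0.3.

Family history: each proband gets n_relatives = 3 first-degree relatives
(two parents and one sibling; all have genetic correlation ½ with the
proband, so one formula serves: g_rel = ½·g + √¾·g_new). Relatives share the
proband's family-environment term, receive their own residual noise scaled
to unit liability variance (their liability omits sex/age terms for
simplicity), and are affected by the same threshold; FH = 1 iff any relative
is affected. With β_prs = 0 and no shared environment, FH is independent of
case status by construction.

Onset ages are exponential with rate λ₀·exp(hazard_β_prs·G) (defaults
λ₀ = 0.002/yr — chosen so the event probability by a mean visit age of ~54.5
roughly matches the default prevalence — and hazard_β_prs = 0.5). A sample
whose onset falls at or before its recruitment visit is an observed case
(event time = onset age); otherwise it is censored at the visit age. The
case column is re-derived from this comparison, so the longitudinal
(onset-based) and cross-sectional (liability-based) case definitions are
alternative generators of the same column; `simulate_cohort(with_onset=...)`
selects which one the final table carries. Because there is no left
truncation (everyone is at risk from age 0), simulated cumulative
incidences by late ages can be high — a deliberate mirror of prevalent-case
inclusion in the analysis this package supports, and a caveat for
interpreting the curves as population incidence.

All randomness derives from one master seed through named substreams
(SeedSequence spawn keys from a CRC of the stage name), so adding or
re-running a stage never perturbs another stage's draws, and identical
configurations produce byte-identical output files.

### What the simulator does not emulate

No linkage disequilibrium (variants are exchangeable and unlinked), no
realistic allele-frequency spectrum, no genotyping error or imputation
uncertainty, no X chromosome, no ancestry admixture, and relatives' onset
ages are not modelled. Passing validation therefore demonstrates the
*statistical machinery* — harmonization, projection, residualization,
estimation, calibration — not robustness to LD-driven weight mis-transfer,
which is a genuinely different (and unsolved) component of PRS portability.

## Pipeline conventions and numerical choices

- **Harmonization truth table** (scoring record vs genotype variant):
  ambiguous (A/T, C/G) → excluded; effect=alt/other=ref → dosage as-is;
  effect=ref/other=alt → 2−d; the same two rules after strand complement;
  anything else dropped and counted. Matching is by variant id first, then
  chrom+pos. Missing dosages are mean-imputed (2×effect-allele frequency),
  keeping the score unbiased under missingness-at-random; a variant with all
  dosages missing is dropped with a report entry.
- **Standardization** uses the population (divide-by-n) SD. The sample-SD
  alternative differs by √(n/(n−1)) — immaterial downstream because every
  consumer is location/scale-invariant, but pinned and tested.
- **PCA**: variants centered by reference mean dosage and scaled by
  √(2p̂(1−p̂)); monomorphic variants dropped; loadings by SVD with signs
  pinned (largest-|loading| entry positive). Study samples are projected
  with the *reference* means/scales — study data never rotates the basis.
  K = 4 because all downstream models use four PCs. Ancestry assignment is
  nearest centroid (Euclidean, first K components), ties broken to the
  lexicographically first label and flagged.
- **Adjustment** is one pooled regression across all samples (not
  per-population). Constant PC columns are dropped with a warning so
  degenerate toy inputs run; non-constant collinearity raises. Residual
  variance below 1e-10 (relative) is treated as exactly zero and raises.
  The aPRS is invariant to positive affine transforms of its input, so
  standardizing before as well as after residualization changes nothing.
- **Percentiles**: a sample is "low" iff its entire tie class lies within
  the bottom 20% (strictly below the order statistic at floor(qn/100)+1)
  and "high" iff within the top 20% (strictly above the order statistic at
  ceil(qn/100)); boundary ties fall inward to "intermediate". With n
  divisible by 5 and no boundary ties this gives exactly 20/60/20.
  Odds-ratio analyses stratify within population; cross-population
  high-score comparisons use the cohort-wide threshold.
- **Logistic models**: Newton ML with tolerance 1e-8; complete separation
  and divergence are detected and reported with the offending column. Wald
  95% CIs (exp(β̂ ± 1.96·se)); p < 0.01 flagged. The FH × score interaction
  is a likelihood-ratio test of the product terms against the additive
  model.
- **Splits and metrics**: 75/25 train/test, stratified by outcome (an
  unstratified split can lose all cases at realistic minority-population
  case counts); AUROC is the midrank Mann–Whitney statistic with a DeLong
  CI; AUPRC is the step-interpolated precision–recall integral.
  Case/control downsampling removes the over-represented side at random
  until the target ratio holds within one sample.
- **Cox**: Efron tie handling (ages are coarse; ties certain), validated
  against an independent Efron partial-likelihood implementation on a tied
  hand example and against R `survival::coxph` on a frozen fixture. The
  proportional-hazards diagnostic is the Grambsch–Therneau scaled-Schoenfeld
  test with the identity time transform (pinned for determinism), both
  per-covariate and global; the global statistic matches R `cox.zph` to
  ~1e-4 on the fixture, while per-covariate values differ slightly
  (average-information approximation). Age is used as the time scale only —
  not additionally as a covariate, which would be circular. Adjusted
  cumulative incidence uses the conditional-at-means convention: stratum
  indicators set, remaining covariates at cohort means; incidence is
  clamped to 0 before the first observed event time.
- **Relatedness pruning**: pairs above kinship 0.0884 form a graph; the
  highest-degree node is removed iteratively with seeded tie-breaking
  (canonicalized by sample id, so the result is independent of input row
  order). For an isolated pair this reduces to retaining one member at
  random; for larger components it deterministically yields an independent
  set.
- **Diagnosis codes**: patterns are concrete codes, ".X" prefix wildcards
  (matching the bare rubric and any subcode, since biobank extracts store
  both 3- and 4-character codes), or bracketed ranges ("K40.[1-4]", en-dash
  accepted). Codes are compared dot-insensitively. Self-reported and
  clinical evidence are unioned. Missing BMI excludes a sample from the
  obesity analysis only (never coded as a control).

## Validation study designs

The studies in `aprs.evaluation` (asserted by the test suite, reported by
`scripts/acceptance.py`) use these problem sizes, chosen to keep Monte-Carlo
error small relative to the property checked while remaining desk-scale:

- distribution-shift correction: 2 × 5,000 samples, 1,000 variants, F = 0.1,
  coupling 0.1; each population's adjusted high-score fraction must be
  within 2 percentage points of 20%.
- Wald CI coverage: 200 replicates at n = 5,000 under the logistic
  generative model (coverage of a known β is only defined when the
  generative and fitted models agree; the liability-threshold cohort is
  exercised separately in the null study below).
- null score: 200 full generator-to-model replicates at n = 5,000 with
  β_prs = 0; the high-vs-intermediate OR CI must cover 1 in ≥ 90%.
- discrimination gain: generative effect grid {0.3, 0.5, 0.7} at n = 5,000;
  the held-out AUROC gain from adding the score must be positive at every
  grid point.
- Cox recovery: two-group exponential, true HR = 2, n = 10,000; estimate
  within [1.9, 2.1].
- proportional-hazards calibration: 500 PH-respecting replicates at
  n = 1,500; global-test type-I error within [0.03, 0.07]. The replicate
  size is set in the regime where the asymptotic chi-square reference of
  the Grambsch–Therneau statistic is accurate; the test is known to be
  mildly anticonservative at a few hundred observations.

## Known limitations

Beyond the simulator gaps above: no LD clumping or p-value thresholding
(the intended inputs are published fixed SNP panels); no penalized or Firth
regression, so quasi-separated designs error rather than shrink; no
competing risks, left truncation or time-varying covariates in the survival
module; and the nearest-centroid ancestry classifier has no "unassigned"
category — samples far from every centroid still receive the nearest label
(the recorded distance supports downstream filtering).
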