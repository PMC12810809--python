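# Methods

## Problem setting

Pathological depth of invasion (pDOI) is a strong predictor of cervical
lymph-node metastasis (CLNM) in tongue squamous cell carcinoma, but it is
only available after surgery. Preoperative imaging estimates it with
modality-specific error: intraoral ultrasound resolves shallow tumours
well but loses accuracy (and tends to underestimate) beyond roughly
10 mm, where probe access and penetration limit it; MRI tracks deep
extension but systematically overestimates depth (peritumoral
inflammation, partial-volume effects) with larger variability. The
package quantifies each modality's agreement with pathology, its ROC
performance for CLNM, and a conditional composite that uses ultrasound
up to a switching threshold and MRI above it.

## Synthetic cohort model

All stages are exercised on synthetic cohorts, since no patient-level
data are distributable.

Structural generator (`generate_cohort`), per patient with true depth
`p` (mm):

    usDOI = p + b_us + s · max(0, p − k) + ε_us,   ε_us ~ N(0, σ_us²)
    mrDOI = p + b_mr + ε_mr,                       ε_mr ~ N(0, σ_mr²)
    CLNM  ~ Bernoulli(expit(β₀ + β₁ p))
    P(usDOI observed) = expit(a₀ + a₁ p),   P(mrDOI observed) = q

Negative simulated measurements are truncated at 0 — a pure transform of
one noise draw per field, which keeps the generator bit-reproducible at
the cost of a slight upward bias for very shallow tumours (well under
0.01 mm at the default calibration; quantified in the test suite's
moment-recovery checks). One random sub-stream per field (depths, US
noise, MRI noise, outcome, US missingness, MRI missingness, in that
fixed order) means adding a field can never perturb earlier draws.

Defaults (units mm unless noted):

| parameter | default | rationale |
|---|---|---|
| pDOI marginal | lognormal, median 8, log-SD 0.95 | right-skewed depth with IQR ≈ 4.2–15.2, bracketing the decile grids seen in practice; gamma also supported |
| b_us (shallow US bias) | +0.88 | published mean US−pathology difference |
| σ_us | 1.59 | published SD of US differences |
| knot k | 10 | depth beyond which US underestimation is reported |
| deep slope s | −1.0 | "strong" regime change: US depth signal fully flattened past the knot |
| b_mr | +2.43 | published mean MRI−pathology difference |
| σ_mr | 2.39 | published SD of MRI differences |
| β₀, β₁ | −1.88, 0.15 /mm | β₁ a moderate depth effect; β₀ solved numerically for ≈43% CLNM prevalence under the default marginal |
| a₀, a₁ | 2.5, −0.25 /mm | a₁ encodes preferential ultrasound use for shallow tumours; a₀ solved for ≈52% marginal US availability |
| q (MRI availability) | 0.956 | ≈44/46 |

The copula generator (`generate_copula_cohort`) instead draws a latent
trivariate Gaussian with corr(us, p) = r_us, corr(mr, p) = r_mr and the
us–mr entry defaulting to r_us·r_mr (conditional independence of the two
imaging errors given pathology; overridable, with an explicit positive-
semidefiniteness check), then maps through the probability integral
transform to the requested marginals. With normal marginals the latent
correlation is exactly the output Pearson correlation, which is what the
correlation-recovery studies use.

What the generator does **not** emulate: formalin-shrinkage mechanics
(absorbed into the biases), inter-rater measurement variability,
non-Gaussian or depth-heteroscedastic imaging error, correlation between
the two modalities' availability, and outcome ascertainment over
follow-up (CLNM is a fixed label). Passing recovery tests therefore
demonstrates the estimators' correctness under this error model, not
clinical performance on real cohorts.

## Agreement statistics

Differences are always **imaging minus pathology** (positive bias =
overestimation); this is stated prominently because sign conventions
vary across software. Limits of agreement use the fixed 1.96 multiplier
on the n−1 sample SD rather than a t quantile — the convention of the
clinical literature — sacrificing small-sample exactness. Proportional
bias is the OLS slope of differences on pairwise means with its t-test;
the regime knot is a generator concept, not an estimator output, so no
changepoint estimation is attempted.

A caveat the test suite encodes: even with depth-independent error the
difference shares half the error term with the pairwise mean, so the
population proportional-bias slope is σ²/2 ÷ var(mean), slightly
positive, not zero. The null-case test asserts recovery of that derived
value.

## ROC analysis

The curve sweeps "positive if score ≥ t" over distinct observed scores
descending, giving one point per distinct threshold plus the (0,0)
anchor; tied scores collapse to a single point. AUC is computed as the
Mann–Whitney pair probability with half-credit ties — tied depth
readings are expected at 0.1 mm resolution — and cross-checked against
the trapezoidal curve area (equal by construction; asserted to 1e−12 on
every call). The optimal-cutoff criterion is Youden's J (the
near-universal clinical default), with closest-to-(0,1) available behind
a flag; cutoff ties break toward the higher threshold (fewer test
positives). Reported cutoffs are midpoints between the adjacent distinct
observed scores, matching common statistical-package output (which is
how non-observed cutoffs such as 9.5 mm arise). No AUC confidence
intervals or DeLong tests are produced: the pipeline reports point
estimates only.

## Composite grid search

Candidate thresholds are the 10th–90th percentiles (default decile
levels) of the complete-case usDOI sample, linear interpolation between
order statistics; the percentile convention is configurable since
printed grids cannot adjudicate it. For each candidate the composite
score is formed (`us` if `us ≤ t`, else `mr`; the boundary stays with
ultrasound), a univariable logistic model is fitted by IRLS (convergence
when the max absolute coefficient update < 1e−8 within 100 iterations;
complete separation returns the last iterate with a warning), and the
composite's AUC computed. Selection uses the composite's AUC directly —
identical to the fitted-probability AUC whenever the slope is positive
(monotone logit; the identity is asserted on every grid cell) and immune
to convergence fragility; a negative fitted slope raises a warning.
Ties at the maximal AUC resolve to the smallest threshold, keeping the
better-validated ultrasound regime for more patients. Analysis is
complete-case only (no imputation) and no optimism correction of the
selected threshold is applied — both mirroring standard exploratory
practice; the selected threshold is therefore an in-sample optimum and
should be treated as hypothesis-generating.

### A structural property of threshold recovery

Replicate studies (100 cohorts of n = 200 with the strong regime change)
show the selected threshold does **not** concentrate at the 10 mm error
knot, and cannot: the switching rule keys on the *measured* usDOI, and
flattened deep tumours read near knot + shallow bias (≈10.9 mm), so any
threshold below that reading already routes them to MRI. Below the knot
the objective changes only through the modest shallow noise contrast
(σ_us = 1.59 vs σ_mr = 2.39), leaving a near-flat AUC plateau whose
population argmax sits several millimetres below the knot. The composite
does beat both single modalities in the large majority of replicates;
the *location* of its optimum is intrinsically weakly identified. This
is a property of AUC-driven switching-threshold selection generally and
is worth bearing in mind when interpreting any single cohort's "optimal"
switching value.

## Numerical and design choices

- Percentile grids validated to lie strictly within [1, 99] and be
  strictly increasing; degenerate samples deduplicate to fewer
  candidates.
- IRLS weights are floored at 1e−12 to keep the weighted normal
  equations solvable near separation.
- Composite construction refuses missing inputs rather than silently
  propagating them; subsetting to complete cases is the caller's
  explicit step (`complete_cases`).
- Report JSON carries full-precision values plus a rounded block (AUCs
  to 3 decimals, millimetres to 2) for rendering.
- Per-stage subset sizes always satisfy
  n_complete ≤ min(n_US, n_MRI) ≤ n_total and are logged together with
  every skipped stage and its reason; AUCs are labelled with their
  cohort because subsets differ and cross-subset AUC comparison is
  treacherous.
- Simulation sizes: moment/correlation recovery uses n = 20,000
  (Monte-Carlo SE ≈ 0.011 mm on the US bias, ≈ 0.0015 on r), replicate
  threshold studies use 100 × n = 200 — sizes at which the checks are
  decisive while the whole suite runs in seconds.

## Known limitations

- The deep-regime ultrasound model is a single-knot piecewise-linear
  bias; real degradation is plausibly heteroscedastic as well as biased.
- Truncation at zero (rather than resampling) slightly biases extreme
  shallow measurements; negligible at the default calibration.
- The logistic outcome model is univariable in depth; stage, site and
  other covariates are out of scope.
- CLNM labels ascertained over follow-up are treated as fixed binary
  outcomes; no time-to-event modelling.
- Selected switching thresholds are in-sample optima with no
  cross-validation; their instability across replicates is documented
  above rather than corrected.
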