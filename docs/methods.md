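# Methods

`homapanel` re-creates, as tested reusable code, a complete multi-metabolite
modelling workflow for insulin resistance: repeated cross-validated
elastic-net selection of a plasma-metabolite panel against HOMA-IR, a
weighted-sum metabolite score, leave-one-out internal validation, external
validation on an independent cohort, a glucose-exclusion sensitivity
analysis, and prediction of longitudinal HOMA-IR changes. Because no
subject-level data from the original two weight-loss cohorts are public, the
package ships a synthetic-cohort generator that emulates their published
baseline characteristics and carries a known planted signal, so every stage
is testable against ground truth.

## The modelling pipeline

**Outcome.** HOMA-IR is computed from its defining identity,
`glucose [mg/dL] × insulin [mIU/L] / 405`. For the discrimination analysis
subjects are split at the cohort's own sample median (values at or below the
median form the reference class, coded 0); for the continuous analysis
HOMA-IR is used untransformed but autoscaled, and predictions are reported
back on the original scale through the stored center and SD. The validation
cohort is always dichotomized at *its own* median and scaled with *its own*
centers and SDs.

**Preprocessing.** Metabolites with 20% or more missing values are excluded
(strictly-less-than-20% are kept — the boundary case is excluded).
Remaining gaps are filled by iterative random-forest imputation in the
missForest style: missing cells start at column means; variables are visited
in order of increasing missingness, each regressed on all others with a
100-tree random forest fitted on its observed rows; iteration stops at the
first rise of the normalized squared-difference criterion
`Σ(X_new − X_old)² / ΣX_new²` over the imputed cells, returning the previous
iterate. Features are then autoscaled (centered, unit sample SD with
`ddof=1`, the convention of the statistical environments this field uses).
Scaling is estimated once on the whole cohort before any model fitting —
the classical whole-cohort convention; `loo_cv_scores(...,
rescale_per_fold=True)` provides the leakage-safe alternative that
re-estimates centers and SDs inside each fold. Each cohort is preprocessed
independently (the design/validation split is preserved throughout).

**Penalized fitting.** The core model is the elastic net,

    min over (b0, β) of  (1/n)·loss(y, b0 + Xβ)
                         + λ·( α·‖β‖₁ + (1−α)/2·‖β‖₂² ),

with the half squared error (Gaussian) or Bernoulli negative log-likelihood
(binomial) as the loss. The solver is pathwise cyclic coordinate descent
with warm starts and active-set iteration; the binomial family wraps the
weighted quadratic solve in an IRLS loop with fitted probabilities clamped
to [1e-5, 1−1e-5] — the construction used by glmnet, against which the
solver is tested (identical selected support and coefficients within 1e-4 on
random small instances; glmnet internally standardizes the Gaussian response
by its population SD, which the comparison accounts for). Convergence is
declared when the maximum weighted squared coefficient update falls below
`tol` (default 1e-7); final refits at a chosen penalty are solved 10⁴ times
tighter. Coefficients below 1e-10 after convergence are numerical dust from
the soft-threshold boundary and are snapped to exact zero.

The mixing parameter α is **not** documented in the source analysis; the
default is α = 0.5 (an equal lasso/ridge mixture) and every selection
property in the test suite is exercised at both α = 0.5 and α = 1.0.

**Penalty tuning.** `tune_lambda_cv` assigns folds by a seeded random
permutation (sizes within one of each other), fits the full penalty path on
each training fold, and averages a per-observation held-out criterion. The
default criterion is the mean squared error — for the binomial family the
squared error of predicted probabilities, following the source analysis's
description, with the Bernoulli deviance available by configuration. The
selected penalty is the curve minimum (`lambda.min`); exact ties resolve to
the largest (sparsest) penalty. The automatic grid is 100 log-spaced values
from the smallest all-zero penalty down to 1e-4 of it. A training fold
containing a single outcome class raises a fold-degeneracy error that
recommends fewer folds.

**Stability (consistency) selection.** The cross-validated fit is repeated
`n_runs = 100` times; runs differ *only* in fold assignment (no subject
resampling — the procedure re-runs CV, it does not bootstrap). Each run
records the full refit coefficient vector at its `lambda.min`. A feature is
*consistently selected* when its coefficient is nonzero in every run; the
summary also reports per-feature selection counts and the median and
2.5th/97.5th percentiles of the coefficient across runs, zeros from
non-selected runs included (the interval then reflects selection
uncertainty, not only coefficient spread). Ranked reports sort by selection
count, then absolute median coefficient, ties alphabetically.

**Scores and validation.** A score model is a weighted sum of autoscaled
metabolite levels; training weights are the per-feature median coefficients
of the consistent panel. Binary score models drop the intercept (the AUC is
intercept-invariant for a fixed model; across LOO folds the intercept tracks
the held-out subject's label through the training class balance and is
actively anti-predictive, so LOO scores for the binomial family are linear
predictors without intercept). Internal validation is leave-one-out: each
subject is scored by a model tuned and fitted on the other n−1 subjects.
Discrimination is the AUC — the Mann–Whitney probability of correct
ranking, ties counted one half, computed from midranks and verified against
exhaustive pair counting — with a 95% interval from the DeLong placement
variance (a seeded stratified bootstrap is available). Continuous
performance is the Pearson correlation with a Fisher-z interval and the
adjusted R², `1 − (1−R²)(n−1)/(n−p−1)` with p the selected panel size.

External validation applies the training-selected panel to the validation
cohort in two first-class modes, reported side by side: **transfer** keeps
the training weights; **refit** (the default) re-estimates weights by
unpenalized logistic or linear regression of the validation outcome on the
panel. Refit-mode metrics are computed in-sample on the validation cohort —
that is the procedure being reproduced — which mildly inflates them when
the panel is large relative to n.

**Sensitivity analysis.** The glucose-exclusion analysis removes named
features from the predictor matrix *before* selection and reruns the entire
selection + validation chain; reports record the exclusions. In synthetic
cohorts the metabolomics glucose measurement is the panel feature
`met_glucose`.

**Longitudinal changes.** End-of-intervention minus baseline changes in
HOMA-IR are tested against the baseline score under three adjustment modes:
raw; adjusted for body-weight change; adjusted for body-weight change and
baseline HOMA-IR. "Adjusted" means residualized — OLS of the change on an
intercept plus covariates, keeping residuals — the standard construction
yielding one adjusted change per subject to median-split. Each mode's
(residualized) changes are median-split and the AUC of the baseline score
against those labels computed as above. Residualization is idempotent and
the raw-mode labels equal the plain median split exactly.

**Cohort description.** Welch's t-test (unequal variances,
Welch–Satterthwaite degrees of freedom) compares continuous baseline
variables and is callable from raw vectors or from printed mean/SD/n
summaries — the latter makes published tables desk-reproducible; the two
routes agree to 1e-12 by construction. Categorical rows use the
continuity-corrected chi-square test by default (Fisher's exact by option);
the source table does not state its categorical method, so no published
categorical p-value is asserted. LDL cholesterol uses Friedewald's formula
`TC − HDL − TG/5`, valid only below 400 mg/dL of triglycerides. Skewed rows
report median [Q1–Q3] with linear-interpolation quantiles.

## The synthetic-cohort generator

One latent insulin-resistance factor `u ~ N(0,1)` per subject drives
everything that should co-vary:

- fasting insulin is log-normal, with log-mean increasing in `u` (loading
  0.75 of the log-SD) — clinical insulin is right-skewed, and the published
  SD ≈ mean strongly suggests skew;
- fasting glucose is normal with mean increasing in `u` (loading 0.40 of the
  SD), truncated at 40 mg/dL;
- each designated signal metabolite j receives `a_j·u` added to its
  standardized noise, `a_j` the signed effect size (defaults: 10 signals,
  magnitudes 1.0 down to 0.5, alternating signs);
- the remaining metabolites carry block-correlated Gaussian noise
  (equicorrelated blocks of 8–14 features at ρ = 0.3–0.7, emulating lipid
  families), plus independent features;
- one feature, `met_glucose`, duplicates the clinical glucose assay up to
  5% measurement noise, so the glucose-exclusion sensitivity analysis has a
  faithful target;
- 10 of the 133 default features receive >20% missingness (exactly-counted
  MCAR) and are the designed exclusions; retained features get 5% MCAR.

Routing the signal through a single shared factor deliberately induces the
metabolite–phenotype collinearity that the elastic net is designed for. It
also means planted signal features are mutually redundant (the signal is
rank one): sparse selection correctly drops weaker proxies when stronger
ones are present, so *exact* support recovery is not an expectation under
this design — recovery tests use an independent-feature regression design
instead (below). The latent loadings (0.75 insulin, 0.40 glucose) were set
by a binormal calculation so that a well-estimated score reaches an
internal LOO AUC near the mid-0.80s, the performance scale reported for the
real cohorts.

Phenotype presets reproduce the published baseline characteristics of the
two studies (training-like: glucose 93.25 ± 11.03 mg/dL, insulin
10.25 ± 8.88 mIU/L, n = 236; validation-like: 101.57 ± 14.67, 5.08 ± 3.04,
n = 102; plus weight, age, sex proportion and the lipid panel). LDL is
derived by Friedewald from simulated TC/HDL/TG, keeping the lipid identity
internally consistent. Follow-up blocks add
`Δhoma = c_w·Δbw + c_b·(homa − mean) + c_u·u + ε`; a negative `c_b` is
regression-to-the-mean, and `c_u` couples the change to the same latent
factor the panel measures — the mechanism behind the qualitative pattern
that full adjustment raises the longitudinal AUC.

What the generator does **not** emulate: real concentration distributions
(metabolite noise is Gaussian; no log-normal abundances, no limit-of-
detection censoring — missingness is MCAR by design, matching the weakest
assumption consistent with the imputation method), instrument batch or
drift effects, more than one latent physiological axis, and any dependence
of missingness on concentration. Passing tests therefore demonstrate that
the pipeline's machinery is correct and behaves as the method promises
under its own assumptions — not that the method would select the same
metabolites in real plasma data.

## Numerical and design choices

- **Fold and run seeds** derive from a master seed through
  `SeedSequence([master, run, redraw])`, kept below 2³¹; identical master
  seeds give bit-identical selection summaries.
- **Degenerate inputs**: constant features raise named errors at
  autoscaling; an all-identical outcome cannot be median-split; a training
  fold with one class raises a fold-degeneracy error, and stability/LOO
  loops redraw such runs (at most 5 times) with fresh entropy.
- **Desk-scale settings**: the demo configuration and the study-scale tests
  run the inner CV at 10 folds (the 100-fold variant is one flag away) with
  a 50-point penalty grid down to 1e-3·λ_max; the library defaults remain
  100 points to 1e-4. The acceptance script's full pipeline (two cohorts,
  two families, 100 selection runs, two LOO sweeps, and the glucose-excluded
  rerun) completes in a few minutes on one CPU at these settings.
- **Open points resolved as package defaults**: imputation runs per cohort
  (never on merged cohorts); HOMA-IR enters the Gaussian path untransformed
  (autoscaled); external validation defaults to refit weighting with
  transfer reported alongside; internal LOO uses each fold's own fitted
  model rather than the consistent panel.

## A note on `lambda.min` and permutation nulls

A finding worth recording, verified independently with `cv.glmnet` on
identical data: for a *fixed* permuted outcome vector, the dataset retains
chance feature–outcome correlations of order √(2·log p / n) (≈ 0.2 at
n = 236, p = 123). Because cross-validation folds are subsamples of the same
dataset, the held-out criterion *validates* those dataset-level chance
correlations, and `lambda.min` then stably selects roughly 10–45 chance
features regardless of the mixing parameter, fold count, or number of
repeated runs — fold re-randomization cannot dislodge a feature whose
advantage lives in the full dataset. Two practical consequences:

1. consistency selection with fold-only re-randomization controls CV
   instability, **not** false selection — a consistent panel can contain
   stably-selected noise, and on planted designs at this scale a handful of
   null features typically survive all 100 runs;
2. a permutation null run through the same machinery frequently returns a
   non-empty consistent panel (roughly one seed in four at this scale), so
   an empty panel under permutation is the usual but not near-certain
   outcome.

Leave-one-out scores are immune to the dataset-level effect (the held-out
subject's pair is independent of the rest), and permuted-label LOO AUCs
center on 0.5 with a mild downward bias — once binary scores omit the
intercept, which otherwise tracks the held-out label through the training
class balance and drives the AUC toward zero.

## Known limitations

- The binomial CV criterion defaults to squared error on probabilities
  (following the reproduced analysis) rather than deviance; both are
  available, and `lambda.min` under either overselects as described above.
- The DeLong interval is normal-theory on the AUC scale, truncated to
  [0, 1]; near-perfect separation at small n makes it conservative (the
  bootstrap option behaves better there).
- Random-forest imputation cost grows as (features with missingness) ×
  iterations × forest size; at 123 features and n ≈ 236 an imputation pass
  takes on the order of a minute per cohort at 100 trees.
- The refit external-validation mode evaluates in-sample on the validation
  cohort (by design, reproducing the published procedure); its metrics carry
  the corresponding optimism of order √(panel size / n).
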