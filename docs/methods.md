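# Methods

## The scores

**PRISM-3** assigns integer points to 17 admission variables
(cardiovascular/neurologic vital signs, blood-gas chemistry, laboratory
values) against age-band-specific thresholds and sums them. Age bands are
neonate [0, 1) month, infant [1, 12], child (12, 144], adolescent
(> 144); the band edges 1, 12 and 144 months were assigned to the younger
band (1 and 12 → infant, 144 → child), matching the inclusive reading of
the printed ranges, and are pinned by tests. The published total-score
logit is

    logit = 0.207·S − 0.005·age_months − 0.433·[postoperative] − 4.782

taken with every non-score term subtractive (the printed formula's
parentheses are unbalanced; the all-subtractive reading is adopted and the
intercept-only value −4.782 is unaffected by the choice).

Threshold semantics follow the printed inequalities verbatim. Where a
value lands on a boundary shared between a closed range row and an open
row (e.g. neonatal SBP exactly 40 or 55 mmHg), the closed range row wins:
SBP 55 scores 3 points, not 0. PaO₂ exactly 42 mmHg scores 3 (the
"42–49.9" row). The acidosis component is a disjunction — 6 points if
pH < 7.0 **or** TCO₂ < 5, else 2 points if pH ∈ [7.0, 7.28] **or**
TCO₂ ∈ [5, 16.9] — and the pH-alkalosis and high-TCO₂ rows are separate
additive components. Coagulation is one combined component: 3 points when
PT > 22 s or PTT exceeds the age-band threshold (85 s neonates, 57 s
otherwise). The `urea` field is read as BUN in mg/dL (thresholds 11.9
neonatal / 14.9 otherwise). Platelets and WBC are in 10³ cells/mm³.

A *missing-as-normal* scoring mode (absent variable ⇒ 0 points) exists
but is off by default; the pipeline always imputes first.

**PIM-3** is the published 13-term linear predictor with intercept
−1.7928; probability of death is its logistic transform. Fixed pupils
means both pupils fixed and dilated; "elective" comes from the admission
type; the three procedure flags and three risk-diagnosis flags are
mutually exclusive one-hot codes; the oxygenation term is
(FiO₂ × 100)/PaO₂ with FiO₂ stored as a fraction. In cohort-level
reporting the "PIM-3 score" is the predicted probability expressed in
percent — the convention that makes a typical healthy admission score ~2
and yields half-unit report cutoffs — which is a strictly monotone
transform of the linear predictor and therefore leaves discrimination
untouched.

## Recalibration

Each score is mapped to each outcome by a univariable logistic model fit
by Newton/IRLS on the centered score, tolerance 1e-8 on the
log-likelihood plus a score-equation (gradient) condition, maximum 100
iterations with step-halving. The gradient condition guarantees
calibration-in-the-large on the training data: mean fitted probability
equals prevalence to < 1e-8. No regularization is applied; a single-class
outcome raises a degenerate-outcome error and a slope diverging past
|β₁| = 50 raises a separation error rather than being silently shrunk.
Confidence intervals are Wald intervals from the observed information; at
the default analysis size (n = 2784) they are numerically
indistinguishable from profile-likelihood intervals for this
one-covariate model, and the suite verifies ≥ 90% empirical coverage of a
known generating link. The implementation is cross-checked against
statsmodels `Logit` to 1e-6 in the tests; statsmodels is deliberately not
used as the fitting engine so the optimism bootstrap can refit thousands
of resamples cheaply.

## Validation metrics

* **Brier score** — mean of (pᵢ − yᵢ)²; computed on recalibrated
  probabilities by default (configurable to original).
* **SMR** — observed deaths / Σ original published-model probabilities
  (the "development set" expectation; recalibrated probabilities would
  make the SMR identically 1 on training data). The 95% CI treats the
  observed count as Poisson with mean equal to the expectation (Byar's
  approximation); a patient-resampling bootstrap CI is available as a
  cross-check.
* **AUC** — Mann-Whitney estimator via midranks (ties counted ½).
  Internal validation follows Harrell's optimism bootstrap: refit the
  score-logit on each of n_boot = 1000 resamples, optimism = mean
  (resample AUC − refit-model AUC on the original sample), corrected
  AUC = apparent − optimism; CI = percentile interval of resample AUCs
  (bias-corrected-accelerated intervals are out of scope). Single-class
  resamples are redrawn and logged. For a univariable monotone refit the
  per-resample optimism is zero in expectation, so the corrected value
  equals the apparent value up to Monte-Carlo noise — the tests assert
  the property with that tolerance.
* **DeLong comparison** — paired structural-components covariance of two
  Mann-Whitney AUCs with a two-sided normal p-value; a zero-variance
  difference (identical or rank-equivalent predictors) reports z = 0,
  p = 1. The components are computed by the midrank identity and verified
  in tests against an exact leave-one-out pseudovalue oracle.
* **Hosmer-Lemeshow** — equal-frequency risk groups (ties kept together),
  χ² summed over deaths and survivors, dof = g − 2 (g − 1 available via a
  flag for external-validation use), upper-tail χ² p-value. 10 groups by
  default; the tabular report uses 5 ("quintiles of risk" layout).
* **Youden operating point** — candidate cutoffs are midpoints between
  consecutive distinct score values (half-integers on integer scores);
  score ≥ cutoff predicts death; ties in J break to the smallest cutoff.

## Pipeline

`run_study` runs ingest (or simulate) → eligibility → imputation →
scoring → recalibration → metrics for 2 scores × 2 outcomes ×
(overall + age-band + hospital slices). Recalibration is fit once per
(score, outcome) on the full analyzed cohort and reused in subgroup
slices — subgroup rows are evaluation slices, not refits (the plausible
alternative, per-subgroup refits, would change subgroup calibration
statistics but not discrimination). The DeLong comparison is computed on
the full cohort per outcome. A subgroup with a single outcome class is
reported as not estimable and the run continues. All randomness flows
from one master seed expanded per stage (`SeedSequence` on a CRC of the
stage name), making reruns byte-identical.

Whether Brier and Hosmer-Lemeshow consume recalibrated or original
probabilities is genuinely underdetermined in external-validation
practice; the defaults are recalibrated for both (SMR always original)
and both choices are configuration-overridable.

## Imputation

Fully conditional specification ("chained equations"): initial marginal
draws, then 10 cycles (configurable) over variables in ascending
missingness order. Continuous variables get a predictive draw from an
OLS linear model plus Gaussian residual noise — not predictive-mean
matching, whose extra fidelity is unverifiable here and unnecessary for
the contract; draws are clamped to the variable's observed range so the
scoring engines always see physiological values; GCS is rounded to an
integer in [3, 15]. Categorical variables (pupillary response) get a draw
from a multinomial logistic conditional with a marginal-frequency
fallback on failure. One completed dataset (m = 1) is produced: the
analysis mirrors single-cohort tabular reporting rather than pooled
multiple-imputation inference, so Rubin pooling is out of scope. The MCAR
tests verify observed cells are untouched, imputed-cell means sit within
3 SE of observed-cell means, and identical seeds reproduce identical
completions.

## Synthetic cohort generator

The generator is the package's study-conditions definition, not a tuning
dial. Defaults: n = 3000 admissions with 216 planted eligibility
violators (half sub-2-hour PICU stays, half sub-24-hour follow-up),
leaving 2784 analyzable; PICU mortality target 12.14% and in-hospital
15.58%; PICU death drawn from logistic(−3.056 + 0.174·S) where S is the
PRISM-3 total computed by the scoring engine itself (so the link is
recoverable downstream); in-hospital death is PICU death OR an
independent score-linked ward event whose intercept is root-solved to the
in-hospital target; 11.3% MCAR missingness over the imputable variables.

A single latent severity factor z ~ N(0,1) shifts consciousness (GCS),
pupillary reaction, blood pressure, oxygenation, acid-base status and
laboratory values jointly; skewed labs are log-normal. The physiological
response saturates at z = 2.6 (beyond that, measured variables stop
deteriorating), which keeps the extreme score tail realistic. Loadings
were fixed once so that the default scenario lands in the reference
regime — implied PICU mortality ≈ 0.125 under the fixed link (within half
a binomial SE of the 12.14% target at n = 2784) and apparent PRISM-3 AUC
≈ 0.80 — and are exposed in the scenario for sensitivity analyses.

What the generator deliberately does **not** emulate: survivor scores
floor near 0–2 rather than the ~5 median of a real mixed PICU population
(with the link, the prevalence and AUC ≈ 0.8 all fixed, a sharper score
distribution is forced); missingness is MCAR only; hospitals A and B are
exchangeable labels without case-mix differences; diagnoses are category
labels, not ICD-10 codes. Consequently, passing tests demonstrate the
statistical machinery — not that any real population is calibrated to
these scores, and not the magnitudes of real-data SMR/Brier values, which
depend on how far the local population sits from the development sets.

## Problem sizes and numerical choices

The test suite runs the coverage checks at the full analysis size
(n = 2784; 100–200 outcome redraws) and the end-to-end
simulate→mask→impute→score→refit recovery at 25 replicates; bootstrap
tests use 150–200 resamples where the default 1000 adds nothing to the
property under test (the pipeline default remains 1000). Probabilities
are computed with sign-split logistic evaluation; log-likelihoods with
`logaddexp`. Equal-frequency grouping uses a stable mergesort so tied
predictions stay together deterministically.
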