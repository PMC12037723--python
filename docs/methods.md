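# Methods

## The fusion model

The package treats classifier fusion as a multi-criteria decision problem.
Each of the seven base classifiers is an *alternative*; its six validation
metrics (AUC, F1, accuracy, precision, sensitivity, specificity) are the
*criteria*.  TOPSIS scores each alternative by its relative Euclidean
closeness to the positive ideal solution (coordinate-wise best over the
seven models, in a column-normalised and index-weighted criteria space)
versus the negative ideal solution (coordinate-wise worst).  The closeness
coefficients, normalised to sum to one, are the fusion weights α; the
fused risk estimate is the convex combination of the seven positive-class
probabilities, thresholded at 0.5 (the threshold comparison is `≥`, so the
positive class wins the boundary).

Assumptions worth stating:

- All six metrics are treated as *benefit* criteria (larger is better), so
  the default orientation uses the metric matrix as-is.  A `cost_transform`
  orientation (per-column `max − x`) is retained behind a flag for audits;
  it reverses the model ordering and is not the default because closeness
  should reward the better-performing models — on the shipped reference
  matrix the benefit orientation assigns the largest weight to the best
  sub-model (GBDT) and the smallest to the weakest all-rounder (SVM).
- Index weights default to uniform 1/6: no metric is privileged.
- The weights are estimated on the *internal validation* split — the same
  data later used to report fused performance.  That mirrors the intended
  development workflow; external cohorts are the honest test of the fused
  model.
- TOPSIS closeness is not guaranteed monotone in single-metric
  improvements; this is a known property of the method, not a defect of the
  implementation.

Degenerate input: if all seven rows are identical, PIS = NIS and closeness
is 0/0; it is then defined as 0.5 for every model, giving uniform weights —
the only symmetric completion.

## Preprocessing cascade

Order: missing-rate filter → Boolean-variance filter → correlation filter →
imputation tournament → entropy-ranked stepwise selection → SMOTE →
min-max scaling.  Boundary semantics are literal: *greater than* 30 %
missing and *more than* 90 % agreement are strict; correlation *not less
than* 0.7 is inclusive.

- **Correlation filter.** Pearson correlations are computed
  pairwise-complete (the filter runs before imputation); pairs with fewer
  than 3 complete observations are skipped and logged.  Flagged pairs are
  processed in descending |r| with name-pair tie-breaks, skipping pairs
  whose member is already gone — a deterministic rule where none is
  canonical.  "Keeps the better predictor" is operationalised as the larger
  direction-free univariate AUC of the raw feature value (`max(A, 1−A)`);
  the comparison function is injectable for alternatives such as a
  one-feature logistic fit.  Ties keep the alphabetically first member.
- **Imputation tournament.** Four candidates: sklearn's k-NN imputer; two
  chained-equations imputers written here (conditional model per column
  type — logistic/linear or k-NN classifier/regressor; mean/mode
  initialisation, five refinement sweeps, conditional-mean updates, one
  completed dataset, no posterior draws); and sklearn's iterative imputer
  with a ridge conditional.  The ridge penalty defaults to `1e-6` — a
  stability-level value giving near-OLS conditionals while keeping exact
  collinearity solvable.  Each candidate's completed table is scored by the
  held-out AUC (25 % stratified holdout) of a fixed-seed gradient-boosted
  reference classifier; highest AUC wins, ties go to list order, a raising
  candidate is disqualified and logged.
- **SMOTE.** Implemented in-package: synthetic minority rows are
  `x + u(x_nn − x)`, `u ~ U(0,1)`, toward one of the k=5 minority-class
  nearest neighbours, until 1:1 balance.  Interpolated Boolean coordinates
  are snapped back to {0,1} so the data model stays valid.  Original rows
  are never modified.
- **Scaling.** Min-max fitted on the (post-SMOTE) training split; constant
  features map to 0; out-of-range validation/external values clip to
  [0,1].

## Entropy-ranked selection

Feature entropy is Shannon entropy in bits over equal-frequency bins
(default 10) for continuous features and over the two categories for
Boolean features.  Equal-frequency binning is robust to the heavy-tailed
lab distributions typical of EHR data, with the consequence that most
continuous features score near `log2(n_bins)` and tie; ties break
alphabetically, so the ranking is deterministic.  The default direction is
`low_entropy_first` (lower entropy read as higher feature value); the
opposite convention is a flag, because neither is decisively better
grounded and the stepwise AUC curve — not the ranking — does the actual
selecting.  The chosen subset is the *first* size k maximising validation
AUC (smaller models preferred on ties); a failed fit at some k is recorded
as a missing point and skipped.

## Base ensemble

Canonical model order everywhere: DT, RF, XGB, LGBM, SVM, NB, GBDT.  Each
family is tuned by seeded random search (default 50 draws) over a modest
space with stratified five-fold CV scored by AUC, then refitted on the full
training split.  The default train/validation split is stratified 80/20.
The SVM is searched without probability estimates (AUC only needs its
decision function, which is rank-equivalent and much cheaper) and the
winning configuration is refitted inside a Platt-style sigmoid calibrator
so it can participate in probability fusion.

## Evaluation

AUC is the Mann–Whitney rank statistic with ties counted one half;
sensitivity/specificity/precision/accuracy/F1 derive from confusion counts
at the 0.5 threshold (precision of an empty positive set is 0, with a
warning).  Confidence intervals are percentile bootstrap (default 1000
patient-level resamples) — the minimal bootstrap reading, no BCa;
resamples lacking a class are redrawn with a capped retry, and the interval
is an error if more than half the resamples fail.  Decision curves use the
standard net benefit `TP/n − FP/n · t/(1−t)` against treat-all and
treat-none references; calibration tables use equal-width bins with empty
bins omitted.  Feature importance is aggregated over the five tree families
only (DT, RF, XGB, LGBM, GBDT) — a maximum-margin hyperplane and a
conditional-independence density model yield no per-feature weights — as
`Σ α_i · importance_i` with the raw α of the tree families (not
renormalised before the sum) and a final renormalisation to sum 1, which
makes the output scale-free either way.  Each model's native importance
vector is normalised to sum 1 before weighting.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes:
~21 % outcome prevalence; a sparse logistic ground truth (default five
informative Gaussian features with log-odds coefficients
(1.2, −1.0, 0.9, 0.8, −0.7), intercept calibrated per sample so mean risk
hits the target prevalence); skewed log-normal and Gaussian noise labs;
Bernoulli history flags including near-constant ones (p = 0.95, 0.93);
Gaussian-copula correlated pairs (both members Gaussian-marginal, so the
target Pearson r is hit directly); and MCAR missingness with three features
above the 30 % filter bound.  Outcomes are drawn before missingness is
applied.  Informative features are the alphabetically first continuous
columns, so recovery tests know their identity.  A multicenter variant
perturbs means/scales per center and optionally overrides prevalence while
sharing the ground-truth coefficients.

What it does *not* emulate: realistic joint lab distributions, MAR/MNAR
missingness (MCAR only by default), temporal structure, and label noise
from outcome adjudication.  Passing tests therefore demonstrate the
machinery is correct under the stated structure, not that any particular
clinical performance transfers to real cohorts.

## Problem sizes and numerical choices

The end-to-end regression test runs the full pipeline on a 3000-patient,
40-feature cohort with 10 random-search draws per family and 200 bootstrap
resamples — sizes chosen so the complete development loop, including the
imputation tournament and the stepwise curve, runs in a few minutes on one
CPU while leaving the sparse signal comfortably recoverable.  The bootstrap
coverage check uses 200 simulated datasets of n = 300 at 200 resamples, a
scaled-down design whose nominal-coverage band (90–99 %) reflects both
percentile-interval undercoverage and Monte-Carlo noise.  Weight
reproduction from the reference metric matrix is asserted to ±0.005 per
component, the resolution supported by its 3-decimal entries.  TOPSIS
arithmetic is validated against an independent straight-line implementation
to 1e-12.

## Known limitations

- The α weights are fitted on the same validation split that reports fused
  performance; nested validation would be needed for an unbiased internal
  estimate.
- Multiple imputation is run as a single completed dataset per method
  (m = 1, configurable); no Rubin pooling.
- Entropy ranking is signal-agnostic by construction; it orders the search,
  it does not find informative features by itself.
- No alternative MCDM schemes (VIKOR, AHP-weighted indices) and no
  per-index weight learning.
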