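# Methods

## The measurement being modelled

A GC–metal-oxide-sensor instrument separates the headspace volatiles of
a stool sample on a GC column and records the sensor's electrical
resistance every 0.5 s over a 40 min run (4801 readings). Compounds
eluting from the column transiently change the resistance, so the trace
is a chromatogram whose peak amplitudes reflect VOC abundances. Disease
effects of interest are multiplicative changes in those abundances;
nuisance structure includes slow baseline drift, retention-time jitter
between runs, and a between-batch sensor change that rescales and
offsets the whole trace.

## Synthetic cohort

The generator emulates that structure explicitly:

- **Trace model**: resistance = smooth drift (offset + linear trend +
  slow sine) + Σ Gaussian peaks + i.i.d. Gaussian noise, floored at a
  tiny positive value. Peaks are symmetric Gaussians; peak tailing is
  deliberately not modelled — it adds nothing the alignment or wavelet
  stages would exercise.
- **Peak library**: 24 peaks spread over 80–1700 s, amplitudes 1–6
  resistance units, widths 6–14 s (fixed, seeded library).
- **Per-sample variation**: each peak's log-amplitude gets N(0, 0.25²)
  scatter; each sample gets a global retention shift N(0, 2 s²) plus
  N(0, 0.5 s²) per-peak jitter; sensor noise sd 0.05 units.
- **Planted effects**: five peaks carry a +0.5 log-amplitude shift in
  all IBD groups (i.e. a 2-standard-deviation effect against the 0.25
  log-scatter); three further peaks carry a ±0.5 shift separating CD
  from UC. Follow-up (month-3) samples retain 50% of the baseline
  effect, so the baseline-vs-follow-up contrast is also non-null.
- **Batch structure**: the validation batch is distorted by gain 1.3,
  offset +2 units and a +4 s global retention shift, mimicking a sensor
  change between batches.
- **Cohort layout** (defaults): training 26 CD + 18 UC + 4 IBDU with 48
  matched controls and 23 follow-ups; validation 16 CD + 10 UC + 2 IBDU
  with 28 matched controls and 14 follow-ups; 152 baseline samples and
  37 follow-ups in total. Matching is exact on sex and site with age
  within ±0.5 years.
- **Faecal calprotectin** is drawn from group-specific log-normals
  (control median 30 µg/g, IBD median 600 µg/g, log-sd 1.0),
  independent of the chromatogram — FCP is a separate clinical
  comparator, not a function of the VOC profile. The defaults imply
  analytic sensitivity/specificity of about 81%/98% at the 250 cutoff
  and 96%/89% at 100.

What the generator does **not** emulate: compound identities and column
chemistry, heteroscedastic or autocorrelated sensor noise, peak
tailing, co-elution/overlap changing with temperature programme, and
site-level assay differences. Passing tests therefore demonstrate that
the pipeline recovers multiplicative peak-amplitude effects under
drift, jitter and batch distortion — not that it would reach any
particular accuracy on real clinical data.

## Preprocessing

Order is enforced (flags on each trace): baseline correction →
normalisation → alignment.

- **Baseline**: asymmetric least squares (Whittaker smoother with
  asymmetric weights; λ = 1e8, p = 0.01, 10 reweighting iterations,
  solved as a banded system). Corrected values are floored at 0. The
  upstream processing chain this mirrors does not pin an algorithm;
  AsLS is the package's own choice and is pluggable via configuration.
- **Normalisation**: division by the within-sample maximum, so the
  highest resistance is exactly 1; scale-invariant by construction.
- **Alignment**: one integer-tick shift per sample maximising
  cross-correlation with the pooled median trace (search window ±30 s),
  zero-filled at the edges; an opt-in piecewise mode aligns fixed
  segments independently. A single global shift addresses the dominant
  batch retention offset; warping is secondary for these traces.
- **Joint processing**: both batches are pooled for the alignment
  reference, then the validation partition is held back; no model ever
  fits on validation samples. All-zero (degenerate) traces are dropped
  with a logged warning rather than failing the batch.

## Wavelet features

The first 1800 s (3601 ticks) of each processed trace is decomposed
with a multilevel discrete wavelet transform (Daubechies-4, maximum
dyadic level = 9, symmetric padding). The concatenated coefficient
arrays [cA9, cD9, …, cD1] are truncated to exactly 3601 entries
(zero-padded if ever shorter). A 40 min run has 4801 ticks, so a
3601-length feature vector forces a windowing decision; the first
1800 s window is this package's explicit choice, and window, wavelet
family and level are configuration keys. The feature_id ↔ (band,
position) map is deterministic and also records each coefficient's
approximate elution-time centre, which is how selected features are
attributed back to peaks.

## Pipeline 1: screen → boruta ∪ RFE → classifier bank

- **Univariate screen**: two-sided Mann–Whitney U per feature (Welch t
  available), keep the 100 smallest p-values, ties broken by feature
  order. The rank test is the default because wavelet coefficients of
  sensor traces are not plausibly normal.
- **Boruta** (authored here): per iteration, a shuffled shadow copy of
  every undecided feature is appended, a random forest is fitted, and
  real features beating the best shadow importance score a hit;
  two-sided binomial tests on hit counts (level 0.05, Bonferroni across
  undecided features) confirm or reject; features still tentative at
  max_iter (default 50) are resolved by median importance against the
  median best-shadow importance.
- **RFE**: repeated elimination of the lowest-importance 10% under a
  random forest yields a full ranking; candidate subset sizes
  (default 2/5/10/25/50/100) are scored by stratified k-fold accuracy
  and the best (smallest on ties) is kept.
- **Union**: boruta ∪ RFE, ordered by the best rank either method gave.
- **Classifiers**: KNN (k = 5, clamped to the training size), PLS
  (2 components), RF (500 trees), LDA, and SVMs with RBF
  (γ = 1/p), linear and cubic-polynomial kernels, all at cost 1.
  Scale-sensitive estimators standardise internally with training
  statistics. All seven expose the same contract: a continuous class-1
  score (probability where available, decision value otherwise) —
  downstream thresholds only need a monotone scale.
- **Validation schemes**: k-fold CV (default 5), double CV, and LOOCV.
  Matched case–control pairs and baseline/follow-up pairs are kept in
  one fold for the k-fold schemes (grouped stratified folds) so
  within-pair correlation cannot leak; LOOCV is plain
  leave-one-sample-out. For CV/LOOCV the leakage policy — feature
  selection once on the full training partition ("outside", the
  default, matching a published-model workflow) or repeated inside
  every fold ("inside") — is an explicit configuration choice. DCV
  always reruns selection inside each outer training fold; its inner
  loop is the selector's own cross-validation (RFE subset-size choice,
  LASSO penalty choice). The frozen final model (selection + classifier
  fitted on the whole training partition) scores the validation batch.

## Pipeline 2: two-step LASSO

L1-penalised logistic regression over a 40-point penalty path
(C ∈ [1e-3, 1e2]), penalty chosen by 10-fold cross-validated deviance
(CV-minimum default, 1-SE optional); features with nonzero coefficients
are then refitted with unpenalised logistic regression whose
probabilities classify new samples. Standardisation always uses
training statistics only. An empty selection falls back to the weakest
penalty admitting ≥1 feature; perfect separation in the refit falls
back to a tiny ridge penalty (logged). By default the LASSO consumes
all 3601 features (it is an alternative to, not a consumer of, the
screen); `lasso_input="screened"` restricts it to the 100 screened
features.

## Reporting

Thresholds are Youden-optimal: the midpoint between adjacent distinct
scores maximising sensitivity + specificity, ties broken toward higher
specificity, verified against an exhaustive scan. Accuracy,
sensitivity and specificity carry 95% Wilson score intervals
(Clopper–Pearson optional); AUC is the rank-statistic value. FCP
predicts IBD when ≥ the cutoff (100 or 250 µg/g). PCA projections are
centred with a deterministic sign convention (largest-magnitude loading
positive); boxplot summaries carry a per-feature train-vs-validation
direction-consistency flag. `run_study` emits one summary row per
comparison × model on the validation batch, a parallel out-of-fold
training table, and per-comparison score/selection/PCA/boxplot CSVs.

## Calibration experiments and problem sizes

`gcvoc.experiments` measures operating characteristics on the
IBD-vs-control contrast (training n = 96, validation n = 56, no
follow-ups):

- **Null calibration**: 20 cohorts with all planted effects set to 0;
  validated SVML (LOOCV pipeline) and LASSO accuracies should average
  within ±0.08 of 0.5. Accuracy here is taken at the score's natural
  cutoff (0 for decision values, 0.5 for probabilities): re-optimising
  the threshold on the evaluation set itself adds ~+0.05 optimism at
  n = 56 that is a thresholding artefact, not miscalibration.
- **Leakage sentinel**: 5 null cohorts under DCV with selection inside
  each of 5 outer folds; outer-fold accuracy must not be inflated.
- **Signal recovery**: 20 cohorts at the default planted effects; a
  planted peak counts as recovered when the boruta ∪ RFE selection
  contains ≥1 coefficient whose time support (centre ± half the dilated
  filter length) overlaps the peak's ±3σ elution window.

These repeated-seed experiments use a reduced selector (100-tree
forests, boruta max_iter 25, RFE sizes 5/10/25/50 with 3-fold CV) and
the screened-input LASSO with a 20-point path and 5-fold CV; the
single-study defaults are larger (see above). The reduced settings are
the package's choice of experiment scale and are recorded alongside the
results.

## Numerical choices and tie-breaks

- All randomness flows from one master seed through named per-stage
  seed derivations (CRC32 of the stage name mixed into a SeedSequence);
  identical configuration gives byte-identical outputs, including the
  on-disk chromatogram text files.
- Ties are broken by stable feature/sample order everywhere (screen
  p-values, forest importances, union ranks).
- Alignment prefers the smaller |shift| on correlation ties; the Youden
  scan prefers the higher threshold on score ties.
- Constant features are dropped before LASSO with a warning; constant
  designs make classifiers fall back to scoring by the training class
  rate.

## Known limitations

- The alignment default is a rigid shift; strongly non-linear retention
  drift needs the piecewise mode, which is only coarsely segmented.
- Boruta importances come from Gini impurity; permutation importance is
  not implemented.
- Confidence intervals are binomial intervals on validation confusion
  counts; they ignore variance from the selection and training process
  itself.
- The synthetic generator's Gaussian, homoscedastic noise is a
  modelling choice, not a claim about the instrument.
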