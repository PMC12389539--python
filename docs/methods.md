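# Methods

This note documents the modeling conventions, the synthetic-data model, and
the numerically load-bearing choices in `shpred`.

## Problem setup

The unit of prediction is a 5-day CGM segment of 480 samples at 15-minute
spacing. A segment is positive iff its final sample coincides with the
onset of a severe-hypoglycemia (SH) event, defined as the first instant
glucose drops below 54 mg/dL in an episode with altered consciousness. The
final sample is removed before any feature is computed, so the classifier
sees data up to 15 minutes before the labeled instant — a 15-minute
prediction horizon.

## Preprocessing conventions

* All device sources of one patient are pooled; readings at exactly the
  same instant are collapsed to their mean.
* The 15-minute grid is anchored at each patient's first reading
  (per-patient anchoring; a global anchor would be equally defensible but
  couples patients' grids for no benefit).
* A grid value is interpolated linearly when the enclosing raw gap is
  ≤ 120 min; raw gaps > 120 min are eliminated and split the curve into
  separate uniform runs. The boundary (exactly 120 min) interpolates. No
  extrapolation beyond the first/last reading; runs need ≥ 2 grid points.
* SH onsets are snapped to the nearest grid point (one grid step at most —
  events farther than 15 min from any point of a run, i.e. outside it, are
  unusable and logged). A positive segment is emitted only when the run
  provides a full 5-day history before the onset; that window is then
  excised and each remaining stretch is partitioned left-to-right into
  non-overlapping 5-day negative segments, discarding leftovers shorter
  than 5 days. Multiple events are processed chronologically; an event
  whose history window would overlap an earlier event's excised window is
  skipped and logged. These rules make sample counts conserve exactly:
  positives + negatives + discarded = run total.

## Features

* Variability is the mean/SD ratio (inverse coefficient of variation),
  with the sample SD floored at 1e-6 mg/dL so constant segments stay
  finite.
* Band percentages count samples with 60 and 160 mg/dL belonging to the
  in-range band (below-range is strictly < 60, above strictly > 160), so
  the three percentages sum to exactly 100.
* The hypoglycemia frequency counts *episodes* — maximal runs of
  consecutive samples < 60 mg/dL — not samples, which would duplicate the
  below-range percentage.
* The trend flag compares the last sample with the sample 45 min (three
  grid steps) earlier, strictly: equality means "not descending". The
  endpoint flag is strictly < 54 mg/dL.
* Both PCA bases (whole 479-sample curve; final 20 samples = last 5 h) keep
  five components, mean-centered, with a deterministic sign convention
  (each loading vector's largest-magnitude entry is positive). Bases are
  fitted on training-fold segments only and applied to test segments;
  fitting them once on all data would leak test-patient curve shapes into
  training.
* Sex is encoded F = 1, M = 0.

## Evaluation pipeline

* Splits draw floor(0.8 · P) patients for training, independently k times
  (default k = 200; the bundled experiments use k = 50 to keep runs fast
  at unchanged precision of the medians).
* Robust normalization subtracts the training median and divides by the
  training IQR (linear-interpolation quantiles); zero IQR divides by 1.
  Boolean predictors pass through unscaled.
* Classifiers are a linear-kernel SVM (linear is also what the RFE ranking
  requires; RBF is available by config) or a random forest, both with
  class weights inversely proportional to class frequency — with ~30:1
  imbalance an unweighted fit would collapse to the majority class, and
  BCR is the stated selection criterion.
* Feature ranking: SVM-RFE by squared weights, random-forest impurity
  importance, or a Wilcoxon consensus (features ordered by the median rank
  of their two-sample rank-test p-values across random 80 % row
  subsamples). Consensus selection scores features by their top-s
  frequency across subsample rankings; ties break by mean rank, then fixed
  feature order. With s = 21 (the default, matching the best reported
  model) selection is the identity and is skipped.
* The decision threshold is 0 on the margin score by default. Because no
  clinically calibrated threshold exists, the evaluation can instead pick
  the BCR-optimal cutoff per split (`decision_threshold: "bcr"`), which is
  what the acceptance run reports.
* AUC uses the Mann–Whitney rank formulation with ties counted ½. PPV is
  undefined when no positives are predicted and is excluded from medians
  rather than imputed. Medians with IQRs are the headline aggregate; means
  are also emitted.
* The Kuncheva index is averaged over all unordered pairs of selected
  sets; it is undefined at s = 0 and s = N (and hence NaN when all 21
  features are used).

## SH event characterization

The event window walks back from the onset while samples are
non-increasing (plateaus count toward the descent) and forward to the
first local maximum above 70 mg/dL after the nadir (the 70 mg/dL floor
operationalizes "first glycemic peak"; windows without one are truncated
at the run end and flagged). Crossings of the 54 mg/dL threshold are
located by linear interpolation, consistent with the resampling
interpolation; duration is time strictly below 54 and the deficit area is
the trapezoidal integral of (54 − glucose) over below-threshold intervals,
so deficit ≤ (54 − nadir) · duration always. Groups are nadir < 45
(group 1, deep/long) and nadir > 52 mg/dL (group 2, shallow/short);
nadirs in [45, 52] are left unassigned, since the two definitions do not
cover that interval. Group contrasts use two-sided Mann–Whitney tests —
rank-based, matching the univariate screen's machinery.

## Shapley explanations

The value of a coalition is the background-averaged model score with the
coalition's features set to the instance's values. Exhaustive enumeration
(≤ 16 features) is exactly additive; the Monte-Carlo permutation estimator
is unbiased with error ∝ 1/√(n_permutations). The background set is the
training-fold feature table. Explanations attribute the continuous score,
not the thresholded label.

## Synthetic cohort model

The generator emulates the statistical structure the analysis assumes, per
patient: a baseline drawn from N(170.9, 33.3²) mg/dL, a 24-h sinusoid
(default amplitude 15 mg/dL, random phase), Gaussian-shaped meal
excursions (3/day, ~45 mg/dL), AR(1) noise (ρ = 0.8, marginal SD
12 mg/dL), values clipped to [20, 500] mg/dL, recording gaps
(0.25/day, 30–300 min, so a fraction exceeds the 2-h elimination
threshold), and non-severe hypoglycemic dips (0.5/day to 55–80 mg/dL) —
the clinical near-misses that make some negative segments end low and
descending, the substrate of false positives.

SH events (Poisson, default 1/patient) *replace* the background over their
window: a linear descent to 54 mg/dL over the configured pre-event descent
time, a symmetric trapezoid below 54 down to the sampled nadir whose total
below-54 time equals the sampled duration, then recovery to a peak above
the pre-event level. The splice is noise-free, so the recorded nadir and
duration are exactly the sampled ground truth. Durations are gamma with
the phenotype means/SDs (deep 161.3 ± 118.9, shallow 106.1 ± 87.2 min),
floored at 20 min. Shallow nadirs are normal truncated to (52, 54) mg/dL
so that onset (< 54) and group-2 membership (> 52) hold simultaneously.

**Deep-nadir dispersion is support-limited.** With every deep nadir
confined to (20, 45) mg/dL, a mean of 40.3 caps the SD at
√((45 − 40.3)(40.3 − 20)) ≈ 9.8 (Bhatia–Davis), below the nominal
10.3 mg/dL. The generator uses a moment-matched beta on [20, 45) with the
SD capped at 95 % of that bound (realized SD ≈ 9.1), the largest
dispersion the constraints admit; the resulting distribution is strongly
bimodal toward the band edges rather than bell-shaped.

What the generator does **not** emulate: insulin/carbohydrate/activity
dynamics, sensor-specific error profiles, behavioral feedback (patients
treating lows), or gradual sensor drift. Because synthetic SH events are
preceded by a long clean descent, the classification task is much easier
than on clinical data: passing signal-recovery tests demonstrates that the
pipeline extracts the signal it is pointed at and is leak-free at the
patient level — it says nothing about achievable clinical performance.

## Problem sizes used in bundled experiments

The packaged experiments and the acceptance run use 50 patients × 60 days
(≈ 330 five-day segments, ≈ 45–50 SH segments) with k = 50 patient-level
resamplings, and 30 patients × 40 days at 2 events/patient for phenotype
recovery — large enough for 3-standard-error parameter-recovery checks and
stable medians, and small enough that the full suite runs in well under a
minute per experiment.

## Known limitations

* The "constant trace" degenerate configuration requires switching off all
  five stochastic components *and* the hypoglycemic dips.
* Events within 15 min outside a run's boundary snap to its edge sample;
  events farther away are dropped rather than interpolated.
* The deficit-area definition is the documented trapezoidal one; no
  attempt is made to reverse-engineer alternative area conventions.
* `loo_deploy` uses the fixed (default 0) threshold, not the BCR-optimal
  one, since threshold optimization needs labeled test data unavailable at
  deployment.
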