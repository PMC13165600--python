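# Methods

`accelhar` classifies 1-second windows of raw triaxial accelerometry as
walking, running or jumping. The intended use is bone-health research:
mechanical-loading prediction equations are activity-specific, so
free-living accelerometer data must first be segmented by activity before
the right equation can be applied. This note documents the signal model,
the feature set, the training and evaluation procedure, the synthetic-data
generator, and the numerical conventions, together with the design choices
that were genuinely open.

## Signal model and windowing

A recording is a continuous stream of (ax, ay, az) triplets in
gravitational units (1 g = 9.807 m/s²), nominally 100 Hz from a body-worn
sensor with a ±16 g dynamic range, placed at the ankle, lower back or hip.
The y axis is the primary vertical axis. Activity labels are stored as
half-open sample-index segments `[start, end)`; windowing starts at each
segment's start, advances by the stride, and drops any trailing partial
window, so a segment of `len` samples emits
`max(0, floor((len − W)/S) + 1)` windows (W = window, S = stride, in
samples). Windows never span segment boundaries.

The default stride equals the window length (non-overlapping 1-s windows).
Overlap is exposed as a parameter: overlapping windows inflate the
apparent sample size through within-bout autocorrelation, and because the
train/test split is at the participant level the choice does not affect
leakage either way.

Out-of-range samples (> 16 g) are rejected by default; an explicit
clip-with-warning mode exists for exports with isolated spikes.

## The 54-feature vector

Each window yields 54 features (fixed order in
`accelhar.features.FEATURE_NAMES`):

| block | count | definition |
|---|---|---|
| time-domain, per axis (x, y, z) | 30 | mean, sd (n−1), cv, skewness, excess kurtosis, min, p25, median, p75, max |
| resultant magnitude | 2 | mean and sd of rᵢ = √(axᵢ²+ayᵢ²+azᵢ²) |
| spectral, per series (x, y, z, r) | 16 | dominant frequency, dominant magnitude, total power, median frequency |
| cross-axis correlations | 3 | Pearson r for (x,y), (x,z), (y,z) |
| orientation | 3 | roll, pitch, yaw from the low-pass gravity estimate |

Conventions that matter when comparing against other implementations:

* **cv = sd / max(|mean|, 10⁻⁶ g).** Horizontal axes are near zero-mean;
  the guard keeps the feature finite and bounded so the standardizer is
  well behaved.
* **Skewness and kurtosis** use central moments with n denominators;
  kurtosis is excess (normal → 0); an exactly constant series returns
  skew = kurt = 0 by convention. R's `e1071::skewness/kurtosis` type 1
  matches these.
* **Percentiles** use linear interpolation between order statistics
  (numpy's default, R's `quantile` type 7).
* **Spectral features** are computed on the mean-removed series over bins
  k = 1…⌊N/2⌋ — the DC bin is excluded, otherwise gravity would be every
  window's "dominant frequency". Dominant magnitude is maxₖ|Xₖ|/N; total
  power is Σₖ|Xₖ|²/N²; median frequency is the lowest bin at which the
  cumulative squared magnitude reaches half the total; argmax ties resolve
  to the lowest frequency. Whether the original pipeline included DC in
  total power is unknowable from the description; excluding it keeps
  `totpower = 0 ⇔ dommag = 0`.
* **Orientation** filters each axis with a 2nd-order Butterworth low-pass
  at 1 Hz, applied forward-backward (zero net phase) with a reflected
  ("even") edge extension of 9 samples per end — edge handling materially
  affects 1-s windows and is pinned as a module constant. With gravity
  estimate (gx, gy, gz): roll = atan2(gy, gz), pitch = atan2(−gx,
  √(gy²+gz²)), yaw = atan2(gx, gy). Yaw — rotation about gravity — is not
  observable from a static accelerometer; the reported value is a declared
  convention kept only to complete the feature set, and no claim is made
  that it matches any other implementation.
* The nominal feature list (10 time stats × 3 axes, 2 magnitude stats,
  4 spectral stats × 3 axes, 3 correlations, 3 angles) totals 50; the
  package reaches the canonical 54 by also computing the four spectral
  features on the resultant magnitude r — the most parsimonious
  composition consistent with the total, pinned in one constant.

## Splitting and preprocessing

The split is at the **participant level** (80% train / 20% test):
window-level splitting would leak participant identity, which these
features encode strongly. Participants are ranked by their fraction of
jumping windows, cut into quartile strata, and the test quota
(`round(0.2·n)`, largest-remainder apportionment across strata) is drawn
within strata, keeping class proportions close. Under a fixed protocol all
participants have identical composition and the procedure degenerates to a
simple random participant split — by design.

Preprocessing is fitted on training rows only: near-zero-variance features
are dropped (zero variance, or most-common/second-most-common frequency
ratio > 19 with < 10% distinct values — the standard 95/5 convention,
both thresholds configurable), then the rest are centered and scaled
(n−1 sd). Inside cross-validation the whole preprocessing is re-fitted on
each fold's analysis portion.

## Training and model selection

Three algorithms: random forest (500 trees fixed; tuned `mtry` =
predictors sampled per split ∈ [1, p], `min_n` = minimum points to split
∈ [2, 40]), SVM with RBF kernel (tuned cost ∈ 2^[−5,10], `rbf_sigma` ∈
10^[−4,0]), and KNN (tuned `n_neighbors` ∈ [1, 2·round(√n)]). Ten
candidate settings are drawn by a seeded Latin hypercube; the original
grids are not published, so the ranges are the package's own, wide enough
to bracket the usual optima for standardized features.

Cross-validation is 5-fold and **grouped by participant** (participants
shuffled once, dealt round-robin to folds), matching the participant-level
outer split and preventing optimistic tuning.

SVM class probabilities are a softmax over the one-vs-rest decision
values. This is an approximation — it is monotone in each class's own
score, so hard labels match the decision rule and within-class rankings
(hence one-vs-all AUC) are those of the margins — chosen over Platt
scaling, which requires an internal cross-validated refit per model fit.

The winning setting maximises mean CV ROC-AUC **compared at 3 decimals**,
with ties broken by mean CV agreement, then by the simpler model (smaller
`mtry`, smaller cost, larger `n_neighbors`). The rounding is load-bearing:
near the AUC ceiling many settings are separated only by ranking noise in
the 4th decimal, and a strict argmax can prefer a degenerate setting whose
margins rank perfectly while its hard-label accuracy is poor. Comparing at
the precision the metric is reported makes agreement the effective
discriminator among near-ceiling settings.

## Evaluation

The confusion matrix has predicted classes as rows and observed classes as
columns (fixed order walking, running, jumping) with a per-column
percentage view. Percent agreement is 100·trace/N. Cohen's κ =
(p_o − p_e)/(1 − p_e) with p_e from the marginals, unweighted (nominal
classes). One-vs-all ROC-AUC uses the rank (Mann–Whitney) formulation with
midranks for ties, per class, and the overall AUC is the unweighted macro
average — the per-class values are convention-free; the macro average is a
documented choice. Per-activity agreement and κ come from collapsing the
3×3 matrix to each class's 2×2 one-vs-rest table.

Permutation importance is computed on held-out test rows with the final
model: for each kept feature, the drop in percent agreement when that
column is shuffled, averaged over 10 independent seeded shuffles. On the
synthetic data the classes are separable through many redundant features,
so single-feature permutations often leave accuracy unchanged and
importances sit near zero — a property of the simulator's redundancy, not
a defect of the estimator (the test suite verifies the estimator on
constructed single-predictor problems).

## The synthetic-data generator

The study protocol (48 participants; per participant 9 walking, 6 running
and 22 jumping trials; three placements) is emulated with a seeded
generator, because the original recordings are not publicly deposited. Per
trial:

* **walking/running** — the vertical axis carries 1 g plus a half-sine
  impact pulse train (duty 20% of the cycle) at the trial cadence
  (walking 1.5–2.2 Hz at 0.3–0.8 g; running 2.4–3.2 Hz at 1.5–3.5 g);
  running adds a mid-cycle low-g dip (aerial phase) whose depth saturates
  with impact amplitude; horizontal axes carry correlated sinusoids at
  ~0.35/0.25 of the impact amplitude.
* **jumping** — cycles at 0.8–1.6 Hz contain a free-fall flight interval
  (resultant → 0 g; fraction 0.2–0.4 of the cycle) followed by a
  high-amplitude landing spike (3–7 g above gravity, duty 8%). The
  flight-plus-spike structure makes running and jumping the confusable
  pair, as in real data.
* Per-participant lognormal effects (σ = 0.1) multiply cadence and
  amplitude; white noise (sd 0.05 g) is added to all axes; placement
  scales impact amplitude (ankle 1.0, hip 0.7, lower back 0.6 — distal
  placements see larger accelerations).
* Trial durations: walking 4 s, running 2 s, jumping 3 s — the order of
  what instrumented bouts of a 10 m walkway (analysed over its middle
  4 m) and short jump trials yield. With 1-s windows this gives 114
  windows per participant and 5472 for the default cohort, a workable
  echo of the study's scale.

Half-sine pulses were chosen because they are band-limited with an
analytically predictable fundamental, so spectral-feature tests can assert
exact dominant frequencies. One global seed determines everything;
participant streams are spawned as `SeedSequence(seed, (participant,))`.

**What the generator does not emulate:** soft-tissue artifact, device
orientation drift, within-trial cadence variability, asymmetric gait,
stochastic jump timing, and any non-target activity. Its classes are
considerably cleaner than real data — the default cohort is separated at
≈100% by all three algorithms, where the original study reports 94–98%.
Passing the separability floor therefore validates the pipeline's
plumbing and the simulator's fitness for purpose, not field performance.

## Degenerate inputs and tie-breaks

Constant series: sd = cv = 0, skew = kurt = 0, zero spectrum (dominant and
median frequency fall back to the lowest bin, magnitudes 0), correlation 0
for a zero-variance axis. κ returns 0 with a warning when expected
agreement is 1. A class absent from the observed labels is excluded from
the macro AUC with a warning. Hard-label argmax ties resolve to the
earliest class in (walking, running, jumping). Windows shorter than the
filter padding (≤ 9 samples) are rejected for orientation features.

## Known limitations

* Results on synthetic data bound nothing about real accelerometry; the
  generator exists to make the pipeline testable, not to claim field
  accuracy.
* Yaw is reported but physically unidentifiable (see above).
* The SVM probability approximation yields well-ranked but uncalibrated
  probabilities; do not interpret them as calibrated class posteriors.
* Free-living data (unsegmented streams, activity transitions, non-target
  movements) are out of scope; the pipeline assumes labeled segments.
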