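# Methods

## Signal model and preprocessing

A session records one passive-stretch examination of a spastic elbow:
twin-axis goniometer angles θx, θy (deg) and myometer force (N) at
1000 Hz, surface EMG (mV) at 2000 Hz.  The physical elbow angle is the
Euclidean resultant √(θx² + θy²).  The cleaning chain is fixed and
order-exact: angle — median filter (order 5) then mean filter (order 5);
force — median, mean, then fix-zero levelling; sEMG — zero-mean
levelling, full-wave rectification, 4th-order Butterworth low-pass at
10 Hz.  Applying the chain twice is not idempotent; the pipeline applies
it exactly once per recording.

Choices the chain's description leaves open, and how they are resolved:

* **Fix-zero levelling** subtracts the mean of the first 100 ms of the
  session, assuming the recording starts at rest.  The baseline window is
  configurable (`baseline_window_s`).
* **The Butterworth envelope is zero-phase** (forward–backward
  `sosfiltfilt`), so the sEMG envelope is not lag-shifted relative to the
  kinematics — a lagged envelope would bias the "angle at maximum sEMG"
  features.  Residual negative ringing is clipped at zero.
* **Rate alignment**: the 10 Hz low-pass leaves no content near the
  500 Hz Nyquist of the target rate, so the envelope is decimated 2:1
  onto the 1000 Hz timebase by sample selection.

## Segmentation

A session contains six stretches — three slow, then three fast — and
grading uses only the fast ones (the catch is velocity-dependent).
Rises of the elbow angle are detected on a 50 ms-smoothed copy by
hysteresis on the angular velocity: sustained runs (≥ 25 ms) above 5% of
the session's peak velocity seed regions, which are extended outward
while the velocity stays above a 0.4% floor.  This is equivalent to
pairing alternating local minima and maxima, but it remains well defined
for staircase-like motion with rest plateaus, where interior maxima do
not exist.

Window boundaries are the **2% / 98% excursion crossings** between the
rest level before the rise and the hold level after it (both estimated as
patch medians, robust to noise).  A smooth stretch has zero velocity at
its true endpoints, so any boundary estimate there is ill-posed; the
crossing convention is the standard movement-onset definition and is the
same convention the synthetic generator uses for its ground-truth
boundaries, making recovery exactly testable.  Crossing levels are
floored at three times the estimated noise amplitude (from the
high-frequency residual of the angle) so sustained noise excursions
cannot fake an onset.

Spurious extra rises are pruned by prominence ranking; fewer rises than
expected is an error naming the count found.  Speed tags are positional
(first half slow) per the examination protocol, with a warning if the
measured peak velocities do not corroborate the tagging.  The default
detection prominence is 10°, scaled down to 40% of the session's angular
span for severely restricted sessions — a rigid (MAS 4) elbow moves only
a few degrees and must still be segmentable for the ROM rule to fire.

## Catch detection and features

The catch is the instant of maximum deceleration.  Differentiating a
1000 Hz signal twice amplifies sensor noise by ~fs², so acceleration is
estimated by a cubic Savitzky–Golay fitted derivative (window 101 ms;
velocity estimates use 25 ms).  A cubic fit reproduces constant-
acceleration segments exactly, which keeps the tie-break test (earliest
index on ties) meaningful; fitted derivatives extrapolate noisily at
segment edges, so peak-velocity estimates exclude the edge half-window,
and the catch search is restricted to the interior 90% of the segment
(guard fraction 5%).  A catch is always reported — for a non-spastic
stretch it is the ordinary peak movement deceleration, whose force ratio
(≈ 1) is itself the discriminative signal for MAS 0.

Feature conventions (17 unique features):

* Catch and argmax angles are measured as **excursion from the segment
  minimum**, so all angle/ROM ratios lie in [0, 1] and compare across
  patients regardless of the absolute goniometer mounting.
* The initial force is the mean over the first 5% of the segment; if
  levelling drives it non-positive it is floored at a small ε with a
  warning rather than producing an infinite ratio.
* "Average slope after X" features are ordinary least-squares slopes over
  the full post-event window.
* "Normalised" denominators are the within-segment maxima of the
  corresponding channel, making those seven features invariant to channel
  gain (asserted by test).
* Clinically the catch-force/initial-force ratio belongs to both the
  kinetic and physiological groups; the vector stores it once (kinetic),
  so the grouping metadata reports 8 + 6 + 4 members over 17 unique
  values.

## Dataset assembly

Training uses fast stretches only; MAS 4 rows are excluded from
classifier training entirely (their grade is a pure rule) and handled by
the cascade.  The 90:10 stratified split allocates per-class test counts
by largest remainder (ties broken in MAS order), which matches the
reference cohort's published total of 28 test rows from class totals
(72, 84, 66, 27, 21, 6); the published per-class test counts themselves
follow no single rounding rule and are treated as reference, not
contract.  The split is by stretch-row, as the published counts imply; a
subject-grouped split (`grouped_split`) is available for stricter
evaluation since same-subject rows on both sides inflate scores.
Standardisation (zero mean, unit variance, population std) is fitted on
the training partition only, after the split and before upsampling.
Random oversampling (ROS — seeded duplication to the majority count) is
the default balancer; SMOTE (convex combinations with one of k = 5
nearest same-class neighbours) is provided as the alternative.  Both are
implemented directly (the algorithms are a few lines each), with
scikit-learn's `NearestNeighbors` for the neighbour search.

## Classifiers and the cascade

Five baselines with fixed tuned hyperparameters: Gaussian naive Bayes
(variance smoothing 0.1203); decision tree (entropy, min leaf 3, min
split 6, best splitter, 8 features); random forest (gini, min leaf 3,
min split 6, 3 features, 25 trees); XGBoost (gbtree, γ = 0.1, learning
rate 0.1, min child weight 5, 100 estimators, softprob objective); SVM
(RBF, C = 15, γ = scale).  Grid-search ranges for re-tuning are exposed
(`DEFAULT_GRIDS`), scored by balanced accuracy under stratified k-fold;
balanced accuracy equals plain accuracy on balanced folds, which is the
relevant regime after upsampling.  A "splitter" setting exists only for
the decision tree — random forests have no such parameter and the grid
honours it for the tree alone.  XGBoost is wrapped for string MAS labels
via internal integer encoding.

The deployed model is the Logical–SVM–RF cascade: ROM < 10° (strict) →
MAS 4; else the SVM's vote is accepted iff it is MAS 1 or 3; else the
random forest's class probabilities are masked to {0, 1+, 2},
renormalised, and the argmax returned with ties broken toward the lower
(clinically conservative) grade.  The sub-models are ordinary 5-class
classifiers with post-hoc role restriction — the alternative reading
(specialised sub-models trained per role) is not adopted because the
restriction-by-masking needs no extra training data and keeps both
models' calibration shared.  Serialisation stores scaler, sub-models,
threshold, class sets, seed and a schema version; loading refuses a
mismatched feature schema.

## Synthetic study conditions

The generator emulates the examination protocol: rest plateau, three
slow stretches, three fast stretches, each a minimum-jerk rise with hold
and return.  Grade profiles respect the ordinal clinical structure —
catch at the end of the range for MAS 1, second half for 1+, first half
for 2; elevated tone, suppressed velocity and reduced range for MAS 3;
range below 10° for MAS 4; no catch and unit force gain for MAS 0.
Default parameters (ROM intervals, tone levels 3–16 N, force gains
1.35–2.2, peak velocities, noise levels ~0.1° / 0.08 N / 4 µV) are
synthetic fixture choices within physiologically plausible ranges, not
estimates of any clinical dataset.

The catch is planted as a Gaussian deceleration pulse (σ = 20 ms) at the
target excursion fraction, followed by an equal re-acceleration pulse
4σ later — the examiner pushing through the resistance — so the velocity
dip (70% of local velocity) is transient and the planted pulse is
symmetric, leaving the detected acceleration minimum unshifted under any
symmetric smoothing.  The force channel steps by the grade's gain just
before the catch; the sEMG is an amplitude-modulated 20–450 Hz noise
carrier with a burst at the catch.  Ground truth (boundaries by the same
2%/98% convention on the clean signal, realised ROM and catch fraction,
force gain) is recorded per stretch, so every pipeline estimate has an
exactly defined target.

**What passing tests show — and do not.**  Recovery and end-to-end tests
demonstrate internal consistency: the pipeline recovers what the
generator planted, and the cascade's structural advantage (the MAS 4
rule) is real — baselines trained without MAS 4 cannot exceed 5/6
accuracy on a balanced test set.  The synthetic profiles are far better
separated than clinical populations, where adjacent grades overlap,
catches are less stereotyped and sensor artefacts are richer; the
near-ceiling synthetic accuracies therefore bound nothing about clinical
performance.  The published clinical scores are instead verified at the
arithmetic level: integer confusion counts are uniquely reconstructed
from the per-class precision/recall rows (supports 7, 9, 7, 2, 2) and
the weighted F-measures recomputed from unrounded values, reproducing
every published baseline summary (0.56 / 0.67 / 0.75 / 0.79 / 0.81).
The published cascade table is self-inconsistent: its per-class rows
(n = 28) recompute to a weighted F of ≈ 0.90 and accuracy 25/28 ≈ 0.89,
while its printed averages (0.91) correspond to a 33-case tally; the
package reproduces the per-class rows and the 30-of-33 headline
arithmetic and documents the discrepancy rather than matching both.

## Numerical conventions

* Rounding for report display is half-up at two decimals (the convention
  under which the published tables are reproducible); weighted averages
  are computed from unrounded per-class values and rounded once.
* Zero-division in precision/recall/F yields 0 with an explicit flag.
* Count reconstruction searches TP ≤ support and predicted-count ≤ the
  test-set size, and errors on zero or multiple consistent solutions.
* All randomness flows from explicit integer seeds; per-session generator
  seeds are spawned from the master seed, so cohorts are bit-reproducible
  and sessions draw from disjoint streams.
* Problem sizes: the shipped end-to-end comparison uses 30 synthetic
  sessions per grade (540 fast stretches) and ten stratified splits;
  recovery tests use noise-free single-session cohorts.  These sizes give
  stable statistics while keeping the full suite fast.

## Known limitations

* The synthetic generator plants one catch per fast stretch at most; it
  does not model clonus (repeated catches), co-contraction artefacts, or
  examiner variability in stretch speed within a phase.
* The myometer yields force, not joint torque; no lever-arm or
  biomechanical modelling is attempted, matching the feature definitions.
* Segmentation assumes the protocol's 3 + 3 structure; sessions with a
  different stretch count need `expected_stretches` set explicitly.
* Feature-importance analysis (e.g. SHAP) is out of scope; the feature
  schema is stable so an external explainer can be applied to the stored
  models if desired.
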