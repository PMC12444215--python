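# Methods

`cmspose` automates the Constant–Murley Scale (CMS), a 100-point shoulder
function instrument: pain (15) + activities of daily living (20) + range of
motion (40, four 10-point items) + strength (25). Subjective components are
questionnaire scores consumed as validated numbers. Objective components are
computed from two sensing modalities: single images of functional postures,
reduced upstream to nine body landmarks by any human-pose-estimation
backend, and tri-axial accelerometer recordings of repeated shoulder
abduction from a phone strapped to the upper arm.

## Range of motion from pose landmarks

Nine landmarks are used — nose, both shoulders, both elbows, both wrists,
both hips — in normalized image coordinates (origin top-left, y down),
optionally with a relative-depth z channel. Images that do not show the head
and both hips (visibility below the detector confidence threshold, default
0.5) are ineligible and reported as such.

Each image is reduced to angles between vectors: all 9×8 = 72 directed
vectors between ordered landmark pairs are formed, and for every unordered
pair of distinct vectors the angle

θ = arccos( a·b / (|a||b|) ), cosine clamped to [−1, 1],

is computed in degrees. This gives C(72,2) = 2556 features per coordinate
mode and 5112 when the 2D and 3D blocks are concatenated. The enumeration is
lexicographic over a fixed landmark index table, so feature columns are
stable across runs and trained models are portable. The representation is
invariant to translation, uniform scale and (in 2D) image-plane rotation,
which removes camera framing as a nuisance factor. Coincident landmarks
(occlusion artifacts) produce NaN sentinels rather than aborting a remote
assessment; sentinels are median-imputed inside the model pipeline, and a
set with more than half its features missing raises a quality error naming
the collisions.

External rotation is classified over five classes (the four photographed
functional items plus class 5 = unable); an item scores 2.5 points when the
predicted class equals its item number, spreading the CMS's 10
external-rotation points evenly over the four items. Internal rotation is
classified over the six CMS hand-reach levels and mapped directly to
{0,2,4,6,8,10} points. Elevations are scored by direct angle measurement —
the angle between the upper-arm vector (shoulder→elbow) and the trunk-down
vector (shoulder→hip) on the declared affected side — banded on the CMS
30-degree ladder with upper-closed intervals so 180° is scoreable. Direct
measurement was chosen for elevations because the classification route only
exists for the rotation items; the elevation angle is an explicit geometric
quantity with no annotation ambiguity.

## Strength from inertial recordings

Sessions are 10 s at 50 Hz, two repetitions per subject. Processing:

1. **Filtering** — zero-phase (forward–backward) Butterworth low-pass,
   cutoff 10 Hz, order 8. Zero-phase application is used because scoring is
   offline and phase distortion would bias zero-crossing counts. The
   normalized cutoff is configurable independently of the physical cutoff.
2. **Windowing** — 2 s windows, 1 s step, retaining windows whose start is
   strictly below duration − window: starts 0–7 s, i.e. 8 segments of 100
   samples for the default session. (The naive enumeration would give 9
   windows; the strict-start convention is the documented behaviour.)
3. **Features** — per axis and for the Euclidean magnitude channel:
   mean, SD, RMS, min, max, range, skewness, kurtosis, mean-centered
   zero-crossing count, signal magnitude area (10 time-domain statistics),
   plus dominant frequency (argmax of the one-sided power spectrum excluding
   DC), total spectral power (normalized so Parseval holds against the
   time-domain mean square), band power in 0–3 Hz and 3–10 Hz, and spectral
   entropy in bits (5 frequency-domain statistics) — 60 features per
   segment. Conventions for degenerate inputs: constant segments have
   skewness/kurtosis 0; all-zero segments have dominant frequency 0 and
   entropy 0.

Segments are classified into strength classes 0–4 (dynamometer pound bins
[0,5), [5,10), [10,15), [15,20), [20,∞)). Per repetition, segment
predictions are combined by majority vote with ties resolved to the lower
class (conservative for a clinical instrument); the final class is the
maximum across repetitions, reflecting that dynamometry reports the best of
repeated efforts. A subject unable to reach 90° of abduction scores 0
unconditionally. Class→point mapping defaults to pound-bin midpoints capped
at the CMS's 25-point maximum ({2.5, 7.5, 12.5, 17.5, 22.5}; CMS awards
roughly one point per pound); `class_step` and raw-`pounds` mappings are
config-switchable because the convention is genuinely open.

## Classifier bank

Each task gets its own classifier chosen among six families: logistic
regression, k-nearest neighbors, decision tree, SVM, random forest,
AdaBoost. The pipeline is median imputation → PCA retaining 95% of variance
→ classifier, tuned by grid search under stratified 5-fold cross-validation
with a fixed seed; PCA and the grid refit inside each fold's training split,
so reported CV accuracy is leakage-free (verified by a permutation-null
test: with shuffled labels, CV accuracy stays within 3 binomial σ of
chance). Grid-search ties resolve to the first grid point in declared order.
Default grids are small: k ∈ {3,5,7,9}; tree depth ∈ {3,5,10,∅}; C ∈
{0.1,1,10} with RBF/linear kernels; 100/300 trees; AdaBoost with a
depth-3/5 tree weak learner (decision stumps cannot express 5–6-class
boundaries, and the weak-learner depth is tuned like any other capacity
parameter) and 50–200 rounds. PCA is applied without feature standardization
because all angle features share one unit (degrees); standardizing was found
to amplify noise-dominated directions.

Class imbalance is handled two ways, mirroring clinical data collection:
reference augmentation (healthy-volunteer exemplars of correct movement as
positive references; severely-impaired exemplars as negative references)
concatenated with provenance tags, and random minority oversampling —
seeded duplication with replacement until all class counts equal the
majority count, which never creates new distinct feature rows.

## Synthetic cohorts

The generator makes every stage testable without patient data.

**Postures** come from a stick-figure forward model: a fixed trunk with the
affected (right) arm posed per task and class — four external-rotation
postures (hand behind/on top of the head, elbow forward/back) plus an
arm-at-side failure posture; six hand-behind-back reach levels for internal
rotation; elevations at each 30°-band midpoint, constructed so the measured
elevation angle equals the target exactly. Landmark noise is isotropic
Gaussian; the default SD of 0.02 normalized image units represents a
few percent of image size, the typical jitter of modern pose estimators.
All templates pass eligibility and adjacent classes differ by more than 5°
in at least one angle feature, so classes are identifiable at zero noise.

**Abduction signals** are a deterministic oscillation model, not a
biomechanical simulation: gravity offset plus a sinusoid whose amplitude
(0.8–5.2 m/s², strictly increasing) and frequency (0.5–2.5 Hz on 0.5 Hz
bins, nondecreasing) grow with strength class, plus white Gaussian noise
(default SD 0.5 m/s²). Frequencies sit on 2 s-window FFT bins so spectral
features are unambiguous. The model's only job is to carry class-separable
time/frequency signatures of the kind the segment features capture.

All randomness flows from one cohort seed through numpy `SeedSequence`
streams with fixed per-task sub-stream ids, so cohorts are bit-reproducible.
Train and test splits use disjoint subject ids.

**What passing synthetic tests do and do not show.** The generator emulates
the statistical structure the pipeline assumes — class-conditional geometry,
strength-dependent oscillation, sensor noise, eligibility failures — but not
real-world difficulty: pose-estimator bias (correlated, pose-dependent
landmark error rather than isotropic jitter), anthropometric variation,
compensatory movement strategies, or off-bin movement frequencies. Perfect
noiseless recovery and high noisy accuracy on synthetic cohorts demonstrate
the pipeline's correctness and internal consistency, not clinical accuracy.

## Agreement statistics

Validation against human raters uses unweighted Cohen κ
((p_o − p_e)/(1 − p_e), p-value from the large-sample normal test with the
Fleiss standard error under H0), the one-way random-effects single-rater
intraclass correlation ICC(1,1) = (MSB − MSW)/(MSB + (k−1)·MSW) with an
F-test on (n−1, n(k−1)) degrees of freedom, mean (SD, n−1 denominator)
differences, and confusion matrices. κ bands follow Landis–Koch (poor ≤ 0 <
slight ≤ 0.20 < fair ≤ 0.40 < moderate ≤ 0.60 < substantial ≤ 0.80 < almost
perfect); ICC bands are unacceptable (<0.20), questionable (0.20–0.40), good
(0.41–0.60), very good (0.61–0.80), excellent (0.81–1.00), with the
(0.40, 0.41) gap mapped to questionable. Degenerate inputs (both raters
constant on one category; zero total variance) return NaN sentinels with a
warning rather than a misleading number.

## Problem sizes and numerical choices

Tests and the acceptance script use cohorts of 10 training and 4–6 test
subjects per class — enough for stratified 5-fold CV on every class while
keeping full six-family grid searches fast. Cosines are clamped to [−1, 1]
before arccos; arccos near ±1 amplifies last-ulp rounding to ~1e-6 degrees,
which bounds the representation's intrinsic precision. CMS totals are summed
as exact rationals so half-point external-rotation scores never drift.

## Known limitations

- The feature enumeration reproduces the 5112-feature count from the unique
  natural combinatorics (72 directed vectors, unordered pairs), but other
  orderings with the same count exist; models are only portable within this
  package's ordering.
- Elevation scoring assumes the camera views the movement plane laterally;
  out-of-plane camera placement biases the 2D angle.
- The strength class→point mapping is a declared convention (see above),
  not a reproduction of any published mapping.
- No temporal smoothing across video frames: single images are scored.
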