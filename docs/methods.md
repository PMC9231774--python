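# Methods

## The measurement problem

During table-top arm cranking the shoulder and elbow trace coupled cyclic
angle trajectories. Movement quality is characterised here by how tightly
the two joints are coordinated: the time lag between corresponding angle
peaks, the mean continuous relative phase, and the cross-correlation of the
two waveforms, alongside cadence, range of motion and peak angular
velocity. The package computes these from five sagittal markers (hand,
wrist, elbow, shoulder, hip) captured at 100 Hz, and pairs the analysis
with a synthetic generator so each estimator can be checked by parameter
recovery instead of against unavailable raw recordings.

## Angle conventions

All angles are degrees in the sagittal plane (x anterior, y superior; 3D
input is projected by dropping the mediolateral coordinate).

* **Shoulder** — signed angle from the downward trunk line (acromion→hip)
  to the upper arm (acromion→lateral epicondyle): 0° with the arm alongside
  the body, flexion positive to 180°, extension negative. Using the
  marker-based trunk line rather than lab vertical makes the angle
  invariant to trunk lean; with a vertical trunk the two coincide.
* **Elbow** — 180° minus the interior angle at the lateral epicondyle
  between the epicondyle→acromion and epicondyle→ulnar-styloid segments:
  full extension 0°, full flexion → 180°. This keeps values directly
  comparable to clinical passive-range measurements (full elbow flexion
  ≈ 140–150°).

The shoulder convention is discontinuous only at ±180°, which arm cranking
cannot reach; a guard warns if a series approaches it.

## The synthetic generator

A planar two-link arm (upper arm L₁, forearm L₂, hand marker a fixed
`hand_offset` beyond the wrist along the forearm line) is anchored at a
static acromion; the hand rides a crank circle of radius r at a
piecewise-constant cadence; the crank holds still during rests. Inverse
kinematics takes the elbow-down (posterior) branch, matching posture at a
table-top ergometer; the reachability and inner-workspace conditions are
validated up front and violations name the offending parameters. The trunk
is static by default (an optional sinusoidal sway exists, default 0). The
third coordinate is emitted as a constant 0 for format compatibility.

**Coordination ground truth.** The configured
`elbow_shoulder_phase_offset` (degrees of crank phase) is defined at the
joint-angle level: the elbow-angle waveform is evaluated at a shifted crank
phase and the wrist and hand markers are rebuilt by forward kinematics from
the unmodified epicondyle, so the shoulder-angle signal is untouched and
both segment lengths stay exactly rigid. Two details matter:

* Shifting all three distal markers together would shift *both* derived
  joint angles identically and produce no relative phase at all — the
  shoulder angle is computed from the epicondyle, so the epicondyle must
  stay on its baseline path.
* The natural (pure-IK) elbow and shoulder waveforms peak at different
  crank phases, so the elbow signal is additionally re-timed by that
  natural peak-phase offset. Offset 0 therefore means *peak-synchronous*
  coordination, and an offset of d° at cadence c makes the elbow-angle
  peaks lead the shoulder's by exactly d/360 × 60/c seconds — a closed-form
  ground truth for the lag and phase estimators.

With a controlled offset the hand deviates slightly from the crank circle
(the kinematic cost of perturbing one joint's timing); with
`elbow_shoulder_phase_offset=None` the generator emits the pure IK solution
and the hand lies on the circle to 10⁻⁶ mm, which is what the geometric
tests use.

Measurement noise is i.i.d. Gaussian per coordinate of each valid frame;
drop-out gaps are Poisson-placed contiguous runs per marker (occlusion
affects individual markers, not whole frames) with uniform lengths. Both
are reproducible under a fixed seed.

**Defaults** (declared placeholders — the study reports no anthropometry
or crank geometry): crank radius 125 mm, upper arm 300 mm, forearm 260 mm,
hand offset 70 mm, shoulder 500 mm above the hip, crank centre 380 mm
anterior and 70 mm below the acromion, session = five 120 s efforts with
30 s rests, sampling 100 Hz.

**What the generator does not emulate:** soft-tissue artifact and marker
jitter correlated in time, trunk and scapular motion strategies,
disease-specific weakness patterns, crank resistance/torque, and 3D
shoulder-girdle kinematics. Passing recovery tests therefore demonstrates
estimator correctness on idealised planar cycling, not robustness to every
artifact of real capture.

## Signal processing

* **Gap fill** — invalid runs no longer than `max_gap_s` (default 0.5 s)
  that are flanked by valid data are filled by a cubic spline through the
  valid samples and marked as repaired in provenance; longer or edge runs
  stay invalid.
* **Smoothing** — zero-phase 4th-order Butterworth low-pass (forward–
  backward), default cutoff 6 Hz: the cycling fundamental is ≈1 Hz, so the
  first few harmonics pass untouched while marker noise is suppressed. Runs
  shorter than the filter warm-up (15 samples) pass through with a
  provenance flag.
* **Angular velocity** — central differences on run interiors, one-sided at
  run boundaries, °/s.

## Feature estimators

* **Cycle peaks** — local maxima with prominence ≥ 10° thinned greedily
  (highest first) to a minimum separation of 0.4 s (admits cadences to
  150 cycles/min); peaks are never placed on gap-adjacent frames, and peak
  times are refined to sub-frame precision by a local parabolic fit whose
  window adapts to the cycle length (≈ ±1/8 cycle, minimum ±4 samples —
  wide enough to average marker noise, narrow enough for the quadratic
  approximation), which is what makes millisecond-scale lag recovery
  possible at 100 Hz under 3 mm marker noise.
* **Cadence** — (n_peaks − 1)/(t_last − t_first) × 60, using the inter-peak
  span rather than the window length to avoid edge bias; undefined (NaN,
  flagged) below two peaks.
* **Time lag** — each elbow peak is matched to the nearest unused shoulder
  peak within ± half a cycle; the mean of (t_shoulder − t_elbow) is
  returned, so positive = elbow leads; unmatched peaks are dropped and
  counted.
* **Mean phase angle** — each series is centred and amplitude-normalised
  cycle by cycle (its own peaks delimit cycles), band-limited to
  0.5–1.5 × the cycle frequency, and given an instantaneous phase by the
  Hilbert transform; each signal's phase is referenced to its own cycle
  peaks (phase at a peak := 90°, using interior peaks only because the
  analytic signal is unreliable within a cycle of the window edges); the
  relative phase is wrapped to
  (−180°, 180°] and the magnitude of its circular mean over the window
  interior (one cycle trimmed per end) is reported, in [0, 180]. The
  band-limiting and peak referencing are deliberate: a plain rectified mean
  of the raw Hilbert phase difference carries an irreducible
  waveform-shape bias (≈11° for perfectly synchronised crank-cycling
  waveforms, because the two joints' harmonic content differs), whereas
  this estimator recovers configured offsets to within ≈1.3° across the
  validation grid. At least 5 full cycles are required (NaN otherwise).
* **Signal correlation** — Pearson coefficient of shoulder[t] against
  elbow[t + k] over the frames valid at each alignment, maximised over
  integer-frame lags within ± one cycle (ties towards the smallest |lag|);
  the zero-lag coefficient is kept in provenance. Positive lag means the
  elbow series is delayed.
* **Range of motion / velocity** — extrema over valid frames; maximum
  absolute angular velocity per joint.

Windows follow the study protocol: 25 s from the start of efforts one and
five (placement configurable and logged); the published protocol states
25–30 s without placement, so the choice of the effort onset is this
package's own and is recorded in every manifest.

## Cohort statistics

Median (IQR) uses the linear-interpolation quantile definition (conventions
differ across software; this one is fixed and documented). The
function–strength association is plain OLS R² of the Oxford Shoulder Score
on right shoulder-flexion strength (the predictor is configurable); no
p-values are computed anywhere, matching the descriptive design. The
strength correlation matrix uses pairwise-complete deletion with the
pairwise n reported next to every coefficient — small cohorts cannot afford
listwise deletion.

The cohort generator draws a driver strength uniformly, builds the other
strength measures as scaled copies plus noise (yielding the strongly
inter-correlated battery typical of clinical cohorts), and generates OSS
and per-effort RPE from linear models in the driver with Gaussian noise,
clamped to their instrument ranges ([0, 48]; Borg [6, 20]). A helper
computes the OSS noise SD that realises a requested population R², used by
the recovery study (true R² ∈ {0.2, 0.5}, n = 15, 200 seeds — the regime of
the reported associations). Note that OLS R² at n = 15 carries a known
small-sample inflation of order (1−ρ²)(1−2ρ²)/n ≈ 0.03 at ρ² = 0.2; the
recovery study measures the estimator as used, so its mean estimate sits
slightly above the population value.

## Unusable recordings

A recording is skipped when any required marker has fewer than 50% valid
frames inside an analysis window — an operationalisation of "insufficient
marker tracking" chosen here, not taken from the study. The demo cohort
deliberately gives 3 of its 15 participants drop-out heavy enough to
trigger it, so a full run reports 12 profiled / 3 skipped, deterministic
under the seed.

## Problem sizes

Validation uses 30 s recordings at 100 Hz (25 s analysis windows, ≈ 25–38
cycles), a 4 × 4 × 3 × 3 recovery grid (cadence × offset × noise × seeds),
20 random instances for each brute-force oracle, and 200 cohorts per R²
level; the demo cohort is 15 full 720 s sessions. These sizes were chosen
so the complete validation suite re-runs in a few minutes on one CPU.

## Known limitations

* Planar analysis only; abduction, rotation and scapular kinematics are out
  of scope.
* The relative-phase estimator assumes a dominant cycle fundamental; it is
  not meaningful for non-cyclic movement.
* The time-lag sign convention (positive = elbow leads) is this package's;
  published lag values without a stated convention cannot be compared
  sign-for-sign.
* Gap repair is interpolation, not measurement: repaired samples are
  flagged in provenance and long gaps are never invented.
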