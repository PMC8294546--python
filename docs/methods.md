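# Methods

This note documents the models, algorithms and parameter choices behind
`cowgait`, the assumptions they rest on, and what the synthetic-data tests
do and do not demonstrate about recorded animal data.

## Data model

A *trial* is one measurement of one cow: up to 11 synchronized 6-axis IMU
streams (accelerometer in m/s², gyroscope in deg/s, 200 Hz default) on a
common 0-based time axis, preceded by a ≥5 s standing-still calibration
window. Streams are stored as delimited text with a `# key: value` header;
floats are written with 17 significant digits so write∘read is the identity.
Accelerations declared in g are converted at ingest; all internal units are
SI plus deg/s.

## Gait event detection

In walk the distal limb (metacarpus/metatarsus) retracts through stance and
protracts through swing, so the *signed* mediolateral gyro separates the
phases: negative rate in stance, a positive raised bump in swing. The
detector

1. low-passes the mediolateral rate (4th-order zero-phase Butterworth,
   15 Hz default) — removes sensor noise without shifting events;
2. flags swing where the rate exceeds `swing_frac` (default 0.10) of a
   robust positive-rate peak (99th percentile); runs shorter than 100 ms are
   discarded, as are streams whose peak never reaches 30 deg/s (no gait);
3. refines **claw-off** to the nearest negative→positive zero crossing of
   the rate within ±50 ms of the swing-run start, accepted only when genuine
   retraction (rate below −threshold) precedes it — this rejects phantom
   events where a recording opens mid-swing;
4. refines **claw-on** to the onset of the accelerometer jerk burst (the
   hoof-impact landmark) within ±50 ms of the swing-run end: the largest
   first-difference of the acceleration norm, walked back over contiguous
   elevated samples, because the burst's largest difference can trail the
   contact by a sample or two. When no burst rises convincingly above the
   noise floor (5× the jerk MAD) the positive→negative rate crossing is used
   instead. Equidistant candidates break toward the earlier sample.

Events are sample-timestamped (no sub-sample interpolation); a stance is the
closed-open interval [claw-on, claw-off). On noise-free synthetic walks the
detector recovers every event within ±1 sample; at the default simulated
noise (0.5 m/s² accel, 2 deg/s gyro) within ±10 ms, comfortably inside the
±30 ms the temporal analysis tolerates.

An earlier design thresholded the *absolute* rate at 10% of the per-stride
peak. Because the stance-phase retraction sweeps ~70° per stride, stance
rates reach 35–70% of the swing peak and an absolute threshold cannot
separate the phases; the signed-rate formulation keeps the same physical
discriminant and the same 10% fraction while actually working.

## Stride segmentation and regularity screening

Strides run between consecutive LH claw-ons. A stride lacking a claw-on for
any limb is flagged `incomplete limb coverage` (this is also the mechanism
behind unequal per-limb stride counts: a limb without a claw-on in the
window simply yields no stance record).

The regularity screen operationalizes interval selection that would
otherwise be done by eye on video: a stride is excluded when any limb's
stance duration deviates from that limb's centered running median (window 9
strides) by more than 25%, or when the instantaneous support count reaches
0 or 4 limbs for longer than 50 ms. Contiguous included runs are capped at
4 per measurement, keeping the longest. All thresholds are configurable.

## Temporal parameters

Per stride: one stance record per limb (the stance whose claw-on falls in
the window), one LH stride record, and support-phase records from a sweep
over all stance boundaries. "Bipedal" and "tripedal" are read as *exactly*
two and three limbs grounded, so the instantaneous configurations partition
the stride and the summed configuration durations conserve total limb-stance
time (verified as an invariant, and against an independent 1 ms
rasterization oracle). Segments never straddle stride boundaries (an LH
claw-on is itself a stance boundary); each maximal constant-configuration
segment is attributed to the stride containing its midpoint, and
same-configuration segments within a stride are summed. Quadrupedal,
single-support and front/hind-pair configurations are recorded but flagged
`non-walk support configuration`.

Speed normalization divides every duration by the LH stride duration of the
same stride (a duty factor). Negative durations and duties outside [0, 1]
are flagged excluded, never deleted; the exclusion ledger in the report
conserves records per parameter (included + excluded = produced).

## Sagittal distal-limb angle

Orientation is tracked by a quaternion complementary filter: the quaternion
is propagated by the body-frame gyro rates each sample, and whenever the
accelerometer norm is within 1 m/s² of gravity the tilt is corrected toward
the measured gravity direction with weight 1−α (α = 0.99 gyro weight per
sample at 200 Hz, a ~0.5 s correction time constant). Gating suspends the
correction during hoof impacts and strong translational transients. The
filter initializes from the mean calibration-window accelerometer, which
defines the gravity reference; a missing calibration window is an error.
The sagittal angle is the rotation about the mediolateral axis
(`atan2(R02, R22)` of the body-to-world matrix), protraction positive; axis
index and sign are configurable because mounting conventions vary.

Per stride the angle is re-zeroed at the limb's midstance (temporal midpoint
of its stance) — so the maxima are relative to the midstance posture, not to
the standing calibration. Maximal protraction/retraction are the extrema
over the full stride window (an open design choice; taking them over swing
only would change nothing on the synthetic trajectories, where the extrema
sit at claw-on/claw-off). Records with non-positive protraction or
non-negative retraction maxima are flagged by the sign rule.

## Vertical displacement

Acceleration is rotated into the gravity-aligned world frame with the same
complementary filter, gravity subtracted, and the vertical channel is
integrated twice per LH stride (trapezoidal). Drift removal is *cyclic*:
after each integration the endpoint-to-endpoint ramp is removed (the true
velocity and displacement are periodic over a gait cycle, so any net change
across the cycle is drift) and the segment is zero-meaned. A least-squares
linear detrend would be wrong here — a sinusoid over one period has a
nonzero best-fit slope, and removing it distorts the harmonic content; the
ramp formulation recovers noise-free synthetic sacrum curves with per-stride
correlation > 0.999 and peak-to-peak amplitude error < 5%. Strides shorter
than 0.3 s or longer than 3 s are skipped with a warning.

Each stride's core (claw-on to claw-on) is linearly interpolated onto a
0–100% scale; the ±10% of stride duration either side is kept as separate
leading/trailing blocks for display, outside the 100-sample scale. (Whether
the padded 120% or the core stride spans the 100 points was genuinely
ambiguous; normalizing the core reconciles figures labeled 0–100% of stride
with padding described separately.)

## Curve statistics

A curve set (per limb for angles, per cow × location for displacement) is
summarized by the pointwise median, the pointwise median absolute deviation
about it, and the *most typical curve*: the member minimizing the summed
pairwise distance to all other members. The distance is RMS over the 100
samples by default (mean absolute available); "difference" could also be
read as distance to the median curve, but the pairwise reading is the
stricter one and both agree on well-behaved sets. Ties break toward the
earliest stride. Mean claw-on/claw-off timings per limb, as % of stride,
annotate the curves with the footfall pattern.

## Inference

Group medians get percentile-bootstrap CIs (default B = 2000, 95%),
resampling at stride level within group; a cow-level cluster bootstrap is
available by flag since stride-level resampling understates between-cow
variance when pooling cows. Empirical coverage for the median of a
symmetric distribution at n = 200 is 93–95% over 500 Monte-Carlo
repetitions — the usual slight anti-conservatism of the percentile method.

Limb differences use a linear mixed model per parameter (REML, via
statsmodels MixedLM): response ~ 0 + group (+ stride-duration deviation from
its median, omitted for duty responses, which are already speed-normalized)
with a cow random intercept. Group coefficients are then group-level
estimated means at the median stride duration; the report carries their 95%
CIs and a pairwise CI non-overlap flag rather than p-values. Bootstrap and
mixed-model intervals answer different questions (marginal median vs
model-based mean) and are labeled accordingly. A singular fit or single-cow
data set falls back to group-wise bootstrap, with the method recorded.
Residuals and random-effect estimates are exported for external diagnostics
in place of rendered QQ plots.

## The synthetic walk generator

The generator emulates the statistical structure the analysis assumes, with
defaults set to the study conditions the package validates against:

- **Footfalls**: lateral sequence LH → LF → RH → RF at quarter-cycle phase
  offsets (configurable, since real cows deviate); stride duration 1.33 s;
  per-limb duty factors LF 0.68, RF 0.69, LH 0.64, RH 0.64 — front stance
  ~0.91 s, hind ~0.85 s. Independent Gaussian jitter (default 15 ms SD) on
  every stance boundary; a draw that would invert an on/off pair is redrawn
  up to 20 times with a warning, then refused.
- **Limb angle**: through stance, protraction-max → 0 (midstance) →
  retraction-max via two monotone smoothstep quarters; through swing a
  raised cosine back to protraction-max. The trajectory is C1 (piecewise
  with zero-slope junctions), its per-stride extrema are exactly the
  configured values (defaults: reference walk medians, e.g. LF +25°/−46°,
  LH +24°/−29°), and its derivative is emitted as the mediolateral gyro
  channel, so trapezoidal integration recovers the angle to < 0.1°. A
  strictly constant-slope stance would make the emitted rate discontinuous
  and integration drift ~0.15°/stride, which is why the smoothstep family
  was chosen. The accelerometer sees gravity rotated by the same angle plus
  a decaying 40 Hz impact burst (20 m/s², τ = 20 ms) at each claw-on — the
  landmark the event detector snaps to.
- **Upper body**: vertical displacement per location is
  `h1·cos(2π(u−φ1)) + h2·cos(4π(u−φ2))` on the (jittered) LH stride
  coordinate u, with phases given as the stride fraction of the peak.
  Defaults phase the sacrum and tuber coxae to peak near the hind-limb
  midstances (25/75% of stride; the TC's stride-frequency term makes the
  ipsilateral peak the higher one) and the withers near the front midstances
  (0/50/100%); amplitudes give ~45–50 mm trunk peak-to-peak and ~90 mm at
  the TC (the larger text-reported TC excursion was preferred over the
  table's mm convention where the two disagreed). Head and collar add slow
  sinusoidal wander. The emitted vertical accelerometer channel is gravity
  plus the exact second derivative.
- **Noise**: white, 0.5 m/s² and 2 deg/s by default — deliberately coarse
  for a MEMS IMU, so recovery tolerances are conservative.
- A single seed governs all randomness; identical seeds give byte-identical
  pipeline reports.

**What the synthetic tests do not show.** The generator has planar limb
motion, no soft-tissue artifact, no sensor-mount wobble (except the collar
wander), no turning, halts, or irregular gait beyond boundary jitter, and
its impact burst is a clean template. Passing recovery tests therefore
demonstrates correctness of the algorithms under the stated signal model,
not field robustness on recorded cows; the detector's landmark logic and the
filter gating are designed for, but not validated on, messier real signals.

## Problem sizes

The end-to-end validation runs 5 synthetic cows × 42 strides (≈210 strides)
for temporal recovery, 25 strides for angle recovery and 30 for displacement
phase — sizes at which the recovered medians are stable to well within the
tolerances tested, while a full run stays in the seconds range on one core.

## Known limitations

- Support durations shorter than the event-timing error (~10 ms at default
  noise) are unreliable; the short ipsilateral bipedal phases are the first
  to suffer, consistent with their larger relative spread.
- The mixed model's CI non-overlap flag is a conservative screening device,
  not a calibrated test; with few cows the random-intercept variance widens
  group CIs even when the within-cow contrast is precise.
- Stride lengths and walking speed in meters are out of scope (no positional
  reference), as are joint angles, 3-D pose, and lameness asymmetry metrics.
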