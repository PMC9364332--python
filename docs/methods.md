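# Methods

This note documents the models, conventions and numerical choices behind
shoulderval: what the simulator emulates, how outcomes are defined and
extracted, how agreement is quantified, and where the genuinely open
design decisions were made.

## Orientation model and the X-Z′-Y″ sequence

Humerus-relative-to-thorax orientation is a rotation; joint angles are its
intrinsic Tait–Bryan X-Z′-Y″ decomposition.  Sign conventions (fixed here,
since upper-limb conventions vary between laboratories): positive X =
abduction, positive Z′ = vertical flexion, positive Y″ = external rotation
/ horizontal extension; the opposing movements are negative excursions of
the same channels.  Outcome extraction takes absolute ranges, so reported
ROM values are magnitudes.

The middle angle of any Tait–Bryan sequence is canonically confined to
[−90°, 90°], yet shoulder flexion routinely exceeds 90° (the default
VFLEX amplitude is 157°).  Two decomposition entry points deal with this:

* `euler_from_rotation` returns the canonical triple.  At |z′| within 0.1°
  of 90° the outer angles are not unique (gimbal lock); the tie-break sets
  y″ = 0, folds the indeterminate remainder into x, and flags the sample.
  This is deterministic and recomposes to the same rotation.
* `euler_series_from_rotations` returns a *continuous* channel
  decomposition for a trial, choosing per region between the two Euler
  solutions `(x, z, y)` and `(x+180°, 180°−z, y+180°)`.  A subtlety drives
  the design: a trajectory that passes *near* but not through the gimbal
  set has a mathematically continuous lift whose middle angle can never
  cross 90° — the outer channels instead swing by ~180° and the flexion
  trace reflects back below 90°.  Exported joint angles from motion-
  capture software do not behave that way; they keep the outer channels
  near their slowly varying anatomical values and let the middle angle
  pass the pole.  The tracker therefore fixes the branch per clear region
  (|cos z′| ≥ sin 25°) by outer-channel continuity across the pole gap,
  and inside a pole region picks per sample the branch closest to a linear
  bridge of the middle angle, with outer-channel continuity as a weighted
  tie-break.  Trajectories passing exactly through the pole decompose to
  machine precision; misaligned near-misses export a small (≤ twice the
  miss distance) kink in the middle angle and transient outer-channel
  swings confined to the pole region.  A start hint (the trial's known
  starting pose) selects the initial branch for trials beginning beyond
  90°, e.g. the PNF start pose.

## The simulator

### Movement profiles

Each trial is lead-in baseline (1.0 s) → outward phase → dwell at the
terminal pose (0.5 s) → reverse phase → tail (0.5 s).  The angular profile
is minimum-jerk by default (zero velocity and acceleration at both ends,
peak velocity 1.875·A/T), matching instructed, self-paced movement; a
raised-cosine alternative is available.  Ground-truth ROM equals the
profile amplitude exactly, which is what makes end-to-end parameter
recovery testable.

Defaults are anchored in published reference (optical) cohort values for
this movement battery: per-movement amplitudes and between-subject SDs
from the reference means ± SDs (e.g. ABD 160.9 ± 10.9°, ER 65.3 ± 12.8°;
PNF start/end poses −50.1/+19.2° frontal, +143.8/−27.3° sagittal,
−14.4/+55.8° transverse), and outward-phase durations chosen so the
minimum-jerk peak matches the reference peak angular velocities
(T = 1.875·A/PAV; e.g. ABD 3.33 s, HEXT 0.52 s).  ER/IR, which have no
published peak velocity, use durations consistent with their mean
velocities (0.72/0.60 s); PNF uses 2.5 s as a comfortable multiplanar
pace.  Per-subject amplitudes are normal draws truncated at 3 SD with a
2° magnitude floor (3 SD alone cannot prevent sign flips for the small
PNF components); per-subject pace varies by a truncated ±10% factor.

### Measurement-error model

Both systems observe the same ground-truth rotation series (500 Hz).  The
error model is applied at the angle level, since the wearable's sensor
fusion is a black box whose *output* errors are what a validation study
sees:

| mechanism | parameter | default (wearable) | emulates |
|---|---|---|---|
| misalignment | fixed random rotation of each segment frame | 4° | sensor placement / tilt, cross-talk |
| amplitude scale | per channel | x 0.75, z 0.93, y 0.85 | soft-tissue attenuation |
| static offset | per channel | 3/−4/5° | calibration-pose error |
| drift | random-walk SD rate | 0.3 °/√s | integration drift, slow magnetic disturbance |
| white noise | per sample | 1.0° | sensor/model noise |
| gyro noise | per sample on velocity | 2.0 °/s | gyroscope noise |

The reference model is 500 Hz with 0.2° noise and 1 °/s velocity noise.
Magnetic disturbance is not modelled separately — at the angle level it is
indistinguishable from drift plus offset.  The wearable scale defaults
reproduce the *order* of attenuation the validation literature reports per
plane; they are conditions of the simulated study, not fitted quantities.

Velocity channels are rendered from the scaled, drifting Euler rates of
the *unmisaligned* truth plus gyroscope noise.  Rationale: gyroscopes
measure body rates directly and bypass the orientation fusion — which is
exactly why velocity outcomes are reported as more robust than ROM for
such systems — and Euler-rate spikes from near-pole degeneracies are an
artifact of the angle representation, not of the gyro signal.  For streams
without velocity channels (e.g. files from other sources),
`angular_velocity` falls back to central finite differences.

## Preprocessing

Both streams are brought to 200 Hz: the 500 Hz reference is low-passed by
a zero-phase 4th-order Butterworth at 50 Hz (two passes of order 2) before
decimation; the 147 Hz wearable is linearly interpolated (error at these
rates ≪ 0.1% for band-limited movement).  No further smoothing is applied.
Synchronization maximizes the cross-correlation of the dominant channel's
velocity (lag searched within ±2 s; a normalized peak below 0.2 falls back
to zero lag with a warning) — cross-correlation is an assumption, as real
exports carry no hardware trigger, and can be disabled.  Baseline offsets
(mean over the first 0.5 s per channel) are subtracted; the removed
offsets stay attached to the series so the calibrated-neutral reference
remains recoverable.

## Outcome extraction

Segmentation: a movement phase is a sustained episode (≥ 100 ms) where the
smoothed |velocity| of the dominant channel exceeds 5% of its peak.
Detected edges are then refined on the raw |velocity| out to a floor —
the larger of 10⁻³ °/s and 3× the pre-movement noise level — which places
noiseless boundaries within ±1 sample of truth (the raw 5% crossing of a
minimum-jerk profile is systematically ~0.06·T late).  In the pipeline the
fragmentation is computed once per trial on the reference stream and the
windows reused for the synchronized wearable stream; independent
segmentation per stream is available but adds ±1-sample boundary jitter
between systems that contaminates the narrow MAV windows even in the
error-free limit.

ROM uses |terminal − baseline|.  The terminal angle is the mean over the
central half of the inter-phase dwell when one exists (≥ 8 samples);
the raw extremum of a noisy plateau is biased upward by ~2.5σ, which would
make bias recovery impossible at 1° noise, while a dwell mean is unbiased
and exact on noiseless profiles.  Without a dwell the signed extremum
within the outward phase is used (earliest sample on ties).

TROM sums the two opposing ROMs: for single-plane movements across the
subject's two opposing trials, for PNF within the trial per channel.  The
PNF start/end components are referenced to the calibrated neutral
(restored from the stored baseline offsets), so static calibration errors
propagate into PNF ROM — a deliberate modelling consequence that matches
the empirically poor multiplanar agreement.

PAV is the min/max velocity over outward ∪ reverse (reported magnitude:
the larger extremum); it is extracted for the six single-plane flexion/
abduction-type movements only (not ER/IR or PNF, where it is not a study
outcome — overridable).  MAV averages |velocity| over the first and last
25% of each phase (the fraction is configurable; the source analyses say
only "narrow windows"); PNF reports start-side (outward-early +
reverse-late) and end-side combinations per channel.

## Agreement statistics

Differences are `reference − test`, so positive bias means the wearable
under-reports.  LoA use the sample SD (n−1).  The ICC is computed from the
two-way ANOVA mean squares; "two-way mixed, single measures" leaves the
consistency/absolute choice open, so consistency ICC(3,1) is the default
and the absolute-agreement form is a flag.  Band edges are half-open:
0.5/0.7/0.9.  Heteroscedasticity — assessed visually in practice — is
automated as Kendall's tau between |d| and the pair means (rank-based,
appropriate at n = 24), with the plot-ready pairs returned.  RMSE is
computed over the per-subject scalar differences; by construction it
satisfies RMSE ≥ |bias|, so a printed table row violating that identity
cannot have been produced by this estimator on the same pairs — a useful
diagnostic when transcribing external tables.

## Numerical choices and edge cases

* Resampling grids start at the stream's t₀ with spacing 1/rate; with
  equal source/target rates interpolation is exact, making the null error
  model bit-transparent.
* Zero-variance paired data make the ICC undefined (raised as an error);
  flat streams make segmentation fail ("no movement detected") and the
  pipeline drops such trials listwise with a log entry, continuing the
  run.
* Config files round-trip losslessly through YAML; all randomness flows
  from `numpy.random.SeedSequence` spawns of one cohort seed, so full runs
  are byte-for-byte reproducible, trial files included.
* Problem sizes used by the test suite and acceptance script — 24-subject
  cohorts, 200 Monte-Carlo replicates for recovery, 10⁵ samples for LoA
  coverage — were chosen to put Monte-Carlo error well below each check's
  tolerance while keeping a full run around a minute.

## What the synthetic cohorts do and do not show

The generator reproduces the *structure* of a two-system validation study
(paired streams, shared ground truth, realistic amplitudes, rates and
error magnitudes) and therefore validates the pipeline: decomposition,
resampling, segmentation, outcome definitions and statistics are all
checked against analytic ground truth.  It does not reproduce real
soft-tissue dynamics (modelled as static scale + misalignment rather than
a skin-motion model), real magnetic environments, vendor fusion behaviour,
or human variability beyond amplitude/pace draws.  Synthetic agreement
values are consequently cleaner than empirical ones — ICCs for single-
plane ROM come out high even under substantial bias because the injected
errors are more systematic than real ones.  Passing tests demonstrate the
*method* is implemented correctly, not that any particular sensor is
valid.

## Known limitations

* The minimum-jerk profile has zero velocity at the dwell boundaries;
  trials without a dwell fall back to extremum-based terminals, which are
  noise-biased.
* PAV from 147 Hz streams carries a small (≲ 0.1 °/s) interpolation
  undershoot for the fastest, shortest movements — the resolution limit of
  linear interpolation at that rate.
* Cross-correlation synchronization assumes overlapping, transient
  content; perfectly periodic signals alias to within one period.
* ICC confidence intervals and test–retest reliability are out of scope
  (each condition is measured once per subject).
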