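# shoulderval

Method-comparison pipeline for validating a wearable inertial sensor (IMU)
system against marker-based optical motion capture (mocap) for active
shoulder kinematics — built around simulated cohorts, so every stage of
the analysis is testable against known ground truth.

## Who this is for

Movement scientists and biomechanists who compare a portable "test" system
against a laboratory reference and want the full chain — movement battery,
Euler-angle processing, outcome extraction, agreement statistics — as
reusable, tested code rather than a spreadsheet workflow.

## What it computes

A simulated cohort (default: 24 subjects) performs nine shoulder movement
conditions: abduction/adduction (ABD/ADD), horizontal flexion/extension
(HFLEX/HEXT), vertical flexion/extension (VFLEX/VEXT), external/internal
rotation (ER/IR), and a multiplanar diagonal pattern (PNF).  Humerus
orientation relative to the thorax is expressed through the intrinsic
X-Z′-Y″ Euler sequence (X = ABD/ADD, Z′ = VFLEX/VEXT, Y″ = HFLEX/HEXT and
ER/IR).  Each trial is observed twice: a 500 Hz low-noise reference and a
147 Hz wearable degraded by soft-tissue amplitude attenuation,
sensor-to-segment misalignment, static calibration offsets, random-walk
drift and white noise.

Both streams are resampled to 200 Hz (anti-aliased when reducing),
synchronized by velocity cross-correlation and baseline-offset-corrected.
Movement phases (outward, dwell, reverse) are detected by a sustained
velocity threshold, then per trial:

* **ROM** — terminal excursion relative to the starting position [°]
* **TROM** — sum of the two opposing terminal ranges [°]
* **PAV** — min/max angular velocity over the movement phases [°/s]
* **MAV** — mean |velocity| over narrow windows just after initiation and
  just before the terminal position of each phase [°/s]

Per movement × outcome, paired subject values yield the agreement table:

* Bland–Altman bias `mean(ref − test)` with 95 % limits of agreement
  `bias ± 1.96·SD(d)`,
* two-way mixed single-measures ICC — consistency form
  `ICC(3,1) = (MS_R − MS_E)/(MS_R + (k−1)MS_E)`, absolute form available —
  banded poor (< 0.5) / moderate [0.5, 0.7) / good [0.7, 0.9) /
  excellent (≥ 0.9),
* `RMSE = sqrt(mean(d²))`, which satisfies
  `RMSE² = bias² + (n−1)/n·var(d)`, hence `RMSE ≥ |bias|`,
* a Kendall-tau heteroscedasticity check of |d| against pair means.

## Worked example

```bash
python analysis/01_simulate_cohort.py --seed 1    # trials + manifest
python analysis/02_extract_outcomes.py            # summaries.csv
python analysis/03_agreement_tables.py            # agreement tables
python analysis/04_parameter_recovery.py          # recovery experiment
```

The ROM table of the seed-1 default cohort begins:

```
movement      outcome    n        ref mean+-SD       test mean+-SD     RMSE     ICC band          bias    upper; lower LoA
--------------------------------------------------------------------------------------------------------------------------
ABD           ROM       24       160.0 +- 11.9        120.2 +- 8.9     39.9   0.959 excellent     39.8          45.7; 33.9
ADD           ROM       24         35.3 +- 9.9         26.5 +- 7.5      9.1   0.962 excellent      8.8           13.5; 4.0
HFLEX         ROM       24        116.9 +- 8.3         99.4 +- 7.0     17.6   0.982 excellent     17.5          20.4; 14.7
PNF-X start   ROM       24         48.4 +- 9.8        31.9 +- 11.6     19.2   0.573 moderate      16.5          36.0; -2.9
```

Reading it: the wearable's frontal-plane attenuation (scale 0.75) turns a
160.0° reference abduction into 120.2°, a systematic bias of 39.8° — far
beyond any clinically acceptable error — while between-subject ordering is
preserved (ICC 0.96).  The multiplanar PNF components additionally absorb
the static calibration offsets (their start/end components are referenced
to the calibrated neutral), which is why their ICCs collapse first.  The
recovery driver confirms the pipeline is calibrated: with an injected
frontal scale of 0.7 it reports
`injected bias 48.27 deg; recovered 48.31 +- 0.13 deg over 20 cohorts`.

The same stages are available as a CLI (`shoulderval run|simulate|extract|
validate|report`) and as library functions (`shoulderval.run_pipeline`).

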