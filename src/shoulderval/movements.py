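"""Shoulder movement battery: labels, planes, channels, and realistic defaults.

The battery consists of eight single-plane movements (abduction/adduction,
horizontal flexion/extension, vertical flexion/extension, external/internal
rotation) and one multiplanar diagonal pattern (PNF) that travels from a
flexed/adducted/internally-rotated start pose to an extended/abducted/
externally-rotated end pose.

Euler channel mapping (intrinsic X-Z'-Y'' sequence, humerus w.r.t. thorax):

* ``x``  — frontal plane: positive = abduction (ABD), negative = adduction.
* ``z``  — sagittal plane (middle angle): positive = vertical flexion
  (VFLEX), negative = vertical extension.
* ``y``  — transverse plane: positive = external rotation / horizontal
  extension, negative = internal rotation / horizontal flexion.

Default amplitudes and between-subject SDs are the reference-system cohort
means of the validation study this pipeline emulates; outward-phase
durations are chosen so a minimum-jerk profile reproduces the corresponding
reference peak angular velocities (peak = 1.875 * amplitude / duration).
"""

from __future__ import annotations

from dataclasses import dataclass

CHANNEL_NAMES = ("x", "z", "y")
CHANNEL_INDEX = {"x": 0, "z": 1, "y": 2}


@dataclass(frozen=True)
class MovementDef:
    """Static description of one single-plane movement condition."""

    label: str
    plane: str
    channel: str                 # dominant Euler channel
    signed_amplitude_deg: float  # terminal position relative to neutral
    amplitude_sd_deg: float      # between-subject SD of the amplitude
    duration_s: float            # outward-phase duration at default pace
    opposing: str                # label of the opposing movement (TROM pair)
    pav_reported: bool           # peak angular velocity is a study outcome


SIMPLE_MOVEMENTS: dict[str, MovementDef] = {
    m.label: m
    for m in (
        MovementDef("ABD", "frontal", "x", +160.9, 10.9, 3.33, "ADD", True),
        MovementDef("ADD", "frontal", "x", -39.0, 12.9, 0.80, "ABD", True),
        MovementDef("HFLEX", "transverse", "y", -114.5, 10.5, 1.99, "HEXT", True),
        MovementDef("HEXT", "transverse", "y", +30.9, 10.6, 0.52, "HFLEX", True),
        MovementDef("VFLEX", "sagittal", "z", +157.0, 11.3, 2.99, "VEXT", True),
        MovementDef("VEXT", "sagittal", "z", -37.7, 10.0, 0.76, "VFLEX", True),
        MovementDef("ER", "transverse", "y", +65.3, 12.8, 0.72, "IR", False),
        MovementDef("IR", "transverse", "y", -65.0, 11.5, 0.60, "ER", False),
    )
}

# Multiplanar pattern: start pose (VFLEX/ADD/IR) -> end pose (VEXT/ABD/ER),
# expressed as signed channel values relative to the calibrated neutral.
PNF_LABEL = "PNF"
PNF_START_DEG = {"x": -50.1, "z": +143.8, "y": -14.4}
PNF_END_DEG = {"x": +19.2, "z": -27.3, "y": +55.8}
PNF_START_SD_DEG = {"x": 8.6, "z": 31.4, "y": 11.9}
PNF_END_SD_DEG = {"x": 14.8, "z": 38.7, "y": 22.7}
PNF_DURATION_S = 2.5

MOVEMENT_LABELS = list(SIMPLE_MOVEMENTS) + [PNF_LABEL]

# TROM pairs, reported on the row of the first (lead) member.
OPPOSING_PAIRS = (("ABD", "ADD"), ("HFLEX", "HEXT"), ("VFLEX", "VEXT"), ("ER", "IR"))

# Report row labels for the PNF per-channel components.
PNF_COMPONENTS = ("PNF-X", "PNF-Z", "PNF-Y")
PNF_COMPONENT_CHANNEL = {"PNF-X": "x", "PNF-Z": "z", "PNF-Y": "y"}


def pair_label(a: str, b: str) -> str:
    return f"{a}/{b}"


def is_movement(label: str) -> bool:
    return label in SIMPLE_MOVEMENTS or label == PNF_LABEL
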