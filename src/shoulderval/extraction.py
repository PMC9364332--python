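"""Movement-phase segmentation and kinematic outcome extraction.

Each trial is fragmented into an outward phase (start pose to terminal
pose) and a reverse phase (terminal back to start), separated by the
dwell at the terminal position, plus a pre-movement baseline window.
Segmentation is automatic: a phase is a sustained episode (>= 100 ms by
default) where the absolute angular velocity of the dominant channel
exceeds 5% of its peak; detected boundaries are then refined by walking
out to a small velocity floor so that on noiseless profiles they land on
the true phase boundaries.

Outcomes follow the study definitions:

* ROM  — absolute excursion of the terminal position relative to the
  starting (baseline) position, degrees.
* TROM — sum of the two opposing terminal ranges about one starting
  position, degrees.
* PAV  — minimum and maximum of the angular-velocity signal over the
  outward and reverse phases, deg/s (single-plane movements).
* MAV  — mean absolute angular velocity over narrow windows just after
  movement initiation and just before the terminal position of each
  phase (first/last 25% of the phase by default), deg/s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import movements as mv
from .rotations import AngleSeries, angular_velocity

__all__ = [
    "MovementPhases",
    "KinematicSummary",
    "SegmentationError",
    "segment",
    "compute_rom",
    "compute_trom",
    "compute_pav",
    "compute_mav",
    "summarize_trial",
]


class SegmentationError(ValueError):
    """No usable movement phases could be detected."""


@dataclass(frozen=True)
class MovementPhases:
    """Half-open sample windows (start, stop) into a 200 Hz series."""

    outward: tuple
    reverse: tuple
    baseline: tuple

    def __post_init__(self):
        b, o, r = self.baseline, self.outward, self.reverse
        if not (b[0] < b[1] <= o[0] < o[1] <= r[0] < r[1]):
            raise ValueError(
                "phases must be non-empty, ordered baseline < outward < reverse"
            )

    @property
    def dwell(self) -> tuple:
        """Inter-phase window at the terminal position."""
        return (self.outward[1], self.reverse[0])


def _runs(mask: np.ndarray) -> list:
    """Contiguous True runs as (start, stop) half-open windows."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[0::2], idx[1::2]))


def segment(
    s: AngleSeries,
    channel: str | None = None,
    threshold: float = 0.05,
    sustain_s: float = 0.1,
    baseline_window_s: float = 0.5,
    floor_deg_s: float = 1e-3,
) -> MovementPhases:
    """Detect outward/reverse phases on the (dominant) channel's velocity.

    ``threshold`` is the fraction of the peak |velocity| that must be
    exceeded for at least ``sustain_s`` to count as movement.  Boundary
    refinement walks each detected run outwards until |velocity| falls to
    the floor, which is the larger of ``floor_deg_s`` and 3x the
    pre-movement noise level.
    """
    s = angular_velocity(s)
    if channel is None:
        channel = mv.CHANNEL_NAMES[int(np.argmax(np.ptp(s.angles_deg, axis=0)))]
    v = np.abs(s.velocity(channel))
    n_sustain = max(1, int(round(sustain_s * s.rate_hz)))

    # smoothed copy for detection only; raw |v| for boundary refinement
    kernel = np.ones(n_sustain) / n_sustain
    v_smooth = np.convolve(v, kernel, mode="same")
    peak = v_smooth.max()
    if peak <= 0:
        raise SegmentationError("no movement detected (flat velocity)")
    mask = v_smooth > threshold * peak
    runs = [r for r in _runs(mask) if r[1] - r[0] >= n_sustain]
    if not runs:
        raise SegmentationError("no movement detected (no sustained episode)")
    if len(runs) < 2:
        raise SegmentationError("reverse movement phase not found")
    if len(runs) > 2:
        # spurious extra episodes (noise): keep the two most substantial,
        # preserving temporal order
        scored = sorted(runs, key=lambda r: -v[r[0]:r[1]].sum())[:2]
        runs = sorted(scored)

    pre = v[: runs[0][0]]
    nb_est = max(3, int(round(0.5 * baseline_window_s * s.rate_hz)))
    noise = float(np.std(pre[:nb_est])) if len(pre) >= 3 else 0.0
    floor = max(floor_deg_s, 3.0 * noise)

    def _refine(run):
        # the smoothed detector smears run edges by half a kernel, so
        # first shrink to samples actually above the floor, then extend
        # down to the true (floor-crossing) boundaries on the raw signal
        lo, hi = int(run[0]), int(run[1])
        while lo < hi - 1 and v[lo] <= floor:
            lo += 1
        while hi > lo + 1 and v[hi - 1] <= floor:
            hi -= 1
        while lo > 0 and v[lo - 1] > floor:
            lo -= 1
        while hi < s.n and v[hi] > floor:
            hi += 1
        return lo, hi

    out = _refine(runs[0])
    rev = _refine(runs[1])
    if out[1] > rev[0]:  # refinement overlapped across a short dwell: split
        lo, hi = rev[0], out[1]
        mid = lo + int(np.argmin(v[lo:hi]))
        out = (out[0], mid)
        rev = (mid, rev[1])

    nb = int(round(baseline_window_s * s.rate_hz))
    b0 = max(0, out[0] - nb)
    if b0 >= out[0]:
        raise SegmentationError("no pre-movement baseline available")
    return MovementPhases(outward=out, reverse=rev, baseline=(b0, out[0]))


def _terminal_value(angle: np.ndarray, ph: MovementPhases, base: float,
                    min_dwell: int = 8) -> float:
    """Angle at the terminal position.

    With a dwell of at least ``min_dwell`` samples between the phases the
    terminal angle is the mean over the central half of the dwell (robust
    to measurement noise, exact on noiseless profiles that hold the pose);
    otherwise the signed extremum within the outward phase (earliest
    sample on ties).
    """
    d0, d1 = ph.dwell
    if d1 - d0 >= min_dwell:
        q = (d1 - d0) // 4
        return float(np.mean(angle[d0 + q:d1 - q]))
    seg = angle[ph.outward[0]:ph.outward[1]]
    idx = int(np.argmax(np.abs(seg - base)))
    return float(seg[idx])


def compute_rom(
    s: AngleSeries,
    ph: MovementPhases,
    channel: str,
    reference_deg: float | None = None,
) -> float:
    """ROM: |terminal angle - starting reference| in degrees.

    The reference defaults to the mean baseline angle; passing an explicit
    value (e.g. the calibrated neutral, 0) supports multiplanar start/end
    components."""
    angle = s.channel(channel)
    base = (
        float(np.mean(angle[ph.baseline[0]:ph.baseline[1]]))
        if reference_deg is None
        else reference_deg
    )
    return abs(_terminal_value(angle, ph, base) - base)


def compute_trom(rom_a: float, rom_b: float) -> float:
    """TROM: sum of the two opposing terminal ranges."""
    if rom_a < 0 or rom_b < 0:
        raise ValueError("ROM values must be non-negative")
    return rom_a + rom_b


def compute_pav(s: AngleSeries, ph: MovementPhases, channel: str) -> tuple:
    """(min, max) angular velocity over the outward and reverse phases."""
    v = s.velocity(channel)
    seg = np.concatenate(
        [v[ph.outward[0]:ph.outward[1]], v[ph.reverse[0]:ph.reverse[1]]]
    )
    if seg.size == 0:
        raise ValueError("empty movement phases")
    return float(seg.min()), float(seg.max())


def compute_mav(
    s: AngleSeries,
    ph: MovementPhases,
    channel: str,
    window_frac: float = 0.25,
) -> dict:
    """Mean |velocity| over the four narrow phase windows.

    Windows are the first and last ``window_frac`` of each phase; the
    pooled value is the sample-weighted mean over all four windows.
    Returned keys: ``outward_early``, ``outward_late``, ``reverse_early``,
    ``reverse_late``, ``pooled``, plus ``_counts`` with window sizes.
    """
    v = np.abs(s.velocity(channel))
    out: dict = {}
    counts: dict = {}
    total, total_n = 0.0, 0
    for name, (p0, p1) in (("outward", ph.outward), ("reverse", ph.reverse)):
        n = p1 - p0
        w = int(round(window_frac * n))
        if w < 3:
            raise ValueError(
                f"{name} MAV window has {w} samples; need at least 3"
            )
        early = v[p0:p0 + w]
        late = v[p1 - w:p1]
        out[f"{name}_early"] = float(early.mean())
        out[f"{name}_late"] = float(late.mean())
        counts[f"{name}_early"] = counts[f"{name}_late"] = w
        total += early.sum() + late.sum()
        total_n += 2 * w
    out["pooled"] = total / total_n
    out["_counts"] = counts
    return out


@dataclass(eq=False)
class KinematicSummary:
    """Per-trial scalar outcomes keyed by report-row label."""

    movement_label: str
    system_label: str
    subject_id: str
    rom_deg: dict
    trom_deg: dict
    mav_deg_s: dict
    pav_min_deg_s: float | None = None
    pav_max_deg_s: float | None = None
    phases: MovementPhases | None = None

    @property
    def pav_deg_s(self) -> float | None:
        """Peak speed (magnitude of the larger velocity extremum)."""
        if self.pav_min_deg_s is None:
            return None
        return max(abs(self.pav_min_deg_s), abs(self.pav_max_deg_s))


def _combine_windows(mavs: dict, keys: tuple) -> float:
    num = sum(mavs[k] * mavs["_counts"][k] for k in keys)
    den = sum(mavs["_counts"][k] for k in keys)
    return num / den


def summarize_trial(
    s: AngleSeries,
    threshold: float = 0.05,
    sustain_s: float = 0.1,
    baseline_window_s: float = 0.5,
    mav_window_frac: float = 0.25,
    compute_pav_always: bool = False,
    phases: MovementPhases | None = None,
) -> KinematicSummary:
    """Extract all study outcomes from one preprocessed trial stream.

    Single-plane movements yield ROM, PAV (where the battery defines it)
    and pooled MAV on the dominant channel.  The multiplanar PNF pattern
    yields per-channel start/end ROM components relative to the calibrated
    neutral (restored from the removed baseline offsets), their TROM, and
    start-/end-side MAV; PAV is not extracted for PNF or ER/IR unless
    ``compute_pav_always`` is set.

    ``phases`` allows the movement fragmentation of a synchronized
    companion stream (typically the reference system) to be reused so both
    systems are evaluated over identical windows.
    """
    label = s.movement_label
    if not mv.is_movement(label):
        raise ValueError(f"series has unknown movement label {label!r}")
    s = angular_velocity(s)

    if label in mv.SIMPLE_MOVEMENTS:
        d = mv.SIMPLE_MOVEMENTS[label]
        ph = phases if phases is not None else segment(
            s, d.channel, threshold, sustain_s, baseline_window_s
        )
        rom = compute_rom(s, ph, d.channel)
        mavs = compute_mav(s, ph, d.channel, mav_window_frac)
        pav_min = pav_max = None
        if d.pav_reported or compute_pav_always:
            pav_min, pav_max = compute_pav(s, ph, d.channel)
        return KinematicSummary(
            movement_label=label,
            system_label=s.system_label,
            subject_id=s.subject_id,
            rom_deg={label: rom},
            trom_deg={},
            mav_deg_s={label: mavs["pooled"]},
            pav_min_deg_s=pav_min,
            pav_max_deg_s=pav_max,
            phases=ph,
        )

    # PNF: segment on the dominant channel, extract per channel
    ph = phases if phases is not None else segment(
        s, None, threshold, sustain_s, baseline_window_s
    )
    offsets = s.baseline_offset_deg
    rom: dict = {}
    trom: dict = {}
    mav: dict = {}
    for comp, ch in mv.PNF_COMPONENT_CHANNEL.items():
        off = 0.0
        if offsets is not None:
            off = float(offsets[mv.CHANNEL_INDEX[ch]])
        angle_raw = s.channel(ch) + off
        base_raw = float(
            np.mean(angle_raw[ph.baseline[0]:ph.baseline[1]])
        )
        term_raw = _terminal_value(angle_raw, ph, base_raw)
        # start/end components relative to the calibrated neutral (zero)
        rom[f"{comp} start"] = abs(base_raw)
        rom[f"{comp} end"] = abs(term_raw)
        trom[comp] = compute_trom(abs(base_raw), abs(term_raw))
        mavs = compute_mav(s, ph, ch, mav_window_frac)
        mav[f"{comp} start"] = _combine_windows(
            mavs, ("outward_early", "reverse_late")
        )
        mav[f"{comp} end"] = _combine_windows(
            mavs, ("outward_late", "reverse_early")
        )
    pav_min = pav_max = None
    if compute_pav_always:
        dom = mv.CHANNEL_NAMES[int(np.argmax(np.ptp(s.angles_deg, axis=0)))]
        pav_min, pav_max = compute_pav(s, ph, dom)
    return KinematicSummary(
        movement_label=label,
        system_label=s.system_label,
        subject_id=s.subject_id,
        rom_deg=rom,
        trom_deg=trom,
        mav_deg_s=mav,
        pav_min_deg_s=pav_min,
        pav_max_deg_s=pav_max,
        phases=ph,
    )
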