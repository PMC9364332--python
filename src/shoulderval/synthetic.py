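"""Synthetic movement trials observed by two imperfect measurement systems.

Ground truth is generated at the joint-angle level: each trial holds a
lead-in baseline pose, moves smoothly (minimum-jerk by default) to the
terminal pose, dwells there, and returns.  A trial's ground-truth range of
motion therefore equals the profile amplitude exactly.

Two streams are rendered per trial — a high-rate, low-noise reference
(emulating marker-based motion capture) and a lower-rate wearable stream —
by degrading the shared ground truth with the error mechanisms that
dominate body-worn inertial sensors: a fixed sensor-to-segment misalignment
(soft-tissue/placement cross-talk), channel-wise amplitude scaling
(soft-tissue attenuation), static angle offsets (calibration-pose error),
integrated random-walk drift, and additive white noise.  Velocity channels
are rendered from gyroscope-like data (derivative of the clean rendered
angle plus gyroscope noise) rather than differentiating the noisy angles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.random import SeedSequence, default_rng
from scipy.spatial.transform import Rotation

from . import movements as mv
from .rotations import AngleSeries, RotationSeries, euler_series_from_rotations

__all__ = [
    "MovementProfile",
    "SystemErrorModel",
    "CohortSpec",
    "TrialPair",
    "simulate_trial",
    "render_stream",
    "simulate_cohort",
]


def minimum_jerk(tau: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile on [0, 1]; zero velocity/acceleration
    at both endpoints, peak velocity 1.875/T."""
    tau = np.asarray(tau)
    return tau**3 * (10.0 - 15.0 * tau + 6.0 * tau**2)


def raised_cosine(tau: np.ndarray) -> np.ndarray:
    """Raised-cosine alternative; zero velocity (not acceleration) at ends."""
    return 0.5 * (1.0 - np.cos(np.pi * np.asarray(tau)))


_SHAPES = {"minimum_jerk": minimum_jerk, "raised_cosine": raised_cosine}


@dataclass
class MovementProfile:
    """Ground-truth description of one out-dwell-back trial.

    ``start_deg``/``end_deg`` give the signed channel values (relative to
    the calibrated neutral) of the starting and terminal poses.  Simple
    movements activate exactly one channel; the PNF pattern all three.
    """

    movement_label: str
    start_deg: dict = field(default_factory=lambda: {"x": 0.0, "z": 0.0, "y": 0.0})
    end_deg: dict = field(default_factory=lambda: {"x": 0.0, "z": 0.0, "y": 0.0})
    duration_s: float = 2.0
    hold_s: float = 0.5
    lead_in_s: float = 1.0
    tail_s: float = 0.5
    shape: str = "minimum_jerk"
    base_rate_hz: float = 500.0
    pace_jitter_frac: float = 0.0

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.shape not in _SHAPES:
            raise ValueError(f"unknown profile shape {self.shape!r}")
        for ch in mv.CHANNEL_NAMES:
            self.start_deg.setdefault(ch, 0.0)
            self.end_deg.setdefault(ch, 0.0)
        active = self.active_channels()
        if self.movement_label in mv.SIMPLE_MOVEMENTS and len(active) > 1:
            raise ValueError(
                f"single-plane movement {self.movement_label} activates {active}"
            )

    def active_channels(self) -> list:
        return [
            ch
            for ch in mv.CHANNEL_NAMES
            if self.end_deg[ch] != self.start_deg[ch]
        ]

    def amplitude_deg(self, channel: str) -> float:
        """Ground-truth ROM of one channel (absolute excursion)."""
        return abs(self.end_deg[channel] - self.start_deg[channel])

    @classmethod
    def from_movement(cls, label: str, **overrides) -> "MovementProfile":
        """Default profile for one battery condition (amplitudes are the
        reference cohort means, durations the reference-pace defaults)."""
        if label == mv.PNF_LABEL:
            return cls(
                movement_label=label,
                start_deg=dict(mv.PNF_START_DEG),
                end_deg=dict(mv.PNF_END_DEG),
                duration_s=mv.PNF_DURATION_S,
                **overrides,
            )
        d = mv.SIMPLE_MOVEMENTS[label]
        end = {ch: 0.0 for ch in mv.CHANNEL_NAMES}
        end[d.channel] = d.signed_amplitude_deg
        return cls(
            movement_label=label,
            start_deg={ch: 0.0 for ch in mv.CHANNEL_NAMES},
            end_deg=end,
            duration_s=d.duration_s,
            **overrides,
        )


def simulate_trial(p: MovementProfile, seed=0) -> RotationSeries:
    """Simulate one trial as a ground-truth orientation series.

    The trial is deterministic for a fixed profile and seed; the seed only
    matters when ``pace_jitter_frac`` > 0 (self-selected-pace variability).
    """
    duration = p.duration_s
    if p.pace_jitter_frac > 0:
        rng = default_rng(seed)
        factor = float(np.clip(rng.normal(1.0, p.pace_jitter_frac), 0.6, 1.4))
        duration *= factor

    rate = p.base_rate_hz
    t1 = p.lead_in_s
    t2 = t1 + duration
    t3 = t2 + p.hold_s
    t4 = t3 + duration
    total = t4 + p.tail_s
    n = int(round(total * rate)) + 1
    t = np.arange(n) / rate

    shape = _SHAPES[p.shape]
    s = np.zeros(n)
    out_m = (t >= t1) & (t < t2)
    s[out_m] = shape((t[out_m] - t1) / duration)
    s[(t >= t2) & (t < t3)] = 1.0
    rev_m = (t >= t3) & (t < t4)
    s[rev_m] = shape((t4 - t[rev_m]) / duration)

    start = np.array([p.start_deg[ch] for ch in mv.CHANNEL_NAMES])
    end = np.array([p.end_deg[ch] for ch in mv.CHANNEL_NAMES])
    angles = start[None, :] + (end - start)[None, :] * s[:, None]
    rots = Rotation.from_euler("XZY", angles, degrees=True)
    return RotationSeries(
        rate_hz=rate,
        rotations=rots,
        movement_label=p.movement_label,
        start_hint_deg=start,
    )


@dataclass
class SystemErrorModel:
    """Angle-level error model of one measurement system.

    Units: degrees for offsets/noise/misalignment, deg/s for gyroscope
    noise, deg per sqrt(second) for the random-walk drift SD rate.
    """

    label: str = "reference"
    rate_hz: float = 500.0
    static_offset_deg: dict = field(
        default_factory=lambda: {"x": 0.0, "z": 0.0, "y": 0.0}
    )
    misalignment_deg: float = 0.0
    amplitude_scale: dict = field(
        default_factory=lambda: {"x": 1.0, "z": 1.0, "y": 1.0}
    )
    drift_rate_deg_per_s: float = 0.0
    noise_sd_deg: float = 0.0
    gyro_noise_sd_deg_s: float = 0.0

    def __post_init__(self):
        if not self.rate_hz > 0:
            raise ValueError("rate_hz must be positive")
        if self.noise_sd_deg < 0 or self.gyro_noise_sd_deg_s < 0:
            raise ValueError("noise SDs must be non-negative")
        for ch in mv.CHANNEL_NAMES:
            self.static_offset_deg.setdefault(ch, 0.0)
            self.amplitude_scale.setdefault(ch, 1.0)
            if not self.amplitude_scale[ch] > 0:
                raise ValueError("amplitude_scale must be positive")

    @classmethod
    def zero(cls, rate_hz: float = 500.0, label: str = "reference"):
        """Error-free system at the given rate (null model)."""
        return cls(label=label, rate_hz=rate_hz)

    @classmethod
    def default_reference(cls) -> "SystemErrorModel":
        """Marker-based reference: 500 Hz, small marker noise only."""
        return cls(
            label="reference",
            rate_hz=500.0,
            noise_sd_deg=0.2,
            gyro_noise_sd_deg_s=1.0,
        )

    @classmethod
    def default_wearable(cls) -> "SystemErrorModel":
        """Wearable at 147 Hz with soft-tissue attenuation, calibration
        offsets, mounting misalignment, drift and sensor noise of the
        magnitude a consumer sensor-software chain exhibits."""
        return cls(
            label="wearable",
            rate_hz=147.0,
            static_offset_deg={"x": 3.0, "z": -4.0, "y": 5.0},
            misalignment_deg=4.0,
            amplitude_scale={"x": 0.75, "z": 0.93, "y": 0.85},
            drift_rate_deg_per_s=0.3,
            noise_sd_deg=1.0,
            gyro_noise_sd_deg_s=2.0,
        )


def render_stream(g: RotationSeries, m: SystemErrorModel, seed=0) -> AngleSeries:
    """Render a ground-truth trial as one system's measured angle stream.

    Pipeline: sensor-frame misalignment (rotation-level) -> continuous
    X-Z'-Y'' decomposition -> resampling to the system rate -> channel
    scaling -> random-walk drift -> gyroscope-like velocity channels ->
    white angle noise and static offsets.  With the all-zero error model at
    the ground-truth rate the output equals the Euler decomposition of the
    input exactly.
    """
    rng = default_rng(seed)

    ang_true = euler_series_from_rotations(
        g.rotations, start_hint_deg=g.start_hint_deg
    )
    if m.misalignment_deg != 0.0:
        # independent small mounting errors of the thorax and humerus frames
        def _small(angle_deg):
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            return Rotation.from_rotvec(np.radians(angle_deg) * axis)

        r_thorax = _small(m.misalignment_deg)
        r_humerus = _small(m.misalignment_deg)
        rots = r_thorax.inv() * g.rotations * r_humerus
        ang = euler_series_from_rotations(rots, start_hint_deg=g.start_hint_deg)
    else:
        ang = ang_true

    t_src = np.arange(g.n) / g.rate_hz
    n_out = int(np.floor(t_src[-1] * m.rate_hz)) + 1
    t_out = np.arange(n_out) / m.rate_hz

    def _interp(a):
        return np.column_stack(
            [np.interp(t_out, t_src, a[:, j]) for j in range(3)]
        )

    scale = np.array([m.amplitude_scale[ch] for ch in mv.CHANNEL_NAMES])
    clean = _interp(ang) * scale[None, :]
    clean_true = clean if ang is ang_true else _interp(ang_true) * scale[None, :]

    dt = 1.0 / m.rate_hz
    if m.drift_rate_deg_per_s > 0:
        drift = np.cumsum(
            rng.normal(0.0, m.drift_rate_deg_per_s * np.sqrt(dt), (n_out, 3)),
            axis=0,
        )
        same = clean_true is clean
        clean = clean + drift
        clean_true = clean if same else clean_true + drift

    # Gyroscope-based velocity channels: body rates bypass the orientation
    # fusion, so they follow the (scaled, drifting) true Euler rates and
    # are unaffected by the misalignment-induced Euler degeneracies.
    vel = np.gradient(clean_true, dt, axis=0)
    if m.gyro_noise_sd_deg_s > 0:
        vel = vel + rng.normal(0.0, m.gyro_noise_sd_deg_s, (n_out, 3))

    offset = np.array([m.static_offset_deg[ch] for ch in mv.CHANNEL_NAMES])
    angles = clean + offset[None, :]
    if m.noise_sd_deg > 0:
        angles = angles + rng.normal(0.0, m.noise_sd_deg, (n_out, 3))

    return AngleSeries(
        rate_hz=m.rate_hz,
        angles_deg=angles,
        velocities_deg_s=vel,
        t0_s=g.t0_s,
        system_label=m.label,
        movement_label=g.movement_label,
    )


@dataclass
class CohortSpec:
    """Study-cohort description: who moves, how variably, and the seed.

    Defaults emulate the validation study: 24 subjects, the full nine-
    condition battery, between-subject amplitude SDs from the reference
    cohort (overridable by a single global SD), ~10% pace variability.
    """

    n_subjects: int = 24
    movements: list = field(default_factory=lambda: list(mv.MOVEMENT_LABELS))
    amplitude_sd_deg: float | None = None  # None -> per-movement defaults
    amplitude_overrides: dict = field(default_factory=dict)
    duration_jitter_frac: float = 0.10
    hold_s: float = 0.5
    lead_in_s: float = 1.0
    tail_s: float = 0.5
    profile_shape: str = "minimum_jerk"
    base_rate_hz: float = 500.0
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        for label in self.movements:
            if not mv.is_movement(label):
                raise ValueError(f"unknown movement label {label!r}")


@dataclass(eq=False)
class TrialPair:
    """One subject x movement trial observed by both systems."""

    subject_id: str
    movement_label: str
    profile: MovementProfile
    truth_deg: dict  # report-row label -> ground-truth ROM
    reference: AngleSeries
    wearable: AngleSeries


def _trunc_normal(rng, mean: float, sd: float, floor: float = 2.0) -> float:
    """Normal draw truncated at 3 SD, with a small positive magnitude floor
    so amplitudes can never collapse to zero or flip sign."""
    if sd <= 0:
        return mean
    for _ in range(100):
        v = rng.normal(mean, sd)
        if abs(v - mean) <= 3.0 * sd:
            break
    else:  # pragma: no cover - practically unreachable
        v = mean
    return max(v, floor)


def _draw_profile(label: str, spec: CohortSpec, rng) -> MovementProfile:
    common = dict(
        hold_s=spec.hold_s,
        lead_in_s=spec.lead_in_s,
        tail_s=spec.tail_s,
        shape=spec.profile_shape,
        base_rate_hz=spec.base_rate_hz,
    )
    if label == mv.PNF_LABEL:
        start, end = {}, {}
        for ch in mv.CHANNEL_NAMES:
            sd_s = spec.amplitude_sd_deg
            sd_e = spec.amplitude_sd_deg
            if sd_s is None:
                sd_s, sd_e = mv.PNF_START_SD_DEG[ch], mv.PNF_END_SD_DEG[ch]
            start[ch] = np.sign(mv.PNF_START_DEG[ch]) * _trunc_normal(
                rng, abs(mv.PNF_START_DEG[ch]), sd_s
            )
            end[ch] = np.sign(mv.PNF_END_DEG[ch]) * _trunc_normal(
                rng, abs(mv.PNF_END_DEG[ch]), sd_e
            )
        duration = mv.PNF_DURATION_S
    else:
        d = mv.SIMPLE_MOVEMENTS[label]
        amp_mean = spec.amplitude_overrides.get(label, d.signed_amplitude_deg)
        sd = spec.amplitude_sd_deg
        if sd is None:
            sd = d.amplitude_sd_deg
        mag = _trunc_normal(rng, abs(amp_mean), sd)
        start = {ch: 0.0 for ch in mv.CHANNEL_NAMES}
        end = {ch: 0.0 for ch in mv.CHANNEL_NAMES}
        end[d.channel] = np.sign(amp_mean) * mag
        duration = d.duration_s
    if spec.duration_jitter_frac > 0:
        duration *= float(
            np.clip(rng.normal(1.0, spec.duration_jitter_frac), 0.7, 1.3)
        )
    return MovementProfile(
        movement_label=label, start_deg=start, end_deg=end,
        duration_s=duration, **common,
    )


def _truth_rows(p: MovementProfile) -> dict:
    if p.movement_label == mv.PNF_LABEL:
        truth = {}
        for comp, ch in mv.PNF_COMPONENT_CHANNEL.items():
            truth[f"{comp} start"] = abs(p.start_deg[ch])
            truth[f"{comp} end"] = abs(p.end_deg[ch])
        return truth
    d = mv.SIMPLE_MOVEMENTS[p.movement_label]
    return {p.movement_label: p.amplitude_deg(d.channel)}


def simulate_cohort(
    c: CohortSpec,
    reference_model: SystemErrorModel,
    wearable_model: SystemErrorModel,
) -> list:
    """Simulate the paired cohort: one reference and one wearable stream
    per subject x movement, sharing one ground truth.  Deterministic for a
    fixed spec (byte-identical streams)."""
    root = SeedSequence(c.seed)
    pairs: list[TrialPair] = []
    for i, subj_seq in enumerate(root.spawn(c.n_subjects)):
        subject_id = f"S{i + 1:02d}"
        for label, mv_seq in zip(c.movements, subj_seq.spawn(len(c.movements))):
            s_prof, s_ref, s_wear = mv_seq.spawn(3)
            profile = _draw_profile(label, c, default_rng(s_prof))
            g = simulate_trial(profile)
            ref = render_stream(g, reference_model, s_ref)
            wear = render_stream(g, wearable_model, s_wear)
            ref.subject_id = wear.subject_id = subject_id
            pairs.append(
                TrialPair(subject_id, label, profile, _truth_rows(profile), ref, wear)
            )
    return pairs
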