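"""Common-timebase preprocessing of paired angle streams.

Both systems record at their native rates (reference 500 Hz, wearable
147 Hz); analysis happens on a shared 200 Hz grid.  Downsampling applies a
zero-phase 4th-order Butterworth low-pass (50 Hz) first to prevent
aliasing; upsampling uses plain linear interpolation.  Beyond
anti-aliasing the angle data are not smoothed.

Streams are optionally synchronized by cross-correlating the dominant
channel's velocity, then baseline angle offsets are removed per channel
using the mean over an initial baseline window (the removed offsets are
retained on the series so extraction can restore the calibrated-neutral
reference where it needs it).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .rotations import AngleSeries, angular_velocity

__all__ = ["SyncedPair", "resample", "synchronize", "remove_offset", "preprocess_pair"]


@dataclass(eq=False)
class SyncedPair:
    """A reference/wearable pair on the common grid, cropped to equal
    length, with the applied lag recorded."""

    reference: AngleSeries
    wearable: AngleSeries
    lag_s: float = 0.0

    def __post_init__(self):
        if self.reference.n != self.wearable.n:
            raise ValueError("paired streams must have equal length")
        if self.reference.rate_hz != self.wearable.rate_hz:
            raise ValueError("paired streams must share one rate")


def resample(
    s: AngleSeries,
    target_hz: float = 200.0,
    antialias: bool = True,
    cutoff_hz: float = 50.0,
) -> AngleSeries:
    """Linearly interpolate a series onto a uniform ``target_hz`` grid
    spanning the original time range.

    When reducing the rate, a zero-phase 4th-order low-pass (Butterworth
    order 2 run forward and backward) at ``cutoff_hz`` is applied first.
    """
    if not target_hz > 0:
        raise ValueError("target_hz must be positive")
    if s.n < 2:
        raise ValueError("need at least 2 samples to resample")

    ang = s.angles_deg
    vel = s.velocities_deg_s
    if antialias and target_hz < s.rate_hz and cutoff_hz < s.rate_hz / 2:
        sos = signal.butter(2, cutoff_hz, fs=s.rate_hz, output="sos")
        ang = signal.sosfiltfilt(sos, ang, axis=0)
        if vel is not None:
            vel = signal.sosfiltfilt(sos, vel, axis=0)

    t_src = np.arange(s.n) / s.rate_hz
    n_out = int(np.floor(t_src[-1] * target_hz)) + 1
    t_out = np.arange(n_out) / target_hz
    ang_out = np.column_stack([np.interp(t_out, t_src, ang[:, j]) for j in range(3)])
    vel_out = None
    if vel is not None:
        vel_out = np.column_stack(
            [np.interp(t_out, t_src, vel[:, j]) for j in range(3)]
        )
    return s.copy(rate_hz=target_hz, angles_deg=ang_out, velocities_deg_s=vel_out)


def _dominant_channel(s: AngleSeries) -> int:
    return int(np.argmax(np.ptp(s.angles_deg, axis=0)))


def synchronize(
    a: AngleSeries,
    b: AngleSeries,
    max_lag_s: float = 2.0,
    min_corr: float = 0.2,
) -> SyncedPair:
    """Align two same-rate streams by maximizing the cross-correlation of
    the dominant channel's velocity; crop both to the common window.

    ``lag_s`` on the returned pair is the estimated delay of ``b``
    relative to ``a`` (positive: b's content starts later).  A degenerate
    pair (flat signals, or peak normalized correlation below ``min_corr``)
    raises a warning and applies zero lag.
    """
    if a.rate_hz != b.rate_hz:
        raise ValueError("synchronize expects streams at a common rate")
    rate = a.rate_hz
    ch = _dominant_channel(a)
    va = angular_velocity(a).velocities_deg_s[:, ch]
    vb = angular_velocity(b).velocities_deg_s[:, ch]
    xa = va - va.mean()
    xb = vb - vb.mean()
    na, nb = len(xa), len(xb)

    delay = 0  # samples b starts later than a (positive: b delayed)
    denom = np.sqrt(np.sum(xa**2) * np.sum(xb**2))
    if denom <= 0:
        warnings.warn("synchronize: flat signals, applying zero lag")
    else:
        c = signal.correlate(xa, xb, mode="full")
        disp = np.arange(-(nb - 1), na)  # displacement d: xa[j+d] ~ xb[j]
        max_lag = int(round(max_lag_s * rate))
        keep = np.abs(disp) <= max_lag
        c, disp = c[keep], disp[keep]
        best = int(np.argmax(c))
        if c[best] / denom < min_corr:
            warnings.warn(
                "synchronize: correlation peak below "
                f"{min_corr}, applying zero lag"
            )
        else:
            delay = -int(disp[best])

    if delay >= 0:
        a_crop, b_crop = a.angles_deg, b.angles_deg[delay:]
        av = a.velocities_deg_s
        bv = None if b.velocities_deg_s is None else b.velocities_deg_s[delay:]
    else:
        a_crop, b_crop = a.angles_deg[-delay:], b.angles_deg
        av = None if a.velocities_deg_s is None else a.velocities_deg_s[-delay:]
        bv = b.velocities_deg_s
    n = min(len(a_crop), len(b_crop))
    a2 = a.copy(angles_deg=a_crop[:n],
                velocities_deg_s=None if av is None else av[:n])
    b2 = b.copy(angles_deg=b_crop[:n],
                velocities_deg_s=None if bv is None else bv[:n])
    return SyncedPair(reference=a2, wearable=b2, lag_s=delay / rate)


def remove_offset(s: AngleSeries, baseline_window_s: float = 0.5) -> AngleSeries:
    """Subtract each channel's mean over the initial baseline window.

    Idempotent; the removed offsets accumulate on
    ``baseline_offset_deg`` so raw (calibrated-neutral) angles remain
    recoverable.
    """
    nb = int(round(baseline_window_s * s.rate_hz))
    if nb < 1 or s.n < 2 * nb:
        raise ValueError("series must be at least twice the baseline window")
    off = s.angles_deg[:nb].mean(axis=0)
    prev = s.baseline_offset_deg if s.baseline_offset_deg is not None else 0.0
    return s.copy(angles_deg=s.angles_deg - off[None, :],
                  baseline_offset_deg=off + prev)


def preprocess_pair(
    reference: AngleSeries,
    wearable: AngleSeries,
    target_rate_hz: float = 200.0,
    antialias: bool = True,
    sync: bool = True,
    baseline_window_s: float = 0.5,
) -> SyncedPair:
    """Full preprocessing chain: resample both streams to the common rate,
    fill velocity channels where missing, synchronize (optional), and
    remove baseline offsets."""
    ref = angular_velocity(resample(reference, target_rate_hz, antialias))
    wear = angular_velocity(resample(wearable, target_rate_hz, antialias))
    if sync:
        pair = synchronize(ref, wear)
    else:
        n = min(ref.n, wear.n)
        pair = SyncedPair(
            reference=ref.copy(
                angles_deg=ref.angles_deg[:n],
                velocities_deg_s=ref.velocities_deg_s[:n],
            ),
            wearable=wear.copy(
                angles_deg=wear.angles_deg[:n],
                velocities_deg_s=wear.velocities_deg_s[:n],
            ),
        )
    return SyncedPair(
        reference=remove_offset(pair.reference, baseline_window_s),
        wearable=remove_offset(pair.wearable, baseline_window_s),
        lag_s=pair.lag_s,
    )
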