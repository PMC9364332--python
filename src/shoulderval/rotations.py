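"""Orientation handling and the intrinsic X-Z'-Y'' Euler sequence.

The humerus orientation relative to the thorax is represented by a rotation
(scipy :class:`~scipy.spatial.transform.Rotation`).  Joint angles are read
off via an intrinsic Tait-Bryan X-Z'-Y'' decomposition: first a rotation
about the segment X axis (frontal plane, abduction positive), then about
the rotated Z axis (sagittal plane, vertical flexion positive — this is
the middle angle, canonically confined to [-90, 90] degrees), then about
the twice-rotated Y axis (transverse plane, external rotation positive).

Two decomposition entry points exist:

* :func:`euler_from_rotation` — canonical single-rotation decomposition
  with an explicit gimbal-lock tie-break (at |z'| = 90 deg the outer angles
  are not unique; y'' is set to 0, the indeterminate sum folded into x, and
  the sample flagged).
* :func:`euler_series_from_rotations` — time-series decomposition with
  continuity tracking.  Real movements (e.g. vertical flexion beyond 90
  deg) cross the canonical branch boundary; motion-capture software exports
  the branch continuous with the calibrated start pose, and this function
  does the same by choosing per sample between the two Euler solutions
  (x, z, y) and (x+180, 180-z, y+180).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "EulerXZY",
    "AngleSeries",
    "RotationSeries",
    "rotation_from_euler",
    "euler_from_rotation",
    "euler_series_from_rotations",
    "angular_velocity",
]

#: |z'| within this margin (degrees) of 90 is treated as gimbal lock.
GIMBAL_MARGIN_DEG = 0.1

#: |z'| within this margin of +-90 counts as a pole approach: the outer
#: channels are ill-conditioned there and series decomposition bridges the
#: span by branch selection (see euler_series_from_rotations).
POLE_MARGIN_DEG = 25.0


@dataclass(frozen=True)
class EulerXZY:
    """One intrinsic X-Z'-Y'' angle triple, degrees.

    ``gimbal_lock`` marks samples where the middle angle was within
    :data:`GIMBAL_MARGIN_DEG` of +-90 degrees and the documented tie-break
    (y'' = 0, remainder folded into x) was applied.
    """

    x_deg: float
    z_deg: float
    y_deg: float
    gimbal_lock: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.x_deg, self.z_deg, self.y_deg], dtype=float)


def rotation_from_euler(a: EulerXZY | np.ndarray) -> Rotation:
    """Compose the intrinsic X -> Z' -> Y'' rotation from an angle triple.

    Accepts an :class:`EulerXZY` or any (..., 3) array of [x, z, y] degrees.
    """
    arr = a.as_array() if isinstance(a, EulerXZY) else np.asarray(a, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("Euler angles must be finite")
    return Rotation.from_euler("XZY", arr, degrees=True)


def _euler_xzy_from_matrix(
    M: np.ndarray, fold_gimbal: bool = True
) -> tuple[np.ndarray, ...]:
    """Vectorised canonical X-Z'-Y'' decomposition of (..., 3, 3) matrices.

    With ``fold_gimbal`` the documented tie-break (y'' = 0, remainder into
    x) is applied inside the gimbal margin; the series tracker disables it
    and relies on branch continuity instead.
    """
    sz = np.clip(-M[..., 0, 1], -1.0, 1.0)
    z = np.degrees(np.arcsin(sz))
    x = np.degrees(np.arctan2(M[..., 2, 1], M[..., 1, 1]))
    y = np.degrees(np.arctan2(M[..., 0, 2], M[..., 0, 0]))

    gimbal = np.abs(np.abs(z) - 90.0) < GIMBAL_MARGIN_DEG
    if fold_gimbal and np.any(gimbal):
        # At z' = +90: R[2,:] = [sin(x-y), 0, cos(x-y)]; fold into x, y = 0.
        # At z' = -90: R[2,:] = [-sin(x+y), 0, cos(x+y)].
        sign = np.where(z > 0, 1.0, -1.0)
        x_fold = np.degrees(np.arctan2(sign * M[..., 2, 0], M[..., 2, 2]))
        x = np.where(gimbal, x_fold, x)
        y = np.where(gimbal, 0.0, y)
    return x, z, y, gimbal


def euler_from_rotation(r: Rotation) -> EulerXZY:
    """Canonical decomposition of a single rotation; z' in [-90, 90]."""
    M = r.as_matrix()
    if M.ndim != 2:
        raise ValueError("euler_from_rotation expects a single rotation; "
                         "use euler_series_from_rotations for sequences")
    x, z, y, gimbal = _euler_xzy_from_matrix(M)
    return EulerXZY(float(x), float(z), float(y), bool(gimbal))


def _wrap180(a):
    """Wrap degrees into (-180, 180]."""
    return -((180.0 - np.asarray(a)) % 360.0 - 180.0)


def euler_series_from_rotations(
    rotations: Rotation, start_hint_deg: np.ndarray | None = None
) -> np.ndarray:
    """Decompose a rotation sequence to continuous X-Z'-Y'' channels.

    Parameters
    ----------
    rotations
        Sequence of N rotations (scipy Rotation of length N).
    start_hint_deg
        Optional [x, z, y] triple near the expected first-sample angles,
        used to select the branch at the start (e.g. a trial beginning in a
        pose with z' beyond 90 deg).  Without a hint the canonical branch
        is used for the first sample.

    Returns
    -------
    (N, 3) float array of [x, z', y''] in degrees, continuous in time
    (channels may leave the canonical ranges across branch crossings).
    """
    M = rotations.as_matrix()
    if M.ndim == 2:
        M = M[None]
    x, z, y, _ = _euler_xzy_from_matrix(M, fold_gimbal=False)
    n = len(x)
    # |cos z'|: well-conditioned pole-proximity measure
    cos_mag = np.hypot(M[..., 0, 0], M[..., 0, 2])
    pole_cos = np.sin(np.radians(POLE_MARGIN_DEG))

    hint = None if start_hint_deg is None else np.asarray(start_hint_deg, float)
    hint_canonical = hint is None or np.abs(hint[1]) <= 89.0
    if cos_mag.min() >= pole_cos and hint_canonical:
        # never near the pole: the canonical branch is globally valid
        out = np.column_stack([
            np.unwrap(x, period=360.0),
            z,
            np.unwrap(y, period=360.0),
        ])
        if hint is not None:
            out += np.round((hint - out[0]) / 360.0) * 360.0
        return out

    # Near-pole trajectories: a path that *misses* the gimbal set has a
    # continuous lift whose middle angle can never cross 90 deg, which
    # would reflect a near-full flexion back below 90 while the outer
    # channels swing by ~180.  Joint-angle software instead keeps the
    # outer channels continuous across the (brief) degenerate span and
    # lets the middle angle pass the pole.  We therefore fix the branch
    # per clear region between pole approaches — chosen so the outer
    # channels connect continuously to the previous region — and inside a
    # pole region select per sample the branch whose middle angle stays
    # closest to the linear bridge between the adjacent regions.
    def _flip_channels(sl, flip):
        if flip:
            return (
                np.unwrap(x[sl] + 180.0, period=360.0),
                np.unwrap(180.0 - z[sl], period=360.0),
                np.unwrap(y[sl] + 180.0, period=360.0),
            )
        return (
            np.unwrap(x[sl], period=360.0),
            z[sl].copy(),
            np.unwrap(y[sl], period=360.0),
        )

    clear = cos_mag >= pole_cos
    idx = np.flatnonzero(np.diff(np.concatenate(([0], clear.view(np.int8), [0]))))
    clear_runs = list(zip(idx[0::2], idx[1::2]))

    out = np.full((n, 3), np.nan)
    if not clear_runs:
        # degenerate: whole series near the pole; pick the branch closest
        # to the hint (or canonical) sample by sample via z continuity
        ref_z = hint[1] if hint is not None else z[0]
        for i in range(n):
            cands = ((x[i], z[i], y[i]),
                     (x[i] + 180.0, 180.0 - z[i], y[i] + 180.0))
            zi = [ref_z + _wrap180(c[1] - ref_z) for c in cands]
            j = int(np.argmin([abs(v - ref_z) for v in zi]))
            prev = out[i - 1] if i else (hint if hint is not None else None)
            xr, yr = cands[j][0], cands[j][2]
            if prev is not None:
                xr = prev[0] + _wrap180(xr - prev[0])
                yr = prev[2] + _wrap180(yr - prev[2])
            out[i] = (xr, zi[j], yr)
            ref_z = zi[j]
        return out

    prev_end = None
    for s, e in clear_runs:
        cands = []
        for flip in (False, True):
            xs, zs, ys = _flip_channels(slice(s, e), flip)
            cands.append((xs, zs, ys))
        ref = prev_end if prev_end is not None else (
            hint if hint is not None else np.array([x[s], z[s], y[s]])
        )
        costs = []
        shifted = []
        for xs, zs, ys in cands:
            dx = np.round((ref[0] - xs[0]) / 360.0) * 360.0
            dz = np.round((ref[1] - zs[0]) / 360.0) * 360.0
            dy = np.round((ref[2] - ys[0]) / 360.0) * 360.0
            xs2, zs2, ys2 = xs + dx, zs + dz, ys + dy
            shifted.append((xs2, zs2, ys2))
            if prev_end is None:
                cost = (abs(xs2[0] - ref[0]) + abs(zs2[0] - ref[1])
                        + abs(ys2[0] - ref[2]))
            else:  # outer-channel continuity decides across the pole gap
                cost = abs(xs2[0] - ref[0]) + abs(ys2[0] - ref[2])
            costs.append(cost)
        xs, zs, ys = shifted[int(np.argmin(costs))]
        out[s:e, 0], out[s:e, 1], out[s:e, 2] = xs, zs, ys
        prev_end = out[e - 1]

    # fill pole-region samples: bridge z linearly between the adjacent
    # clear samples, pick the closer branch, keep outer channels continuous
    gaps = np.flatnonzero(np.isnan(out[:, 0]))
    if len(gaps):
        splits = np.flatnonzero(np.diff(gaps) > 1)
        for grp in np.split(gaps, splits + 1):
            g0, g1 = grp[0], grp[-1]
            left = out[g0 - 1] if g0 > 0 else None
            right = out[g1 + 1] if g1 + 1 < n else None
            if left is None:
                left = right
            if right is None:
                right = left
            m = len(grp)
            z_bridge = np.linspace(left[1], right[1], m + 2)[1:-1]
            prev = left
            for j, i in enumerate(grp):
                zt = z_bridge[j]
                best, best_cost = None, np.inf
                for xi, zi, yi in (
                    (x[i], z[i], y[i]),
                    (x[i] + 180.0, 180.0 - z[i], y[i] + 180.0),
                ):
                    xa = prev[0] + _wrap180(xi - prev[0])
                    ya = prev[2] + _wrap180(yi - prev[2])
                    za = zt + _wrap180(zi - zt)
                    cost = (abs(za - zt)
                            + 0.5 * (abs(xa - prev[0]) + abs(ya - prev[2])))
                    if cost < best_cost:
                        best, best_cost = (xa, za, ya), cost
                out[i] = best
                prev = out[i]
    return out


@dataclass(eq=False)
class AngleSeries:
    """Uniformly sampled Euler-angle channels of one trial and system.

    ``angles_deg`` is (n, 3) with columns x, z', y'' in degrees;
    ``velocities_deg_s`` (same shape, deg/s) is optional — filled by the
    simulator from gyroscope-like data or by :func:`angular_velocity`.
    ``baseline_offset_deg`` records per-channel offsets removed by
    preprocessing so the calibrated-neutral reference can be restored.
    """

    rate_hz: float
    angles_deg: np.ndarray
    velocities_deg_s: np.ndarray | None = None
    t0_s: float = 0.0
    system_label: str = ""
    movement_label: str = ""
    subject_id: str = ""
    baseline_offset_deg: np.ndarray | None = None

    def __post_init__(self):
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.angles_deg.ndim != 2 or self.angles_deg.shape[1] != 3:
            raise ValueError("angles_deg must have shape (n, 3)")
        if self.angles_deg.shape[0] < 2:
            raise ValueError("an AngleSeries needs at least 2 samples")
        if not self.rate_hz > 0:
            raise ValueError("rate_hz must be positive")
        if self.velocities_deg_s is not None:
            self.velocities_deg_s = np.asarray(self.velocities_deg_s, dtype=float)
            if self.velocities_deg_s.shape != self.angles_deg.shape:
                raise ValueError("velocity channels must match angle shape")
        if self.baseline_offset_deg is not None:
            self.baseline_offset_deg = np.asarray(self.baseline_offset_deg, float)

    @property
    def n(self) -> int:
        return self.angles_deg.shape[0]

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n) / self.rate_hz

    @property
    def duration_s(self) -> float:
        return (self.n - 1) / self.rate_hz

    def channel(self, name: str) -> np.ndarray:
        from .movements import CHANNEL_INDEX

        return self.angles_deg[:, CHANNEL_INDEX[name]]

    def velocity(self, name: str) -> np.ndarray:
        from .movements import CHANNEL_INDEX

        if self.velocities_deg_s is None:
            raise ValueError("series carries no velocity channels; "
                             "call angular_velocity() first")
        return self.velocities_deg_s[:, CHANNEL_INDEX[name]]

    def copy(self, **changes) -> "AngleSeries":
        base = dict(
            rate_hz=self.rate_hz,
            angles_deg=self.angles_deg.copy(),
            velocities_deg_s=None if self.velocities_deg_s is None
            else self.velocities_deg_s.copy(),
            t0_s=self.t0_s,
            system_label=self.system_label,
            movement_label=self.movement_label,
            subject_id=self.subject_id,
            baseline_offset_deg=None if self.baseline_offset_deg is None
            else self.baseline_offset_deg.copy(),
        )
        base.update(changes)
        return AngleSeries(**base)


@dataclass(eq=False)
class RotationSeries:
    """Timestamped ground-truth orientation sequence of one trial."""

    rate_hz: float
    rotations: Rotation
    t0_s: float = 0.0
    movement_label: str = ""
    start_hint_deg: np.ndarray | None = None

    def __post_init__(self):
        if not self.rate_hz > 0:
            raise ValueError("rate_hz must be positive")
        if self.n < 1:
            raise ValueError("empty rotation series")

    @property
    def n(self) -> int:
        return len(self.rotations)

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n) / self.rate_hz


def angular_velocity(s: AngleSeries) -> AngleSeries:
    """Fill velocity channels by finite differences (deg/s).

    Central differences on interior samples, one-sided at the endpoints.
    Streams that already carry gyroscope velocity channels are passed
    through unchanged, mirroring measurement systems that export gyroscope
    data directly.
    """
    if s.velocities_deg_s is not None:
        return s
    if s.n < 3:
        raise ValueError("need at least 3 samples to differentiate")
    v = np.gradient(s.angles_deg, 1.0 / s.rate_hz, axis=0)
    return s.copy(velocities_deg_s=v)
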