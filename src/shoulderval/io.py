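"""Plain-text trial file dialect.

Trials are stored as diff-able CSV with a commented metadata header::

    # shoulderval-trial v1
    # system=wearable
    # movement=ABD
    # subject=S01
    # rate_hz=147
    # t0_s=0
    time_s,x_deg,z_deg,y_deg,vx_deg_s,vz_deg_s,vy_deg_s
    0.000000,0.000000,...

Angles are degrees, velocities deg/s, time seconds.  Formatting is fixed
to six decimals so identical series produce byte-identical files.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .rotations import AngleSeries

__all__ = ["read_trial_file", "write_trial_file", "TrialFileError"]

FORMAT_TAG = "shoulderval-trial v1"
_ANGLE_COLS = ["x_deg", "z_deg", "y_deg"]
_VEL_COLS = ["vx_deg_s", "vz_deg_s", "vy_deg_s"]
_REQUIRED_HEADER = ("system", "movement", "rate_hz")


class TrialFileError(ValueError):
    """Malformed trial file."""


def write_trial_file(s: AngleSeries, path) -> Path:
    """Write a series to the trial dialect; deterministic formatting."""
    if s.n < 2:
        raise ValueError("refusing to write an empty/degenerate series")
    path = Path(path)
    cols = [s.times_s] + [s.angles_deg[:, j] for j in range(3)]
    names = ["time_s"] + _ANGLE_COLS
    if s.velocities_deg_s is not None:
        cols += [s.velocities_deg_s[:, j] for j in range(3)]
        names += _VEL_COLS
    header = (
        f"# {FORMAT_TAG}\n"
        f"# system={s.system_label}\n"
        f"# movement={s.movement_label}\n"
        f"# subject={s.subject_id}\n"
        f"# rate_hz={s.rate_hz:g}\n"
        f"# t0_s={s.t0_s:g}\n"
        + ",".join(names)
    )
    data = np.column_stack(cols)
    buf = _io.StringIO()
    np.savetxt(buf, data, fmt="%.6f", delimiter=",", header=header, comments="")
    path.write_text(buf.getvalue())
    return path


def read_trial_file(path) -> AngleSeries:
    """Read and validate a trial file.

    Raises :class:`TrialFileError` naming the offending line for missing
    header fields, NaN values, or non-monotone/non-uniform time stamps.
    """
    path = Path(path)
    meta = {}
    n_header = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
    for key in _REQUIRED_HEADER:
        if key not in meta:
            raise TrialFileError(f"{path}: missing header field '{key}'")
    try:
        rate = float(meta["rate_hz"])
    except ValueError as e:
        raise TrialFileError(f"{path}: bad rate_hz header") from e
    t0 = float(meta.get("t0_s", 0.0))

    df = pd.read_csv(path, comment="#")
    for col in ["time_s"] + _ANGLE_COLS:
        if col not in df.columns:
            raise TrialFileError(f"{path}: missing column '{col}'")
    if len(df) < 2:
        raise TrialFileError(f"{path}: fewer than 2 data rows")

    nan_rows = df.index[df.isna().any(axis=1)]
    if len(nan_rows):
        line_no = int(nan_rows[0]) + n_header + 2  # header lines + column row
        raise TrialFileError(f"{path}: NaN value at line {line_no}")

    t = df["time_s"].to_numpy()
    dt = np.diff(t)
    if np.any(dt <= 0):
        line_no = int(np.argmax(dt <= 0)) + n_header + 3
        raise TrialFileError(f"{path}: non-monotone time at line {line_no}")
    step = 1.0 / rate
    if np.max(np.abs(dt - step)) > 0.01 * step:
        line_no = int(np.argmax(np.abs(dt - step) > 0.01 * step)) + n_header + 3
        raise TrialFileError(
            f"{path}: non-uniform sampling (expected {step:.6f} s) at line {line_no}"
        )

    vel = None
    if all(c in df.columns for c in _VEL_COLS):
        vel = df[_VEL_COLS].to_numpy()
    return AngleSeries(
        rate_hz=rate,
        angles_deg=df[_ANGLE_COLS].to_numpy(),
        velocities_deg_s=vel,
        t0_s=t0,
        system_label=meta.get("system", ""),
        movement_label=meta.get("movement", ""),
        subject_id=meta.get("subject", ""),
    )
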