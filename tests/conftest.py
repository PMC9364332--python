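import numpy as np
import pytest

from shoulderval.rotations import AngleSeries
from shoulderval.synthetic import MovementProfile, SystemErrorModel, simulate_trial


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def abd_profile():
    return MovementProfile.from_movement("ABD")


@pytest.fixture
def abd_stream_200(abd_profile):
    """Noiseless ABD trial rendered error-free at the analysis rate."""
    g = simulate_trial(abd_profile)
    from shoulderval.synthetic import render_stream

    return render_stream(g, SystemErrorModel.zero(200.0, "reference"), seed=0)


def make_series(angles, rate=200.0, vel=None, **kw):
    angles = np.asarray(angles, dtype=float)
    if angles.ndim == 1:
        z = np.zeros_like(angles)
        angles = np.column_stack([angles, z, z])
    return AngleSeries(rate_hz=rate, angles_deg=angles, velocities_deg_s=vel, **kw)


@pytest.fixture
def make_angle_series():
    return make_series
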