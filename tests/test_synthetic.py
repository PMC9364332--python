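"""Trial simulator and measurement-system error models."""

import numpy as np
import pytest

from shoulderval import movements as mv
from shoulderval.config import RunConfig
from shoulderval.extraction import summarize_trial
from shoulderval.preprocess import preprocess_pair
from shoulderval.synthetic import (
    CohortSpec,
    MovementProfile,
    SystemErrorModel,
    minimum_jerk,
    render_stream,
    simulate_cohort,
    simulate_trial,
)


def _extract_rom(stream, label="ABD"):
    s = stream.copy()
    from shoulderval.preprocess import remove_offset

    return summarize_trial(remove_offset(s)).rom_deg[label]


class TestProfiles:
    def test_minimum_jerk_boundary_conditions(self):
        tau = np.linspace(0, 1, 1001)
        s = minimum_jerk(tau)
        assert s[0] == 0 and s[-1] == 1
        v = np.gradient(s, tau)
        assert abs(v[0]) < 1e-4 and abs(v[-1]) < 1e-4
        assert np.max(v) == pytest.approx(1.875, rel=1e-4)

    def test_single_plane_invariant(self):
        with pytest.raises(ValueError):
            MovementProfile(
                movement_label="ABD",
                end_deg={"x": 30.0, "z": 10.0, "y": 0.0},
            )

    def test_pnf_activates_all_channels(self):
        p = MovementProfile.from_movement("PNF")
        assert sorted(p.active_channels()) == ["x", "y", "z"]

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            MovementProfile(movement_label="ABD", duration_s=0.0)


class TestSimulateTrial:
    def test_ground_truth_rom_equals_amplitude(self, abd_profile):
        g = simulate_trial(abd_profile)
        from shoulderval.rotations import euler_series_from_rotations

        ang = euler_series_from_rotations(g.rotations, g.start_hint_deg)
        assert np.ptp(ang[:, 0]) == pytest.approx(160.9, abs=1e-9)

    def test_zero_amplitude_constant_identity(self):
        p = MovementProfile(movement_label="ABD")
        g = simulate_trial(p)
        np.testing.assert_allclose(
            g.rotations.as_matrix() - np.eye(3), 0.0, atol=1e-12
        )

    def test_determinism(self, abd_profile):
        abd_profile.pace_jitter_frac = 0.1
        a = simulate_trial(abd_profile, seed=3)
        b = simulate_trial(abd_profile, seed=3)
        np.testing.assert_array_equal(a.rotations.as_quat(), b.rotations.as_quat())

    def test_zero_velocity_at_phase_boundaries(self, abd_stream_200):
        v = np.abs(abd_stream_200.velocities_deg_s[:, 0])
        n = abd_stream_200.n
        # lead-in and tail stationary
        assert v[: int(0.9 * 200)].max() < 1e-9
        assert v[n - int(0.4 * 200):].max() < 1e-9


class TestRenderStream:
    def test_zero_error_matching_rate_is_exact(self, abd_profile):
        g = simulate_trial(abd_profile)
        out = render_stream(g, SystemErrorModel.zero(rate_hz=g.rate_hz), seed=0)
        from shoulderval.rotations import euler_series_from_rotations

        np.testing.assert_allclose(
            out.angles_deg,
            euler_series_from_rotations(g.rotations, g.start_hint_deg),
            atol=1e-12,
        )

    def test_zero_error_wearable_rate_rom(self, abd_profile):
        g = simulate_trial(abd_profile)
        out = render_stream(g, SystemErrorModel.zero(147.0, "wearable"), seed=0)
        out.subject_id = "S"
        assert _extract_rom(out) == pytest.approx(160.9, abs=0.1)

    def test_amplitude_scale_attenuates_rom(self, abd_profile):
        g = simulate_trial(abd_profile)
        m = SystemErrorModel(
            label="wearable", rate_hz=147.0,
            amplitude_scale={"x": 0.70, "z": 1.0, "y": 1.0},
        )
        out = render_stream(g, m, seed=0)
        assert _extract_rom(out) == pytest.approx(0.70 * 160.9, abs=0.1)

    def test_noise_does_not_bias_rom(self, abd_profile):
        """Monte-Carlo: with 1 deg angle noise the mean extracted ROM stays
        within 0.5 deg of scale x amplitude."""
        g = simulate_trial(abd_profile)
        m = SystemErrorModel(
            label="wearable", rate_hz=147.0, noise_sd_deg=1.0,
        )
        roms = [
            _extract_rom(render_stream(g, m, seed=seed)) for seed in range(100)
        ]
        assert np.mean(roms) == pytest.approx(160.9, abs=0.5)

    def test_static_offset_cancels_in_rom(self, abd_profile):
        g = simulate_trial(abd_profile)
        m = SystemErrorModel(
            label="wearable", rate_hz=147.0,
            static_offset_deg={"x": 10.0, "z": 0.0, "y": 0.0},
        )
        out = render_stream(g, m, seed=0)
        # raw angles carry the offset; the range does not
        assert out.angles_deg[0, 0] == pytest.approx(10.0, abs=1e-6)
        assert _extract_rom(out) == pytest.approx(160.9, abs=0.1)

    def test_scale_equivariance_of_velocity(self, abd_profile):
        g = simulate_trial(abd_profile)
        m1 = SystemErrorModel(label="w", rate_hz=200.0)
        m2 = SystemErrorModel(
            label="w", rate_hz=200.0,
            amplitude_scale={"x": 0.5, "z": 1.0, "y": 1.0},
        )
        v1 = render_stream(g, m1, seed=0).velocities_deg_s[:, 0]
        v2 = render_stream(g, m2, seed=0).velocities_deg_s[:, 0]
        np.testing.assert_allclose(v2, 0.5 * v1, atol=1e-9)


class TestCohort:
    def test_determinism_byte_identical(self):
        spec = CohortSpec(n_subjects=3, movements=["ABD", "ER"], seed=11)
        ref = SystemErrorModel.default_reference()
        wear = SystemErrorModel.default_wearable()
        a = simulate_cohort(spec, ref, wear)
        b = simulate_cohort(spec, ref, wear)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.reference.angles_deg,
                                          pb.reference.angles_deg)
            np.testing.assert_array_equal(pa.wearable.angles_deg,
                                          pb.wearable.angles_deg)

    def test_structure(self):
        spec = CohortSpec(n_subjects=2, seed=0)
        pairs = simulate_cohort(
            spec,
            SystemErrorModel.default_reference(),
            SystemErrorModel.default_wearable(),
        )
        assert len(pairs) == 2 * len(mv.MOVEMENT_LABELS)
        p = pairs[0]
        assert p.reference.rate_hz == 500.0
        assert p.wearable.rate_hz == 147.0
        assert p.reference.movement_label == p.wearable.movement_label

    def test_amplitudes_truncated_and_positive(self):
        spec = CohortSpec(n_subjects=30, movements=["HEXT", "PNF"],
                          amplitude_sd_deg=15.0, seed=2)
        pairs = simulate_cohort(
            spec, SystemErrorModel.zero(), SystemErrorModel.zero(147, "wearable")
        )
        for p in pairs:
            for ch in p.profile.active_channels():
                assert p.profile.amplitude_deg(ch) > 0

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(n_subjects=1)


class TestOffsetAndScaleInvariants:
    """Range and derivative kill constants; scaling is equivariant."""

    @pytest.mark.parametrize("offset", [-25.0, 10.0, 180.0])
    def test_offset_invariance_of_outcomes(self, abd_stream_200, offset):
        from shoulderval.preprocess import remove_offset

        base = summarize_trial(remove_offset(abd_stream_200))
        shifted = abd_stream_200.copy()
        shifted.angles_deg = shifted.angles_deg + offset
        got = summarize_trial(remove_offset(shifted))
        assert got.rom_deg["ABD"] == pytest.approx(base.rom_deg["ABD"], abs=1e-9)
        assert got.pav_max_deg_s == pytest.approx(base.pav_max_deg_s, abs=1e-9)
        assert got.mav_deg_s["ABD"] == pytest.approx(
            base.mav_deg_s["ABD"], abs=1e-9
        )

    def test_scale_equivariance_of_outcomes(self, abd_stream_200):
        from shoulderval.preprocess import remove_offset

        base = summarize_trial(remove_offset(abd_stream_200))
        scaled = abd_stream_200.copy()
        scaled.angles_deg = scaled.angles_deg * 0.6
        scaled.velocities_deg_s = scaled.velocities_deg_s * 0.6
        got = summarize_trial(remove_offset(scaled))
        assert got.rom_deg["ABD"] == pytest.approx(0.6 * base.rom_deg["ABD"],
                                                   rel=1e-6)
        assert got.pav_max_deg_s == pytest.approx(0.6 * base.pav_max_deg_s,
                                                  rel=1e-6)
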