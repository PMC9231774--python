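"""Joint angles, gap repair, smoothing and angular velocity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from armcycle.errors import ValidationError
from armcycle.kinematics import (JointAngleSeries, angular_velocity,
                                 compute_joint_angles, fill_gaps, lowpass_filter)
from armcycle.markers import MarkerTrajectorySet


def _static_pose(acromion, hip, epicondyle, ulnar, n=5):
    """Trajectory of one repeated static pose (hand placed past the wrist)."""
    ulnar = np.asarray(ulnar, dtype=float)
    epi = np.asarray(epicondyle, dtype=float)
    f = ulnar - epi
    hand = ulnar + f / np.linalg.norm(f) * 60.0
    markers = np.array([hand, ulnar, epi, acromion, hip], dtype=float)
    positions = np.tile(markers[None, :, :], (n, 1, 1))
    positions = np.concatenate([positions, np.zeros((n, 5, 1))], axis=2)
    return MarkerTrajectorySet(positions=positions,
                               validity_mask=np.ones((n, 5), bool),
                               sampling_rate=100.0)


def _angles_from(values_s, values_e, fs=100.0, valid_s=None, valid_e=None):
    n = len(values_s)
    return JointAngleSeries(
        time=np.arange(n) / fs,
        shoulder_deg=np.asarray(values_s, float),
        elbow_deg=np.asarray(values_e, float),
        shoulder_valid=np.ones(n, bool) if valid_s is None else valid_s,
        elbow_valid=np.ones(n, bool) if valid_e is None else valid_e,
        sampling_rate=fs,
    )


class TestAngleConventions:
    def test_arm_alongside_body_is_zero(self):
        """Arm hanging parallel to the trunk: shoulder 0°, elbow 0°."""
        traj = _static_pose((0, 1000), (0, 500), (0, 700), (0, 440))
        angles = compute_joint_angles(traj)
        assert angles.shoulder_deg[0] == pytest.approx(0.0, abs=1e-9)
        assert angles.elbow_deg[0] == pytest.approx(0.0, abs=1e-9)

    def test_horizontal_arm_vertical_forearm_is_90_90(self):
        traj = _static_pose((0, 1000), (0, 500), (300, 1000), (300, 1260))
        angles = compute_joint_angles(traj)
        assert angles.shoulder_deg[0] == pytest.approx(90.0, abs=1e-9)
        assert angles.elbow_deg[0] == pytest.approx(90.0, abs=1e-9)

    def test_posterior_arm_reads_negative_extension(self):
        traj = _static_pose((0, 1000), (0, 500), (-150, 740), (-150, 480))
        angles = compute_joint_angles(traj)
        assert angles.shoulder_deg[0] < 0

    def test_matches_simulator_ground_truth(self, short_trajectory):
        truth = short_trajectory.meta["truth"]
        angles = compute_joint_angles(short_trajectory)
        assert np.abs(angles.shoulder_deg - truth["shoulder_angle_deg"]).max() < 1e-6
        assert np.abs(angles.elbow_deg - truth["elbow_angle_deg"]).max() < 1e-6

    def test_missing_marker_masks_dependent_joint(self, short_trajectory):
        traj = short_trajectory.copy()
        traj.validity_mask[50, traj.marker_names.index("ULN_STY")] = False
        traj.positions[50, traj.marker_names.index("ULN_STY")] = np.nan
        angles = compute_joint_angles(traj)
        assert not angles.elbow_valid[50]
        assert angles.shoulder_valid[50]  # shoulder does not use the wrist

    def test_coincident_markers_mask_with_warning(self):
        traj = _static_pose((0, 1000), (0, 500), (0, 700), (0, 440))
        traj.positions[2, 3] = traj.positions[2, 4]  # acromion collapses onto hip
        with pytest.warns(UserWarning, match="coincident"):
            angles = compute_joint_angles(traj)
        assert not angles.shoulder_valid[2]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(angle=st.floats(-np.pi, np.pi),
           tx=st.floats(-500, 500), ty=st.floats(-500, 500))
    def test_rigid_transform_invariance(self, angle, tx, ty):
        """In-plane rotation + translation of all markers leaves angles fixed."""
        traj = _static_pose((0, 1000), (0, 500), (120, 760), (300, 860), n=3)
        ref = compute_joint_angles(traj)
        rot = np.array([[np.cos(angle), -np.sin(angle)],
                        [np.sin(angle), np.cos(angle)]])
        moved = traj.copy()
        moved.positions[..., :2] = traj.positions[..., :2] @ rot.T + (tx, ty)
        out = compute_joint_angles(moved)
        assert abs(out.shoulder_deg[0] - ref.shoulder_deg[0]) < 1e-9
        assert abs(out.elbow_deg[0] - ref.elbow_deg[0]) < 1e-9


class TestFillGaps:
    def test_gap_free_series_unchanged(self, sinusoid_angles):
        t, s, e, fs = sinusoid_angles
        angles = _angles_from(s, e, fs)
        out = fill_gaps(angles, 0.5)
        np.testing.assert_array_equal(out.shoulder_deg, angles.shoulder_deg)

    def test_short_gap_filled_close_to_truth(self, sinusoid_angles):
        t, s, e, fs = sinusoid_angles
        valid = np.ones(len(s), bool)
        valid[1000:1020] = False  # 0.2 s carved out
        angles = _angles_from(s, e, fs, valid_s=valid.copy(), valid_e=valid.copy())
        out = fill_gaps(angles, 0.5)
        assert out.shoulder_valid[1000:1020].all()
        assert np.abs(out.shoulder_deg[1000:1020] - s[1000:1020]).max() < 0.5
        assert out.provenance["filled"]["shoulder"][1000:1020].all()

    def test_long_gap_left_invalid(self, sinusoid_angles):
        t, s, e, fs = sinusoid_angles
        valid = np.ones(len(s), bool)
        valid[1000:1100] = False  # 1 s
        angles = _angles_from(s, e, fs, valid_s=valid.copy(), valid_e=valid.copy())
        out = fill_gaps(angles, 0.5)
        assert not out.shoulder_valid[1000:1100].any()

    def test_all_invalid_errors(self):
        angles = _angles_from(np.zeros(100), np.zeros(100),
                              valid_s=np.zeros(100, bool),
                              valid_e=np.zeros(100, bool))
        with pytest.raises(ValidationError):
            fill_gaps(angles, 0.5)


class TestLowpass:
    def test_dc_unchanged(self):
        angles = _angles_from(np.full(1000, 42.0), np.full(1000, 17.0))
        out = lowpass_filter(angles, 6.0)
        np.testing.assert_allclose(out.shoulder_deg, 42.0, atol=1e-8)

    def test_passband_attenuation_below_1pct(self, sinusoid_angles):
        t, s, e, fs = sinusoid_angles
        out = lowpass_filter(_angles_from(s, e, fs), 6.0)
        amp = (out.shoulder_deg[500:2500].max() - out.shoulder_deg[500:2500].min()) / 2
        assert amp == pytest.approx(22.0, rel=0.01)

    def test_stopband_attenuation_above_95pct(self):
        fs = 100.0
        t = np.arange(3000) / fs
        mix = 20 * np.sin(2 * np.pi * t) + 5 * np.sin(2 * np.pi * 25 * t)
        out = lowpass_filter(_angles_from(mix, mix, fs), 6.0)
        resid = out.shoulder_deg[500:2500] - 20 * np.sin(2 * np.pi * t[500:2500])
        # amplitude of what remains of the 25 Hz component
        high = resid - resid.mean()
        assert np.abs(high).max() < 0.05 * 5

    def test_cutoff_at_nyquist_rejected(self, sinusoid_angles):
        t, s, e, fs = sinusoid_angles
        with pytest.raises(ValidationError):
            lowpass_filter(_angles_from(s, e, fs), 50.0)

    def test_short_runs_passed_through_with_flag(self):
        valid = np.zeros(100, bool)
        valid[:12] = True  # shorter than the filtfilt warm-up (15 samples)
        raw = np.sin(np.arange(100.0))
        angles = _angles_from(raw.copy(), raw.copy(),
                              valid_s=valid.copy(), valid_e=valid.copy())
        out = lowpass_filter(angles, 6.0)
        np.testing.assert_array_equal(out.shoulder_deg[:12], raw[:12])
        assert out.provenance["unfiltered_runs"]


class TestAngularVelocity:
    def test_constant_angle_zero_velocity(self):
        vel = angular_velocity(_angles_from(np.full(500, 90.0), np.full(500, 45.0)))
        np.testing.assert_allclose(vel.shoulder_velocity, 0.0, atol=1e-10)

    def test_sinusoid_peak_velocity_matches_analytic(self):
        fs = 100.0
        t = np.arange(3000) / fs
        theta = 40.0 * np.sin(2 * np.pi * t)
        vel = angular_velocity(_angles_from(theta, theta, fs))
        expected = 2 * np.pi * 40.0  # ≈ 251.3 °/s
        assert np.abs(vel.shoulder_velocity).max() == pytest.approx(expected, rel=0.005)

    def test_linear_ramp_exact(self):
        fs = 100.0
        ramp = 10.0 * np.arange(500) / fs
        vel = angular_velocity(_angles_from(ramp, ramp, fs))
        np.testing.assert_allclose(vel.shoulder_velocity[1:-1], 10.0, atol=1e-9)

    def test_all_invalid_errors(self):
        angles = _angles_from(np.zeros(10), np.zeros(10),
                              valid_s=np.zeros(10, bool),
                              valid_e=np.zeros(10, bool))
        with pytest.raises(ValidationError):
            angular_velocity(angles)

    def test_filter_then_differentiate_preserves_peak_velocity(self):
        """< 1% change in max velocity for a noiseless band-limited signal."""
        fs = 100.0
        t = np.arange(3000) / fs
        theta = 30.0 * np.sin(2 * np.pi * t) + 5.0 * np.sin(2 * np.pi * 2 * t)
        raw = angular_velocity(_angles_from(theta, theta, fs))
        filt = angular_velocity(lowpass_filter(_angles_from(theta, theta, fs), 6.0))
        vmax_raw = np.abs(raw.shoulder_velocity[300:2700]).max()
        vmax_filt = np.abs(filt.shoulder_velocity[300:2700]).max()
        assert vmax_filt == pytest.approx(vmax_raw, rel=0.01)
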