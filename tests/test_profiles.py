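"""Movement-profile features: peaks, cadence, lag, phase, correlation, ROM."""

import numpy as np
import pytest

from armcycle.errors import ValidationError
from armcycle.kinematics import angular_velocity, compute_joint_angles
from armcycle.pipeline import process_angles
from armcycle.profiles import (ProfileParams, build_movement_profile,
                               compute_cadence, compute_time_lag,
                               detect_cycle_peaks, effort_window,
                               extract_window, mean_phase_angle, rom_summary,
                               signal_correlation)
from armcycle.simulate import SimulationConfig, simulate_crank_cycling

FS = 100.0


def _sine(freq=1.0, amp=40.0, offset=0.0, duration=30.0, mean=0.0):
    t = np.arange(int(duration * FS)) / FS
    return mean + amp * np.sin(2 * np.pi * freq * t + np.radians(offset))


def brute_force_xcorr(x, y, fs, max_lag_s):
    """Independent oracle: per-lag Pearson coefficient by explicit loops."""
    n = len(x)
    max_lag = int(round(max_lag_s * fs))
    best = (-2.0, None)
    for k in range(-max_lag, max_lag + 1):
        pairs = [(x[t], y[t + k]) for t in range(n)
                 if 0 <= t + k < n
                 and np.isfinite(x[t]) and np.isfinite(y[t + k])]
        if len(pairs) < 3:
            continue
        a = np.array([p[0] for p in pairs])
        b = np.array([p[1] for p in pairs])
        a -= a.mean()
        b -= b.mean()
        r = float(a @ b / np.sqrt((a @ a) * (b @ b)))
        if r > best[0] + 1e-12 or (abs(r - best[0]) <= 1e-12
                                   and abs(k) < abs(best[1])):
            best = (r, k)
    return best[0], best[1] / fs


def brute_force_peaks(values, prominence, min_sep_frames):
    """All strict local maxima with simple prominence, greedily thinned."""
    cands = []
    for i in range(1, len(values) - 1):
        if not (values[i] > values[i - 1] and values[i] >= values[i + 1]):
            continue
        left = values[:i + 1][::-1]
        right = values[i:]
        base_l = min(left[:np.argmax(left >= values[i], ) + 1].min(), values[i])
        lo_l = left.min() if (left >= values[i]).sum() <= 1 else \
            left[1:np.flatnonzero(left[1:] > values[i])[0] + 1].min() \
            if (left[1:] > values[i]).any() else left.min()
        lo_r = right.min() if not (right[1:] > values[i]).any() else \
            right[1:np.flatnonzero(right[1:] > values[i])[0] + 1].min()
        if values[i] - max(lo_l, lo_r) < prominence:
            continue
        cands.append(i)
    cands.sort(key=lambda i: -values[i])
    kept = []
    for i in cands:
        if all(abs(i - j) >= min_sep_frames for j in kept):
            kept.append(i)
    return sorted(kept)


class TestWindowing:
    def test_full_length_window_is_identity(self, sinusoid_angles):
        t, s, e, fs = sinusoid_angles
        cfg = SimulationConfig(cadence_profile=60.0, duration=30.0)
        angles = compute_joint_angles(simulate_crank_cycling(cfg))
        out = extract_window(angles, 0.0, 30.0)
        np.testing.assert_array_equal(out.shoulder_deg, angles.shoulder_deg)

    def test_window_frame_arithmetic(self):
        cfg = SimulationConfig(session_structure=((120.0, 30.0),) * 2)
        angles = compute_joint_angles(simulate_crank_cycling(cfg))
        win = effort_window(angles, 1, 0.0, 30.0)
        assert win.n_frames == 3000

    def test_window_beyond_recording_rejected(self, sinusoid_angles):
        cfg = SimulationConfig(cadence_profile=60.0, duration=10.0)
        angles = compute_joint_angles(simulate_crank_cycling(cfg))
        with pytest.raises(ValidationError, match="exceeds"):
            extract_window(angles, 5.0, 10.0)

    def test_window_crossing_rest_names_effort_bounds(self):
        cfg = SimulationConfig(session_structure=((20.0, 10.0), (20.0, 10.0)))
        angles = compute_joint_angles(simulate_crank_cycling(cfg))
        with pytest.raises(ValidationError, match="effort 1"):
            effort_window(angles, 1, 10.0, 15.0)


class TestPeaksAndCadence:
    def test_sinusoid_peak_count_and_spacing(self):
        x = _sine(freq=1.0, amp=40.0)
        peaks = detect_cycle_peaks(x, np.ones(len(x), bool), FS,
                                   min_prominence_deg=10.0)
        assert len(peaks) == 30
        assert np.abs(np.diff(peaks) - 1.0).max() < 0.01

    def test_constant_series_has_no_peaks(self):
        peaks = detect_cycle_peaks(np.full(1000, 5.0), np.ones(1000, bool), FS)
        assert peaks.size == 0

    def test_separation_constraint_matches_brute_force(self):
        """Two interleaved trains: the greedy filter keeps what the oracle keeps."""
        t = np.arange(3000) / FS
        x = 30 * np.sin(2 * np.pi * 0.7 * t) + 20 * np.sin(2 * np.pi * 1.2 * t)
        got = detect_cycle_peaks(x, np.ones(len(x), bool), FS,
                                 min_prominence_deg=10.0, min_separation_s=1.5)
        expected = brute_force_peaks(x, 10.0, int(1.5 * FS))
        assert len(got) == len(expected)
        assert np.abs(got - np.array(expected) / FS).max() < 0.02

    def test_no_peak_on_gap_adjacent_frames(self):
        x = _sine()
        valid = np.ones(len(x), bool)
        # carve gaps right next to the true peak at t=0.25 s
        valid[24:26] = False
        peaks = detect_cycle_peaks(x, valid, FS)
        assert np.abs(peaks - 0.25).min() > 0.005

    def test_cadence_arithmetic(self):
        peaks = np.linspace(0.0, 30.0, 31)  # 31 peaks spanning 30 s
        assert compute_cadence(peaks) == pytest.approx(60.0)

    def test_cadence_recovery_from_simulation(self):
        cfg = SimulationConfig(cadence_profile=68.0, duration=30.0)
        angles = compute_joint_angles(simulate_crank_cycling(cfg))
        peaks = detect_cycle_peaks(angles.elbow_deg, angles.elbow_valid, FS)
        assert compute_cadence(peaks) == pytest.approx(68.0, abs=0.5)

    def test_single_peak_cadence_undefined(self):
        assert np.isnan(compute_cadence(np.array([3.0])))


class TestTimeLag:
    def test_identical_peak_lists_zero_lag(self):
        peaks = np.arange(10.0)
        assert compute_time_lag(peaks, peaks, 1.0).lag_s == pytest.approx(0.0)

    def test_simulated_offset_recovers_tenth_second(self):
        cfg = SimulationConfig(cadence_profile=60.0, duration=30.0,
                               elbow_shoulder_phase_offset=36.0)
        angles = compute_joint_angles(simulate_crank_cycling(cfg))
        ps = detect_cycle_peaks(angles.shoulder_deg, angles.shoulder_valid, FS)
        pe = detect_cycle_peaks(angles.elbow_deg, angles.elbow_valid, FS)
        lag = compute_time_lag(ps, pe, 1.0)
        assert lag.lag_s == pytest.approx(0.10, abs=0.01)

    def test_late_elbow_gives_negative_lag(self):
        shoulder = np.arange(10.0)
        elbow = shoulder + 0.2
        lag = compute_time_lag(shoulder, elbow, 1.0)
        assert lag.lag_s == pytest.approx(-0.2)

    def test_unpaired_peaks_dropped_and_counted(self):
        shoulder = np.array([0.0, 1.0, 2.0, 3.0])
        elbow = np.array([0.05, 1.05, 7.0])
        lag = compute_time_lag(shoulder, elbow, 1.0)
        assert lag.n_pairs == 2 and lag.n_dropped == 3

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            compute_time_lag(np.array([]), np.array([1.0]), 1.0)


class TestMeanPhaseAngle:
    def test_identical_signals_zero_phase(self):
        x = _sine()
        assert mean_phase_angle(x, x, FS) == pytest.approx(0.0, abs=0.5)

    def test_sinusoids_offset_36_degrees(self):
        s = _sine(offset=0.0, amp=1.0)
        e = _sine(offset=36.0, amp=1.0)
        assert mean_phase_angle(s, e, FS) == pytest.approx(36.0, abs=0.5)

    def test_antiphase_sinusoids(self):
        s = _sine()
        assert mean_phase_angle(s, -s, FS) == pytest.approx(180.0, abs=0.5)

    def test_insufficient_cycles_flagged_nan(self):
        s = _sine(duration=3.0)
        assert np.isnan(mean_phase_angle(s, s, FS))

    def test_zero_amplitude_rejected(self):
        with pytest.raises(ValidationError):
            mean_phase_angle(np.zeros(3000), _sine(), FS)

    def test_consistent_with_time_lag_for_sinusoids(self):
        """lag × cadence/60 × 360 equals the phase angle within 2°."""
        s = _sine(amp=30.0)
        e = _sine(amp=30.0, offset=25.0)
        phase = mean_phase_angle(s, e, FS)
        ps = detect_cycle_peaks(s, np.ones(len(s), bool), FS)
        pe = detect_cycle_peaks(e, np.ones(len(e), bool), FS)
        lag = compute_time_lag(ps, pe, 1.0).lag_s
        assert lag * 1.0 * 360 == pytest.approx(phase, abs=2.0)


class TestSignalCorrelation:
    def test_autocorrelation_is_one_at_zero_lag(self):
        x = _sine()
        res = signal_correlation(x, x, FS, max_lag_s=0.5)
        assert res.r_max == pytest.approx(1.0, abs=1e-12)
        assert res.lag_s == 0.0

    def test_delayed_copy_found_at_its_delay(self):
        t = np.arange(3000) / FS
        x = 40 * np.sin(2 * np.pi * t)
        y = 40 * np.sin(2 * np.pi * (t - 0.1))
        res = signal_correlation(x, y, FS, max_lag_s=0.5)
        assert res.lag_s == pytest.approx(0.1, abs=1e-9)
        assert res.r_max > 0.999

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            n = int(rng.integers(400, 1200))
            x = rng.normal(size=n).cumsum()
            y = rng.normal(size=n).cumsum()
            res = signal_correlation(x, y, FS, max_lag_s=0.3)
            r_ref, lag_ref = brute_force_xcorr(x, y, FS, 0.3)
            assert abs(res.r_max - r_ref) < 1e-10
            assert res.lag_s == pytest.approx(lag_ref, abs=1e-12)

    def test_noise_stays_below_null_bound(self):
        x = _sine()
        rng = np.random.default_rng(0)
        worst = max(signal_correlation(x, rng.normal(size=len(x)), FS, 1.0).r_max
                    for _ in range(50))
        assert worst < 0.2

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            signal_correlation(np.full(3000, 3.0), _sine(), FS, 0.5)

    def test_time_reversal_negates_lag(self):
        t = np.arange(3000) / FS
        x = 40 * np.sin(2 * np.pi * t) + 3 * np.sin(2 * np.pi * 2 * t)
        y = 40 * np.sin(2 * np.pi * (t - 0.07))
        fwd = signal_correlation(x, y, FS, 0.4)
        rev = signal_correlation(x[::-1].copy(), y[::-1].copy(), FS, 0.4)
        assert rev.lag_s == pytest.approx(-fwd.lag_s, abs=1e-9)


class TestRomSummary:
    def test_constant_series(self):
        assert rom_summary(np.full(10, 90.0)) == (90.0, 90.0, 0.0)

    def test_sinusoid_extrema(self):
        x = _sine(amp=22.0, mean=105.0)
        mn, mx, rng = rom_summary(x)
        assert mn == pytest.approx(83.0, abs=0.01)
        assert mx == pytest.approx(127.0, abs=0.01)
        assert rng == pytest.approx(44.0, abs=0.02)

    def test_masked_spike_excluded(self):
        x = _sine()
        x[500] = 1e6
        valid = np.ones(len(x), bool)
        valid[500] = False
        assert rom_summary(x, valid)[1] < 100

    def test_all_invalid_rejected(self):
        with pytest.raises(ValidationError):
            rom_summary(np.array([np.nan, np.nan]))


class TestBuildMovementProfile:
    def test_noiseless_simulation_recovered(self):
        cfg = SimulationConfig(cadence_profile=60.0, duration=30.0,
                               elbow_shoulder_phase_offset=36.0)
        traj = simulate_crank_cycling(cfg)
        angles = process_angles(traj)
        profile = build_movement_profile(angles, angular_velocity(angles))
        assert profile.cadence_cpm == pytest.approx(60.0, abs=0.5)
        assert profile.time_lag_s == pytest.approx(0.10, abs=0.01)
        assert profile.mean_phase_angle_deg == pytest.approx(36.0, abs=1.0)
        assert profile.signal_correlation >= 0.95
        assert profile.n_cycles >= 28
        assert profile.shoulder_range_deg == pytest.approx(
            profile.shoulder_max_deg - profile.shoulder_min_deg)

    def test_all_masked_input_yields_flags_not_crash(self):
        import numpy as np
        from armcycle.kinematics import JointAngleSeries
        n = 1000
        angles = JointAngleSeries(
            time=np.arange(n) / FS,
            shoulder_deg=np.full(n, np.nan), elbow_deg=np.full(n, np.nan),
            shoulder_valid=np.zeros(n, bool), elbow_valid=np.zeros(n, bool),
            sampling_rate=FS)
        profile = build_movement_profile(angles)
        assert profile.flags  # plenty of them
        assert np.isnan(profile.cadence_cpm)

    def test_deterministic_on_identical_input(self):
        cfg = SimulationConfig(cadence_profile=52.0, duration=30.0,
                               elbow_shoulder_phase_offset=20.0)
        traj = simulate_crank_cycling(cfg)
        angles = process_angles(traj)
        a = build_movement_profile(angles, angular_velocity(angles))
        b = build_movement_profile(angles, angular_velocity(angles))
        for name in a.FEATURE_NAMES:
            assert getattr(a, name) == getattr(b, name)

    def test_time_reversal_negates_time_lag(self):
        cfg = SimulationConfig(cadence_profile=60.0, duration=30.0,
                               elbow_shoulder_phase_offset=30.0)
        angles = process_angles(simulate_crank_cycling(cfg))
        fwd = build_movement_profile(angles)
        rev = angles.copy()
        rev.shoulder_deg = rev.shoulder_deg[::-1].copy()
        rev.elbow_deg = rev.elbow_deg[::-1].copy()
        bwd = build_movement_profile(rev)
        assert bwd.time_lag_s == pytest.approx(-fwd.time_lag_s, abs=0.01)
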