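"""Movement-profile features of windowed shoulder/elbow angle series.

The feature set characterises inter-joint coordination during cyclic arm
cranking: cycle peaks and cadence, the mean time lag between elbow- and
shoulder-angle peaks (positive = elbow leads), the mean continuous relative
phase between the two joints, the lag-maximised normalised
cross-correlation, per-joint range-of-motion extrema, maximum angular
velocities, and the paired angle-angle samples used for coordination plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, hilbert

from .errors import ValidationError
from .kinematics import AngularVelocitySeries, JointAngleSeries, _valid_runs

__all__ = [
    "ProfileParams",
    "MovementProfile",
    "CorrelationResult",
    "TimeLagResult",
    "extract_window",
    "effort_window",
    "detect_cycle_peaks",
    "compute_cadence",
    "compute_time_lag",
    "mean_phase_angle",
    "signal_correlation",
    "rom_summary",
    "build_movement_profile",
]


@dataclass
class ProfileParams:
    """Feature-extraction parameters.

    Defaults: peak prominence 10° and separation 0.4 s (admits cadences up
    to 150 cycles/min); cross-correlation searched over ±1 cycle of lag; a
    minimum of 5 cycles for the relative-phase estimate.
    """

    min_prominence_deg: float = 10.0
    min_separation_s: float = 0.4
    max_lag_cycles: float = 1.0
    min_cycles_for_phase: int = 5


@dataclass
class TimeLagResult:
    lag_s: float  # nan when undefined
    n_pairs: int
    n_dropped: int


@dataclass
class CorrelationResult:
    r_max: float
    lag_s: float
    r_zero_lag: float


@dataclass
class MovementProfile:
    """Per-recording/per-effort feature bundle."""

    participant_id: str
    effort_index: int
    window: tuple[float, float]  # (start_s, duration_s)
    cadence_cpm: float = np.nan
    time_lag_s: float = np.nan  # positive = elbow peak precedes shoulder peak
    mean_phase_angle_deg: float = np.nan
    signal_correlation: float = np.nan
    correlation_lag_s: float = np.nan
    shoulder_min_deg: float = np.nan
    shoulder_max_deg: float = np.nan
    shoulder_range_deg: float = np.nan
    elbow_min_deg: float = np.nan
    elbow_max_deg: float = np.nan
    elbow_range_deg: float = np.nan
    shoulder_max_velocity: float = np.nan
    elbow_max_velocity: float = np.nan
    n_cycles: int = 0
    angle_angle_pairs: np.ndarray | None = None
    flags: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    FEATURE_NAMES = (
        "cadence_cpm", "time_lag_s", "mean_phase_angle_deg", "signal_correlation",
        "correlation_lag_s", "shoulder_min_deg", "shoulder_max_deg",
        "shoulder_range_deg", "elbow_min_deg", "elbow_max_deg", "elbow_range_deg",
        "shoulder_max_velocity", "elbow_max_velocity", "n_cycles",
    )

    def to_row(self) -> dict:
        row = {"participant_id": self.participant_id,
               "effort_index": self.effort_index,
               "window_start_s": self.window[0],
               "window_duration_s": self.window[1]}
        row.update({name: getattr(self, name) for name in self.FEATURE_NAMES})
        row["flags"] = ";".join(sorted(self.flags)) if self.flags else ""
        return row


# ---------------------------------------------------------------------------
# windowing


def extract_window(angles: JointAngleSeries, start_s: float,
                   duration_s: float) -> JointAngleSeries:
    """Slice ``[start_s, start_s + duration_s)`` out of an angle series."""
    if duration_s <= 0:
        raise ValidationError("duration_s must be positive")
    fs = angles.sampling_rate
    i0 = int(round(start_s * fs))
    i1 = i0 + int(round(duration_s * fs))
    if i0 < 0 or i1 > angles.n_frames:
        raise ValidationError(
            f"window [{start_s}, {start_s + duration_s}) s exceeds recording of "
            f"{angles.n_frames / fs:.2f} s")
    sl = slice(i0, i1)
    return JointAngleSeries(
        time=angles.time[sl].copy(),
        shoulder_deg=angles.shoulder_deg[sl].copy(),
        elbow_deg=angles.elbow_deg[sl].copy(),
        shoulder_valid=angles.shoulder_valid[sl].copy(),
        elbow_valid=angles.elbow_valid[sl].copy(),
        sampling_rate=fs,
        effort_labels=None if angles.effort_labels is None
        else angles.effort_labels[sl].copy(),
        participant_id=angles.participant_id,
        provenance={**angles.provenance, "window": (start_s, duration_s)},
    )


def effort_window(angles: JointAngleSeries, effort_index: int,
                  offset_s: float = 0.0, duration_s: float = 25.0) -> JointAngleSeries:
    """Window addressed as (effort index, offset): slice ``duration_s`` of an
    exercise effort starting ``offset_s`` after the effort begins."""
    if angles.effort_labels is None:
        raise ValidationError("series carries no effort labels")
    idx = np.flatnonzero(angles.effort_labels == effort_index)
    if idx.size == 0:
        raise ValidationError(f"no frames labelled effort {effort_index}")
    fs = angles.sampling_rate
    start = idx[0] / fs + offset_s
    effort_end = (idx[-1] + 1) / fs
    if start + duration_s > effort_end + 0.5 / fs:
        raise ValidationError(
            f"window [{start:.2f}, {start + duration_s:.2f}) s crosses the end of "
            f"effort {effort_index} (spans {idx[0] / fs:.2f}–{effort_end:.2f} s)")
    return extract_window(angles, start, duration_s)


# ---------------------------------------------------------------------------
# peaks, cadence, lag


def _refine_peak_time(time: np.ndarray, values: np.ndarray, i: int,
                      half_width: int = 4) -> float:
    """Sub-frame peak time by a least-squares parabola around sample ``i``."""
    lo = max(0, i - half_width)
    hi = min(len(values), i + half_width + 1)
    if hi - lo < 3:
        return float(time[i])
    t = time[lo:hi] - time[i]
    coef = np.polyfit(t, values[lo:hi], 2)
    if coef[0] >= 0:  # not locally concave; keep the sample time
        return float(time[i])
    t_peak = -coef[1] / (2 * coef[0])
    dt = time[1] - time[0]
    t_peak = float(np.clip(t_peak, -half_width * dt, half_width * dt))
    return float(time[i] + t_peak)


def detect_cycle_peaks(values: np.ndarray, valid: np.ndarray, sampling_rate: float,
                       min_prominence_deg: float = 10.0,
                       min_separation_s: float = 0.4,
                       time: np.ndarray | None = None) -> np.ndarray:
    """Times of cycle peaks: local maxima with the requested prominence,
    thinned so no two survive within ``min_separation_s`` (greedy by height,
    as in :func:`scipy.signal.find_peaks`). Peaks adjacent to gaps are
    discarded; an empty array (not an error) is returned when nothing
    qualifies. Peak times are refined to sub-frame precision by a local
    parabolic fit.
    """
    valid = np.asarray(valid, dtype=bool)
    if not valid.any():
        raise ValidationError("series has no valid run")
    if time is None:
        time = np.arange(len(values)) / sampling_rate
    candidates: list[tuple[float, float]] = []  # (time, height)
    for start, stop in _valid_runs(valid):
        seg = np.asarray(values[start:stop], dtype=float)
        if len(seg) < 3:
            continue
        peaks, _ = find_peaks(seg, prominence=min_prominence_deg)
        # parabola half-width ~ 1/8 cycle: wide enough to average noise,
        # narrow enough for the quadratic approximation to hold
        if len(peaks) >= 2:
            half_width = max(4, int(np.median(np.diff(peaks)) / 8))
        else:
            half_width = 4
        for p in peaks:
            if p <= 0 or p >= len(seg) - 1:
                continue  # never place a peak on a gap-adjacent frame
            t = _refine_peak_time(time[start:stop], seg, int(p), half_width)
            candidates.append((t, float(seg[p])))
    if not candidates:
        return np.array([])
    # greedy separation filter, highest peak first
    candidates.sort(key=lambda c: -c[1])
    kept: list[float] = []
    for t, _ in candidates:
        if all(abs(t - k) >= min_separation_s for k in kept):
            kept.append(t)
    return np.array(sorted(kept))


def compute_cadence(peak_times: np.ndarray,
                    window_duration_s: float | None = None) -> float:
    """Cycles per minute from the inter-peak span: ``(n−1)/(t_last−t_first)·60``.

    The window length is deliberately not used, to avoid edge bias. Returns
    NaN (undefined) with fewer than two peaks.
    """
    peak_times = np.asarray(peak_times, dtype=float)
    if peak_times.size < 2:
        return float("nan")
    span = peak_times[-1] - peak_times[0]
    if span <= 0:
        return float("nan")
    return float((peak_times.size - 1) / span * 60.0)


def compute_time_lag(shoulder_peaks: np.ndarray, elbow_peaks: np.ndarray,
                     cycle_period_s: float) -> TimeLagResult:
    """Mean of (shoulder peak time − nearest elbow peak time) over pairs
    matched within ± half a cycle; positive means the elbow leads.

    Each shoulder peak is used at most once; unmatched peaks are dropped and
    counted.
    """
    if cycle_period_s <= 0 or not np.isfinite(cycle_period_s):
        raise ValidationError("cycle_period_s must be positive")
    shoulder_peaks = np.sort(np.asarray(shoulder_peaks, dtype=float))
    elbow_peaks = np.sort(np.asarray(elbow_peaks, dtype=float))
    if shoulder_peaks.size == 0 or elbow_peaks.size == 0:
        raise ValidationError("both peak lists must be non-empty")
    tol = cycle_period_s / 2.0
    available = np.ones(shoulder_peaks.size, dtype=bool)
    diffs: list[float] = []
    for te in elbow_peaks:
        order = np.argsort(np.abs(shoulder_peaks - te))
        for j in order:
            if available[j] and abs(shoulder_peaks[j] - te) <= tol:
                diffs.append(shoulder_peaks[j] - te)
                available[j] = False
                break
    n_pairs = len(diffs)
    n_dropped = (elbow_peaks.size - n_pairs) + int(available.sum())
    lag = float(np.mean(diffs)) if n_pairs else float("nan")
    return TimeLagResult(lag_s=lag, n_pairs=n_pairs, n_dropped=n_dropped)


# ---------------------------------------------------------------------------
# continuous relative phase


def _per_cycle_normalise(values: np.ndarray, peak_times: np.ndarray,
                         time: np.ndarray) -> np.ndarray:
    """Centre and amplitude-normalise a cyclic signal cycle by cycle.

    Cycle boundaries are the signal's own peaks; each segment is mapped to
    roughly [−1, 1] by its mid-range and half-range. Edge segments reuse the
    neighbouring cycle's scaling.
    """
    bounds = np.searchsorted(time, peak_times)
    edges = np.concatenate([[0], bounds, [len(values)]])
    out = np.empty_like(values, dtype=float)
    segments = [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)
                if edges[i + 1] > edges[i]]
    scales: list[tuple[float, float]] = []
    for start, stop in segments:
        seg = values[start:stop]
        vmax, vmin = np.nanmax(seg), np.nanmin(seg)
        scales.append(((vmax + vmin) / 2.0, (vmax - vmin) / 2.0))
    for k, ((start, stop), (center, half_range)) in enumerate(zip(segments, scales)):
        if half_range <= 1e-12:  # flat edge segment: borrow the neighbour's scale
            neighbour = scales[1] if k == 0 else scales[k - 1]
            center, half_range = neighbour
        if half_range <= 1e-12:
            raise ValidationError("zero-amplitude series: relative phase undefined")
        out[start:stop] = (values[start:stop] - center) / half_range
    return out


def _circmean(angles: np.ndarray) -> float:
    return float(np.angle(np.mean(np.exp(1j * angles))))


def mean_phase_angle(shoulder: np.ndarray, elbow: np.ndarray, sampling_rate: float,
                     params: ProfileParams | None = None) -> float:
    """Mean continuous relative phase between elbow and shoulder, degrees.

    Procedure: each series is centred and amplitude-normalised cycle by
    cycle (its own peaks delimit the cycles), band-limited to the cycle
    fundamental (0.5–1.5 × the cycle frequency, zero-phase Butterworth) and
    given an instantaneous phase by the analytic (Hilbert) signal. Each
    signal's phase is referenced to its own cycle peaks (phase at a peak is
    90° by definition), so the relative phase φ(t) = φ_elbow − φ_shoulder,
    wrapped to (−180°, 180°], measures elbow lead directly in cycle
    fractions. The magnitude of the circular mean of φ over the window
    interior (one cycle trimmed at each end) is returned, in [0, 180].

    The band-limiting and peak referencing remove the rectification and
    waveform-shape biases a naive mean of |φ| suffers at small offsets;
    without them a perfectly synchronised but non-sinusoidal pair would
    report several degrees of spurious phase.

    Requires ≥ ``params.min_cycles_for_phase`` full cycles (NaN otherwise)
    and gap-free input (fill gaps first); zero-amplitude input is an error.
    """
    params = params or ProfileParams()
    shoulder = np.asarray(shoulder, dtype=float)
    elbow = np.asarray(elbow, dtype=float)
    if shoulder.shape != elbow.shape:
        raise ValidationError("series must have equal length")
    if not (np.isfinite(shoulder).all() and np.isfinite(elbow).all()):
        raise ValidationError("relative phase requires gap-free input; fill gaps first")
    if np.ptp(shoulder) < 1e-12 or np.ptp(elbow) < 1e-12:
        raise ValidationError("zero-amplitude series: relative phase undefined")
    time = np.arange(len(shoulder)) / sampling_rate
    valid = np.ones(len(shoulder), dtype=bool)
    # prominence adapted to the excursion so unit-amplitude signals also work
    prom_s = min(params.min_prominence_deg, 0.25 * float(np.ptp(shoulder)))
    prom_e = min(params.min_prominence_deg, 0.25 * float(np.ptp(elbow)))
    peaks_s = detect_cycle_peaks(shoulder, valid, sampling_rate,
                                 prom_s, params.min_separation_s)
    peaks_e = detect_cycle_peaks(elbow, valid, sampling_rate,
                                 prom_e, params.min_separation_s)
    n_cycles = min(peaks_s.size, peaks_e.size) - 1
    if n_cycles < params.min_cycles_for_phase:
        return float("nan")
    xs = _per_cycle_normalise(shoulder, peaks_s, time)
    xe = _per_cycle_normalise(elbow, peaks_e, time)
    f0 = 1.0 / float(np.median(np.diff(peaks_s)))
    nyq = sampling_rate / 2.0
    if 1.5 * f0 < nyq:
        from scipy.signal import butter, filtfilt
        b, a = butter(2, [0.5 * f0 / nyq, min(1.5 * f0, 0.99 * nyq) / nyq],
                      btype="band")
        xs = filtfilt(b, a, xs)
        xe = filtfilt(b, a, xe)
    phase_s = np.angle(hilbert(xs))
    phase_e = np.angle(hilbert(xe))
    # the phase reference uses interior peaks only: the analytic signal is
    # unreliable within ~one cycle of the window edges
    t_end = len(xs) / sampling_rate
    margin = 1.0 / f0

    def _interior(peaks: np.ndarray) -> np.ndarray:
        inner = peaks[(peaks >= margin) & (peaks <= t_end - margin)]
        return inner if inner.size else peaks

    idx_s = np.clip(np.round(_interior(peaks_s) * sampling_rate).astype(int),
                    0, len(xs) - 1)
    idx_e = np.clip(np.round(_interior(peaks_e) * sampling_rate).astype(int),
                    0, len(xe) - 1)
    phase_s = phase_s + (np.pi / 2 - _circmean(phase_s[idx_s]))
    phase_e = phase_e + (np.pi / 2 - _circmean(phase_e[idx_e]))
    rel = np.angle(np.exp(1j * (phase_e - phase_s)))  # wrap to (−π, π]
    trim = int(round(sampling_rate / f0))
    core = rel[trim:len(rel) - trim] if len(rel) > 2 * trim else rel
    return float(abs(np.degrees(_circmean(core))))


# ---------------------------------------------------------------------------
# cross-correlation


def signal_correlation(shoulder: np.ndarray, elbow: np.ndarray, sampling_rate: float,
                       max_lag_s: float,
                       shoulder_valid: np.ndarray | None = None,
                       elbow_valid: np.ndarray | None = None) -> CorrelationResult:
    """Lag-maximised normalised cross-correlation between the two series.

    For every integer-frame lag k in [−max_lag_s, +max_lag_s] the Pearson
    coefficient of shoulder[t] against elbow[t + k] is computed over the
    frames valid in both at the shifted alignment; the maximum and its lag
    are returned (ties broken towards the smallest |lag|), along with the
    zero-lag coefficient. Positive lag means the elbow series is delayed
    relative to the shoulder's.
    """
    x = np.asarray(shoulder, dtype=float)
    y = np.asarray(elbow, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("series must have equal length")
    vx = np.isfinite(x) if shoulder_valid is None else np.asarray(shoulder_valid, bool)
    vy = np.isfinite(y) if elbow_valid is None else np.asarray(elbow_valid, bool)
    vx = vx & np.isfinite(x)
    vy = vy & np.isfinite(y)
    if max_lag_s < 0:
        raise ValidationError("max_lag_s must be >= 0")
    n = len(x)
    max_lag = int(round(max_lag_s * sampling_rate))
    if (vx & vy).sum() < max(2, 2 * max_lag):
        raise ValidationError("common valid support shorter than 2 × max_lag_s")
    lags = np.arange(-max_lag, max_lag + 1)
    rs = np.full(lags.shape, -np.inf)
    for idx, k in enumerate(lags):
        if k >= 0:
            xs, ys = x[: n - k], y[k:]
            m = vx[: n - k] & vy[k:]
        else:
            xs, ys = x[-k:], y[: n + k]
            m = vx[-k:] & vy[: n + k]
        if m.sum() < 3:
            continue
        a, b = xs[m], ys[m]
        a = a - a.mean()
        b = b - b.mean()
        denom = np.sqrt((a @ a) * (b @ b))
        if denom == 0:
            raise ValidationError("zero-variance input in correlation window")
        rs[idx] = (a @ b) / denom
    r_best = rs.max()
    if not np.isfinite(r_best):
        raise ValidationError("no lag had sufficient overlapping support")
    near = np.flatnonzero(rs >= r_best - 1e-12)
    best = near[np.argmin(np.abs(lags[near]))]
    zero_idx = max_lag
    return CorrelationResult(
        r_max=float(rs[best]),
        lag_s=float(lags[best] / sampling_rate),
        r_zero_lag=float(rs[zero_idx]) if np.isfinite(rs[zero_idx]) else float("nan"),
    )


def rom_summary(values: np.ndarray, valid: np.ndarray | None = None
                ) -> tuple[float, float, float]:
    """(min, max, range) in degrees over the valid frames."""
    values = np.asarray(values, dtype=float)
    if valid is not None:
        values = values[np.asarray(valid, bool)]
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValidationError("no valid frames for range-of-motion summary")
    vmin, vmax = float(values.min()), float(values.max())
    return vmin, vmax, vmax - vmin


# ---------------------------------------------------------------------------
# aggregation


def build_movement_profile(angles: JointAngleSeries,
                           velocities: AngularVelocitySeries | None = None,
                           params: ProfileParams | None = None,
                           participant_id: str | None = None,
                           effort_index: int = 0) -> MovementProfile:
    """Run every feature operation on one windowed angle series.

    Failures of individual features are recorded in ``profile.flags`` and
    the profile is still returned — degenerate recordings yield a profile
    of flags, never an exception.
    """
    params = params or ProfileParams()
    window = (float(angles.time[0]) if angles.n_frames else 0.0,
              angles.n_frames / angles.sampling_rate)
    profile = MovementProfile(
        participant_id=participant_id if participant_id is not None
        else angles.participant_id,
        effort_index=effort_index,
        window=window,
    )
    fs = angles.sampling_rate
    rel_time = angles.time - (angles.time[0] if angles.n_frames else 0.0)

    peaks = {}
    for joint in ("shoulder", "elbow"):
        values, valid = angles.joint(joint)
        try:
            peaks[joint] = detect_cycle_peaks(
                values, valid, fs, params.min_prominence_deg,
                params.min_separation_s, time=rel_time)
        except ValidationError:
            peaks[joint] = np.array([])
        if peaks[joint].size == 0:
            profile.flags[f"no_{joint}_peaks"] = True
        try:
            (mn, mx, rng) = rom_summary(values, valid)
            setattr(profile, f"{joint}_min_deg", mn)
            setattr(profile, f"{joint}_max_deg", mx)
            setattr(profile, f"{joint}_range_deg", rng)
        except ValidationError:
            profile.flags[f"{joint}_rom_undefined"] = True

    cadence = compute_cadence(peaks["elbow"])
    profile.cadence_cpm = cadence
    profile.n_cycles = max(0, peaks["elbow"].size - 1)
    if not np.isfinite(cadence):
        profile.flags["cadence_undefined"] = True
        period = float("nan")
    else:
        period = 60.0 / cadence

    if np.isfinite(period) and peaks["shoulder"].size and peaks["elbow"].size:
        lag = compute_time_lag(peaks["shoulder"], peaks["elbow"], period)
        profile.time_lag_s = lag.lag_s
        profile.provenance["time_lag_pairs"] = (lag.n_pairs, lag.n_dropped)
        if not np.isfinite(lag.lag_s):
            profile.flags["time_lag_undefined"] = True
    else:
        profile.flags["time_lag_undefined"] = True

    sv, svalid = angles.shoulder_deg, angles.shoulder_valid
    ev, evalid = angles.elbow_deg, angles.elbow_valid
    both = svalid & evalid
    try:
        if not both.all():
            # phase needs a gap-free support: use the longest common valid run
            runs = _valid_runs(both)
            if not runs:
                raise ValidationError("no common valid support")
            start, stop = max(runs, key=lambda r: r[1] - r[0])
            phase = mean_phase_angle(sv[start:stop], ev[start:stop], fs, params)
        else:
            phase = mean_phase_angle(sv, ev, fs, params)
        profile.mean_phase_angle_deg = phase
        if not np.isfinite(phase):
            profile.flags["phase_insufficient_cycles"] = True
    except ValidationError:
        profile.flags["phase_undefined"] = True

    try:
        max_lag_s = params.max_lag_cycles * period if np.isfinite(period) else 1.0
        corr = signal_correlation(sv, ev, fs, max_lag_s, svalid, evalid)
        profile.signal_correlation = corr.r_max
        profile.correlation_lag_s = corr.lag_s
        profile.provenance["r_zero_lag"] = corr.r_zero_lag
    except ValidationError:
        profile.flags["correlation_undefined"] = True

    if velocities is not None:
        for joint, vel, vvalid in (
                ("shoulder", velocities.shoulder_velocity, velocities.shoulder_valid),
                ("elbow", velocities.elbow_velocity, velocities.elbow_valid)):
            v = np.abs(vel[vvalid])
            if v.size:
                setattr(profile, f"{joint}_max_velocity", float(v.max()))
            else:
                profile.flags[f"{joint}_velocity_undefined"] = True

    pairs = np.column_stack([sv[both], ev[both]])
    profile.angle_angle_pairs = pairs
    return profile
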