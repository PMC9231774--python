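"""Synthetic crank-cycling kinematics and cohort assessment generator.

The generator emulates a participant turning a table-top arm ergometer seen
from the sagittal side: the hand (MCP5) rides the crank circle, the wrist /
elbow follow from planar two-link inverse kinematics of the upper arm and
forearm anchored at a fixed acromion, and the trunk (acromion→hip line) is
static by default. Every stochastic element (measurement noise, marker
drop-out gaps, cohort draws) is reproducible under a fixed seed, and the
noiseless ground-truth joint-angle signals are carried in ``meta["truth"]``
so downstream stages can be tested by parameter recovery.

Coordination ground truth
-------------------------
``elbow_shoulder_phase_offset`` (degrees of crank phase) is the configured
lead of the elbow-angle peaks over the shoulder-angle peaks. It is realised
by evaluating the elbow-angle waveform at a shifted crank phase and
rebuilding the wrist and hand markers by forward kinematics from the
baseline epicondyle, so the shoulder-angle signal is untouched and both
segment lengths stay exactly rigid. The elbow waveform is additionally
re-timed by the geometry's natural peak-phase offset, so offset 0 means
peak-synchronous shoulder/elbow coordination and an offset of ``d`` degrees
at cadence ``c`` makes the elbow lead by exactly ``d/360 * 60/c`` seconds.
With ``elbow_shoulder_phase_offset=None`` the pure inverse-kinematics
solution is emitted instead and the hand lies exactly on the crank circle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import GeometryError, ValidationError
from .markers import CANONICAL_MARKERS, MarkerTrajectorySet

__all__ = [
    "SimulationConfig",
    "CohortSimConfig",
    "simulate_crank_cycling",
    "add_measurement_noise",
    "inject_gaps",
    "simulate_cohort_assessments",
    "oss_noise_sd_for_r2",
]

#: default session: five 2-minute efforts separated by 30 s of rest
DEFAULT_SESSION: tuple[tuple[float, float], ...] = tuple(((120.0, 30.0),) * 5)

_EXTENSION_TOL = 1e-9  # cos(angle) slack before the straight-arm singularity


@dataclass
class SimulationConfig:
    """Full parameterisation of one synthetic crank-cycling recording.

    Geometry is sagittal (x anterior, y superior, origin at the hip marker),
    lengths in millimetres. Defaults place a 125 mm crank anterior to the
    shoulder at roughly acromion height, with conventional adult segment
    lengths (upper arm 300 mm, forearm 260 mm); the source study reports no
    anthropometry, so these are declared placeholders, not estimates.
    """

    crank_radius: float = 125.0
    crank_center: tuple[float, float] = (380.0, 430.0)
    shoulder_position: tuple[float, float] = (0.0, 500.0)
    upper_arm_length: float = 300.0
    forearm_length: float = 260.0
    hand_offset: float = 70.0  # wrist→MCP5 along the forearm extension
    hip_offset: tuple[float, float] = (0.0, -500.0)  # acromion→hip
    #: cycles/min: a constant, or piecewise-constant [(start_s, cpm), ...]
    cadence_profile: float | Sequence[tuple[float, float]] = 60.0
    #: degrees of crank phase the elbow-angle peaks lead the shoulder's;
    #: None = natural (pure inverse-kinematics) coupling
    elbow_shoulder_phase_offset: float | None = 0.0
    noise_sd: float = 0.0
    gap_rate: float = 0.0  # expected gaps per minute per marker
    gap_length_range: tuple[float, float] = (0.1, 0.5)
    sampling_rate: float = 100.0
    duration: float | None = None  # seconds; None = from session_structure
    seed: int = 0
    #: list of (effort_duration_s, rest_duration_s); trailing rest dropped
    session_structure: Sequence[tuple[float, float]] | None = None
    trunk_sway_deg: float = 0.0  # amplitude of optional sinusoidal trunk sway

    def resolved_duration(self) -> float:
        if self.duration is not None:
            return float(self.duration)
        session = self.session_structure or DEFAULT_SESSION
        total = sum(e + r for e, r in session) - session[-1][1]
        return float(total)

    def validate(self) -> None:
        for name in ("crank_radius", "upper_arm_length", "forearm_length",
                     "hand_offset", "sampling_rate"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")
        if self.resolved_duration() <= 0:
            raise ValidationError("duration must be positive")
        cadences = ([self.cadence_profile] if np.isscalar(self.cadence_profile)
                    else [c for _, c in self.cadence_profile])
        if not cadences:
            raise ValidationError("cadence_profile is empty")
        for c in cadences:
            if not 0 < c < 200:
                raise ValidationError(f"cadence {c} outside (0, 200) cycles/min")
        shoulder = np.asarray(self.shoulder_position, dtype=float)
        center = np.asarray(self.crank_center, dtype=float)
        dist = float(np.hypot(*(center - shoulder)))
        reach = self.upper_arm_length + self.forearm_length
        if not reach > dist + self.crank_radius:
            raise GeometryError(
                "unreachable crank: upper_arm_length + forearm_length = "
                f"{reach:.1f} mm must exceed |shoulder→crank_center| + crank_radius = "
                f"{dist + self.crank_radius:.1f} mm"
            )
        # the hand (wrist + hand_offset) is the IK target: inner workspace limit
        eff = self.forearm_length + self.hand_offset
        if dist - self.crank_radius < abs(self.upper_arm_length - eff):
            raise GeometryError(
                "crank circle enters the inner workspace boundary: "
                f"|shoulder→crank_center| − crank_radius = {dist - self.crank_radius:.1f} mm "
                f"< |upper_arm − (forearm + hand_offset)| = "
                f"{abs(self.upper_arm_length - eff):.1f} mm"
            )


# ---------------------------------------------------------------------------
# geometry helpers


def _rot(v: np.ndarray, ang: np.ndarray) -> np.ndarray:
    """Rotate 2D vectors ``v`` (…,2) by angles ``ang`` (radians, CCW)."""
    c, s = np.cos(ang), np.sin(ang)
    return np.stack([c * v[..., 0] - s * v[..., 1],
                     s * v[..., 0] + c * v[..., 1]], axis=-1)


@dataclass
class _ChainSolution:
    hand: np.ndarray      # IK target on the crank circle (n, 2)
    epicondyle: np.ndarray
    upper_dir: np.ndarray  # acromion→epicondyle unit vector
    forearm_dir: np.ndarray
    elbow_signed: np.ndarray  # signed elbow flexion angle, radians
    shoulder_angle: np.ndarray  # signed shoulder flexion angle, radians


def _solve_chain(theta: np.ndarray, cfg: SimulationConfig,
                 shoulder: np.ndarray | None = None) -> _ChainSolution:
    """Planar two-link inverse kinematics for crank phase array ``theta``.

    Takes the elbow-down (posterior) branch: the elbow sits clockwise of the
    shoulder→hand line, matching arm posture at a table-top ergometer.
    """
    center = np.asarray(cfg.crank_center, dtype=float)
    if shoulder is None:
        shoulder = np.asarray(cfg.shoulder_position, dtype=float)
    shoulder = np.broadcast_to(shoulder, theta.shape + (2,))
    hand = center + cfg.crank_radius * np.stack([np.cos(theta), np.sin(theta)], axis=-1)
    l1 = cfg.upper_arm_length
    l2 = cfg.forearm_length + cfg.hand_offset  # wrist and MCP5 are collinear
    v = hand - shoulder
    d = np.linalg.norm(v, axis=-1)
    cos_a = (l1**2 + d**2 - l2**2) / (2.0 * l1 * d)
    if np.any(cos_a > 1.0 + 1e-9) or np.any(cos_a < -1.0 - 1e-9):
        raise GeometryError(
            "two-link chain cannot reach crank position: check crank_radius, "
            "crank_center, upper_arm_length, forearm_length, hand_offset"
        )
    if np.any(cos_a >= 1.0 - _EXTENSION_TOL):
        warnings.warn(
            "fully extended two-link singularity: elbow placed on the "
            "shoulder–wrist line", stacklevel=2,
        )
    alpha = np.arccos(np.clip(cos_a, -1.0, 1.0))
    u = _rot(v / d[..., None], -alpha)  # elbow-down branch
    epi = shoulder + l1 * u
    f = hand - epi
    f /= np.linalg.norm(f, axis=-1)[..., None]
    elbow_signed = np.arctan2(u[..., 0] * f[..., 1] - u[..., 1] * f[..., 0],
                              np.einsum("...i,...i->...", u, f))
    down = np.asarray(cfg.hip_offset, dtype=float)
    down = down / np.linalg.norm(down)
    shoulder_angle = np.arctan2(down[0] * u[..., 1] - down[1] * u[..., 0],
                                u[..., 0] * down[0] + u[..., 1] * down[1])
    return _ChainSolution(hand, epi, u, f, elbow_signed, shoulder_angle)


def _refine_circular_argmax(phases: np.ndarray, values: np.ndarray) -> float:
    """Peak phase of a periodic sample via quadratic interpolation."""
    i = int(np.argmax(values))
    n = len(values)
    y0, y1, y2 = values[(i - 1) % n], values[i], values[(i + 1) % n]
    denom = y0 - 2 * y1 + y2
    delta = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    step = phases[1] - phases[0]
    return float(phases[i] + delta * step)


def _natural_peak_offset(cfg: SimulationConfig) -> float:
    """Crank-phase lead of the natural elbow-angle peak over the shoulder's."""
    ph = np.linspace(0.0, 2 * np.pi, 7200, endpoint=False)
    sol = _solve_chain(ph, cfg)
    pk_e = _refine_circular_argmax(ph, np.abs(sol.elbow_signed))
    pk_s = _refine_circular_argmax(ph, sol.shoulder_angle)
    return float((pk_e - pk_s + np.pi) % (2 * np.pi) - np.pi)


# ---------------------------------------------------------------------------
# session timing


def _effort_labels(cfg: SimulationConfig, n: int) -> np.ndarray:
    """Per-frame label: 0 = rest, 1..k = effort index."""
    t = np.arange(n) / cfg.sampling_rate
    labels = np.zeros(n, dtype=int)
    if cfg.session_structure is None and cfg.duration is not None:
        labels[:] = 1  # a bare duration is one continuous effort
        return labels
    session = cfg.session_structure or DEFAULT_SESSION
    cursor = 0.0
    for k, (effort_s, rest_s) in enumerate(session, start=1):
        labels[(t >= cursor) & (t < cursor + effort_s)] = k
        cursor += effort_s + rest_s
    return labels


def _cadence_per_frame(cfg: SimulationConfig, n: int, labels: np.ndarray) -> np.ndarray:
    t = np.arange(n) / cfg.sampling_rate
    if np.isscalar(cfg.cadence_profile):
        cpm = np.full(n, float(cfg.cadence_profile))
    else:
        prof = sorted(cfg.cadence_profile)
        cpm = np.full(n, float(prof[0][1]))
        for start_s, value in prof:
            cpm[t >= start_s] = float(value)
    cpm[labels == 0] = 0.0  # crank holds during rest
    return cpm


# ---------------------------------------------------------------------------
# public operations


def simulate_crank_cycling(config: SimulationConfig) -> MarkerTrajectorySet:
    """Generate a noiseless five-marker recording of table-top arm cycling.

    Returns a :class:`MarkerTrajectorySet` with a complete validity mask,
    per-frame effort/rest labels, and ground truth under ``meta["truth"]``:
    crank phase (deg), total revolutions, the shoulder/elbow angle signals
    (deg) and the configured coordination offset.
    """
    config.validate()
    fs = config.sampling_rate
    duration = config.resolved_duration()
    n = int(round(duration * fs))
    labels = _effort_labels(config, n)
    cpm = _cadence_per_frame(config, n, labels)
    omega = cpm * 2 * np.pi / 60.0
    dt = 1.0 / fs
    theta = np.concatenate([[0.0], np.cumsum(omega[:-1] * dt)])
    total_rev = float(np.sum(omega) * dt / (2 * np.pi))

    if config.trunk_sway_deg:
        hipvec = np.asarray(config.hip_offset, dtype=float)
        hip = np.asarray(config.shoulder_position, dtype=float) + hipvec
        sway = np.radians(config.trunk_sway_deg) * np.sin(theta)
        shoulder = hip + _rot(np.broadcast_to(-hipvec, theta.shape + (2,)), sway)
    else:
        shoulder = None

    base = _solve_chain(theta, config, shoulder)
    if config.elbow_shoulder_phase_offset is None:
        elbow_signed = base.elbow_signed
        forearm_dir = base.forearm_dir
        true_offset = np.degrees(_natural_peak_offset(config))
    else:
        shift = np.radians(config.elbow_shoulder_phase_offset) + _natural_peak_offset(config)
        elbow_signed = _solve_chain(theta + shift, config, shoulder).elbow_signed
        forearm_dir = _rot(base.upper_dir, elbow_signed)
        true_offset = float(config.elbow_shoulder_phase_offset)

    wrist = base.epicondyle + config.forearm_length * forearm_dir
    hand = wrist + config.hand_offset * forearm_dir
    hip_fixed = np.asarray(config.shoulder_position, float) + np.asarray(config.hip_offset, float)
    if shoulder is None:
        acr = np.broadcast_to(np.asarray(config.shoulder_position, float), (n, 2)).copy()
    else:
        acr = shoulder  # swaying trunk rotates the acromion about the fixed hip
    hip_marker = np.broadcast_to(hip_fixed, (n, 2)).copy()

    xy = np.stack([hand, wrist, base.epicondyle, acr, hip_marker], axis=1)
    positions = np.concatenate([xy, np.zeros((n, 5, 1))], axis=2)
    truth = {
        "crank_phase_deg": np.degrees(theta),
        "total_revolutions": total_rev,
        "shoulder_angle_deg": np.degrees(base.shoulder_angle),
        "elbow_angle_deg": np.degrees(np.abs(elbow_signed)),
        "phase_offset_deg": true_offset,
        "cadence_cpm_per_frame": cpm,
    }
    return MarkerTrajectorySet(
        positions=positions,
        validity_mask=np.ones((n, 5), dtype=bool),
        sampling_rate=fs,
        marker_names=CANONICAL_MARKERS,
        participant_id="SIM",
        effort_labels=labels,
        meta={"truth": truth, "config": config},
    )


def add_measurement_noise(traj: MarkerTrajectorySet, noise_sd: float,
                          seed: int) -> MarkerTrajectorySet:
    """Add independent zero-mean Gaussian noise (mm) to every valid sample.

    Masked frames are untouched; identical seeds give identical output.
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    out = traj.copy()
    if noise_sd == 0:
        return out
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=out.positions.shape[:2] + (2,))
    out.positions[..., :2] += np.where(out.validity_mask[..., None], noise, 0.0)
    out.meta["noise_sd"] = float(noise_sd)
    return out


def inject_gaps(traj: MarkerTrajectorySet, gap_rate: float,
                gap_length_range: tuple[float, float], seed: int) -> MarkerTrajectorySet:
    """Invalidate Poisson-placed contiguous runs independently per marker.

    ``gap_rate`` is the expected number of gaps per minute per marker; gap
    lengths are uniform over ``gap_length_range`` seconds. The realised
    invalid fraction per marker is recorded in ``meta["gap_fraction"]``.
    """
    if gap_rate < 0:
        raise ValidationError("gap_rate must be >= 0")
    lo, hi = gap_length_range
    if not 0 < lo <= hi:
        raise ValidationError("gap_length_range must satisfy 0 < lo <= hi")
    out = traj.copy()
    if not out.validity_mask.any():
        warnings.warn("all frames already invalid; gaps not injected", stacklevel=2)
        return out
    if gap_rate == 0:
        out.meta["gap_fraction"] = {m: 0.0 for m in out.marker_names}
        return out
    rng = np.random.default_rng(seed)
    fs, n = out.sampling_rate, out.n_frames
    duration_min = n / fs / 60.0
    fractions: dict[str, float] = {}
    for j, name in enumerate(out.marker_names):
        before = out.validity_mask[:, j].mean()
        for _ in range(rng.poisson(gap_rate * duration_min)):
            start = rng.uniform(0.0, n / fs)
            length = rng.uniform(lo, hi)
            i0 = int(start * fs)
            i1 = min(n, i0 + max(1, int(round(length * fs))))
            out.validity_mask[i0:i1, j] = False
        out.positions[~out.validity_mask[:, j], j] = np.nan
        fractions[name] = float(before - out.validity_mask[:, j].mean())
    out.meta["gap_fraction"] = fractions
    return out


# ---------------------------------------------------------------------------
# cohort assessments


@dataclass
class CohortSimConfig:
    """Parameters for a synthetic cohort assessment table.

    Each participant draws a right-shoulder-flexion strength uniformly over
    ``strength_range`` (kgf); the Oxford Shoulder Score and per-effort RPE
    follow linear models in that strength with Gaussian noise, clamped to
    their instrument ranges ([0, 48] and [6, 20]). The remaining strength
    measures are scaled copies of the driver plus noise, giving the strongly
    inter-correlated strength matrix seen in clinical cohorts.
    """

    n_participants: int = 15
    strength_range: tuple[float, float] = (25.0, 130.0)
    oss_slope: float = 0.15          # OSS points per kgf
    oss_intercept: float = 16.0
    oss_noise_sd: float = 6.0
    rpe_slope: float = -0.02         # stronger participants rate lower effort
    rpe_intercept: float = 13.0
    rpe_noise_sd: float = 1.0
    strength_cross_noise_sd: float = 8.0  # kgf, across secondary measures
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 2:
            raise ValidationError("n_participants must be >= 2")
        for name in ("oss_noise_sd", "rpe_noise_sd", "strength_cross_noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        lo, hi = self.strength_range
        if hi < lo:
            raise ValidationError("strength_range bounds inverted")


def oss_noise_sd_for_r2(config: CohortSimConfig, target_r2: float) -> float:
    """Noise SD making the population R² of OSS on strength equal the target.

    Uses R² = s²/(s²+σ²) with signal SD s = |slope|·SD(strength) for a
    uniform strength draw; clamping is assumed inactive.
    """
    if not 0 < target_r2 < 1:
        raise ValidationError("target_r2 must be in (0, 1)")
    lo, hi = config.strength_range
    signal_sd = abs(config.oss_slope) * (hi - lo) / np.sqrt(12.0)
    return float(signal_sd * np.sqrt(1.0 / target_r2 - 1.0))


#: (joint, side, movement) keys of the strength battery, mirroring the
#: bilateral shoulder flexion/extension/abduction + elbow flexion/extension set
STRENGTH_KEYS: tuple[tuple[str, str, str], ...] = tuple(
    (joint, side, movement)
    for joint, movements in (("shoulder", ("flexion", "extension", "abduction")),
                             ("elbow", ("flexion", "extension")))
    for movement in movements
    for side in ("right", "left")
)

#: typical passive range-of-movement medians (degrees) used as PROM centres
_PROM_CENTERS: dict[tuple[str, str], float] = {
    ("shoulder", "flexion"): 100.0,
    ("shoulder", "extension"): 50.0,
    ("shoulder", "abduction"): 108.0,
    ("elbow", "flexion"): 144.0,
    ("elbow", "extension"): 2.0,
}


def simulate_cohort_assessments(config: CohortSimConfig):
    """Draw a cohort of assessment records with known linear ground truth.

    Returns a list of :class:`armcycle.marker_io.AssessmentRecord` whose
    participant identifiers (P01, P02, ...) match the trajectory fixtures.
    """
    from .marker_io import AssessmentRecord  # local import to avoid a cycle

    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.strength_range
    records = []
    for i in range(config.n_participants):
        pid = f"P{i + 1:02d}"
        driver = rng.uniform(lo, hi)  # right shoulder flexion strength, kgf
        strength: dict[tuple[str, str, str], float] = {}
        for key in STRENGTH_KEYS:
            if key == ("shoulder", "right", "flexion"):
                strength[key] = driver
            else:
                scale = rng.uniform(0.85, 1.1)
                strength[key] = max(
                    0.0, scale * driver + rng.normal(0.0, config.strength_cross_noise_sd))
        oss = config.oss_intercept + config.oss_slope * driver \
            + rng.normal(0.0, config.oss_noise_sd)
        oss = int(round(np.clip(oss, 0.0, 48.0)))
        rpe = []
        for effort in range(5):
            value = (config.rpe_intercept + 0.5 * effort
                     + config.rpe_slope * driver
                     + rng.normal(0.0, config.rpe_noise_sd))
            rpe.append(float(np.clip(np.round(value), 6.0, 20.0)))
        resistance = [int(min(7, 1 + effort // 2 + rng.integers(0, 2)))
                      for effort in range(5)]
        prom = {}
        for (joint, movement), center in _PROM_CENTERS.items():
            for side in ("right", "left"):
                prom[(joint, side, movement)] = float(
                    np.clip(center + rng.normal(0.0, 0.12 * max(center, 10.0)),
                            -30.0, 200.0))
        records.append(AssessmentRecord(
            participant_id=pid,
            oxford_shoulder_score=oss,
            prom=prom,
            max_strength=strength,
            rpe_per_effort=rpe,
            resistance_per_effort=resistance,
            age=int(rng.integers(20, 60)),
            sex=str(rng.choice(["F", "M"])),
        ))
    return records
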