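"""Marker trajectories → shoulder/elbow flexion-extension angle series.

Angle conventions (degrees, sagittal plane):

* **Shoulder** — signed angle from the downward trunk line (acromion→hip) to
  the upper-arm segment (acromion→lateral epicondyle). Arm alongside the
  body is 0°, anterior elevation (flexion) is positive up to 180°,
  extension is negative.
* **Elbow** — 180° minus the interior angle at the lateral epicondyle
  between the epicondyle→acromion and epicondyle→ulnar-styloid segments:
  full extension (collinear upper arm and forearm) is 0°, full flexion
  approaches 180°.

3D inputs are projected to the sagittal plane by dropping the mediolateral
coordinate. Gap repair (cubic interpolation of short invalid runs),
zero-phase Butterworth smoothing and central-difference angular velocity
operate per joint on the angle series and record what they did in
``provenance``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt

from .errors import ValidationError
from .markers import MarkerTrajectorySet

__all__ = [
    "JointAngleSeries",
    "AngularVelocitySeries",
    "compute_joint_angles",
    "fill_gaps",
    "lowpass_filter",
    "angular_velocity",
]


@dataclass
class JointAngleSeries:
    """Per-frame shoulder and elbow angles (degrees) with validity masks."""

    time: np.ndarray
    shoulder_deg: np.ndarray
    elbow_deg: np.ndarray
    shoulder_valid: np.ndarray
    elbow_valid: np.ndarray
    sampling_rate: float
    effort_labels: np.ndarray | None = None
    participant_id: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("shoulder_deg", "elbow_deg", "shoulder_valid", "elbow_valid"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"{name} length must match time")
        self.shoulder_deg = np.where(self.shoulder_valid, self.shoulder_deg, np.nan)
        self.elbow_deg = np.where(self.elbow_valid, self.elbow_deg, np.nan)

    @property
    def n_frames(self) -> int:
        return len(self.time)

    def joint(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """(values, validity) for ``"shoulder"`` or ``"elbow"``."""
        if name == "shoulder":
            return self.shoulder_deg, self.shoulder_valid
        if name == "elbow":
            return self.elbow_deg, self.elbow_valid
        raise ValidationError(f"unknown joint {name!r}")

    def copy(self) -> "JointAngleSeries":
        return replace(
            self,
            time=self.time.copy(),
            shoulder_deg=self.shoulder_deg.copy(),
            elbow_deg=self.elbow_deg.copy(),
            shoulder_valid=self.shoulder_valid.copy(),
            elbow_valid=self.elbow_valid.copy(),
            effort_labels=None if self.effort_labels is None else self.effort_labels.copy(),
            provenance=dict(self.provenance),
        )


@dataclass
class AngularVelocitySeries:
    """Shoulder and elbow angular velocities (degrees/second)."""

    time: np.ndarray
    shoulder_velocity: np.ndarray
    elbow_velocity: np.ndarray
    shoulder_valid: np.ndarray
    elbow_valid: np.ndarray
    sampling_rate: float


def _signed_angle(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Signed angle (radians) from vectors ``a`` to ``b``, CCW positive."""
    cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    dot = np.einsum("ij,ij->i", a, b)
    return np.arctan2(cross, dot)


def compute_joint_angles(traj: MarkerTrajectorySet) -> JointAngleSeries:
    """Compute the shoulder and elbow angle series from the five markers.

    Frames where any marker needed by a joint is missing, or where a
    defining segment degenerates to zero length, are masked for that joint
    (with a warning for degenerate segments, which indicate marker overlap).
    """
    xy = {name: traj.marker(name)[:, :2] for name in
          ("HIP", "ACROMION", "LAT_EPI", "ULN_STY")}
    valid = {name: traj.marker_valid(name) for name in xy}

    with np.errstate(invalid="ignore"):
        trunk_down = xy["HIP"] - xy["ACROMION"]
        upper = xy["LAT_EPI"] - xy["ACROMION"]
        epi_to_acr = -upper
        forearm = xy["ULN_STY"] - xy["LAT_EPI"]

        shoulder_valid = valid["HIP"] & valid["ACROMION"] & valid["LAT_EPI"]
        elbow_valid = valid["ACROMION"] & valid["LAT_EPI"] & valid["ULN_STY"]

        degenerate = np.zeros(traj.n_frames, dtype=bool)
        for seg, mask_name in ((trunk_down, "shoulder"), (upper, "both"),
                               (forearm, "elbow")):
            zero = np.linalg.norm(seg, axis=1) < 1e-9
            if mask_name in ("shoulder", "both"):
                zero_here = zero & shoulder_valid
                shoulder_valid = shoulder_valid & ~zero
                degenerate |= zero_here
            if mask_name in ("elbow", "both"):
                zero_here = zero & elbow_valid
                elbow_valid = elbow_valid & ~zero
                degenerate |= zero_here
        if degenerate.any():
            warnings.warn(
                f"{int(degenerate.sum())} frame(s) masked: coincident markers give "
                "a zero-length segment", stacklevel=2)

        shoulder = np.degrees(_signed_angle(trunk_down, upper))
        cosint = np.einsum("ij,ij->i", epi_to_acr, forearm)
        norms = np.linalg.norm(epi_to_acr, axis=1) * np.linalg.norm(forearm, axis=1)
        with np.errstate(divide="ignore"):
            interior = np.degrees(np.arccos(np.clip(cosint / norms, -1.0, 1.0)))
        elbow = 180.0 - interior

    if np.any(np.abs(shoulder[shoulder_valid]) > 175.0):
        warnings.warn("shoulder angle approaches ±180°; the convention is not "
                      "continuous there", stacklevel=2)
    return JointAngleSeries(
        time=traj.time,
        shoulder_deg=shoulder,
        elbow_deg=elbow,
        shoulder_valid=shoulder_valid,
        elbow_valid=elbow_valid,
        sampling_rate=traj.sampling_rate,
        effort_labels=None if traj.effort_labels is None else traj.effort_labels.copy(),
        participant_id=traj.participant_id,
        provenance={"projected_sagittal": True},
    )


def _invalid_runs(valid: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs where ``valid`` is False."""
    padded = np.concatenate([[True], valid, [True]])
    starts = np.flatnonzero(~padded[1:] & padded[:-1])
    stops = np.flatnonzero(padded[1:] & ~padded[:-1])
    return list(zip(starts, stops))


def _valid_runs(valid: np.ndarray) -> list[tuple[int, int]]:
    return _invalid_runs(~valid)


def fill_gaps(angles: JointAngleSeries, max_gap_s: float = 0.5) -> JointAngleSeries:
    """Cubic-interpolate invalid runs no longer than ``max_gap_s`` seconds.

    Only interior gaps (flanked by valid samples on both sides) are filled;
    filled frames become valid and are recorded in
    ``provenance["filled"][joint]`` so no repaired sample masquerades as a
    measurement. Longer runs and edge runs are untouched.
    """
    if max_gap_s < 0:
        raise ValidationError("max_gap_s must be >= 0")
    out = angles.copy()
    max_len = int(round(max_gap_s * out.sampling_rate))
    filled_prov = out.provenance.setdefault("filled", {})
    for joint in ("shoulder", "elbow"):
        values, valid = out.joint(joint)
        if not valid.any():
            raise ValidationError(f"{joint} series has no valid samples")
        if valid.all():
            continue
        spline = CubicSpline(out.time[valid], values[valid])
        filled = np.zeros_like(valid)
        for start, stop in _invalid_runs(valid):
            if stop - start > max_len or start == 0 or stop == len(valid):
                continue
            values[start:stop] = spline(out.time[start:stop])
            valid[start:stop] = True
            filled[start:stop] = True
        if filled.any():
            filled_prov[joint] = filled
    out.provenance["max_gap_s"] = max_gap_s
    return out


def lowpass_filter(angles: JointAngleSeries, cutoff_hz: float = 6.0) -> JointAngleSeries:
    """Zero-phase 4th-order Butterworth low-pass, per contiguous valid run.

    Runs shorter than the filter warm-up are passed through unfiltered and
    listed in ``provenance["unfiltered_runs"]``.
    """
    fs = angles.sampling_rate
    if not 0 < cutoff_hz < fs / 2:
        raise ValidationError(f"cutoff_hz must lie in (0, {fs / 2}) Hz")
    b, a = butter(4, cutoff_hz / (fs / 2))
    padlen = 3 * max(len(a), len(b))
    out = angles.copy()
    skipped: list[tuple[str, int, int]] = []
    for joint in ("shoulder", "elbow"):
        values, valid = out.joint(joint)
        for start, stop in _valid_runs(valid):
            if stop - start <= padlen:
                skipped.append((joint, int(start), int(stop)))
                continue
            values[start:stop] = filtfilt(b, a, values[start:stop])
    out.provenance["lowpass_cutoff_hz"] = cutoff_hz
    if skipped:
        out.provenance["unfiltered_runs"] = skipped
    return out


def angular_velocity(angles: JointAngleSeries) -> AngularVelocitySeries:
    """Differentiate the angle series: central differences on run interiors,
    one-sided differences at run boundaries, degrees/second."""
    fs = angles.sampling_rate
    out = {}
    masks = {}
    any_run = False
    for joint in ("shoulder", "elbow"):
        values, valid = angles.joint(joint)
        vel = np.full_like(values, np.nan)
        for start, stop in _valid_runs(valid):
            if stop - start >= 3:
                any_run = True
            if stop - start >= 2:
                vel[start:stop] = np.gradient(values[start:stop], 1.0 / fs)
        out[joint] = vel
        masks[joint] = valid & np.isfinite(vel)
    if not any_run:
        raise ValidationError("need at least 3 consecutive valid frames")
    return AngularVelocitySeries(
        time=angles.time.copy(),
        shoulder_velocity=out["shoulder"],
        elbow_velocity=out["elbow"],
        shoulder_valid=masks["shoulder"],
        elbow_valid=masks["elbow"],
        sampling_rate=fs,
    )
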