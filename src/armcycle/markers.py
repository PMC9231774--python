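"""Canonical marker set and the in-memory marker trajectory container.

The five-marker sagittal set used throughout the package:

======== ==============================================
name     anatomical landmark
======== ==============================================
MCP5     distal head of the fifth metacarpal (hand)
ULN_STY  styloid process of the ulna (wrist)
LAT_EPI  lateral epicondyle of the humerus (elbow)
ACROMION lateral aspect of the acromion process
HIP      most lateral point of the hip (trunk reference)
======== ==============================================

Coordinates are millimetres in a sagittal frame: x anterior, y superior,
z mediolateral (emitted as 0 by the simulator), origin at the hip marker.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError

CANONICAL_MARKERS: tuple[str, ...] = ("MCP5", "ULN_STY", "LAT_EPI", "ACROMION", "HIP")

#: case-insensitive aliases accepted by the readers
_MARKER_ALIASES: dict[str, str] = {
    "mcp5": "MCP5",
    "mcp": "MCP5",
    "hand": "MCP5",
    "fifth_metacarpal": "MCP5",
    "uln_sty": "ULN_STY",
    "ulna": "ULN_STY",
    "ulnar_styloid": "ULN_STY",
    "wrist": "ULN_STY",
    "lat_epi": "LAT_EPI",
    "elbow": "LAT_EPI",
    "lateral_epicondyle": "LAT_EPI",
    "acromion": "ACROMION",
    "acr": "ACROMION",
    "shoulder": "ACROMION",
    "hip": "HIP",
    "lateral_hip": "HIP",
}


def canonical_marker_name(name: str) -> str:
    """Map a marker label (any case, common aliases) to its canonical name.

    Raises
    ------
    ValidationError
        If the label is not recognised.
    """
    key = str(name).strip().lower()
    if key in _MARKER_ALIASES:
        return _MARKER_ALIASES[key]
    raise ValidationError(f"unknown marker name: {name!r}")


@dataclass
class MarkerTrajectorySet:
    """Time-indexed positions of the five canonical markers.

    Parameters
    ----------
    positions
        Array of shape ``(n_frames, n_markers, 3)``, millimetres. Invalid
        frames hold NaN.
    validity_mask
        Boolean array of shape ``(n_frames, n_markers)``; ``False`` marks a
        missing (occluded) sample for that marker.
    sampling_rate
        Capture rate in Hz.
    effort_labels
        Optional per-frame integer label: 0 = rest, 1..k = exercise effort
        index.
    meta
        Free-form provenance (simulation ground truth, gap statistics, ...).
    """

    positions: np.ndarray
    validity_mask: np.ndarray
    sampling_rate: float
    marker_names: tuple[str, ...] = CANONICAL_MARKERS
    units: str = "mm"
    participant_id: str = ""
    effort_labels: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.validity_mask = np.asarray(self.validity_mask, dtype=bool)
        self.marker_names = tuple(self.marker_names)
        if self.positions.ndim != 3 or self.positions.shape[2] not in (2, 3):
            raise ValidationError(
                f"positions must be (n_frames, n_markers, 2|3), got {self.positions.shape}"
            )
        if self.positions.shape[2] == 2:  # pad a constant mediolateral 0
            pad = np.zeros(self.positions.shape[:2] + (1,))
            self.positions = np.concatenate([self.positions, pad], axis=2)
        if len(set(self.marker_names)) != len(self.marker_names):
            raise ValidationError("marker names must be unique")
        if self.positions.shape[1] != len(self.marker_names):
            raise ValidationError("positions second axis must match marker_names")
        if self.validity_mask.shape != self.positions.shape[:2]:
            raise ValidationError("validity_mask must be (n_frames, n_markers)")
        if not self.sampling_rate > 0:
            raise ValidationError("sampling_rate must be positive")
        if self.effort_labels is not None:
            self.effort_labels = np.asarray(self.effort_labels, dtype=int)
            if self.effort_labels.shape != (self.positions.shape[0],):
                raise ValidationError("effort_labels must have one entry per frame")
        # invalid frames never carry finite coordinates
        self.positions[~self.validity_mask] = np.nan

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def duration(self) -> float:
        """Recording duration in seconds (frame count over sampling rate)."""
        return self.n_frames / self.sampling_rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.sampling_rate

    def _index(self, name: str) -> int:
        try:
            return self.marker_names.index(canonical_marker_name(name))
        except ValueError:
            raise ValidationError(f"marker {name!r} not present") from None

    def marker(self, name: str) -> np.ndarray:
        """Positions of one marker, shape ``(n_frames, 3)``."""
        return self.positions[:, self._index(name), :]

    def marker_valid(self, name: str) -> np.ndarray:
        """Validity mask of one marker, shape ``(n_frames,)``."""
        return self.validity_mask[:, self._index(name)]

    def valid_fraction(self) -> dict[str, float]:
        """Fraction of valid frames per marker."""
        return {
            name: float(self.validity_mask[:, i].mean())
            for i, name in enumerate(self.marker_names)
        }

    def copy(self) -> "MarkerTrajectorySet":
        return replace(
            self,
            positions=self.positions.copy(),
            validity_mask=self.validity_mask.copy(),
            effort_labels=None if self.effort_labels is None else self.effort_labels.copy(),
            meta=dict(self.meta),
        )
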