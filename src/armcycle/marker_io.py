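"""On-disk formats: TRC-like trajectory files and assessment tables.

Trajectory format (tab-delimited text, open and diff-able)::

    armcycle_trc	1
    sampling_rate_hz	100
    units	mm
    n_frames	6000
    participant_id	P01
    markers	MCP5	ULN_STY	LAT_EPI	ACROMION	HIP
    Frame	Time_s	MCP5_X	MCP5_Y	MCP5_Z	...	HIP_Z	Effort
    1	0.000000	505.123456	430.000000	0.000000	...	0	1

Missing samples are written as empty cells (never sentinel numbers) so they
cannot masquerade as coordinates; the ``Effort`` column (0 = rest, 1..k =
effort index) is optional. Coordinates are written with six decimal places,
which round-trips losslessly through the reader.

Assessment tables are headed delimited text (tab preferred, comma accepted)
in long format: one row per (participant, measure, joint, side, movement,
effort) with participant-level columns repeated. Recognised measures:
``oss``, ``prom``, ``strength``, ``rpe``, ``resistance``.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, SchemaError, ValidationError
from .markers import CANONICAL_MARKERS, MarkerTrajectorySet, canonical_marker_name

__all__ = [
    "AssessmentRecord",
    "read_trajectories",
    "write_trajectories",
    "read_assessments",
    "write_assessments",
    "assessments_to_frame",
]

_MAGIC = "armcycle_trc"
_KNOWN_UNITS = {"mm": 1.0, "m": 1000.0, "cm": 10.0}
_COORD_FMT = "{:.6f}"


@dataclass
class AssessmentRecord:
    """Per-participant clinical measures.

    ``prom`` and ``max_strength`` are keyed by (joint, side, movement);
    strength is the maximum of three dynamometry attempts, in kgf.
    """

    participant_id: str
    oxford_shoulder_score: int | None = None  # 0–48, higher = better function
    prom: dict[tuple[str, str, str], float] = field(default_factory=dict)
    max_strength: dict[tuple[str, str, str], float] = field(default_factory=dict)
    rpe_per_effort: list[float] | None = None  # Borg 6–20, five efforts
    resistance_per_effort: list[int] | None = None
    age: int | None = None
    sex: str | None = None

    def __post_init__(self) -> None:
        if self.oxford_shoulder_score is not None and not (
                0 <= self.oxford_shoulder_score <= 48):
            raise ValidationError(
                f"{self.participant_id}: Oxford Shoulder Score "
                f"{self.oxford_shoulder_score} outside [0, 48]")
        for seq, name, n in ((self.rpe_per_effort, "rpe_per_effort", 5),
                             (self.resistance_per_effort, "resistance_per_effort", 5)):
            if seq is not None and len(seq) != n:
                raise ValidationError(
                    f"{self.participant_id}: {name} must have exactly {n} entries")
        if self.rpe_per_effort is not None:
            for v in self.rpe_per_effort:
                if not 6 <= v <= 20:
                    raise ValidationError(
                        f"{self.participant_id}: RPE {v} outside the Borg range [6, 20]")
        for key, v in self.max_strength.items():
            if v < 0:
                raise ValidationError(f"{self.participant_id}: strength {key} < 0")
        for key, v in self.prom.items():
            if not -30.0 <= v <= 200.0:
                raise ValidationError(
                    f"{self.participant_id}: PROM {key}={v}° outside [−30, 200]°")


# ---------------------------------------------------------------------------
# trajectories


def write_trajectories(traj: MarkerTrajectorySet, path: str | Path) -> None:
    """Write a trajectory set in the documented TRC-like format."""
    path = Path(path)
    lines = [
        f"{_MAGIC}\t1",
        f"sampling_rate_hz\t{traj.sampling_rate:g}",
        f"units\t{traj.units}",
        f"n_frames\t{traj.n_frames}",
        f"participant_id\t{traj.participant_id}",
        "markers\t" + "\t".join(traj.marker_names),
    ]
    header = ["Frame", "Time_s"]
    for name in traj.marker_names:
        header += [f"{name}_X", f"{name}_Y", f"{name}_Z"]
    has_effort = traj.effort_labels is not None
    if has_effort:
        header.append("Effort")
    lines.append("\t".join(header))
    columns: dict[str, object] = {
        "Frame": np.arange(1, traj.n_frames + 1),
        "Time_s": pd.Series(traj.time).map(lambda v: f"{v:.6f}"),
    }
    for j, name in enumerate(traj.marker_names):
        block = traj.positions[:, j, :]
        valid = traj.validity_mask[:, j]
        for k, axis in enumerate(("X", "Y", "Z")):
            col = pd.Series(block[:, k]).map(
                lambda v: "" if not np.isfinite(v) else _COORD_FMT.format(v))
            col[~valid] = ""
            columns[f"{name}_{axis}"] = col
    if has_effort:
        columns["Effort"] = traj.effort_labels
    frame = pd.DataFrame(columns)
    buf = io.StringIO()
    buf.write("\n".join(lines) + "\n")
    frame.to_csv(buf, sep="\t", index=False, header=False)
    path.write_text(buf.getvalue())


def read_trajectories(path: str | Path) -> MarkerTrajectorySet:
    """Read a TRC-like trajectory file written by :func:`write_trajectories`.

    Blank coordinate cells become invalid-masked frames; header sampling
    rate, units and frame count are honoured (a frame-count mismatch is an
    error). Marker labels are canonicalised through the alias map.
    """
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    if not lines or not lines[0].startswith(_MAGIC):
        raise FormatError(f"{path}: not an armcycle trajectory file")
    header: dict[str, str] = {}
    markers: list[str] = []
    data_start = None
    for i, line in enumerate(lines[1:], start=1):
        cells = line.split("\t")
        key = cells[0].strip().lower()
        if key == "markers":
            markers = [canonical_marker_name(c) for c in cells[1:] if c.strip()]
        elif key == "frame":
            data_start = i
            column_names = [c.strip() for c in cells]
            break
        else:
            header[key] = cells[1] if len(cells) > 1 else ""
    if data_start is None:
        raise FormatError(f"{path}: no data header row found")
    if len(set(markers)) != len(markers) or not markers:
        raise FormatError(f"{path}: missing or duplicate marker declarations")
    for required in CANONICAL_MARKERS:
        if required not in markers:
            raise SchemaError(f"{path}: required marker {required} missing")
    try:
        fs = float(header["sampling_rate_hz"])
        n_declared = int(header["n_frames"])
    except (KeyError, ValueError) as exc:
        raise FormatError(f"{path}: bad or missing header field: {exc}") from exc
    units = header.get("units", "mm")
    if units not in _KNOWN_UNITS:
        raise FormatError(
            f"{path}: unknown unit tag {units!r} (known: {sorted(_KNOWN_UNITS)})")
    scale = _KNOWN_UNITS[units]

    expected_cols = ["Frame", "Time_s"]
    for name in markers:
        expected_cols += [f"{name}_X", f"{name}_Y", f"{name}_Z"]
    has_effort = column_names[-1] == "Effort"
    base_cols = expected_cols + (["Effort"] if has_effort else [])
    got = [canonical_marker_name(c.rsplit("_", 1)[0]) + "_" + c.rsplit("_", 1)[1]
           if c not in ("Frame", "Time_s", "Effort") else c for c in column_names]
    missing = [c for c in expected_cols if c not in got]
    if missing:
        raise SchemaError(f"{path}: missing columns: {missing}")
    if len(got) != len(base_cols):
        raise FormatError(f"{path}: unexpected column count {len(got)}")

    df = pd.read_csv(io.StringIO("\n".join(lines[data_start + 1:])), sep="\t",
                     names=got, header=None, dtype=float)
    if len(df) != n_declared:
        raise FormatError(
            f"{path}: header declares {n_declared} frames but file has {len(df)}")
    t = df["Time_s"].to_numpy()
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise FormatError(f"{path}: time column is not strictly increasing")
    if np.isnan(t).any():
        raise FormatError(f"{path}: missing values in the time column")

    n = len(df)
    positions = np.full((n, len(markers), 3), np.nan)
    mask = np.zeros((n, len(markers)), dtype=bool)
    for j, name in enumerate(markers):
        block = df[[f"{name}_X", f"{name}_Y", f"{name}_Z"]].to_numpy() * scale
        positions[:, j] = block
        mask[:, j] = np.isfinite(block).all(axis=1)
    effort = df["Effort"].to_numpy().astype(int) if has_effort else None
    return MarkerTrajectorySet(
        positions=positions,
        validity_mask=mask,
        sampling_rate=fs,
        marker_names=tuple(markers),
        units="mm",
        participant_id=header.get("participant_id", ""),
        effort_labels=effort,
    )


# ---------------------------------------------------------------------------
# assessments

_ASSESS_COLUMNS = ["participant_id", "age", "sex", "measure", "joint", "side",
                   "movement", "effort", "value"]


def _sniff_delimiter(first_line: str) -> str:
    return "\t" if "\t" in first_line else ","


def assessments_to_frame(records: list[AssessmentRecord]) -> pd.DataFrame:
    """Long-format DataFrame (one row per measure entry) for a record list."""
    rows = []
    for rec in records:
        base = {"participant_id": rec.participant_id, "age": rec.age, "sex": rec.sex}
        if rec.oxford_shoulder_score is not None:
            rows.append({**base, "measure": "oss", "value": rec.oxford_shoulder_score})
        for (joint, side, movement), v in sorted(rec.prom.items()):
            rows.append({**base, "measure": "prom", "joint": joint, "side": side,
                         "movement": movement, "value": v})
        for (joint, side, movement), v in sorted(rec.max_strength.items()):
            rows.append({**base, "measure": "strength", "joint": joint, "side": side,
                         "movement": movement, "value": v})
        for name, seq in (("rpe", rec.rpe_per_effort),
                          ("resistance", rec.resistance_per_effort)):
            if seq is not None:
                for k, v in enumerate(seq, start=1):
                    rows.append({**base, "measure": name, "effort": k, "value": v})
    return pd.DataFrame(rows, columns=_ASSESS_COLUMNS)


def write_assessments(records: list[AssessmentRecord], path: str | Path,
                      delimiter: str = "\t") -> None:
    """Write an assessment table as headed delimited text (long format)."""
    frame = assessments_to_frame(records)
    frame.to_csv(Path(path), sep=delimiter, index=False,
                 quoting=csv.QUOTE_MINIMAL)


def read_assessments(path: str | Path) -> list[AssessmentRecord]:
    """Read an assessment table; delimiter sniffed (tab, then comma).

    Range validation (RPE in [6, 20], OSS in [0, 48], ...) raises a
    :class:`ValidationError` citing the offending participant; duplicate
    measure rows for the same participant are an error. A file with a
    header and no rows yields an empty list.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    sep = _sniff_delimiter(first)
    df = pd.read_csv(path, sep=sep, dtype={"participant_id": str, "sex": str})
    missing = [c for c in ("participant_id", "measure", "value") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns: {missing}")
    for col in _ASSESS_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan

    key_cols = ["participant_id", "measure", "joint", "side", "movement", "effort"]
    dup = df.duplicated(subset=key_cols, keep=False)
    if dup.any():
        first_dup = df[dup].iloc[0]
        raise ValidationError(
            f"{path}: duplicate rows for participant {first_dup['participant_id']!r} "
            f"measure {first_dup['measure']!r}")

    records = []
    for pid, group in df.groupby("participant_id", sort=True):
        kwargs: dict = {"participant_id": str(pid)}
        ages = group["age"].dropna().unique()
        sexes = group["sex"].dropna().unique()
        kwargs["age"] = int(ages[0]) if len(ages) else None
        kwargs["sex"] = str(sexes[0]) if len(sexes) else None
        prom, strength = {}, {}
        rpe: dict[int, float] = {}
        resistance: dict[int, int] = {}
        for row_idx, row in group.iterrows():
            measure = str(row["measure"]).lower()
            value = row["value"]
            if measure == "oss":
                if not float(value).is_integer():
                    raise ValidationError(
                        f"{path} row {row_idx}: OSS must be an integer, got {value}")
                kwargs["oxford_shoulder_score"] = int(value)
            elif measure in ("prom", "strength"):
                key = (str(row["joint"]).lower(), str(row["side"]).lower(),
                       str(row["movement"]).lower())
                (prom if measure == "prom" else strength)[key] = float(value)
            elif measure == "rpe":
                if not 6 <= float(value) <= 20:
                    raise ValidationError(
                        f"{path} row {row_idx}: RPE {value} outside [6, 20]")
                rpe[int(row["effort"])] = float(value)
            elif measure == "resistance":
                resistance[int(row["effort"])] = int(value)
            else:
                raise FormatError(f"{path} row {row_idx}: unknown measure {measure!r}")
        kwargs["prom"] = prom
        kwargs["max_strength"] = strength
        if rpe:
            kwargs["rpe_per_effort"] = [rpe[k] for k in sorted(rpe)]
        if resistance:
            kwargs["resistance_per_effort"] = [resistance[k] for k in sorted(resistance)]
        records.append(AssessmentRecord(**kwargs))
    return records
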