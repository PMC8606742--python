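"""File formats: SIMM-style .mot motion files, CSV tables, envelope meshes.

The package ships a transcription of the published echidna forelimb
excursion table (per-specimen min/max per joint DOF, three animals, five
limb sides) as its in-repo reference dataset; the raw trial recordings were
not deposited.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .rom_analysis import RangeRecord, ROMEnvelope
from .torque_model import MuscleArchitecture

REFERENCE_RANGES_RESOURCE = "echidna_forelimb_ranges.csv"


class DataError(ValueError):
    """Malformed or inconsistent input data."""


# ---------------------------------------------------------------------------
# SIMM motion (.mot) files
# ---------------------------------------------------------------------------

@dataclass
class MotionFile:
    """A SIMM-style motion: a name plus a time + generalized-coordinate table."""

    name: str
    data: pd.DataFrame  # first column is time (s)

    def __post_init__(self) -> None:
        if self.data.shape[0] == 0:
            raise DataError("motion has no data rows")
        if self.data.shape[1] < 2:
            raise DataError("motion needs a time column plus >= 1 coordinate")


def write_mot(motion: MotionFile, path) -> None:
    """Write the minimal common .mot dialect: a header block (name,
    datacolumns, datarows, range, endheader), a tab-delimited label row,
    then tab-delimited numeric rows at full precision."""
    df = motion.data
    time = df.iloc[:, 0]
    lines = [
        f"name {motion.name}",
        f"datacolumns {df.shape[1]}",
        f"datarows {df.shape[0]}",
        f"range {time.iloc[0]:.17g} {time.iloc[-1]:.17g}",
        "endheader",
        "\t".join(str(c) for c in df.columns),
    ]
    for row in df.itertuples(index=False):
        lines.append("\t".join(f"{v:.17g}" for v in row))
    try:
        Path(path).write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write motion file {path}: {exc}") from exc


def read_mot(path) -> MotionFile:
    try:
        text = Path(path).read_text()
    except OSError as exc:
        raise OSError(f"cannot read motion file {path}: {exc}") from exc
    lines = text.splitlines()
    header: dict[str, str] = {}
    body_start = None
    for i, line in enumerate(lines):
        if line.strip() == "endheader":
            body_start = i + 1
            break
        parts = line.split(None, 1)
        if parts:
            header[parts[0]] = parts[1] if len(parts) > 1 else ""
    if body_start is None:
        raise DataError(f"{path}: no endheader line")
    columns = lines[body_start].split("\t")
    rows = [[float(v) for v in line.split("\t")]
            for line in lines[body_start + 1:] if line.strip()]
    df = pd.DataFrame(rows, columns=columns)
    declared_cols = int(header.get("datacolumns", df.shape[1]))
    declared_rows = int(header.get("datarows", df.shape[0]))
    if (declared_cols, declared_rows) != df.shape[::-1]:
        raise DataError(
            f"{path}: declared {declared_rows}x{declared_cols} but payload is "
            f"{df.shape[0]}x{df.shape[1]}")
    return MotionFile(name=header.get("name", Path(path).stem), data=df)


def pose_series_to_mot(poses: pd.DataFrame, frame_rate: float,
                       name: str = "trial") -> MotionFile:
    """Wrap a per-frame joint-pose table (DOF columns) as a motion file."""
    df = poses.reset_index(drop=True).copy()
    df.insert(0, "time", np.arange(len(df)) / frame_rate)
    return MotionFile(name=name, data=df)


# ---------------------------------------------------------------------------
# Range records
# ---------------------------------------------------------------------------

_RANGE_COLUMNS = ["specimen", "side", "joint", "dof", "kind", "units",
                  "min", "max"]


def read_range_csv(path) -> list[RangeRecord]:
    df = pd.read_csv(path)
    missing = set(_RANGE_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    return [
        RangeRecord(specimen=str(r.specimen), side=str(r.side),
                    joint=str(r.joint), dof=str(r.dof),
                    min_value=float(r.min), max_value=float(r.max),
                    units=str(r.units))
        for r in df.itertuples()
    ]


def write_range_csv(records: list[RangeRecord], path) -> None:
    pd.DataFrame([
        {"specimen": r.specimen, "side": r.side, "joint": r.joint,
         "dof": r.dof, "kind": "rotation" if r.units == "deg" else "translation",
         "units": r.units, "min": r.min_value, "max": r.max_value}
        for r in records
    ]).to_csv(path, index=False)


def load_reference_ranges() -> list[RangeRecord]:
    """Per-specimen echidna forelimb joint excursions shipped with the package."""
    ref = resources.files("geomma.data") / REFERENCE_RANGES_RESOURCE
    with resources.as_file(ref) as path:
        return read_range_csv(path)


def group_records(records: list[RangeRecord]
                  ) -> dict[tuple[str, str], list[RangeRecord]]:
    """Group range records by (joint, dof), preserving table order."""
    groups: dict[tuple[str, str], list[RangeRecord]] = {}
    for r in records:
        groups.setdefault((r.joint, r.dof), []).append(r)
    return groups


# ---------------------------------------------------------------------------
# Marker and architecture CSVs
# ---------------------------------------------------------------------------

def write_marker_csv(markers: dict[str, np.ndarray], path) -> None:
    """Long-format marker trajectories: frame, marker_id, x, y, z (mm)."""
    frames = []
    for mid, xyz in markers.items():
        xyz = np.asarray(xyz, dtype=float)
        df = pd.DataFrame(xyz, columns=["x", "y", "z"])
        df.insert(0, "marker_id", mid)
        df.insert(0, "frame", np.arange(len(df)))
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_marker_csv(path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path)
    needed = {"frame", "marker_id", "x", "y", "z"}
    if not needed <= set(df.columns):
        raise DataError(f"{path}: marker CSV needs columns {sorted(needed)}")
    out: dict[str, np.ndarray] = {}
    for mid, sub in df.groupby("marker_id", sort=False):
        sub = sub.sort_values("frame")
        if not np.array_equal(sub["frame"].to_numpy(), np.arange(len(sub))):
            raise DataError(f"{path}: marker {mid!r} has missing frames")
        out[str(mid)] = sub[["x", "y", "z"]].to_numpy()
    return out


def read_architecture_csv(path) -> dict[tuple[str, str], MuscleArchitecture]:
    """Muscle architecture table: muscle, head, pcsa_mm2, lopt_mm, lslack_mm,
    pennation_deg -> architecture keyed by (muscle, head)."""
    df = pd.read_csv(path)
    needed = {"muscle", "head", "pcsa_mm2", "lopt_mm", "lslack_mm",
              "pennation_deg"}
    if not needed <= set(df.columns):
        raise DataError(f"{path}: architecture CSV needs columns {sorted(needed)}")
    out = {}
    for r in df.itertuples():
        out[(str(r.muscle), str(r.head))] = MuscleArchitecture(
            pcsa=float(r.pcsa_mm2), optimal_fibre_length=float(r.lopt_mm),
            tendon_slack_length=float(r.lslack_mm),
            pennation=float(r.pennation_deg))
    return out


# ---------------------------------------------------------------------------
# Envelope export
# ---------------------------------------------------------------------------

def export_envelope(envelope: ROMEnvelope, obj_path, json_path=None) -> None:
    """Write the envelope boundary as an OBJ mesh plus JSON metadata
    (alpha, dialect, volume, counts)."""
    lines = [f"v {p[0]:.9g} {p[1]:.9g} {p[2]:.9g}" for p in envelope.points]
    lines += [f"f {a + 1} {b + 1} {c + 1}" for a, b, c in envelope.boundary_facets]
    Path(obj_path).write_text("\n".join(lines) + "\n")
    if json_path is not None:
        meta = {
            "alpha": envelope.alpha,
            "dialect": envelope.dialect,
            "volume_cubic_degrees": envelope.volume,
            "n_points": int(envelope.points.shape[0]),
            "n_tetrahedra": int(envelope.tetrahedra.shape[0]),
            "n_boundary_facets": int(envelope.boundary_facets.shape[0]),
        }
        Path(json_path).write_text(json.dumps(meta, indent=2) + "\n")
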