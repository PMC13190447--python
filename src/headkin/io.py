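"""Readers and writers for the package's plain-text interchange formats.

Rotation CSV dialect (shared by all modules): header
``frame,t_ms,r11,r12,r13,r21,r22,r23,r31,r32,r33`` — the ``frame``
column carries the reference-frame label (C | G | H), matrices are
row-major, one row per sample, '.' decimal separator.

Marker TSV: header ``t_ms`` followed by ``<label>_x/_y/_z`` triplets for
the five skull landmarks, positions in mm in the global frame; missing
samples are empty fields.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Dict

import numpy as np

from headkin.mocap import MARKER_LABELS, MarkerTrajectory
from headkin.so3 import RotationSequence

__all__ = [
    "write_rotation_csv",
    "read_rotation_csv",
    "write_marker_tsv",
    "read_marker_tsv",
]

_ROT_COLS = ["r11", "r12", "r13", "r21", "r22", "r23", "r31", "r32", "r33"]
_FLOAT_FMT = "%.10g"


def write_rotation_csv(path: str | Path, seq: RotationSequence) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame", "t_ms"] + _ROT_COLS)
        for t, m in zip(seq.times, seq.matrices):
            writer.writerow(
                [seq.frame, _FLOAT_FMT % t] + [_FLOAT_FMT % v for v in m.ravel()]
            )


def read_rotation_csv(path: str | Path, rate: float | None = None) -> RotationSequence:
    """Read a rotation CSV; the rate is inferred from the times if not given."""
    times: list[float] = []
    mats: list[np.ndarray] = []
    frame = "G"
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or reader.fieldnames[:2] != ["frame", "t_ms"]:
            raise ValueError(f"{path}: expected header starting 'frame,t_ms'")
        for row in reader:
            frame = row["frame"]
            times.append(float(row["t_ms"]))
            mats.append(np.array([float(row[c]) for c in _ROT_COLS]).reshape(3, 3))
    if not times:
        raise ValueError(f"{path}: no rows")
    if rate is None:
        rate = 1000.0 / (times[1] - times[0]) if len(times) > 1 else float("nan")
    return RotationSequence(np.array(times), np.stack(mats), frame=frame, rate=rate)


def write_marker_tsv(path: str | Path, markers: Dict[str, MarkerTrajectory]) -> None:
    labels = [lab for lab in MARKER_LABELS if lab in markers]
    times = markers[labels[0]].times
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        header = ["t_ms"]
        for lab in labels:
            header += [f"{lab}_x", f"{lab}_y", f"{lab}_z"]
        writer.writerow(header)
        for i, t in enumerate(times):
            row = [_FLOAT_FMT % t]
            for lab in labels:
                traj = markers[lab]
                if traj.gaps[i]:
                    row += ["", "", ""]
                else:
                    row += [_FLOAT_FMT % v for v in traj.positions[i]]
            writer.writerow(row)


def read_marker_tsv(path: str | Path) -> Dict[str, MarkerTrajectory]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header[0] != "t_ms":
            raise ValueError(f"{path}: first column must be t_ms")
        labels = []
        for col in header[1:None:3]:
            if not col.endswith("_x"):
                raise ValueError(f"{path}: malformed marker column {col!r}")
            labels.append(col[:-2])
        rows = list(reader)
    times = np.array([float(r[0]) for r in rows])
    out: Dict[str, MarkerTrajectory] = {}
    for k, lab in enumerate(labels):
        pos = np.full((len(rows), 3), np.nan)
        for i, r in enumerate(rows):
            vals = r[1 + 3 * k : 4 + 3 * k]
            if all(v != "" for v in vals):
                pos[i] = [float(v) for v in vals]
        out[lab] = MarkerTrajectory(lab, times, pos)
    return out
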