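"""Pose-accuracy metrics: geodesic and incremental geodesic errors.

The geodesic error (GE) between reference and predicted orientations is
the angle of the relative rotation R^T R_hat — the minimal angular
displacement aligning the two, coordinate-free and immune to the
convention and gimbal-lock pitfalls of Euler-angle errors.  The
incremental geodesic error (IGE) compares the *magnitude of
frame-to-frame rotational change* between the two sequences,
|d(R_prev^T R) - d(R_hat_prev^T R_hat)|, isolating dynamic-tracking
fidelity: it is invariant to any constant offset on either sequence and
therefore unaffected by the anatomical alignment step.

All reported values are degrees; computation is in radians internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from headkin.so3 import RotationSequence, geodesic_distance

__all__ = [
    "ErrorSeries",
    "geodesic_error_series",
    "incremental_geodesic_error_series",
    "magnitude_series",
    "increment_series",
    "summarize_errors",
]


def _check_matched(reference: RotationSequence, predicted: RotationSequence) -> None:
    if len(reference) != len(predicted):
        raise ValueError(f"sequence lengths differ ({len(reference)} vs {len(predicted)})")
    if not np.allclose(reference.times, predicted.times, atol=1e-6):
        raise ValueError("sequence times do not match")


def geodesic_error_series(
    reference: RotationSequence, predicted: RotationSequence
) -> np.ndarray:
    """Per-frame geodesic error in degrees."""
    _check_matched(reference, predicted)
    return np.degrees(
        [geodesic_distance(r, p) for r, p in zip(reference.matrices, predicted.matrices)]
    )


def increment_series(seq: RotationSequence) -> np.ndarray:
    """Frame-to-frame rotation magnitude d(R_prev, R) in degrees; length n-1."""
    if len(seq) < 2:
        raise ValueError("increments need at least 2 frames")
    return np.degrees(
        [geodesic_distance(a, b) for a, b in zip(seq.matrices[:-1], seq.matrices[1:])]
    )


def magnitude_series(seq: RotationSequence) -> np.ndarray:
    """Rotation magnitude from the identity, d(R, I), in degrees per frame."""
    eye = np.eye(3)
    return np.degrees([geodesic_distance(eye, r) for r in seq.matrices])


def incremental_geodesic_error_series(
    reference: RotationSequence, predicted: RotationSequence
) -> np.ndarray:
    """Per-frame-pair incremental geodesic error in degrees; length n-1."""
    _check_matched(reference, predicted)
    if len(reference) < 2:
        raise ValueError("incremental errors need at least 2 frames")
    return np.abs(increment_series(reference) - increment_series(predicted))


@dataclass
class ErrorSeries:
    """Per-trial error series with grouping labels.

    ``ige`` has length n-1 and is indexed by the *later* frame of each
    pair (``times[1:]``); consistent with that convention, the first
    visibility sample of a sequence is never used in incremental
    analyses.
    """

    times: np.ndarray
    ge: np.ndarray
    ige: np.ndarray
    magnitude_ref: np.ndarray
    magnitude_pred: np.ndarray
    increment_ref: np.ndarray
    increment_pred: np.ndarray
    visibility: np.ndarray | None = None
    labels: dict | None = None

    @classmethod
    def from_sequences(
        cls,
        reference: RotationSequence,
        predicted: RotationSequence,
        visibility: np.ndarray | None = None,
        **labels,
    ) -> "ErrorSeries":
        inc_ref = increment_series(reference)
        inc_pred = increment_series(predicted)
        return cls(
            times=reference.times.copy(),
            ge=geodesic_error_series(reference, predicted),
            ige=np.abs(inc_ref - inc_pred),
            magnitude_ref=magnitude_series(reference),
            magnitude_pred=magnitude_series(predicted),
            increment_ref=inc_ref,
            increment_pred=inc_pred,
            visibility=None if visibility is None else np.asarray(visibility, float),
            labels=labels or None,
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format per-frame table; IGE is NaN on each sequence's first frame."""
        n = len(self.times)
        ige = np.full(n, np.nan)
        ige[1:] = self.ige
        data = {
            "frame": np.arange(n),
            "t_ms": self.times,
            "ge_deg": self.ge,
            "ige_deg": ige,
            "magnitude_ref_deg": self.magnitude_ref,
            "magnitude_pred_deg": self.magnitude_pred,
        }
        if self.visibility is not None:
            data["visibility"] = self.visibility
        df = pd.DataFrame(data)
        for key, value in (self.labels or {}).items():
            df[key] = value
        return df


def summarize_errors(
    series: Iterable[ErrorSeries] | pd.DataFrame,
    by: Sequence[str] = (),
) -> pd.DataFrame:
    """Pooled per-frame mean/median GE and IGE, optionally per group.

    Pooling is per frame (every frame counts once), not a mean of
    per-trial means; per-trial summaries for paired statistics are a
    separate groupby on the long table.  Empty groups are dropped with a
    warning.
    """
    if isinstance(series, pd.DataFrame):
        df = series
    else:
        frames = [s.to_frame() for s in series]
        if not frames:
            raise ValueError("no error series supplied")
        df = pd.concat(frames, ignore_index=True)

    def _agg(sub: pd.DataFrame) -> pd.Series:
        ige = sub["ige_deg"].dropna()
        return pd.Series(
            {
                "mean_ge_deg": sub["ge_deg"].mean(),
                "median_ge_deg": sub["ge_deg"].median(),
                "mean_ige_deg": ige.mean() if len(ige) else np.nan,
                "median_ige_deg": ige.median() if len(ige) else np.nan,
                "n_frames": len(sub),
            }
        )

    if not by:
        return _agg(df).to_frame().T
    groups = []
    for key, sub in df.groupby(list(by), sort=True):
        if sub.empty:  # pragma: no cover - groupby never yields empty groups
            warnings.warn(f"empty group {key}; omitted")
            continue
        row = _agg(sub)
        if not isinstance(key, tuple):
            key = (key,)
        for col, val in zip(by, key):
            row[col] = val
        groups.append(row)
    out = pd.DataFrame(groups)
    return out[list(by) + ["mean_ge_deg", "median_ge_deg", "mean_ige_deg", "median_ige_deg", "n_frames"]]
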