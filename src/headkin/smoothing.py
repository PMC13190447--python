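"""Tangent-space Gaussian smoothing of rotation sequences.

Per-frame pose estimators produce temporally inconsistent orientation
sequences; smoothing that respects the rotation geometry maps the
sequence into the tangent space (Lie algebra so(3)) at a base point via
the matrix logarithm, convolves each tangent component with a discrete
Gaussian kernel, and maps back with the matrix exponential.  The base
point is the sequence's Karcher mean by default, keeping the whole
window (excursions of a few tens of degrees) inside a single chart.

The filter-width sweep mirrors the usual tuning step: smooth, align,
score by geodesic and incremental-geodesic error, pick the width that
minimises the chosen objective.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from headkin import metrics as _metrics
from headkin.alignment import KarcherError, align_predictions, karcher_mean
from headkin.so3 import RotationSequence, exp_map, log_map, project_to_rotation

logger = logging.getLogger(__name__)

__all__ = ["SmoothingSpec", "smooth_sequence", "sigma_sweep", "SweepResult"]


@dataclass(frozen=True)
class SmoothingSpec:
    """Gaussian smoothing parameters.

    ``sigma`` is the kernel standard deviation in *frames* (0 disables
    smoothing); ``truncation`` the kernel half-width in units of sigma;
    ``base_point_policy`` selects the tangent-space chart origin.
    """

    sigma: float = 1.5
    truncation: float = 4.0
    base_point_policy: Literal["sequence-mean", "identity"] = "sequence-mean"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.truncation < 1:
            raise ValueError("truncation must be >= 1")


def _gaussian_kernel(sigma: float, truncation: float) -> np.ndarray:
    half = int(np.ceil(truncation * sigma))
    offsets = np.arange(-half, half + 1)
    w = np.exp(-0.5 * (offsets / sigma) ** 2)
    return w / w.sum()


def smooth_sequence(seq: RotationSequence, spec: SmoothingSpec) -> RotationSequence:
    """Smooth a rotation sequence in the tangent space at its mean.

    Edge frames use the truncated kernel renormalised to unit mass (no
    signal extension — the six-frame video windows are too short for
    reflection padding to be anything but distortive).  ``sigma = 0``
    returns the input unchanged; constant sequences are fixed points for
    any sigma.  If the sequence is too dispersed for a unique Karcher
    mean the chart falls back to the identity with a logged warning.
    """
    if len(seq) == 0:
        raise ValueError("cannot smooth an empty sequence")
    if spec.sigma == 0 or len(seq) == 1:
        return seq.with_matrices(seq.matrices.copy())
    if spec.base_point_policy == "sequence-mean":
        try:
            base, _, _ = karcher_mean(seq.matrices)
        except KarcherError:
            logger.warning(
                "sequence dispersion too large for a unique mean; "
                "smoothing in the chart at the identity"
            )
            base = np.eye(3)
    else:
        base = np.eye(3)
    tangent = np.array([log_map(base.T @ r) for r in seq.matrices])
    weights = _gaussian_kernel(spec.sigma, spec.truncation)
    half = (len(weights) - 1) // 2
    n = len(seq)
    smoothed = np.empty_like(tangent)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        w = weights[half - (i - lo) : half + (hi - i)]
        w = w / w.sum()
        smoothed[i] = w @ tangent[lo:hi]
    matrices = np.stack([project_to_rotation(base @ exp_map(v)) for v in smoothed])
    return seq.with_matrices(matrices)


@dataclass
class SweepResult:
    """Filter-width sensitivity curves and the selected width."""

    sigmas: np.ndarray
    mean_ge_deg: np.ndarray
    median_ge_deg: np.ndarray
    mean_ige_deg: np.ndarray
    median_ige_deg: np.ndarray
    selected_sigma: float
    objective: str

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "sigma": self.sigmas,
                "mean_ge_deg": self.mean_ge_deg,
                "median_ge_deg": self.median_ge_deg,
                "mean_ige_deg": self.mean_ige_deg,
                "median_ige_deg": self.median_ige_deg,
            }
        )


def sigma_sweep(
    reference: RotationSequence | Sequence[RotationSequence],
    predicted: RotationSequence | Sequence[RotationSequence],
    grid: Sequence[float],
    objective: Literal["ge", "ige", "sum"] = "sum",
    truncation: float = 4.0,
    align: bool = True,
) -> SweepResult:
    """Sweep the smoothing width and pick the error-minimising value.

    For each sigma in the (ascending, non-negative) grid, predictions
    are smoothed, anatomically aligned per sequence, and scored by the
    mean geodesic and incremental-geodesic errors pooled over all
    supplied sequences (a single pair is accepted too).  The selected
    sigma minimises the objective — mean GE, mean IGE, or their
    equal-weight sum in degrees (default) — with ties broken toward the
    smaller width, i.e. toward less distortion of genuine motion.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("sigma grid must be non-empty")
    if np.any(grid < 0) or np.any(np.diff(grid) < 0):
        raise ValueError("sigma grid must be non-negative and ascending")
    if isinstance(reference, RotationSequence):
        reference = [reference]
        predicted = [predicted]  # type: ignore[list-item]
    if len(reference) != len(predicted):
        raise ValueError("need one predicted sequence per reference sequence")

    mean_ge = np.empty(grid.size)
    med_ge = np.empty(grid.size)
    mean_ige = np.empty(grid.size)
    med_ige = np.empty(grid.size)
    for k, sigma in enumerate(grid):
        spec = SmoothingSpec(sigma=float(sigma), truncation=truncation)
        ge_all: list[np.ndarray] = []
        ige_all: list[np.ndarray] = []
        for ref, pred in zip(reference, predicted):
            smoothed = smooth_sequence(pred, spec)
            if align:
                smoothed, _ = align_predictions(ref, smoothed)
            ge_all.append(_metrics.geodesic_error_series(ref, smoothed))
            ige_all.append(_metrics.incremental_geodesic_error_series(ref, smoothed))
        ge = np.concatenate(ge_all)
        ige = np.concatenate(ige_all)
        mean_ge[k], med_ge[k] = float(np.mean(ge)), float(np.median(ge))
        mean_ige[k], med_ige[k] = float(np.mean(ige)), float(np.median(ige))

    scores = {"ge": mean_ge, "ige": mean_ige, "sum": mean_ge + mean_ige}[objective]
    selected = float(grid[int(np.argmin(scores))])  # argmin takes first minimum: smaller sigma
    return SweepResult(
        sigmas=grid,
        mean_ge_deg=mean_ge,
        median_ge_deg=med_ge,
        mean_ige_deg=mean_ige,
        median_ige_deg=med_ige,
        selected_sigma=selected,
        objective=objective,
    )
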