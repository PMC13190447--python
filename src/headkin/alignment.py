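"""Camera-to-global mapping and Karcher-mean anatomical alignment.

Pose estimators report head orientation in the camera frame; the
calibrated extrinsics carry it into the global frame by
left-multiplication.  A constant discrepancy then remains because the
estimator's notion of the head's anatomical coordinate system differs
from the marker-defined one.  That offset is estimated as the Karcher
(intrinsic) mean of the framewise relative errors on SO(3) and removed
by a single right-composition per sequence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from headkin.so3 import (
    RotationSequence,
    assert_rotation,
    exp_map,
    geodesic_distance,
    log_map,
    project_to_rotation,
)

__all__ = [
    "CameraExtrinsics",
    "AlignmentResult",
    "KarcherError",
    "camera_to_global",
    "framewise_relative_errors",
    "karcher_mean",
    "align_predictions",
]


class KarcherError(RuntimeError):
    """Karcher mean failed: excessive dispersion or non-convergence."""

    def __init__(self, message: str, last_iterate: np.ndarray | None = None):
        super().__init__(message)
        self.last_iterate = last_iterate


@dataclass(frozen=True)
class CameraExtrinsics:
    """Calibrated camera pose: rotation camera->global and position (m, global)."""

    label: str
    rotation_gc: np.ndarray
    position_m: np.ndarray

    def __post_init__(self) -> None:
        assert_rotation(self.rotation_gc)

    @classmethod
    def from_json(cls, path: str | Path) -> "CameraExtrinsics":
        data = json.loads(Path(path).read_text())
        return cls(
            label=data["label"],
            rotation_gc=np.asarray(data["rotation_row_major"], float).reshape(3, 3),
            position_m=np.asarray(data["position_m"], float),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "label": self.label,
                    "rotation_row_major": [float(x) for x in self.rotation_gc.ravel()],
                    "position_m": [float(x) for x in self.position_m],
                },
                indent=2,
            )
            + "\n"
        )


@dataclass
class AlignmentResult:
    """Outcome of anatomical alignment.

    ``delta_hat`` is the estimated constant anatomical offset: the
    Karcher mean of the framewise relative errors delta_i =
    predicted_i^T reference_i, so that aligned predictions are
    ``predicted_i @ delta_hat``.  (Equivalently, the mean *error* in the
    prediction-minus-reference sense is ``delta_hat.T``, and the
    operation is the usual right-composition by its transpose.)
    """

    delta_hat: np.ndarray
    framewise_errors: np.ndarray
    iterations: int
    final_step_norm: float
    converged: bool

    def to_dict(self) -> dict:
        angle_axis = log_map(self.delta_hat)
        return {
            "delta_hat_row_major": [float(x) for x in self.delta_hat.ravel()],
            "delta_hat_axis_angle_rad": [float(x) for x in angle_axis],
            "delta_hat_angle_deg": float(np.degrees(np.linalg.norm(angle_axis))),
            "iterations": self.iterations,
            "final_step_norm": self.final_step_norm,
            "converged": self.converged,
        }


def camera_to_global(seq: RotationSequence, cam: CameraExtrinsics) -> RotationSequence:
    """Re-express a camera-frame sequence in the global frame.

    Each orientation is left-multiplied by the camera-to-global rotation
    (R_HG = R_GC R_HC); times and length are preserved and the frame
    label becomes ``"G"``.
    """
    if seq.frame != "C":
        raise ValueError(f"sequence frame is {seq.frame!r}; camera_to_global expects 'C'")
    matrices = np.einsum("ij,njk->nik", cam.rotation_gc, seq.matrices)
    return RotationSequence(seq.times.copy(), matrices, frame="G", rate=seq.rate)


def _check_matched(reference: RotationSequence, predicted: RotationSequence) -> None:
    if len(reference) != len(predicted):
        raise ValueError(
            f"sequence lengths differ ({len(reference)} vs {len(predicted)})"
        )
    if not np.allclose(reference.times, predicted.times, atol=1e-6):
        raise ValueError("sequence times do not match")
    if reference.frame != predicted.frame:
        raise ValueError(
            f"sequences are in different frames ({reference.frame!r} vs {predicted.frame!r})"
        )


def framewise_relative_errors(
    reference: RotationSequence, predicted: RotationSequence
) -> np.ndarray:
    """Per-frame relative errors delta_i = predicted_i^T reference_i, shape (n, 3, 3)."""
    _check_matched(reference, predicted)
    return np.einsum("nji,njk->nik", predicted.matrices, reference.matrices)


def karcher_mean(
    rotations: Sequence[np.ndarray] | np.ndarray,
    tolerance: float = 1e-9,
    max_iterations: int = 100,
) -> tuple[np.ndarray, int, bool]:
    """Karcher (intrinsic) mean of rotations by iterative log-exp averaging.

    Iterates ``mu <- mu exp(mean_i log(mu^T r_i))`` until the tangent
    mean's norm drops below ``tolerance``; the result is a stationary
    point of the sum of squared geodesic distances.  The mean is only
    guaranteed unique when the inputs are concentrated, so dispersion
    beyond a geodesic ball of radius pi/2 around the chordal mean is
    rejected.  Initialisation is the first element — the anatomical
    offsets this is applied to cluster tightly, where convergence is
    quadratic.

    Returns ``(mean, iterations, converged)``; non-convergence raises
    :class:`KarcherError` carrying the last iterate.
    """
    rotations = np.asarray(rotations, dtype=float)
    if rotations.ndim != 3 or rotations.shape[1:] != (3, 3) or len(rotations) == 0:
        raise ValueError("need a non-empty (n, 3, 3) stack of rotations")
    if len(rotations) == 1:
        return rotations[0].copy(), 0, True
    chordal = project_to_rotation(rotations.mean(axis=0))
    dispersion = max(geodesic_distance(chordal, r) for r in rotations)
    if dispersion >= np.pi / 2:
        raise KarcherError(
            f"rotation dispersion {dispersion:.3f} rad exceeds the pi/2 ball; "
            "the Karcher mean is not guaranteed unique"
        )
    mu = rotations[0].copy()
    for iteration in range(1, max_iterations + 1):
        tangent = np.mean([log_map(mu.T @ r) for r in rotations], axis=0)
        step = float(np.linalg.norm(tangent))
        mu = project_to_rotation(mu @ exp_map(tangent))
        if step < tolerance:
            return mu, iteration, True
    raise KarcherError(
        f"Karcher mean did not converge in {max_iterations} iterations "
        f"(last step {step:.3g} rad)",
        last_iterate=mu,
    )


def align_predictions(
    reference: RotationSequence,
    predicted: RotationSequence,
    tolerance: float = 1e-9,
    max_iterations: int = 100,
) -> tuple[RotationSequence, AlignmentResult]:
    """Remove the constant anatomical offset from a predicted sequence.

    The offset estimate is the Karcher mean of the framewise relative
    errors delta_i = predicted_i^T reference_i; aligned predictions are
    ``predicted_i @ delta_hat``, which cancels any constant right
    (body-frame) offset exactly and minimises the sum of squared
    geodesic errors over constant right-compositions.
    """
    deltas = framewise_relative_errors(reference, predicted)
    delta_hat, iterations, converged = karcher_mean(
        deltas, tolerance=tolerance, max_iterations=max_iterations
    )
    tangent = np.mean([log_map(delta_hat.T @ d) for d in deltas], axis=0)
    aligned = predicted.with_matrices(
        np.einsum("nij,jk->nik", predicted.matrices, delta_hat)
    )
    result = AlignmentResult(
        delta_hat=delta_hat,
        framewise_errors=deltas,
        iterations=iterations,
        final_step_norm=float(np.linalg.norm(tangent)),
        converged=converged,
    )
    return aligned, result
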