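"""Rotation-group (SO(3)) primitives.

All orientation computation in the package runs on 3x3 rotation
matrices; a rotation maps head-frame coordinates into its reference
frame (columns are the head axes expressed in that frame), so a change
of reference frame is a plain left-multiplication.  Axis-angle vectors
(elements of the Lie algebra so(3)) appear only as the tangent-space
representation used by averaging and smoothing; Euler angles exist for
display only.

Orthogonality is *checked*, never silently repaired: matrices that fail
the 1e-8 tolerance must be passed through :func:`project_to_rotation`
explicitly by the caller, which surfaces corrupt input data instead of
hiding it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np

ORTHOGONALITY_TOL = 1e-8

__all__ = [
    "ORTHOGONALITY_TOL",
    "EulerAngles",
    "RotationSequence",
    "assert_rotation",
    "is_rotation",
    "project_to_rotation",
    "log_map",
    "exp_map",
    "geodesic_distance",
    "relative_rotation",
    "random_rotation",
    "euler_from_rotation",
    "rotation_from_euler",
    "quaternion_from_rotation",
]


def is_rotation(matrix: np.ndarray, tol: float = ORTHOGONALITY_TOL) -> bool:
    """True if ``matrix`` is orthogonal with determinant +1 within ``tol``."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (3, 3):
        return False
    ortho_dev = np.linalg.norm(matrix.T @ matrix - np.eye(3))
    return ortho_dev <= tol and abs(np.linalg.det(matrix) - 1.0) <= tol


def assert_rotation(matrix: np.ndarray, tol: float = ORTHOGONALITY_TOL) -> np.ndarray:
    """Validate a rotation matrix, returning it as a float array.

    Raises
    ------
    ValueError
        If the matrix is not orthogonal with determinant +1 within
        ``tol``.  Callers holding noisy data should project it with
        :func:`project_to_rotation` first.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (3, 3):
        raise ValueError(f"expected a 3x3 matrix, got shape {matrix.shape}")
    ortho_dev = np.linalg.norm(matrix.T @ matrix - np.eye(3))
    det = np.linalg.det(matrix)
    if ortho_dev > tol or abs(det - 1.0) > tol:
        raise ValueError(
            f"matrix is not a rotation (orthogonality deviation {ortho_dev:.3g}, "
            f"determinant {det:.9f}); use project_to_rotation to repair noisy input"
        )
    return matrix


def project_to_rotation(matrix: np.ndarray) -> np.ndarray:
    """Nearest rotation matrix in the Frobenius norm (via SVD).

    Idempotent on valid rotations.  Raises ``ValueError`` for singular
    input or input whose nearest orthogonal matrix is a reflection
    (negative determinant), both of which signal invalid orientation
    data rather than mere numerical drift.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (3, 3):
        raise ValueError(f"expected a 3x3 matrix, got shape {matrix.shape}")
    if not np.all(np.isfinite(matrix)):
        raise ValueError("matrix contains non-finite entries")
    u, s, vt = np.linalg.svd(matrix)
    if s[-1] <= 0 or s[0] / s[-1] > 1e12:
        raise ValueError("matrix is singular or near-singular; cannot project")
    if np.linalg.det(matrix) < 0:
        raise ValueError(
            "matrix has negative determinant (reflection); not a valid orientation"
        )
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, 1.0, d]) @ vt


def _hat(v: np.ndarray) -> np.ndarray:
    """Skew-symmetric (cross-product) matrix of a 3-vector."""
    return np.array(
        [
            [0.0, -v[2], v[1]],
            [v[2], 0.0, -v[0]],
            [-v[1], v[0], 0.0],
        ]
    )


def log_map(r: np.ndarray) -> np.ndarray:
    """Principal matrix logarithm of a rotation, as an axis-angle 3-vector.

    The returned vector has norm in [0, pi].  At the cut locus (angle
    exactly pi) the logarithm is two-valued; the branch is fixed by
    making the first nonzero component of the axis positive, a
    deterministic tie-break.
    """
    r = np.asarray(r, dtype=float)
    cos_angle = np.clip((np.trace(r) - 1.0) / 2.0, -1.0, 1.0)
    angle = float(np.arccos(cos_angle))
    if angle < 1e-10:
        # first-order: log(R) ~ skew part
        return np.array([r[2, 1] - r[1, 2], r[0, 2] - r[2, 0], r[1, 0] - r[0, 1]]) / 2.0
    if angle < 1.9:
        skew = (r - r.T) / (2.0 * np.sin(angle))
        return angle * np.array([skew[2, 1], skew[0, 2], skew[1, 0]])
    # large angles: the sin-based formula loses precision as the skew
    # part vanishes; extract axis-angle through the (stable) quaternion
    q = quaternion_from_rotation(r)
    if q[0] < 0:
        q = -q
    vec = q[1:]
    n = float(np.linalg.norm(vec))
    if n < 1e-15:  # pragma: no cover - angle >= 1.9 implies a nonzero vector part
        return np.zeros(3)
    angle = 2.0 * float(np.arctan2(n, q[0]))
    v = angle * vec / n
    if angle > np.pi - 1e-6:
        # cut-locus branch tie-break: first nonzero component positive
        nz = np.nonzero(np.abs(v) > 1e-9)[0]
        if nz.size and v[nz[0]] < 0:
            v = -v
    return v


def exp_map(v: np.ndarray) -> np.ndarray:
    """Matrix exponential of an axis-angle vector (Rodrigues' formula)."""
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("axis-angle vector contains non-finite entries")
    angle = float(np.linalg.norm(v))
    if angle < 1e-12:
        k = _hat(v)
        return np.eye(3) + k + 0.5 * (k @ k)
    k = _hat(v / angle)
    return np.eye(3) + np.sin(angle) * k + (1.0 - np.cos(angle)) * (k @ k)


def geodesic_distance(r1: np.ndarray, r2: np.ndarray) -> float:
    """Geodesic (angular) distance between two rotations, in radians.

    ``d(R1, R2) = arccos((tr(R1^T R2) - 1) / 2)``, the magnitude of the
    minimal rotation aligning the two; lies in [0, pi], is symmetric and
    bi-invariant.  The trace argument is clamped to [-1, 1] before the
    arccos to absorb rounding.
    """
    tr = float(np.trace(np.asarray(r1, dtype=float).T @ np.asarray(r2, dtype=float)))
    return float(np.arccos(np.clip((tr - 1.0) / 2.0, -1.0, 1.0)))


def relative_rotation(r_from: np.ndarray, r_to: np.ndarray) -> np.ndarray:
    """Rotation carrying ``r_from`` to ``r_to``: ``r_from^T r_to``."""
    return np.asarray(r_from, dtype=float).T @ np.asarray(r_to, dtype=float)


def random_rotation(
    rng: np.random.Generator, concentration: float | None = None
) -> np.ndarray:
    """Draw a random rotation.

    Without ``concentration``, uniform (Haar) on SO(3), via a normalised
    Gaussian quaternion.  With ``concentration`` sigma (radians), the
    exponential of an isotropic tangent-space normal with per-axis
    standard deviation sigma — the small-noise model used throughout the
    synthetic data.  sigma = 0 returns the identity.
    """
    if concentration is None:
        q = rng.standard_normal(4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        return np.array(
            [
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ]
        )
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    if concentration == 0:
        return np.eye(3)
    return exp_map(rng.normal(0.0, concentration, size=3))


def quaternion_from_rotation(r: np.ndarray) -> np.ndarray:
    """Unit quaternion (w, x, y, z) of a rotation; internal oracle helper."""
    r = np.asarray(r, dtype=float)
    tr = np.trace(r)
    if tr > 0:
        s = np.sqrt(tr + 1.0) * 2.0
        q = np.array(
            [0.25 * s, (r[2, 1] - r[1, 2]) / s, (r[0, 2] - r[2, 0]) / s, (r[1, 0] - r[0, 1]) / s]
        )
    else:
        i = int(np.argmax(np.diag(r)))
        j, k = (i + 1) % 3, (i + 2) % 3
        s = np.sqrt(max(1.0 + r[i, i] - r[j, j] - r[k, k], 0.0)) * 2.0
        q = np.empty(4)
        q[0] = (r[k, j] - r[j, k]) / s
        q[1 + i] = 0.25 * s
        q[1 + j] = (r[j, i] + r[i, j]) / s
        q[1 + k] = (r[k, i] + r[i, k]) / s
    return q / np.linalg.norm(q)


class EulerAngles(NamedTuple):
    """Intrinsic z-y'-x'' (yaw-pitch-roll) angles in degrees, display only."""

    yaw: float
    pitch: float
    roll: float
    gimbal_lock: bool = False


GIMBAL_LOCK_PITCH_DEG = 89.0


def euler_from_rotation(r: np.ndarray) -> EulerAngles:
    """Decompose a rotation into intrinsic z-y'-x'' yaw, pitch, roll (degrees).

    Within the gimbal-lock neighbourhood (|pitch| >= 89 deg) yaw and roll
    are not separable; the convention here sets roll to 0, folds the
    remaining spin into yaw, and flags the output.
    """
    r = np.asarray(r, dtype=float)
    sp = -r[2, 0]
    pitch = float(np.degrees(np.arcsin(np.clip(sp, -1.0, 1.0))))
    if abs(pitch) >= GIMBAL_LOCK_PITCH_DEG:
        yaw = float(np.degrees(np.arctan2(-r[0, 1], r[1, 1])))
        return EulerAngles(yaw=yaw, pitch=pitch, roll=0.0, gimbal_lock=True)
    yaw = float(np.degrees(np.arctan2(r[1, 0], r[0, 0])))
    roll = float(np.degrees(np.arctan2(r[2, 1], r[2, 2])))
    return EulerAngles(yaw=yaw, pitch=pitch, roll=roll, gimbal_lock=False)


def rotation_from_euler(yaw: float, pitch: float, roll: float) -> np.ndarray:
    """Compose a rotation from intrinsic z-y'-x'' yaw, pitch, roll (degrees)."""
    cy, sy = np.cos(np.radians(yaw)), np.sin(np.radians(yaw))
    cp, sp = np.cos(np.radians(pitch)), np.sin(np.radians(pitch))
    cr, sr = np.cos(np.radians(roll)), np.sin(np.radians(roll))
    rz = np.array([[cy, -sy, 0.0], [sy, cy, 0.0], [0.0, 0.0, 1.0]])
    ry = np.array([[cp, 0.0, sp], [0.0, 1.0, 0.0], [-sp, 0.0, cp]])
    rx = np.array([[1.0, 0.0, 0.0], [0.0, cr, -sr], [0.0, sr, cr]])
    return rz @ ry @ rx


@dataclass
class RotationSequence:
    """Time-stamped orientation sequence in a named reference frame.

    Parameters
    ----------
    times : array of float
        Sample times in ms relative to the window start; strictly
        increasing.
    matrices : array, shape (n, 3, 3)
        One rotation matrix per sample.
    frame : str
        Reference-frame label: ``"C"`` (camera), ``"G"`` (global) or
        ``"H"`` (anatomical head).
    rate : float
        Nominal sampling rate in Hz.
    """

    times: np.ndarray
    matrices: np.ndarray
    frame: str
    rate: float
    _validated: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.matrices = np.asarray(self.matrices, dtype=float)
        if self.matrices.ndim != 3 or self.matrices.shape[1:] != (3, 3):
            raise ValueError("matrices must have shape (n, 3, 3)")
        if len(self.times) != len(self.matrices):
            raise ValueError("times and matrices must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def validate(self, tol: float = ORTHOGONALITY_TOL) -> "RotationSequence":
        """Check every matrix against the rotation invariants; returns self."""
        for i, m in enumerate(self.matrices):
            try:
                assert_rotation(m, tol=tol)
            except ValueError as exc:
                raise ValueError(f"frame {i} (t={self.times[i]} ms): {exc}") from exc
        self._validated = True
        return self

    def with_matrices(self, matrices: np.ndarray, frame: str | None = None) -> "RotationSequence":
        """Copy with new matrices (and optionally a new frame label)."""
        return replace(
            self,
            matrices=np.asarray(matrices, dtype=float),
            frame=self.frame if frame is None else frame,
            _validated=False,
        )

    @classmethod
    def from_list(
        cls,
        times: Sequence[float],
        rotations: Sequence[np.ndarray],
        frame: str,
        rate: float,
    ) -> "RotationSequence":
        return cls(np.asarray(times, float), np.stack([np.asarray(r, float) for r in rotations]), frame, rate)
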