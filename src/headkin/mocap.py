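"""Marker-based reference orientations from optical motion capture.

Raw marker trajectories (five skull landmarks at 1000 Hz) become
reference head-orientation sequences through: gap filling, zero-lag
Butterworth low-pass filtering with residual-analysis cutoff selection
and an FFT sanity check, anatomical-coordinate-system (ACS)
construction on the Frankfort plane, impact-window extraction, and
mapping of 50 Hz video frames onto the 1000 Hz capture.

The head ACS follows the convention standard in head-impact work: the
origin is the midpoint of the external auditory meatus (EAM) markers,
the y-axis points left along the inter-EAM line, the z-axis is
perpendicular to the Frankfort plane (superior, with the inferior
orbital rim (IOR) markers supplying the anterior reference direction),
and the x-axis points anterior within the plane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Sequence

import numpy as np
from scipy import signal as sp_signal

from headkin.so3 import RotationSequence, project_to_rotation

MARKER_LABELS = ("EAM_L", "EAM_R", "IOR_L", "IOR_R", "SNA")

__all__ = [
    "MARKER_LABELS",
    "MarkerTrajectory",
    "FilterSpec",
    "AnatomicalFrame",
    "GapError",
    "fill_gaps",
    "butterworth_zero_lag",
    "select_cutoff_residual",
    "fft_threshold_check",
    "construct_acs",
    "rigid_fit",
    "extract_impact_window",
    "map_video_frames",
    "reference_sequence_from_markers",
]


class GapError(ValueError):
    """Raised when a signal contains gaps that must be filled first."""


@dataclass
class MarkerTrajectory:
    """One labelled marker: times (ms), positions (mm, global frame), gap mask."""

    label: str
    times: np.ndarray
    positions: np.ndarray
    gaps: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.times), 3):
            raise ValueError("positions must have shape (n, 3)")
        if self.gaps is None:
            self.gaps = ~np.all(np.isfinite(self.positions), axis=1)
        self.gaps = np.asarray(self.gaps, dtype=bool)
        if len(self.times) > 1:
            dt = np.diff(self.times)
            if not np.allclose(dt, dt[0], atol=1e-6):
                raise ValueError(f"{self.label}: times must be uniformly spaced")
            if dt[0] <= 0:
                raise ValueError(f"{self.label}: times must be strictly increasing")
        finite = self.positions[~self.gaps]
        if finite.size and np.max(np.abs(finite)) >= 1e4:
            raise ValueError(f"{self.label}: positions exceed capture-volume sanity bound (10^4 mm)")

    @property
    def rate(self) -> float:
        """Nominal sampling rate in Hz."""
        if len(self.times) < 2:
            return float("nan")
        return 1000.0 / float(self.times[1] - self.times[0])


@dataclass(frozen=True)
class FilterSpec:
    """Zero-lag Butterworth specification.

    ``order`` is the *net* order after the forward-backward pass; the
    underlying one-way filter has order ``order // 2``.
    """

    order: int = 4
    cutoff: float = 50.0
    rate: float = 1000.0

    def __post_init__(self) -> None:
        if self.order < 2 or self.order % 2:
            raise ValueError("net filter order must be an even integer >= 2")
        if not 0 < self.cutoff < self.rate / 2:
            raise ValueError("cutoff must lie in (0, Nyquist)")


@dataclass(frozen=True)
class AnatomicalFrame:
    """Head anatomical coordinate system: origin (mm) and rotation (head -> global)."""

    origin: np.ndarray
    rotation: np.ndarray


def fill_gaps(traj: MarkerTrajectory, max_gap_ms: float = 10.0) -> MarkerTrajectory:
    """Linearly interpolate gaps up to ``max_gap_ms``; longer gaps raise GapError."""
    if not traj.gaps.any():
        return traj
    if traj.gaps[0] or traj.gaps[-1]:
        raise GapError(f"{traj.label}: gap at trajectory boundary cannot be interpolated")
    # find contiguous gap runs
    idx = np.flatnonzero(traj.gaps)
    runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    dt = traj.times[1] - traj.times[0]
    for run in runs:
        if len(run) * dt > max_gap_ms:
            raise GapError(
                f"{traj.label}: gap of {len(run) * dt:.0f} ms exceeds the "
                f"{max_gap_ms:.0f} ms interpolation limit"
            )
    good = ~traj.gaps
    positions = traj.positions.copy()
    for axis in range(3):
        positions[traj.gaps, axis] = np.interp(
            traj.times[traj.gaps], traj.times[good], traj.positions[good, axis]
        )
    return MarkerTrajectory(traj.label, traj.times, positions, np.zeros(len(traj.times), bool))


def butterworth_zero_lag(series: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Forward-backward Butterworth low-pass with zero phase lag.

    A half-order filter applied forward then backward gives the net
    ``spec.order`` and cancels the phase delay (amplitude gain at the
    cutoff is therefore 1/2, two passes of -3 dB).  Edges are handled by
    odd-symmetric signal extension of three times the net order, the
    standard choice for biomechanical trajectories.  No cutoff
    correction factor is applied.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("expected a 1-D series; filter each channel separately")
    if not np.all(np.isfinite(series)):
        raise GapError("signal contains gaps (non-finite samples); fill_gaps first")
    if len(series) < 3 * spec.order:
        raise ValueError("series too short for the requested filter order")
    b, a = sp_signal.butter(spec.order // 2, spec.cutoff, fs=spec.rate)
    return sp_signal.filtfilt(b, a, series, padtype="odd", padlen=3 * spec.order)


def select_cutoff_residual(
    series: np.ndarray,
    rate: float,
    cutoff_grid: Sequence[float],
    order: int = 4,
) -> tuple[float, np.ndarray]:
    """Residual-analysis cutoff selection.

    For each candidate cutoff the RMS residual between the raw and
    filtered signal is computed.  A straight line is fitted to the
    high-cutoff tail of the residual curve (upper half of the grid),
    where the residual is dominated by removed noise and is nearly
    linear in cutoff; its zero-frequency intercept estimates the noise
    RMS.  The chosen cutoff is the lowest grid value whose residual
    falls to or below that intercept — the classic compromise between
    signal distortion and noise passing.

    Returns ``(chosen_cutoff, residuals)`` with residuals aligned to the
    grid.
    """
    cutoff_grid = np.asarray(cutoff_grid, dtype=float)
    if len(cutoff_grid) < 4:
        raise ValueError("cutoff grid needs at least 4 points for the tail line fit")
    if not np.all(np.diff(cutoff_grid) > 0):
        raise ValueError("cutoff grid must be ascending")
    if cutoff_grid[0] <= 0 or cutoff_grid[-1] >= rate / 2:
        raise ValueError("cutoff grid must lie in (0, Nyquist)")
    series = np.asarray(series, dtype=float)
    residuals = np.empty(len(cutoff_grid))
    for i, fc in enumerate(cutoff_grid):
        filtered = butterworth_zero_lag(series, FilterSpec(order=order, cutoff=fc, rate=rate))
        residuals[i] = float(np.sqrt(np.mean((series - filtered) ** 2)))
    tail = slice(len(cutoff_grid) // 2, None)
    slope, intercept = np.polyfit(cutoff_grid[tail], residuals[tail], 1)
    below = np.flatnonzero(residuals <= intercept)
    chosen = float(cutoff_grid[below[0]]) if below.size else float(cutoff_grid[-1])
    return chosen, residuals


def fft_threshold_check(
    series: np.ndarray, rate: float, threshold_fraction: float = 0.1
) -> float:
    """Highest frequency whose FFT magnitude exceeds a fraction of the peak.

    One-sided spectrum, DC excluded from the peak; used as a sanity
    check that the chosen filter cutoff sits above the signal content.
    """
    series = np.asarray(series, dtype=float)
    if len(series) < 64:
        raise ValueError("series too short for a meaningful spectrum (need >= 64 samples)")
    mags = np.abs(np.fft.rfft(series - np.mean(series)))
    freqs = np.fft.rfftfreq(len(series), d=1.0 / rate)
    mags[0] = 0.0
    peak = mags.max()
    if peak == 0:
        return 0.0
    above = np.flatnonzero(mags > threshold_fraction * peak)
    return float(freqs[above[-1]]) if above.size else 0.0


def construct_acs(markers: Mapping[str, np.ndarray]) -> AnatomicalFrame:
    """Anatomical coordinate system from one instant's marker positions.

    origin = midpoint(EAM_L, EAM_R); y = unit(EAM_L - EAM_R);
    anterior reference a = unit(midpoint(IOR_L, IOR_R) - origin);
    z = unit(a x y) (superior); x = y x z (anterior, in the Frankfort
    plane).  Rotation columns are (x, y, z): head axes expressed in the
    global frame.
    """
    try:
        eam_l = np.asarray(markers["EAM_L"], float)
        eam_r = np.asarray(markers["EAM_R"], float)
        ior_l = np.asarray(markers["IOR_L"], float)
        ior_r = np.asarray(markers["IOR_R"], float)
    except KeyError as exc:
        raise ValueError(f"missing required marker {exc} for ACS construction") from exc
    origin = (eam_l + eam_r) / 2.0
    y = eam_l - eam_r
    ny = np.linalg.norm(y)
    if ny < 1e-9:
        raise ValueError("EAM markers coincide; degenerate geometry")
    y = y / ny
    a = (ior_l + ior_r) / 2.0 - origin
    na = np.linalg.norm(a)
    if na < 1e-9:
        raise ValueError("IOR midpoint coincides with ACS origin; degenerate geometry")
    a = a / na
    z = np.cross(a, y)
    nz = np.linalg.norm(z)
    if nz < 1e-9:
        raise ValueError("EAM and IOR markers are collinear; degenerate geometry")
    z = z / nz
    x = np.cross(y, z)
    return AnatomicalFrame(origin=origin, rotation=np.column_stack([x, y, z]))


def rigid_fit(
    reference: Mapping[str, np.ndarray] | np.ndarray,
    observed: Mapping[str, np.ndarray] | np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid transform (Kabsch) mapping reference -> observed.

    Accepts either matching label->position mappings (intersection of
    labels used) or (n, 3) arrays in corresponding order.  Returns
    ``(rotation, translation, rmsd_mm)`` with determinant +1 enforced.
    This is the noise-robust alternative to :func:`construct_acs` that
    exploits all available markers against a per-participant reference
    geometry, including the nasion redundancy marker.
    """
    if isinstance(reference, Mapping):
        if not isinstance(observed, Mapping):
            raise TypeError("reference and observed must both be mappings or both arrays")
        labels = [k for k in reference if k in observed]
        ref = np.array([reference[k] for k in labels], dtype=float)
        obs = np.array([observed[k] for k in labels], dtype=float)
    else:
        ref = np.asarray(reference, dtype=float)
        obs = np.asarray(observed, dtype=float)
    if ref.shape != obs.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("need matching (n, 3) point sets")
    if len(ref) < 3:
        raise ValueError("rigid fit needs at least 3 correspondences")
    ref_c = ref - ref.mean(axis=0)
    obs_c = obs - obs.mean(axis=0)
    s = np.linalg.svd(ref_c, compute_uv=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise ValueError("reference points are collinear; rigid fit underdetermined")
    h = ref_c.T @ obs_c
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    translation = obs.mean(axis=0) - rotation @ ref.mean(axis=0)
    residuals = obs - (ref @ rotation.T + translation)
    rmsd = float(np.sqrt(np.mean(np.sum(residuals**2, axis=1))))
    return rotation, translation, rmsd


def extract_impact_window(
    obj: RotationSequence | MarkerTrajectory,
    impact_time: float,
    pre: float = 20.0,
    post: float = 80.0,
):
    """Extract the half-open impact window [impact - pre, impact + post) ms.

    At 1000 Hz with the default 20/80 ms split this yields exactly 100
    samples.  Times in the returned object are re-expressed relative to
    the window start.
    """
    if pre + post <= 0:
        raise ValueError("window must have positive length")
    t0, t1 = impact_time - pre, impact_time + post
    times = obj.times
    if t0 < times[0] - 1e-9 or t1 > times[-1] + (times[1] - times[0]) + 1e-9:
        raise ValueError(
            f"window [{t0}, {t1}) ms extends outside the recording "
            f"[{times[0]}, {times[-1]}] ms"
        )
    mask = (times >= t0 - 1e-9) & (times < t1 - 1e-9)
    if not mask.any():
        raise ValueError("window contains no samples")
    new_times = times[mask] - t0
    if isinstance(obj, RotationSequence):
        return RotationSequence(new_times, obj.matrices[mask], obj.frame, obj.rate)
    return MarkerTrajectory(obj.label, new_times, obj.positions[mask], obj.gaps[mask])


def map_video_frames(
    window: RotationSequence | MarkerTrajectory,
    video_rate: float = 50.0,
    n_frames: int = 6,
) -> np.ndarray:
    """Indices of the capture samples nearest each video frame time.

    Video frame k sits at t = k / video_rate within the window; the
    final frame of the default 6-frame / 100-sample layout falls at the
    window's open boundary (100 ms) and is clamped to the last in-window
    sample (index 99), reproducing the six-video / hundred-capture frame
    pairing of a 100 ms window.
    """
    times = window.times
    frame_times = np.arange(n_frames) * 1000.0 / video_rate
    idx = np.abs(times[None, :] - frame_times[:, None]).argmin(axis=1)
    return idx.astype(int)


def reference_sequence_from_markers(
    markers: Dict[str, MarkerTrajectory],
    filter_spec: FilterSpec | None = None,
    max_gap_ms: float = 10.0,
    use_rigid_fit: bool = True,
    n_reference_frames: int = 10,
) -> RotationSequence:
    """Full marker pipeline: gap fill, filter, per-frame head orientation.

    The per-participant reference geometry is the marker cloud expressed
    in the first frames' ACS, averaged over ``n_reference_frames``; each
    subsequent frame's orientation is then the rigid (Kabsch) fit of
    that geometry, which uses all five markers including the nasion
    redundancy marker.  With ``use_rigid_fit=False`` the ACS is rebuilt
    per frame from the four primary markers only.
    """
    missing = [lab for lab in ("EAM_L", "EAM_R", "IOR_L", "IOR_R") if lab not in markers]
    if missing:
        raise ValueError(f"missing required markers: {missing}")
    filled = {lab: fill_gaps(traj, max_gap_ms) for lab, traj in markers.items()}
    times = next(iter(filled.values())).times
    rate = next(iter(filled.values())).rate
    for traj in filled.values():
        if not np.array_equal(traj.times, times):
            raise ValueError("marker trajectories are not sampled on a common time base")
    if filter_spec is not None:
        for lab, traj in filled.items():
            pos = np.column_stack(
                [butterworth_zero_lag(traj.positions[:, k], filter_spec) for k in range(3)]
            )
            filled[lab] = MarkerTrajectory(lab, traj.times, pos)
    n = len(times)
    rotations = np.empty((n, 3, 3))
    if use_rigid_fit:
        n_ref = min(n_reference_frames, n)
        local_clouds = []
        labels = sorted(filled)
        for i in range(n_ref):
            frame_markers = {lab: filled[lab].positions[i] for lab in labels}
            acs = construct_acs(frame_markers)
            cloud = np.array(
                [acs.rotation.T @ (frame_markers[lab] - acs.origin) for lab in labels]
            )
            local_clouds.append(cloud)
        reference_cloud = np.mean(local_clouds, axis=0)
        for i in range(n):
            obs = np.array([filled[lab].positions[i] for lab in labels])
            rotations[i], _, _ = rigid_fit(reference_cloud, obs)
    else:
        for i in range(n):
            acs = construct_acs({lab: filled[lab].positions[i] for lab in filled})
            rotations[i] = acs.rotation
    rotations = np.stack([project_to_rotation(r) for r in rotations])
    return RotationSequence(times, rotations, frame="G", rate=rate)
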