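"""Synthetic heading-trial generator with fully known ground truth.

Real heading datasets pair 1000 Hz marker-based reference orientations
with six 50 Hz video frames over a 100 ms impact window, and are not
publicly shareable; this module generates structurally identical trials
in which every quantity the pipeline estimates — the anatomical offset,
the noise level, the visibility profile — is known exactly, so each
stage has a parameter-recovery test.

What a trial emulates:

* a pitch (flexion) pulse peaking just after ball contact, with peak
  excursion drawn from the 22-36 degree band typical of headers, plus a
  small smooth roll; rotational (R) trials add a smooth yaw ramp as the
  player redirects the ball 90 degrees to the right;
* five skull-landmark markers rigidly attached to the moving head, with
  additive isotropic position noise;
* a visibility dip centred on the impact frame (the ball occluding the
  face), realised as actual face/occluder boxes, with an extra
  yaw-dependent attenuation of the side camera for R trials
  (self-occlusion);
* per-model "prediction profiles": a constant anatomical offset (the
  systematic discrepancy between a pose model's head frame and the
  marker-defined one) composed with visibility-dependent body-frame
  tangent noise, sigma(v) = sigma0 + sigma1 * (1 - v) degrees per axis,
  expressed in the camera frame so the pipeline must undo the
  extrinsics.

Noise sits on the right (body frame), which makes the chi-3 closed form
for the mean geodesic error exact and offset recovery clean.  All
randomness flows from a single seed through spawned generators;
regeneration with the same seed is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np

from headkin.detection import Box, FrameBoxes, save_boxes_json, load_boxes_json
from headkin.io import write_marker_tsv, write_rotation_csv, read_marker_tsv, read_rotation_csv
from headkin.mocap import MarkerTrajectory, extract_impact_window, map_video_frames
from headkin.alignment import CameraExtrinsics
from headkin.so3 import (
    RotationSequence,
    exp_map,
    log_map,
    project_to_rotation,
    rotation_from_euler,
)

__all__ = [
    "ModelProfile",
    "SimConfig",
    "TrialRecord",
    "DEFAULT_PROFILES",
    "default_extrinsics",
    "generate_ground_truth",
    "generate_markers",
    "generate_visibility",
    "generate_predictions",
    "generate_trial",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
]

# Canonical head-frame marker geometry (mm).  Invented defaults,
# constrained only by the construction the anatomical frame assumes:
# EAM and IOR markers coplanar in z = 0 (the Frankfort plane), EAMs on
# the y-axis, IORs anterior.
CANONICAL_MARKERS: Dict[str, np.ndarray] = {
    "EAM_R": np.array([0.0, -70.0, 0.0]),
    "EAM_L": np.array([0.0, 70.0, 0.0]),
    "IOR_R": np.array([75.0, -35.0, 0.0]),
    "IOR_L": np.array([75.0, 35.0, 0.0]),
    "SNA": np.array([85.0, 0.0, 15.0]),
}


@dataclass(frozen=True)
class ModelProfile:
    """Noise/offset profile emulating one class of pose estimator.

    ``sigma0_deg`` is the per-axis tangent noise floor, ``sigma1_deg``
    the extra noise at zero visibility; ``smoothing_sigma`` the filter
    width (frames) used for this profile when no sweep is run;
    ``offset_axis``/``offset_angle_deg`` define the constant anatomical
    offset.
    """

    name: str
    sigma0_deg: float
    sigma1_deg: float
    smoothing_sigma: float
    offset_axis: tuple = (1.0, 0.0, 0.0)
    offset_angle_deg: float = 15.0

    @property
    def offset(self) -> np.ndarray:
        axis = np.asarray(self.offset_axis, float)
        axis = axis / np.linalg.norm(axis)
        return exp_map(np.radians(self.offset_angle_deg) * axis)


# Three built-in profiles spanning the behaviours seen in practice:
# face-driven estimators whose error balloons under occlusion (high or
# moderate sigma1) and a body-context model that barely notices the face
# disappearing (low sigma1, slightly higher floor).
DEFAULT_PROFILES: Dict[str, ModelProfile] = {
    "face_high": ModelProfile(
        "face_high", sigma0_deg=2.0, sigma1_deg=14.0, smoothing_sigma=1.5,
        offset_axis=(1.0, 0.3, 0.0),
    ),
    "face_moderate": ModelProfile(
        "face_moderate", sigma0_deg=2.2, sigma1_deg=8.0, smoothing_sigma=1.5,
        offset_axis=(0.5, 1.0, 0.2),
    ),
    "body_low": ModelProfile(
        "body_low", sigma0_deg=2.9, sigma1_deg=1.0, smoothing_sigma=0.5,
        offset_axis=(0.0, 0.6, 1.0),
    ),
}


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the synthetic dataset.

    Defaults mirror the heading-trial protocol: ten participants, five
    linear (L) and five rotational (R) headers each, two cameras, 1000
    Hz capture with six 50 Hz video frames over a 100 ms window (20 ms
    pre-, 80 ms post-impact).
    """

    n_participants: int = 10
    trials_per_type: int = 5
    trial_types: tuple = ("L", "R")
    cameras: tuple = ("F", "S")
    recording_duration_ms: float = 900.0
    impact_time_ms: float = 500.0
    window_pre_ms: float = 20.0
    window_post_ms: float = 80.0
    mocap_rate: float = 1000.0
    video_rate: float = 50.0
    pitch_amplitude_deg: tuple = (22.0, 36.0)
    pitch_peak_lag_ms: float = 10.0
    pitch_width_ms: float = 55.0
    yaw_amplitude_r_deg: float = 45.0
    yaw_ramp_ms: float = 300.0
    roll_amplitude_deg: float = 2.0
    occlusion_depth: tuple = (0.3, 0.95)
    occlusion_width_ms: float = 15.0
    visibility_baseline: tuple = (0.2, 1.0)
    visibility_jitter: float = 0.04
    marker_noise_mm: float = 0.5
    head_path_mm: float = 80.0
    seed: int = 0

    @property
    def n_video_frames(self) -> int:
        window = self.window_pre_ms + self.window_post_ms
        return int(round(window * self.video_rate / 1000.0)) + 1


@dataclass
class TrialRecord:
    """One header trial as seen by one camera."""

    participant: int
    trial: int
    trial_type: str
    camera: str
    reference: RotationSequence  # 1000 Hz impact window, global frame
    reference_video: RotationSequence  # video frames, global frame
    predictions: Dict[str, RotationSequence]  # profile -> camera-frame sequence
    markers: Dict[str, MarkerTrajectory]
    boxes: List[FrameBoxes]
    visibility: np.ndarray  # intended per-video-frame ratios
    true_offsets: Dict[str, np.ndarray]
    extrinsics: CameraExtrinsics

    @property
    def trial_id(self) -> str:
        return f"p{self.participant:02d}_t{self.trial:02d}_{self.camera}"


def default_extrinsics() -> Dict[str, CameraExtrinsics]:
    """Front and side camera poses; the side view is yawed 90 degrees."""
    front_rot = rotation_from_euler(180.0, 0.0, -90.0)
    side_rot = rotation_from_euler(-90.0, 0.0, 0.0) @ front_rot
    return {
        "F": CameraExtrinsics("F", project_to_rotation(front_rot), np.array([5.0, -0.4, 2.6])),
        "S": CameraExtrinsics("S", project_to_rotation(side_rot), np.array([-0.1, 3.0, 0.9])),
    }


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def generate_ground_truth(
    config: SimConfig, trial_type: str, rng: np.random.Generator
) -> RotationSequence:
    """Head orientation over the full recording at the capture rate.

    Pitch is a Gaussian-shaped flexion pulse peaking ``pitch_peak_lag_ms``
    after impact with amplitude drawn from the configured band; R trials
    add a smooth (smoothstep) yaw ramp starting at impact; roll is a
    small pulse peaking later in the follow-through.  All channels are
    C2-smooth by construction.
    """
    if trial_type not in ("L", "R"):
        raise ValueError(f"unknown trial type {trial_type!r}")
    dt = 1000.0 / config.mocap_rate
    times = np.arange(0.0, config.recording_duration_ms, dt)
    amp = float(rng.uniform(*config.pitch_amplitude_deg))
    t_peak = config.impact_time_ms + config.pitch_peak_lag_ms
    pitch = amp * np.exp(-(((times - t_peak) / config.pitch_width_ms) ** 2))
    if trial_type == "R":
        yaw = config.yaw_amplitude_r_deg * _smoothstep(
            (times - config.impact_time_ms) / config.yaw_ramp_ms
        )
    else:
        yaw = np.zeros_like(times)
    roll = config.roll_amplitude_deg * np.exp(
        -(((times - (config.impact_time_ms + 60.0)) / 50.0) ** 2)
    )
    matrices = np.stack(
        [rotation_from_euler(y, p, r) for y, p, r in zip(yaw, pitch, roll)]
    )
    return RotationSequence(times, matrices, frame="G", rate=config.mocap_rate)


def generate_markers(
    reference: RotationSequence, config: SimConfig, rng: np.random.Generator
) -> Dict[str, MarkerTrajectory]:
    """Marker trajectories rigidly attached to the ground-truth motion.

    The canonical head-frame marker cloud is rotated by each frame's
    orientation, carried along a smooth forward head path, and corrupted
    with isotropic Gaussian noise of ``marker_noise_mm``.
    """
    times = reference.times
    path = np.zeros((len(times), 3))
    path[:, 0] = config.head_path_mm * _smoothstep(
        (times - (config.impact_time_ms - 150.0)) / 400.0
    )
    path += np.array([1000.0, 800.0, 1600.0])  # head height / capture-volume offset
    out: Dict[str, MarkerTrajectory] = {}
    for label, local in CANONICAL_MARKERS.items():
        pos = np.einsum("nij,j->ni", reference.matrices, local) + path
        pos = pos + rng.normal(0.0, config.marker_noise_mm, size=pos.shape)
        out[label] = MarkerTrajectory(label, times.copy(), pos)
    return out


def _video_times(config: SimConfig) -> np.ndarray:
    return np.arange(config.n_video_frames) * 1000.0 / config.video_rate


def generate_visibility(
    config: SimConfig,
    trial_type: str,
    camera: str,
    yaw_deg_video: np.ndarray,
    rng: np.random.Generator,
    occlusion_depth: float | None = None,
    baseline: float | None = None,
) -> tuple[np.ndarray, List[FrameBoxes]]:
    """Per-video-frame visibility ratios and the boxes that realise them.

    The intended ratio is a per-trial baseline (how much of the face
    this camera sees over the whole header — partial turns, hands and
    arms vary trial to trial and persist across the short window) with
    small per-frame downward jitter, times a Gaussian occlusion dip of
    the trial's depth centred at the impact frame (the ball), times a
    yaw-dependent self-occlusion factor for the side camera on
    rotational trials.  The boxes consist of a fixed face box and one
    occluder covering the complementary width fraction, so recomputing
    visible areas from the boxes reproduces the intended ratios (up to
    the per-camera max normalisation).
    """
    t = _video_times(config)
    depth = float(rng.uniform(*config.occlusion_depth)) if occlusion_depth is None else occlusion_depth
    if baseline is None:
        baseline = float(rng.uniform(*config.visibility_baseline))
    base = baseline * (1.0 - rng.uniform(0.0, config.visibility_jitter, size=len(t)))
    dip = 1.0 - depth * np.exp(-(((t - config.window_pre_ms) / config.occlusion_width_ms) ** 2))
    vis = base * dip
    if camera == "S" and trial_type == "R":
        vis = vis * (1.0 - 0.5 * np.abs(yaw_deg_video) / 90.0)
    vis = np.clip(vis, 0.0, 1.0)
    face = Box(595.0, 205.0, 90.0, 110.0) if camera == "F" else Box(640.0, 215.0, 80.0, 100.0)
    head = Box(face.x - 0.1 * face.w, face.y - 0.1 * face.h, 1.2 * face.w, 1.2 * face.h)
    frames: List[FrameBoxes] = []
    for k, v in enumerate(vis):
        occluders = []
        if v < 1.0:
            occluders.append(Box(face.x, face.y, face.w * (1.0 - v), face.h))
        det: List[Box] = []
        miss_p = 0.3 if v < 0.2 else 0.02
        if rng.random() >= miss_p:
            jitter = rng.normal(0.0, 2.0, size=4)
            det.append(Box(head.x + jitter[0], head.y + jitter[1],
                           max(head.w + jitter[2], 1.0), max(head.h + jitter[3], 1.0)))
        if rng.random() < 0.01:
            det.append(Box(float(rng.uniform(0, 1100)), float(rng.uniform(0, 600)), 60.0, 60.0))
        frames.append(
            FrameBoxes(frame=k, face=face, occluders=occluders, detections=det,
                       ground_truth=[head])
        )
    return vis, frames


def generate_predictions(
    reference_video: RotationSequence,
    visibility: np.ndarray,
    profile: ModelProfile,
    extrinsics: CameraExtrinsics,
    rng: np.random.Generator,
) -> RotationSequence:
    """Noisy camera-frame predictions with a constant anatomical offset.

    predicted_i = R_GC^T (reference_i * Delta * exp(eps_i)) with eps_i
    isotropic body-frame tangent noise of per-axis standard deviation
    sigma0 + sigma1 * (1 - v_i) degrees: a floor for the estimator's
    intrinsic jitter plus a visibility-dependent occlusion penalty.
    """
    if len(reference_video) != len(visibility):
        raise ValueError("visibility must have one value per video frame")
    delta = profile.offset
    mats = np.empty_like(reference_video.matrices)
    for i, (ref, v) in enumerate(zip(reference_video.matrices, visibility)):
        sigma = np.radians(profile.sigma0_deg + profile.sigma1_deg * (1.0 - v))
        noise = exp_map(rng.normal(0.0, sigma, size=3)) if sigma > 0 else np.eye(3)
        mats[i] = extrinsics.rotation_gc.T @ (ref @ delta @ noise)
    return RotationSequence(reference_video.times.copy(), mats, frame="C",
                            rate=reference_video.rate)


def generate_trial(
    config: SimConfig,
    participant: int,
    trial: int,
    trial_type: str,
    rng: np.random.Generator,
    profiles: Dict[str, ModelProfile] | None = None,
    extrinsics: Dict[str, CameraExtrinsics] | None = None,
) -> List[TrialRecord]:
    """Generate one header trial as seen by every camera."""
    profiles = profiles or DEFAULT_PROFILES
    extrinsics = extrinsics or default_extrinsics()
    ground_truth = generate_ground_truth(config, trial_type, rng)
    markers = generate_markers(ground_truth, config, rng)
    window = extract_impact_window(
        ground_truth, config.impact_time_ms, config.window_pre_ms, config.window_post_ms
    )
    vidx = map_video_frames(window, config.video_rate, config.n_video_frames)
    video_times = _video_times(config)
    reference_video = RotationSequence(
        video_times, window.matrices[vidx], frame="G", rate=config.video_rate
    )
    from headkin.so3 import euler_from_rotation

    yaw_video = np.array([euler_from_rotation(m).yaw for m in reference_video.matrices])
    # depth and baseline are properties of the trial (ball flight, arm
    # position), shared by both camera views
    depth = float(rng.uniform(*config.occlusion_depth))
    baseline = float(rng.uniform(*config.visibility_baseline))
    records: List[TrialRecord] = []
    for camera in config.cameras:
        cam = extrinsics[camera]
        vis, boxes = generate_visibility(
            config, trial_type, camera, yaw_video, rng,
            occlusion_depth=depth, baseline=baseline,
        )
        predictions = {
            name: generate_predictions(reference_video, vis, prof, cam, rng)
            for name, prof in profiles.items()
        }
        records.append(
            TrialRecord(
                participant=participant,
                trial=trial,
                trial_type=trial_type,
                camera=camera,
                reference=window,
                reference_video=reference_video,
                predictions=predictions,
                markers=markers,
                boxes=boxes,
                visibility=vis,
                true_offsets={name: prof.offset for name, prof in profiles.items()},
                extrinsics=cam,
            )
        )
    return records


def generate_dataset(
    config: SimConfig | None = None,
    profiles: Dict[str, ModelProfile] | None = None,
) -> List[TrialRecord]:
    """Full synthetic dataset: participants x trials x cameras.

    Deterministic under ``config.seed``: every trial draws from a
    generator spawned from a single seed sequence, so the output is
    byte-identical across runs.
    """
    config = config or SimConfig()
    profiles = profiles or DEFAULT_PROFILES
    extr = default_extrinsics()
    root = np.random.SeedSequence(config.seed)
    records: List[TrialRecord] = []
    n_trials = config.trials_per_type * len(config.trial_types)
    children = root.spawn(config.n_participants * n_trials)
    k = 0
    for participant in range(1, config.n_participants + 1):
        for trial in range(1, n_trials + 1):
            trial_type = config.trial_types[(trial - 1) // config.trials_per_type]
            rng = np.random.default_rng(children[k])
            k += 1
            records.extend(
                generate_trial(config, participant, trial, trial_type, rng,
                               profiles=profiles, extrinsics=extr)
            )
    return records


def write_dataset(records: List[TrialRecord], out_dir: str | Path,
                  config: SimConfig | None = None) -> Path:
    """Write every interchange file plus the truth manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": None if config is None else config.seed, "trials": {}}
    written_markers: set[str] = set()
    for cam_label in sorted({r.camera for r in records}):
        rec = next(r for r in records if r.camera == cam_label)
        rec.extrinsics.to_json(out / f"extrinsics_{cam_label}.json")
    for rec in records:
        tid = rec.trial_id
        marker_key = f"p{rec.participant:02d}_t{rec.trial:02d}"
        if marker_key not in written_markers:
            write_marker_tsv(out / f"{marker_key}_markers.tsv", rec.markers)
            written_markers.add(marker_key)
        write_rotation_csv(out / f"{tid}_ref_video.csv", rec.reference_video)
        for name, seq in rec.predictions.items():
            write_rotation_csv(out / f"{tid}_pred_{name}.csv", seq)
        save_boxes_json(out / f"{tid}_boxes.json", rec.camera, rec.boxes)
        manifest["trials"][tid] = {
            "participant": rec.participant,
            "trial": rec.trial,
            "trial_type": rec.trial_type,
            "camera": rec.camera,
            "visibility": [round(float(v), 6) for v in rec.visibility],
            "offsets_axis_angle_rad": {
                name: [float(x) for x in log_map(off)]
                for name, off in rec.true_offsets.items()
            },
        }
    if config is not None:
        manifest["config"] = {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()
        }
    (out / "truth_manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return out


def read_dataset(data_dir: str | Path) -> List[TrialRecord]:
    """Reconstruct trial records from an on-disk dataset.

    The 1000 Hz reference window is not stored (it is derivable from the
    markers); records read back carry the video-frame reference as both
    ``reference`` and ``reference_video``.
    """
    data_dir = Path(data_dir)
    manifest = json.loads((data_dir / "truth_manifest.json").read_text())
    extr = {
        p.stem.split("_")[1]: CameraExtrinsics.from_json(p)
        for p in sorted(data_dir.glob("extrinsics_*.json"))
    }
    records: List[TrialRecord] = []
    for tid, meta in sorted(manifest["trials"].items()):
        ref = read_rotation_csv(data_dir / f"{tid}_ref_video.csv")
        predictions = {
            p.stem.replace(f"{tid}_pred_", ""): read_rotation_csv(p)
            for p in sorted(data_dir.glob(f"{tid}_pred_*.csv"))
        }
        _, _, boxes = load_boxes_json(data_dir / f"{tid}_boxes.json")
        marker_key = f"p{meta['participant']:02d}_t{meta['trial']:02d}"
        markers = read_marker_tsv(data_dir / f"{marker_key}_markers.tsv")
        records.append(
            TrialRecord(
                participant=meta["participant"],
                trial=meta["trial"],
                trial_type=meta["trial_type"],
                camera=meta["camera"],
                reference=ref,
                reference_video=ref,
                predictions=predictions,
                markers=markers,
                boxes=boxes,
                visibility=np.array(meta["visibility"], float),
                true_offsets={
                    name: exp_map(np.array(v))
                    for name, v in meta["offsets_axis_angle_rad"].items()
                },
                extrinsics=extr[meta["camera"]],
            )
        )
    return records
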