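"""Synthetic heading-trial generator: determinism, kinematics, closure."""

import hashlib
from pathlib import Path

import numpy as np
import pytest

from headkin.alignment import align_predictions, camera_to_global
from headkin.detection import visible_face_area
from headkin.mocap import construct_acs
from headkin.simulate import (
    DEFAULT_PROFILES,
    CANONICAL_MARKERS,
    ModelProfile,
    SimConfig,
    default_extrinsics,
    generate_dataset,
    generate_ground_truth,
    generate_markers,
    generate_predictions,
    generate_visibility,
    read_dataset,
    write_dataset,
)
from headkin.so3 import RotationSequence, euler_from_rotation, geodesic_distance


def _dir_hash(path: Path) -> str:
    digest = hashlib.sha256()
    for f in sorted(path.rglob("*")):
        if f.is_file():
            digest.update(f.name.encode())
            digest.update(f.read_bytes())
    return digest.hexdigest()


class TestGroundTruth:
    CFG = SimConfig(recording_duration_ms=900.0, impact_time_ms=500.0)

    def test_zero_amplitudes_give_identity_motion(self):
        cfg = SimConfig(pitch_amplitude_deg=(0.0, 0.0), yaw_amplitude_r_deg=0.0,
                        roll_amplitude_deg=0.0)
        seq = generate_ground_truth(cfg, "R", np.random.default_rng(0))
        assert max(geodesic_distance(np.eye(3), m) for m in seq.matrices) < 1e-12

    def test_linear_trials_have_no_yaw(self):
        seq = generate_ground_truth(self.CFG, "L", np.random.default_rng(1))
        yaws = [euler_from_rotation(m).yaw for m in seq.matrices]
        assert max(abs(y) for y in yaws) < 5.0

    def test_rotational_trials_reach_target_yaw(self):
        seq = generate_ground_truth(self.CFG, "R", np.random.default_rng(2))
        final_yaw = euler_from_rotation(seq.matrices[-1]).yaw
        assert abs(final_yaw - self.CFG.yaw_amplitude_r_deg) < 0.1 * self.CFG.yaw_amplitude_r_deg

    def test_peak_window_excursion_in_configured_band(self):
        """Peak d(R, I) over the impact window tracks the drawn amplitude band
        (small slack for the cross-axis roll/yaw contributions)."""
        lo, hi = self.CFG.pitch_amplitude_deg
        for seed in range(100):
            trial_type = "L" if seed % 2 else "R"
            seq = generate_ground_truth(self.CFG, trial_type, np.random.default_rng(seed))
            win = (seq.times >= 480.0) & (seq.times < 580.0)
            peak = np.degrees(
                max(geodesic_distance(np.eye(3), m) for m in seq.matrices[win])
            )
            assert lo - 0.5 <= peak <= hi + 1.0

    def test_smoothness_bounded_angular_acceleration(self):
        seq = generate_ground_truth(self.CFG, "R", np.random.default_rng(3))
        inc = np.array(
            [geodesic_distance(a, b) for a, b in zip(seq.matrices[:-1], seq.matrices[1:])]
        )
        accel = np.abs(np.diff(inc))  # rad per ms^2
        assert accel.max() < 5e-3

    def test_unknown_trial_type_rejected(self):
        with pytest.raises(ValueError):
            generate_ground_truth(self.CFG, "X", np.random.default_rng(0))


class TestMarkers:
    def test_noiseless_markers_recover_frame_rotations(self):
        cfg = SimConfig(marker_noise_mm=0.0, recording_duration_ms=200.0, impact_time_ms=100.0)
        rng = np.random.default_rng(5)
        truth = generate_ground_truth(cfg, "L", rng)
        markers = generate_markers(truth, cfg, rng)
        for i in (0, 50, 150):
            frame = {lab: markers[lab].positions[i] for lab in markers}
            acs = construct_acs(frame)
            assert geodesic_distance(acs.rotation, truth.matrices[i]) < 1e-9

    def test_identity_motion_keeps_marker_shape_constant(self):
        cfg = SimConfig(marker_noise_mm=0.0, pitch_amplitude_deg=(0.0, 0.0),
                        yaw_amplitude_r_deg=0.0, roll_amplitude_deg=0.0, head_path_mm=0.0,
                        recording_duration_ms=200.0, impact_time_ms=100.0)
        rng = np.random.default_rng(6)
        truth = generate_ground_truth(cfg, "L", rng)
        markers = generate_markers(truth, cfg, rng)
        for lab, traj in markers.items():
            assert np.ptp(traj.positions, axis=0).max() < 1e-9


class TestVisibility:
    CFG = SimConfig()

    def test_zero_depth_keeps_baseline_near_one(self):
        vis, _ = generate_visibility(self.CFG, "L", "F", np.zeros(6),
                                     np.random.default_rng(7), occlusion_depth=0.0,
                                     baseline=1.0)
        assert np.all(vis >= 1.0 - self.CFG.visibility_jitter - 1e-9)

    def test_dip_depth_realised_at_impact_frame(self):
        vis, _ = generate_visibility(self.CFG, "L", "F", np.zeros(6),
                                     np.random.default_rng(8), occlusion_depth=0.6,
                                     baseline=1.0)
        assert vis[1] == pytest.approx(0.4, abs=self.CFG.visibility_jitter + 0.01)

    def test_boxes_reproduce_intended_ratios(self):
        rng = np.random.default_rng(9)
        vis, frames = generate_visibility(self.CFG, "L", "F", np.zeros(6), rng,
                                          occlusion_depth=0.7)
        face_area = frames[0].face.area
        realised = np.array([visible_face_area(f) / face_area for f in frames])
        np.testing.assert_allclose(realised, vis, atol=0.02)

    def test_side_camera_self_occlusion_for_rotational_trials(self, small_records):
        side_r = [r.visibility.mean() for r in small_records
                  if r.camera == "S" and r.trial_type == "R"]
        front_r = [r.visibility.mean() for r in small_records
                   if r.camera == "F" and r.trial_type == "R"]
        assert np.mean(side_r) < np.mean(front_r)


class TestPredictions:
    def test_noiseless_identity_offset_round_trips(self, rng):
        cfg = SimConfig()
        truth = generate_ground_truth(cfg, "L", rng)
        idx = np.array([480, 500, 520, 540, 560, 580])
        ref = RotationSequence(np.arange(6) * 20.0, truth.matrices[idx], "G", 50.0)
        profile = ModelProfile("null", 0.0, 0.0, 0.0, offset_angle_deg=0.0)
        cam = default_extrinsics()["F"]
        pred = generate_predictions(ref, np.ones(6), profile, cam, rng)
        assert pred.frame == "C"
        back = camera_to_global(pred, cam)
        for a, b in zip(back.matrices, ref.matrices):
            assert geodesic_distance(a, b) < 1e-10

    def test_constant_offset_recovered_by_alignment(self, rng):
        cfg = SimConfig()
        truth = generate_ground_truth(cfg, "R", rng)
        idx = np.array([480, 500, 520, 540, 560, 580])
        ref = RotationSequence(np.arange(6) * 20.0, truth.matrices[idx], "G", 50.0)
        profile = ModelProfile("offset", 0.0, 0.0, 0.0,
                               offset_axis=(0.2, 1.0, 0.5), offset_angle_deg=15.0)
        cam = default_extrinsics()["S"]
        pred = generate_predictions(ref, np.ones(6), profile, cam, rng)
        pred_g = camera_to_global(pred, cam)
        ge_before = np.degrees(
            np.mean([geodesic_distance(a, b) for a, b in zip(pred_g.matrices, ref.matrices)])
        )
        aligned, result = align_predictions(ref, pred_g)
        ge_after = max(
            geodesic_distance(a, b) for a, b in zip(aligned.matrices, ref.matrices)
        )
        assert ge_before == pytest.approx(15.0, abs=1e-6)
        assert ge_after < 1e-8
        assert geodesic_distance(result.delta_hat, profile.offset.T) < 1e-8


class TestDataset:
    def test_default_design_yields_200_records(self):
        cfg = SimConfig(seed=3)
        records = generate_dataset(cfg)
        assert len(records) == 200
        assert {r.trial_type for r in records} == {"L", "R"}
        assert {r.camera for r in records} == {"F", "S"}
        assert all(len(r.reference_video) == 6 for r in records)
        assert all(len(r.reference) == 100 for r in records)

    def test_byte_identical_regeneration(self, tmp_path, small_config):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_dataset(generate_dataset(small_config), d1, config=small_config)
        write_dataset(generate_dataset(small_config), d2, config=small_config)
        assert _dir_hash(d1) == _dir_hash(d2)

    def test_round_trip_through_disk(self, tmp_path, small_records, small_config):
        out = write_dataset(small_records, tmp_path / "ds", config=small_config)
        loaded = read_dataset(out)
        assert len(loaded) == len(small_records)
        orig = {r.trial_id: r for r in small_records}
        for rec in loaded:
            src = orig[rec.trial_id]
            np.testing.assert_allclose(
                rec.reference_video.matrices, src.reference_video.matrices, atol=1e-9
            )
            for name, seq in rec.predictions.items():
                np.testing.assert_allclose(
                    seq.matrices, src.predictions[name].matrices, atol=1e-9
                )
            for name, off in rec.true_offsets.items():
                assert geodesic_distance(off, src.true_offsets[name]) < 1e-9

    def test_visibility_spans_low_and_high_strata(self, default_records):
        vis = np.concatenate([r.visibility for r in default_records])
        assert vis.min() < 0.2 and vis.max() > 0.95

    def test_end_to_end_offset_recovery_against_manifest(self, small_records):
        """The trial-averaged offset estimate matches the manifest truth."""
        from headkin.alignment import karcher_mean

        delta_hats = []
        for rec in small_records:
            pred = camera_to_global(rec.predictions["body_low"], rec.extrinsics)
            _, result = align_predictions(rec.reference_video, pred)
            delta_hats.append(result.delta_hat)
        pooled, _, _ = karcher_mean(np.stack(delta_hats))
        truth = small_records[0].true_offsets["body_low"].T
        assert np.degrees(geodesic_distance(pooled, truth)) < 2.0
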