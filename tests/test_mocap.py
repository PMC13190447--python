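"""Marker processing: filtering, cutoff selection, ACS construction, windows."""

import numpy as np
import pytest

from headkin.mocap import (
    AnatomicalFrame,
    FilterSpec,
    GapError,
    MarkerTrajectory,
    butterworth_zero_lag,
    construct_acs,
    extract_impact_window,
    fft_threshold_check,
    fill_gaps,
    map_video_frames,
    reference_sequence_from_markers,
    rigid_fit,
    select_cutoff_residual,
)
from headkin.simulate import CANONICAL_MARKERS, SimConfig, generate_ground_truth, generate_markers
from headkin.so3 import RotationSequence, geodesic_distance, random_rotation, rotation_from_euler


def _sine(freq, rate=1000.0, duration=1.0, amp=1.0):
    t = np.arange(0.0, duration, 1.0 / rate)
    return t, amp * np.sin(2 * np.pi * freq * t)


class TestButterworth:
    def test_dc_invariance(self):
        series = np.full(200, 5.0)
        out = butterworth_zero_lag(series, FilterSpec(4, 50.0, 1000.0))
        np.testing.assert_allclose(out, series, atol=1e-9)

    def test_zero_phase_lag(self):
        _, s = _sine(10.0)
        out = butterworth_zero_lag(s, FilterSpec(4, 50.0, 1000.0))
        lags = np.arange(-20, 21)
        xc = [np.dot(out, np.roll(s, k)) for k in lags]
        assert lags[int(np.argmax(xc))] == 0

    def test_gain_at_cutoff_is_half(self):
        """Two passes of -3 dB: amplitude gain 0.5 at the cutoff frequency."""
        t, s = _sine(50.0, duration=2.0)
        out = butterworth_zero_lag(s, FilterSpec(4, 50.0, 1000.0))
        mid = slice(500, 1500)
        # amplitude via quadrature projection on the known frequency
        c = np.cos(2 * np.pi * 50.0 * t[mid])
        sn = np.sin(2 * np.pi * 50.0 * t[mid])
        amp = 2.0 * np.hypot(np.dot(out[mid], sn), np.dot(out[mid], c)) / len(t[mid])
        assert abs(amp - 0.5) < 0.05

    def test_gap_raises(self):
        s = np.ones(100)
        s[50] = np.nan
        with pytest.raises(GapError):
            butterworth_zero_lag(s, FilterSpec(4, 50.0, 1000.0))

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            FilterSpec(3, 50.0, 1000.0)
        with pytest.raises(ValueError):
            FilterSpec(4, 600.0, 1000.0)


class TestResidualAnalysis:
    GRID = np.arange(4.0, 101.0, 4.0)

    def test_noiseless_sinusoid_selects_where_distortion_vanishes(self):
        """Without noise the intercept is ~0, so the chosen cutoff is the
        first grid value whose Butterworth roll-off no longer touches the
        5 Hz signal; residuals above the signal frequency shrink fast."""
        _, s = _sine(5.0, amp=30.0)
        chosen, residuals = select_cutoff_residual(s, 1000.0, self.GRID)
        assert 5.0 < chosen <= 60.0
        assert np.all(residuals[self.GRID >= 20.0] < 0.01 * 30.0 / np.sqrt(2))
        assert residuals[np.searchsorted(self.GRID, chosen)] < 0.05

    def test_intercept_recovers_noise_rms(self):
        """Monte Carlo: the tail-line intercept estimates the noise RMS."""
        _, clean = _sine(5.0, amp=30.0)
        ratios = []
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            s = clean + rng.normal(0.0, 0.5, clean.size)
            _, residuals = select_cutoff_residual(s, 1000.0, self.GRID)
            tail = slice(len(self.GRID) // 2, None)
            _, intercept = np.polyfit(self.GRID[tail], residuals[tail], 1)
            ratios.append(intercept / 0.5)
        assert abs(np.mean(ratios) - 1.0) < 0.2

    def test_white_noise_residual_decreases_with_cutoff(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            s = rng.normal(0.0, 1.0, 1000)
            _, residuals = select_cutoff_residual(s, 1000.0, self.GRID)
            assert np.all(np.diff(residuals) < 0)

    def test_short_grid_rejected(self):
        _, s = _sine(5.0)
        with pytest.raises(ValueError):
            select_cutoff_residual(s, 1000.0, [10.0, 20.0, 30.0])


class TestFftCheck:
    def test_single_tone(self):
        _, s = _sine(8.0)
        assert abs(fft_threshold_check(s, 1000.0) - 8.0) <= 1.0

    @pytest.mark.parametrize("amp2,expected", [(0.05, 8.0), (0.2, 40.0)])
    def test_two_tone_threshold(self, amp2, expected):
        t, s = _sine(8.0)
        s = s + amp2 * np.sin(2 * np.pi * 40.0 * t)
        assert abs(fft_threshold_check(s, 1000.0, 0.1) - expected) <= 1.0


class TestAnatomicalFrame:
    def test_canonical_markers_give_identity(self):
        acs = construct_acs(CANONICAL_MARKERS)
        np.testing.assert_allclose(acs.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(acs.origin, [0.0, 0.0, 0.0], atol=1e-12)

    def test_equivariance_under_rigid_motion(self, rng):
        for _ in range(20):
            r = random_rotation(rng)
            t = rng.normal(0, 500, 3)
            moved = {k: r @ v + t for k, v in CANONICAL_MARKERS.items()}
            acs = construct_acs(moved)
            assert np.linalg.norm(acs.rotation - r) < 1e-9
            np.testing.assert_allclose(acs.origin, r @ np.zeros(3) + t, atol=1e-9)

    def test_noise_propagation_below_one_degree(self, rng):
        errs = []
        for _ in range(1000):
            noisy = {k: v + rng.normal(0, 0.5, 3) for k, v in CANONICAL_MARKERS.items()}
            errs.append(geodesic_distance(construct_acs(noisy).rotation, np.eye(3)))
        assert np.degrees(np.mean(errs)) < 1.0

    def test_degenerate_geometry_rejected(self):
        collinear = {
            "EAM_L": np.array([0.0, 70.0, 0.0]),
            "EAM_R": np.array([0.0, -70.0, 0.0]),
            "IOR_L": np.array([0.0, 35.0, 0.0]),
            "IOR_R": np.array([0.0, -35.0, 0.0]),
        }
        with pytest.raises(ValueError):
            construct_acs(collinear)


class TestRigidFit:
    def test_identity_on_equal_clouds(self):
        pts = np.array(list(CANONICAL_MARKERS.values()))
        r, t, rmsd = rigid_fit(pts, pts)
        np.testing.assert_allclose(r, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(t, np.zeros(3), atol=1e-9)
        assert rmsd < 1e-10

    def test_exact_transform_recovered(self, rng):
        pts = np.array(list(CANONICAL_MARKERS.values()))
        r_true = random_rotation(rng)
        t_true = rng.normal(0, 100, 3)
        obs = pts @ r_true.T + t_true
        r, t, rmsd = rigid_fit(pts, obs)
        assert geodesic_distance(r, r_true) < 1e-10
        np.testing.assert_allclose(t, t_true, atol=1e-8)
        assert rmsd < 1e-10

    def test_outlier_marker_beats_random_rotations(self, rng):
        pts = np.array(list(CANONICAL_MARKERS.values()))
        obs = pts.copy()
        obs[0] += [5.0, 0.0, 0.0]
        r, t, rmsd = rigid_fit(pts, obs)
        assert rmsd > 0
        best = np.sum((obs - (pts @ r.T + t)) ** 2)
        for _ in range(1000):
            rr = random_rotation(rng)
            centred = obs.mean(0) - rr @ pts.mean(0)
            assert np.sum((obs - (pts @ rr.T + centred)) ** 2) >= best - 1e-9

    def test_agrees_with_acs_on_noiseless_markers(self, rng):
        r_true = random_rotation(rng)
        moved = {k: r_true @ v for k, v in CANONICAL_MARKERS.items()}
        r, _, _ = rigid_fit(CANONICAL_MARKERS, moved)
        acs = construct_acs(moved)
        assert geodesic_distance(r, acs.rotation) < 1e-9

    def test_collinear_rejected(self):
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        with pytest.raises(ValueError):
            rigid_fit(line, line)


class TestWindowing:
    def _seq(self, rate=1000.0, duration=1000.0):
        dt = 1000.0 / rate
        times = np.arange(0.0, duration, dt)
        mats = np.tile(np.eye(3), (len(times), 1, 1))
        return RotationSequence(times, mats, "G", rate)

    def test_100_frames_at_capture_rate(self):
        win = extract_impact_window(self._seq(), 500.0)
        assert len(win) == 100
        np.testing.assert_allclose(win.times, np.arange(100.0))

    def test_window_count_independent_of_impact_time(self):
        for impact in (100.0, 333.0, 800.0):
            assert len(extract_impact_window(self._seq(), impact)) == 100

    def test_video_rate_window(self):
        win = extract_impact_window(self._seq(rate=50.0), 500.0)
        np.testing.assert_allclose(win.times, [0.0, 20.0, 40.0, 60.0, 80.0])

    def test_degenerate_and_out_of_range(self):
        with pytest.raises(ValueError):
            extract_impact_window(self._seq(), 500.0, pre=0.0, post=0.0)
        with pytest.raises(ValueError):
            extract_impact_window(self._seq(), 990.0)

    def test_video_frame_mapping(self):
        win = extract_impact_window(self._seq(), 500.0)
        idx = map_video_frames(win)
        np.testing.assert_array_equal(idx, [0, 20, 40, 60, 80, 99])


class TestGapFilling:
    def _traj(self, gap_idx):
        times = np.arange(100.0)
        pos = np.column_stack([times, 2 * times, -times])
        pos[gap_idx] = np.nan
        return MarkerTrajectory("SNA", times, pos)

    def test_short_gap_interpolated_exactly_on_linear_motion(self):
        filled = fill_gaps(self._traj([40, 41, 42]))
        assert not filled.gaps.any()
        np.testing.assert_allclose(filled.positions[:, 0], np.arange(100.0), atol=1e-12)

    def test_long_gap_rejected(self):
        with pytest.raises(GapError):
            fill_gaps(self._traj(list(range(40, 60))))


class TestMarkerPipelineClosure:
    def test_noiseless_markers_reproduce_ground_truth(self):
        cfg = SimConfig(marker_noise_mm=0.0, recording_duration_ms=300.0, impact_time_ms=150.0)
        rng = np.random.default_rng(3)
        truth = generate_ground_truth(cfg, "L", rng)
        markers = generate_markers(truth, cfg, rng)
        seq = reference_sequence_from_markers(markers)
        worst = max(
            np.linalg.norm(a - b) for a, b in zip(seq.matrices, truth.matrices)
        )
        assert worst < 1e-8

    def test_default_noise_closure_within_half_degree(self):
        """Markers -> filter -> rigid fit reproduces the generating motion."""
        cfg = SimConfig(recording_duration_ms=300.0, impact_time_ms=150.0)
        rng = np.random.default_rng(4)
        truth = generate_ground_truth(cfg, "R", rng)
        markers = generate_markers(truth, cfg, rng)
        seq = reference_sequence_from_markers(markers, FilterSpec(4, 50.0, 1000.0))
        errs = [geodesic_distance(a, b) for a, b in zip(seq.matrices, truth.matrices)]
        assert np.degrees(np.mean(errs)) < 0.5
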