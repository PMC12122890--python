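"""Curves, threshold segmentation and feature extraction."""

import numpy as np
import pytest

import reachgrasp as rg
from reachgrasp import kinematics as kin
from reachgrasp.errors import (
    InvalidInputError,
    NoGraspError,
    NoMovementError,
)


def direct_gaussian_smooth(x, sigma):
    """Independent oracle: explicit kernel sum with edge renormalisation."""
    r = int(np.ceil(4 * sigma))
    out = np.empty_like(x, dtype=float)
    for i in range(len(x)):
        num = den = 0.0
        for o in range(-r, r + 1):
            j = i + o
            if 0 <= j < len(x):
                w = np.exp(-0.5 * (o / sigma) ** 2)
                num += w * x[j]
                den += w
        out[i] = num / den
    return out


class TestSmoothCurve:
    def test_preserves_constant(self):
        assert np.allclose(kin.smooth_curve([5.0, 5, 5, 5]), 5.0)

    def test_impulse_matches_direct_convolution(self):
        x = np.zeros(21)
        x[10] = 1.0
        got = kin.smooth_curve(x, 0.93)
        want = direct_gaussian_smooth(x, 0.93)
        assert np.allclose(got, want, atol=1e-12)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=50), rng.normal(size=50)
        lhs = kin.smooth_curve(a) + kin.smooth_curve(b)
        assert np.allclose(lhs, kin.smooth_curve(a + b), atol=1e-12)

    def test_rejects_empty_and_bad_sigma(self):
        with pytest.raises(InvalidInputError):
            kin.smooth_curve([])
        with pytest.raises(InvalidInputError):
            kin.smooth_curve([1.0, 2.0], sigma=0.0)


def _make_trial(wrist, thumb, index, fs=120.0):
    return kin.MarkerTrial("t", fs, wrist, thumb, index)


class TestComputeCurves:
    def test_constant_velocity_wrist_speed(self):
        n, fs, v = 60, 120.0, 100.0
        t = np.arange(n) / fs
        wrist = np.column_stack([v * t, np.zeros(n), np.zeros(n)])
        still = np.tile([200.0, 0.0, 0.0], (n, 1))
        curves = kin.compute_curves(_make_trial(wrist, still, still + [60, 0, 0]))
        interior = curves.speed_r[8:-8]
        assert np.allclose(interior, v, rtol=1e-6)

    def test_stationary_fingers_constant_aperture(self):
        n = 40
        wrist = np.tile([0.0, 0, 0], (n, 1))
        thumb = np.tile([10.0, 0, 0], (n, 1))
        index = np.tile([70.0, 0, 0], (n, 1))
        curves = kin.compute_curves(_make_trial(wrist, thumb, index))
        assert np.allclose(curves.ga, 60.0)
        assert np.allclose(curves.vel_ga, 0.0, atol=1e-9)

    def test_minimum_jerk_peak_speed_closed_form(self):
        fs, dur, dist = 120.0, 1.0, 300.0
        n = int(fs * dur) + 1
        tau = np.linspace(0, 1, n)
        prof = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
        wrist = np.column_stack([dist * prof, np.zeros(n), np.zeros(n)])
        still = np.tile([100.0, 0, 0], (n, 1))
        curves = kin.compute_curves(_make_trial(wrist, still, still + [50, 0, 0]))
        expected = 1.875 * dist / dur
        assert abs(curves.speed_r.max() - expected) / expected < 0.01

    def test_too_few_frames(self):
        with pytest.raises(rg.errors.InsufficientDataError):
            _make_trial(np.zeros((3, 3)), np.zeros((3, 3)), np.zeros((3, 3)))


def _curves_from_wrist(pos, fs=120.0):
    """KinematicCurves with given raw wrist positions and an inert aperture."""
    n = pos.shape[0]
    return kin.KinematicCurves(
        sampling_rate=fs,
        ga=np.full(n, 60.0),
        vel_ga=np.zeros(n),
        acc_ga=np.zeros(n),
        rx=pos[:, 0],
        ry=pos[:, 1],
        rz=pos[:, 2],
        speed_r=np.zeros(n),
        acc_r=np.zeros(n),
        thumb_y=np.zeros(n),
        index_y=np.zeros(n),
    )


def oracle_onset(disp, thr, run):
    """Exhaustive scan for the first frame opening a supra-threshold run
    (any-axis indicator)."""
    flags = (np.abs(disp) > thr).any(axis=1)
    for i in range(len(flags) - run + 1):
        if flags[i : i + run].all():
            return i + 1  # displacement i belongs to frame i+1
    return None


class TestDetectReachPhase:
    def test_stationary_wrist_raises(self):
        pos = np.tile([1.0, 2.0, 3.0], (50, 1)) + 0.05 * np.sin(
            np.arange(50)
        ).reshape(-1, 1)
        with pytest.raises(NoMovementError):
            kin.detect_reach_phase(_curves_from_wrist(pos))

    def test_planted_onset_frame(self):
        n = 100
        pos = np.zeros((n, 3))
        pos[37:, 0] = 0.5 * np.arange(1, n - 36)  # 0.5 mm steps into frame 37
        curves = _curves_from_wrist(pos)
        onset, _ = kin.detect_reach_phase(curves)
        disp = np.diff(np.column_stack([curves.rx, curves.ry, curves.rz]), axis=0)
        assert onset == oracle_onset(disp, 0.3, 3) == 37

    def test_two_frame_spike_rejected(self):
        n = 120
        pos = np.zeros((n, 3))
        pos[20, 1] = 0.8
        pos[21, 1] = 1.6
        pos[22:, 1] = 1.6  # spike of 2 supra-threshold frames only
        pos[60:, 2] = 0.6 * np.arange(1, n - 59)
        onset, _ = kin.detect_reach_phase(_curves_from_wrist(pos))
        assert onset == 60

    def test_end_candidate_nearest_grasp_end(self):
        n = 150
        pos = np.zeros((n, 3))
        pos[10:80, 0] = np.cumsum(np.full(70, 1.0))  # x moves frames 10..79
        pos[80:, 0] = pos[79, 0]
        pos[10:120, 2] = np.cumsum(np.full(110, 0.8))  # z moves until 119
        pos[120:, 2] = pos[119, 2]
        curves = _curves_from_wrist(pos)
        _, end_near_80 = kin.detect_reach_phase(curves, grasp_end=82)
        _, end_near_120 = kin.detect_reach_phase(curves, grasp_end=118)
        assert abs(end_near_80 - 80) <= 1
        assert abs(end_near_120 - 120) <= 1


class TestDetectGraspPhase:
    def test_constant_aperture_raises(self):
        curves = _curves_from_wrist(np.zeros((50, 3)))
        with pytest.raises(NoGraspError):
            kin.detect_grasp_phase(curves)

    def test_open_close_plateau_end(self):
        n = 120
        ga = np.full(n, 10.0)
        ga[20:50] = 10 + 2.0 * np.arange(1, 31)  # opens into frame 20
        ga[50:80] = 70 - 0.6 * np.arange(1, 31)  # closes
        ga[80:] = ga[79]  # plateau from frame 80
        curves = _curves_from_wrist(np.zeros((n, 3)))
        object.__setattr__(curves, "ga", ga)
        onset, max_ap, end = kin.detect_grasp_phase(curves)
        assert onset == 20
        assert max_ap == 49
        assert end == 80

    def test_noise_free_synthetic_matches_ground_truth(self, clean_trials):
        trials, truths = clean_trials
        for trial, truth in zip(trials, truths):
            curves = kin.compute_curves(trial)
            seg = kin.segment_trial(curves)
            assert seg.reach_onset == truth.segmentation.reach_onset
            assert seg.reach_end == truth.segmentation.reach_end
            assert seg.grasp_onset == truth.segmentation.grasp_onset
            assert seg.max_aperture_frame == truth.segmentation.max_aperture_frame
            assert seg.grasp_end == truth.segmentation.grasp_end


class TestExtractFeatures:
    def test_triangular_aperture_constructed_case(self):
        n, fs = 121, 120.0
        ga = np.concatenate([np.linspace(0, 60, 41), np.linspace(60, 0, 81)[1:]])
        pos = np.zeros((n, 3))
        curves = _curves_from_wrist(pos, fs)
        object.__setattr__(curves, "ga", ga)
        seg = kin.PhaseSegmentation(
            reach_onset=0,
            reach_end=100,
            grasp_onset=0,
            max_aperture_frame=40,
            grasp_end=120,
            contact_frame=120,
        )
        feats = kin.extract_features(curves, seg)
        assert feats["GRange"] == pytest.approx(60.0)
        assert feats["GTotDur"] == pytest.approx(120 / fs * 1000)
        assert feats["GOpenDur"] == pytest.approx(40 / fs * 1000)
        assert feats["GCloseDur"] == pytest.approx(80 / fs * 1000)

    def test_hand_position_is_mean_of_finger_heights(self):
        n = 40
        wrist = np.zeros((n, 3))
        wrist[10:30, 0] = np.cumsum(np.full(20, 2.0))
        wrist[30:, 0] = wrist[29, 0]
        thumb = np.tile([0.0, 30.0, 0.0], (n, 1))
        index = np.tile([60.0, 50.0, 0.0], (n, 1))
        curves = kin.compute_curves(_make_trial(wrist, thumb, index))
        seg = kin.PhaseSegmentation(10, 30, 5, 20, 35, 35)
        feats = kin.extract_features(curves, seg)
        assert feats["HandPos"] == pytest.approx(40.0)

    def test_feature_name_contract(self, clean_trials):
        trials, _ = clean_trials
        _, _, feats = kin.analyze_trial(trials[0])
        assert tuple(feats) == kin.FEATURE_NAMES
        assert len(feats) == 17
        curves = kin.compute_curves(trials[0])
        seg = kin.segment_trial(curves)
        extras = kin.extract_features(curves, seg, include_extras=True)
        assert set(kin.EXTRA_FEATURE_NAMES) <= set(extras)


class TestInvariants:
    def test_rigid_translation(self, clean_trials):
        trials, _ = clean_trials
        base = trials[0]
        shift = np.array([123.0, -45.0, 67.0])
        moved = kin.MarkerTrial(
            "t", base.sampling_rate, base.wrist + shift, base.thumb + shift,
            base.index + shift,
        )
        _, seg0, f0 = kin.analyze_trial(base)
        _, seg1, f1 = kin.analyze_trial(moved)
        assert (seg0.reach_onset, seg0.grasp_end) == (seg1.reach_onset, seg1.grasp_end)
        assert f1["HandPos"] - f0["HandPos"] == pytest.approx(shift[1], abs=1e-9)
        for k in ("GRange", "RTotDur", "RPSpeed"):
            assert f1[k] == pytest.approx(f0[k], rel=1e-9)

    def test_time_rescaling_scales_durations_and_speeds(self, clean_trials):
        # stretch a trial in time by k, resampled at the same rate
        k = 1.1
        base = clean_trials[0][1]
        n = base.n_frames
        n2 = int(round(k * (n - 1))) + 1
        src, dst = np.arange(n), np.linspace(0, n - 1, n2)

        def stretch(a):
            return np.column_stack([np.interp(dst, src, a[:, j]) for j in range(3)])

        slow = kin.MarkerTrial(
            "r", base.sampling_rate, stretch(base.wrist), stretch(base.thumb),
            stretch(base.index),
        )
        _, _, f0 = kin.analyze_trial(base)
        _, _, f1 = kin.analyze_trial(slow)
        assert f1["RTotDur"] / f0["RTotDur"] == pytest.approx(k, rel=0.02)
        assert f1["GTotDur"] / f0["GTotDur"] == pytest.approx(k, rel=0.02)
        assert f1["RPSpeed"] / f0["RPSpeed"] == pytest.approx(1 / k, rel=0.02)
        assert f1["GOpenPVel"] / f0["GOpenPVel"] == pytest.approx(1 / k, rel=0.02)

    def test_grange_is_max_aperture_over_grasp_window(self, noisy_trials):
        trials, _ = noisy_trials
        for trial in trials[:10]:
            curves = kin.compute_curves(trial)
            seg = kin.segment_trial(curves)
            feats = kin.extract_features(curves, seg)
            assert feats["GRange"] == np.max(
                curves.ga[seg.grasp_onset : seg.grasp_end + 1]
            )
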