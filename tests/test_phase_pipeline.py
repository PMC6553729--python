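import dataclasses

import numpy as np
import pytest

from gaitsync import (
    Drift,
    GaitParams,
    SegmentRejected,
    analyze_frames,
    clean_series,
    detrend_ankle,
    generate_pair_scene,
    hilbert_phase,
    lowpass,
    relative_phase,
    walking_frequency,
    wrap_angle,
)
from gaitsync.skeleton import LEFT_ANKLE, N_PARTS, NECK, NOSE, RIGHT_ANKLE
from gaitsync.tracking import TrackedSegment


def manual_tracked(y_by_part: dict, n: int = 10, fps: float = 30.0) -> TrackedSegment:
    """Two identical walkers with hand-set part ordinates (per-frame constant)."""
    xy = np.full((2, n, N_PARTS, 2), np.nan)
    for part, y in y_by_part.items():
        xy[:, :, part, 0] = 50.0
        xy[:, :, part, 1] = y
    return TrackedSegment(
        xy=xy, fps=fps, frame_indices=np.arange(n), assigned_person=np.zeros((2, n), dtype=int)
    )


class TestDetrend:
    def test_neck_referenced_height_normalized_value(self):
        # top at 100, ankles at 300 -> l = 200; (300 - 100)/200 = 1.0
        tracked = manual_tracked({NOSE: 100.0, NECK: 100.0, LEFT_ANKLE: 300.0, RIGHT_ANKLE: 300.0})
        a1, _ = detrend_ankle(tracked)
        np.testing.assert_allclose(a1.y_left, 1.0)
        np.testing.assert_allclose(a1.y_right, 1.0)

    def test_translation_invariance(self):
        tracked = manual_tracked({NOSE: 100.0, NECK: 130.0, LEFT_ANKLE: 290.0, RIGHT_ANKLE: 310.0})
        shifted = dataclasses.replace(tracked, xy=tracked.xy + 50.0)
        a, _ = detrend_ankle(tracked)
        b, _ = detrend_ankle(shifted)
        np.testing.assert_allclose(b.y_left, a.y_left)
        np.testing.assert_allclose(b.y_right, a.y_right)

    def test_uniform_scaling_invariance(self):
        tracked = manual_tracked({NOSE: 100.0, NECK: 130.0, LEFT_ANKLE: 290.0, RIGHT_ANKLE: 310.0})
        scaled = dataclasses.replace(tracked, xy=tracked.xy * 3.0)
        a, _ = detrend_ankle(tracked)
        b, _ = detrend_ankle(scaled)
        np.testing.assert_allclose(b.y_left, a.y_left)

    def test_camera_drift_cancels_against_no_drift_scene(self):
        from gaitsync import track_pair

        base = GaitParams(step_frequency=1.8, seed=4)
        drifted = dataclasses.replace(base, drift=Drift("linear", 20.0))
        t0 = track_pair(generate_pair_scene(base)[0], (0, 1), fps=base.fps)
        t1 = track_pair(generate_pair_scene(drifted)[0], (0, 1), fps=base.fps)
        a0, _ = detrend_ankle(t0)
        a1, _ = detrend_ankle(t1)
        np.testing.assert_allclose(a1.y_left, a0.y_left, atol=1e-9)
        np.testing.assert_allclose(a1.y_right, a0.y_right, atol=1e-9)

    def test_bad_length_frame_becomes_nan(self):
        tracked = manual_tracked({NOSE: 100.0, NECK: 130.0, LEFT_ANKLE: 290.0, RIGHT_ANKLE: 310.0})
        tracked.xy[0, 3, :, :] = np.nan  # walker 1 fully unmatched in frame 3
        a, _ = detrend_ankle(tracked)
        assert np.isnan(a.y_left[3])
        assert np.isfinite(np.delete(a.y_left, 3)).all()


class TestCleanSeries:
    def test_missing_value_linearly_interpolated(self):
        z, info = clean_series(np.array([1.0, np.nan, 3.0]))
        # middle sample is 2 before normalization -> equals the mean -> 0 after
        assert z[1] == pytest.approx(0.0)
        assert list(info["interpolated"]) == [False, True, False]

    def test_spike_replaced_and_moments_restored(self):
        rng = np.random.default_rng(0)
        t = np.arange(300) / 30.0
        x = np.sin(2 * np.pi * 0.9 * t)
        x[150] = 5.0 * x.std()
        z, info = clean_series(x)
        assert info["outlier_replaced"][150]
        assert z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.std() == pytest.approx(1.0, abs=1e-9)
        assert abs(z[150]) < 2.0

    def test_idempotent_on_clean_normalized_series(self):
        t = np.arange(200) / 30.0
        x = np.sin(2 * np.pi * 0.9 * t)
        x = (x - x.mean()) / x.std()
        z, info = clean_series(x)
        assert not info["outlier_replaced"].any()
        np.testing.assert_allclose(z, x, atol=1e-9)

    def test_constant_series_rejected(self):
        with pytest.raises(SegmentRejected, match="constant"):
            clean_series(np.ones(50))

    def test_all_missing_rejected(self):
        with pytest.raises(SegmentRejected):
            clean_series(np.array([np.nan, np.nan, 1.0]))


class TestLowpass:
    def test_in_band_sine_preserved(self):
        t = np.arange(600) / 30.0
        x = np.sin(2 * np.pi * 1.0 * t)
        y = lowpass(x, 30.0)
        assert np.abs(y[100:-100]).max() == pytest.approx(1.0, rel=0.02)

    def test_out_of_band_sine_attenuated(self):
        """6 Hz is 3x the 2 Hz cutoff: squared 3rd-order Butterworth magnitude
        (forward-backward) leaves well under 10% of the amplitude."""
        t = np.arange(600) / 30.0
        x = np.sin(2 * np.pi * 6.0 * t)
        y = lowpass(x, 30.0)
        assert np.abs(y[100:-100]).max() < 0.1

    def test_constant_series_unchanged(self):
        np.testing.assert_allclose(lowpass(np.full(100, 3.7), 30.0), 3.7, atol=1e-9)

    def test_nyquist_violation_raises(self):
        with pytest.raises(ValueError, match="resample"):
            lowpass(np.zeros(100), 4.0)


class TestHilbertPhase:
    def test_cosine_phase_advances_linearly(self):
        t = np.arange(300) / 30.0
        p = hilbert_phase(np.cos(2 * np.pi * 1.0 * t))
        expected = wrap_angle(2 * np.pi * 1.0 * t)
        err = np.abs(wrap_angle(p[30:-30] - expected[30:-30]))
        assert err.max() < 0.05

    def test_identical_signals_zero_phase_difference(self):
        t = np.arange(300) / 30.0
        d = np.sin(2 * np.pi * 0.9 * t)
        np.testing.assert_allclose(relative_phase(hilbert_phase(d), hilbert_phase(d)), 0.0)

    def test_negated_signal_shifts_phase_by_pi(self):
        t = np.arange(300) / 30.0
        d = np.sin(2 * np.pi * 0.9 * t)
        dphi = np.abs(relative_phase(hilbert_phase(d), hilbert_phase(-d)))
        np.testing.assert_allclose(dphi[30:-30], np.pi, atol=1e-6)

    def test_all_zero_rejected(self):
        with pytest.raises(SegmentRejected):
            hilbert_phase(np.zeros(100))


class TestRelativePhase:
    def test_wraps_to_half_open_interval(self):
        assert relative_phase(np.array([3 * np.pi / 2]), np.array([0.0]))[0] == pytest.approx(-np.pi / 2)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            relative_phase(np.zeros(5), np.zeros(6))


class TestWalkingFrequency:
    def test_doubling_rule_exact_on_pure_sine(self):
        t = np.arange(150) / 30.0
        est = walking_frequency(np.sin(2 * np.pi * 0.9 * t), 30.0)
        assert est.steps_per_s == pytest.approx(1.8, abs=1e-9)
        assert est.confident

    def test_cadence_two_recovered_within_bin(self):
        params = GaitParams(step_frequency=2.0, duration=10.0, seed=1)
        frames, _ = generate_pair_scene(params)
        res, _ = analyze_frames(frames, params.fps)
        assert res.cadence1.steps_per_s == pytest.approx(2.0, abs=0.02)

    def test_white_noise_flagged_low_confidence(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            est = walking_frequency(rng.normal(size=150), 30.0)
            assert not est.confident

    def test_short_segment_flagged(self):
        t = np.arange(30) / 30.0  # one second: under 2 cycles at 0.9 Hz
        est = walking_frequency(np.sin(2 * np.pi * 0.9 * t), 30.0)
        assert not est.confident


class TestAnalyzeSegment:
    def test_in_phase_pair_mean_near_zero(self):
        params = GaitParams(relative_phase=0.0, step_frequency=1.8, seed=2)
        frames, _ = generate_pair_scene(params)
        res, _ = analyze_frames(frames, params.fps)
        assert abs(wrap_angle(res.mean_rel_phase)) < 1e-3

    def test_anti_phase_pair_mean_at_pi(self):
        params = GaitParams(relative_phase=np.pi, step_frequency=1.8, seed=2)
        frames, _ = generate_pair_scene(params)
        res, _ = analyze_frames(frames, params.fps)
        assert abs(wrap_angle(res.mean_rel_phase - np.pi)) < 1e-3

    def test_noise_free_phase_locking_variance_tiny(self):
        for dphi in (0.0, np.pi / 2, 2.0):
            params = GaitParams(relative_phase=dphi, step_frequency=1.8, seed=6)
            frames, _ = generate_pair_scene(params)
            res, _ = analyze_frames(frames, params.fps)
            assert res.rel_phase_variance < 0.01

    def test_walker_swap_negates_mean_phase(self):
        params = GaitParams(relative_phase=np.pi / 2, step_frequency=1.8, noise_sd=0.75, seed=8)
        frames, _ = generate_pair_scene(params)
        from gaitsync import analyze_segment, track_pair

        tracked = track_pair(frames, (0, 1), fps=params.fps)
        res = analyze_segment(tracked)
        swapped = dataclasses.replace(
            tracked, xy=tracked.xy[::-1].copy(), assigned_person=tracked.assigned_person[::-1].copy()
        )
        res_swapped = analyze_segment(swapped)
        assert abs(wrap_angle(res_swapped.mean_rel_phase + res.mean_rel_phase)) < 1e-6

    def test_swapping_both_walkers_ankle_labels_preserves_mean_phase(self):
        params = GaitParams(relative_phase=np.pi / 2, step_frequency=1.8, noise_sd=0.75, seed=8)
        frames, _ = generate_pair_scene(params)
        from gaitsync import analyze_segment, track_pair

        tracked = track_pair(frames, (0, 1), fps=params.fps)
        res = analyze_segment(tracked)
        xy = tracked.xy.copy()
        xy[:, :, [LEFT_ANKLE, RIGHT_ANKLE]] = xy[:, :, [RIGHT_ANKLE, LEFT_ANKLE]]
        res_flipped = analyze_segment(dataclasses.replace(tracked, xy=xy))
        assert abs(wrap_angle(res_flipped.mean_rel_phase - res.mean_rel_phase)) < 1e-6

    def test_too_short_segment_rejected(self):
        params = GaitParams(duration=1.0, step_frequency=1.8, seed=0)
        frames, _ = generate_pair_scene(params)
        with pytest.raises(SegmentRejected, match="duration"):
            analyze_frames(frames, params.fps)

    def test_quality_reports_interpolation_fraction(self):
        params = GaitParams(missing_prob=0.05, step_frequency=1.8, seed=3)
        frames, _ = generate_pair_scene(params)
        res, _ = analyze_frames(frames, params.fps)
        assert 0.0 < res.quality["frac_interpolated"] < 0.2


class TestParameterRecovery:
    @pytest.mark.parametrize("cadence", [1.4, 1.8, 2.2])
    @pytest.mark.parametrize("dphi", [0.0, np.pi / 2, -np.pi / 2, np.pi])
    def test_grid_recovery_under_noise(self, cadence, dphi):
        """5% keypoint noise, 20 seeds: circular RMSE of the mean relative
        phase stays under 0.2 rad and cadence RMSE under 0.05 steps/s."""
        phase_errs, cad_errs = [], []
        for seed in range(20):
            params = GaitParams(
                relative_phase=dphi, step_frequency=cadence, noise_sd=0.75, seed=1000 + seed
            )
            frames, truth = generate_pair_scene(params)
            res, _ = analyze_frames(frames, params.fps)
            phase_errs.append(wrap_angle(res.mean_rel_phase - truth.true_relative_phase))
            cad_errs += [res.cadence1.steps_per_s - cadence, res.cadence2.steps_per_s - cadence]
        assert np.sqrt(np.mean(np.square(phase_errs))) < 0.2
        assert np.sqrt(np.mean(np.square(cad_errs))) < 0.05
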