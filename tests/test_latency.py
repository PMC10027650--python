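"""Latency estimation: preprocessing, frame-shift search, end-to-end harness."""

import numpy as np
import pytest

from mirrorkit import (
    calibrate_end_to_end,
    estimate_frame_shift,
    frames_to_ms,
    preprocess_track,
)
from mirrorkit.latency import PoseTrack


def _fft_circular_shift_oracle(ref, mim, period_frames):
    """Independent oracle: circular cross-correlation via FFT, argmax over
    lags restricted to one period."""
    n = ref.size
    fr = np.fft.rfft(ref - ref.mean(), n)
    fm = np.fft.rfft(mim - mim.mean(), n)
    xcorr = np.fft.irfft(np.conj(fr) * fm, n)
    return int(np.argmax(xcorr[:period_frames]))


class TestPreprocess:
    def test_z_transform_yields_zero_mean_unit_sd(self, calibration_yaw):
        out = preprocess_track(PoseTrack(120, calibration_yaw), smooth_window=1)
        assert out.samples.mean() == pytest.approx(0.0, abs=1e-9)
        assert out.samples.std() == pytest.approx(1.0, abs=1e-9)

    def test_smoothing_is_centered_moving_average(self):
        impulse = np.zeros(51)
        impulse[25] = 1.0
        track = PoseTrack(120, impulse)
        out = preprocess_track(track, smooth_window=5)
        z = (impulse - impulse.mean()) / impulse.std()
        expected = np.convolve(z, np.ones(5) / 5, mode="same")  # direct oracle
        np.testing.assert_allclose(out.samples, expected, atol=1e-12)
        # the impulse spreads into 5 equal consecutive values
        peak = out.samples[23:28]
        assert np.allclose(peak, peak[0])

    def test_constant_track_cannot_be_standardized(self):
        with pytest.raises(ValueError):
            preprocess_track(PoseTrack(120, np.full(100, 3.0)))


class TestFrameShift:
    def test_identical_tracks_give_zero_shift(self, calibration_track):
        est = estimate_frame_shift(calibration_track, calibration_track, 2.0,
                                   n_sub=50, seed=0)
        assert est.mean_frames == 0.0
        assert est.sd_frames == 0.0

    def test_roll_by_24_frames_recovered_exactly(self, calibration_yaw):
        ref = preprocess_track(PoseTrack(120, calibration_yaw), 5)
        mim = preprocess_track(PoseTrack(120, np.roll(calibration_yaw, 24)), 5)
        est = estimate_frame_shift(ref, mim, 2.0, n_sub=50, seed=1)
        assert est.mean_frames == 24.0
        assert est.sd_frames == 0.0
        oracle = _fft_circular_shift_oracle(ref.samples, mim.samples, 240)
        assert oracle == 24

    @pytest.mark.parametrize("k", [0, 1, 100, 239, 240, 360, 719])
    def test_shift_identifiable_modulo_period(self, calibration_yaw, k):
        ref = preprocess_track(PoseTrack(120, calibration_yaw), 5)
        mim = preprocess_track(PoseTrack(120, np.roll(calibration_yaw, k)), 5)
        est = estimate_frame_shift(ref, mim, 2.0, n_sub=10, seed=2)
        assert est.mean_frames == k % 240
        assert est.sd_frames == 0.0

    def test_noise_robust_within_one_frame(self, calibration_yaw):
        # standardized-scale gaussian noise, a handful of seeded replicates
        ref_z = preprocess_track(PoseTrack(120, calibration_yaw), 1).samples
        mim_z = np.roll(ref_z, 24)
        rng = np.random.default_rng(99)
        for _ in range(10):
            ref = PoseTrack(120, ref_z + 0.1 * rng.standard_normal(ref_z.size))
            mim = PoseTrack(120, mim_z + 0.1 * rng.standard_normal(mim_z.size))
            ref_s = preprocess_track(ref, 5)
            mim_s = preprocess_track(mim, 5)
            est = estimate_frame_shift(ref_s, mim_s, 2.0, n_sub=50,
                                       seed=int(rng.integers(2**31)))
            assert abs(est.mean_frames - 24) <= 1.0

    def test_averaging_reduces_variance_of_the_mean(self, calibration_yaw):
        ref_z = preprocess_track(PoseTrack(120, calibration_yaw), 1).samples
        mim_z = np.roll(ref_z, 24)
        rng = np.random.default_rng(7)
        means, singles = [], []
        for _ in range(20):
            ref = preprocess_track(
                PoseTrack(120, ref_z + 1.0 * rng.standard_normal(ref_z.size)), 5)
            mim = preprocess_track(
                PoseTrack(120, mim_z + 1.0 * rng.standard_normal(mim_z.size)), 5)
            seed = int(rng.integers(2**31))
            est = estimate_frame_shift(ref, mim, 2.0, n_sub=50, seed=seed)
            means.append(est.mean_frames)
            singles.extend(est.shifts)
        assert np.std(singles) > 0  # noise strong enough to perturb single lags
        assert np.std(means) <= np.std(singles)

    def test_mismatched_fps_rejected(self, calibration_track):
        other = PoseTrack(60, calibration_track.samples)
        with pytest.raises(ValueError):
            estimate_frame_shift(calibration_track, other, 2.0)

    def test_short_track_rejected(self):
        short = PoseTrack(120, np.sin(np.arange(100)))
        with pytest.raises(ValueError):
            estimate_frame_shift(short, short, 2.0)


class TestFramesToMs:
    @pytest.mark.parametrize(
        "frames,fps,expected",
        [(0, 120, 0.0), (24, 120, 200.0), (19.3, 120, 160.83)],
    )
    def test_conversion(self, frames, fps, expected):
        assert frames_to_ms(frames, fps) == pytest.approx(expected, abs=0.01)

    def test_estimate_scales_with_fps(self, calibration_script):
        # doubling fps leaves the ms estimate within one frame interval
        from mirrorkit import sample_states

        results = {}
        for fps in (60, 120):
            samples = sample_states(calibration_script, fps, int(30 * fps))
            yaw = np.array([s.state.pose.ry for s in samples])
            shift_frames = int(round(0.2 * fps))  # 200 ms in frames
            ref = preprocess_track(PoseTrack(fps, yaw), 5)
            mim = preprocess_track(PoseTrack(fps, np.roll(yaw, shift_frames)), 5)
            est = estimate_frame_shift(ref, mim, 2.0, n_sub=20, seed=3)
            results[fps] = frames_to_ms(est.mean_frames, fps)
        assert abs(results[60] - results[120]) <= 1000 / 60


class TestEndToEndHarness:
    def test_injected_delay_recovered_within_one_frame(self):
        report = calibrate_end_to_end(
            "synth_source fps=120\ntracker_stub\ndelay delay_ms=200\nsink",
            duration_s=15, fps=120, seed=5, n_sub=20,
        )
        assert report.end_to_end_ms == pytest.approx(200.0, abs=1000 / 120)

    def test_zero_delay_passthrough_below_one_frame(self):
        report = calibrate_end_to_end(
            "synth_source fps=120\ntracker_stub\nsink",
            duration_s=15, fps=120, seed=5, n_sub=20,
        )
        assert report.end_to_end_ms <= 1000 / 120

    def test_report_invariant_ms_equals_shift_over_fps(self):
        report = calibrate_end_to_end(
            "synth_source fps=120\ndelay delay_ms=100\nsink",
            duration_s=15, fps=120, seed=5, n_sub=20,
        )
        assert report.end_to_end_ms == pytest.approx(
            report.shift.mean_frames * 1000 / 120
        )
        assert report.n_subsequences == 20

    def test_duration_too_short_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            calibrate_end_to_end("synth_source fps=120\nsink", duration_s=3, fps=120)
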