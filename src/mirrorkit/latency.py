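"""End-to-end latency estimation by sub-sequence cross-correlation.

The measurement principle: a video of a stimulus face performing a periodic
abrupt head turn (frontal 1.5 s, then 25 degrees yaw for 0.5 s) is replayed
in front of the mirror while the mirror's avatar imitates it; both yaw
tracks are recorded at a known frame rate.  The latency is the frame shift
between the two tracks, converted to milliseconds.

Estimation exploits the periodicity of the stimulus: the tracks are
z-transformed and smoothed, N sub-sequences of 1.5x the motion period
(3 s for the 2 s stimulus) are sampled from the reference track, and for
each sub-sequence the integer lag in ``[0, period)`` maximising the Pearson
correlation with the lag-shifted mimic track is recorded.  The mean over
sub-sequences is the frame-shift estimate; its SD quantifies precision.
Shifts are therefore reported modulo the period (minimal non-negative
representative), which is the identifiable quantity for a periodic
stimulus.

The simulated end-to-end harness in :func:`calibrate_end_to_end` covers
software delay only (tracker-to-render path under a simulated clock);
hardware contributions such as camera exposure and display response are
physical-device properties outside any simulation's reach, and a report
from this harness must be read as the software share of latency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .clock import SimulatedClock
from .face import MotionScript, make_calibration_script
from .pipeline import Pipeline, PipelineSpec, RunReport, module_timing, parse_pipeline_spec


@dataclass(frozen=True)
class PoseTrack:
    """A sampled yaw-angle time series at a known frame rate."""

    fps: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("track needs at least 2 samples")


@dataclass(frozen=True)
class ShiftEstimate:
    """Frame-shift estimate over sampled sub-sequences."""

    mean_frames: float
    sd_frames: float
    shifts: tuple[int, ...]

    @property
    def n_subsequences(self) -> int:
        return len(self.shifts)


@dataclass
class LatencyReport:
    """Per-module and end-to-end latency summary.

    Invariant: ``end_to_end_ms == mean(shifts) * 1000 / fps``.
    """

    fps: float
    shift: ShiftEstimate
    end_to_end_ms: float
    end_to_end_sd_ms: float
    module_stats: Optional[pd.DataFrame] = None
    notes: str = "software-only estimate (simulated harness); hardware lag excluded"

    @property
    def n_subsequences(self) -> int:
        return self.shift.n_subsequences


def preprocess_track(track: PoseTrack, smooth_window: int = 5) -> PoseTrack:
    """Standardize (z-transform) a track, then smooth it.

    The z-transform maps the raw track to mean 0, SD 1; smoothing is a
    centered moving average of width ``smooth_window`` frames (a unit
    impulse becomes ``smooth_window`` consecutive values of
    ``1/smooth_window``).  A constant track cannot be standardized and
    raises ``ValueError``.
    """
    x = track.samples
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant track")
    z = (x - x.mean()) / sd
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        z = np.convolve(z, kernel, mode="same")
    return PoseTrack(fps=track.fps, samples=z)


def estimate_frame_shift(
    reference: PoseTrack,
    mimic: PoseTrack,
    period_s: float,
    n_sub: int = 50,
    factor: float = 1.5,
    seed: int = 0,
) -> ShiftEstimate:
    """Estimate the integer frame shift between two periodic tracks.

    ``n_sub`` sub-sequence start frames are drawn uniformly without
    replacement from the admissible range; for each, the integer lag in
    ``[0, period_frames)`` maximising the Pearson correlation between the
    reference sub-sequence and the lag-shifted mimic window is recorded
    (ties broken toward the smallest lag).  Returns mean, population SD,
    and the individual lags.
    """
    if reference.fps != mimic.fps:
        raise ValueError("reference and mimic tracks must share the same fps")
    fps = reference.fps
    period_frames = int(round(period_s * fps))
    if period_frames < 2:
        raise ValueError("period too short at this fps")
    sub_len = int(round(factor * period_s * fps))
    n = min(reference.samples.size, mimic.samples.size)
    max_start = n - sub_len - (period_frames - 1)
    if sub_len > n or max_start < 1:
        raise ValueError(
            f"tracks too short: need at least {sub_len + period_frames} frames, "
            f"have {n}"
        )
    rng = np.random.default_rng(seed)
    n_starts = min(n_sub, max_start)
    starts = np.sort(rng.choice(max_start, size=n_starts, replace=False))

    ref = reference.samples
    mim = mimic.samples
    shifts = np.empty(n_starts, dtype=int)
    for i, s in enumerate(starts):
        ref_w = ref[s : s + sub_len]
        ref_c = ref_w - ref_w.mean()
        ref_norm = np.sqrt((ref_c**2).sum())
        windows = np.lib.stride_tricks.sliding_window_view(
            mim[s : s + sub_len + period_frames - 1], sub_len
        )  # (period_frames, sub_len)
        wc = windows - windows.mean(axis=1, keepdims=True)
        w_norm = np.sqrt((wc**2).sum(axis=1))
        denom = ref_norm * w_norm
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = (wc @ ref_c) / denom
        corr[denom == 0] = -np.inf
        shifts[i] = int(np.argmax(corr))  # first max -> smallest lag on ties
    return ShiftEstimate(
        mean_frames=float(shifts.mean()),
        sd_frames=float(shifts.std(ddof=0)),
        shifts=tuple(int(v) for v in shifts),
    )


def frames_to_ms(shift_frames: float, fps: float) -> float:
    """Convert a frame shift to milliseconds: ``shift * 1000 / fps``."""
    if fps <= 0:
        raise ValueError("fps must be > 0")
    return shift_frames * 1000.0 / fps


def tracks_from_csv(reference_path, mimic_path, fps: float) -> tuple[PoseTrack, PoseTrack]:
    """Load two recorded track CSVs (offline analysis of real recordings)
    and extract their yaw series as :class:`PoseTrack` objects."""
    from .face import read_track

    ref = read_track(reference_path)
    mim = read_track(mimic_path)
    return (
        PoseTrack(fps=fps, samples=np.array([s.state.pose.ry for s in ref])),
        PoseTrack(fps=fps, samples=np.array([s.state.pose.ry for s in mim])),
    )


def calibrate_end_to_end(
    spec: PipelineSpec | str,
    stimulus_script: Optional[MotionScript] = None,
    duration_s: float = 30.0,
    fps: float = 120.0,
    seed: int = 0,
    n_sub: int = 50,
    factor: float = 1.5,
    smooth_window: int = 5,
) -> LatencyReport:
    """Measure a pipeline's software end-to-end latency with a simulated
    recorder.

    The stimulus script (default: the periodic calibration head turn) is
    driven through the pipeline frame by frame under a simulated clock; a
    virtual second camera samples the stimulus yaw and the pipeline's output
    yaw at ``fps``.  Both tracks are z-transformed and smoothed, the frame
    shift is estimated over ``n_sub`` sub-sequences, and the result is
    converted to milliseconds.  A pipeline containing a ``delay`` module
    therefore serves as a self-test with known injected latency.
    """
    if isinstance(spec, str):
        spec = parse_pipeline_spec(spec)
    if stimulus_script is None:
        stimulus_script = make_calibration_script()
    period_s = stimulus_script.period_s
    n_frames = int(round(duration_s * fps))
    needed = int(round(factor * period_s * fps)) + int(round(period_s * fps))
    if n_frames < needed + 1:
        raise ValueError(
            f"duration too short: need > {needed} frames at {fps} fps "
            f"({(needed + 1) / fps:.2f} s), got {n_frames}"
        )

    clock = SimulatedClock()
    pipeline = Pipeline(spec, clock=clock, seed=seed)
    pipeline.source.fps = fps
    pipeline.source.set_script(stimulus_script)

    stim_yaw = np.empty(n_frames)
    mimic_yaw = np.empty(n_frames)

    def record(msg):
        i = msg.frame_id
        stim_yaw[i] = stimulus_script.state_at(msg.capture_time_ms / 1000.0).pose.ry
        mimic_yaw[i] = msg.data.get("pose.ry", 0.0)

    report: RunReport = pipeline.run_stepped(n_frames, on_frame=record)
    if not report.ok:
        raise RuntimeError(f"pipeline failed in module {report.failed_module!r}")

    ref = preprocess_track(PoseTrack(fps=fps, samples=stim_yaw), smooth_window)
    mim = preprocess_track(PoseTrack(fps=fps, samples=mimic_yaw), smooth_window)
    shift = estimate_frame_shift(ref, mim, period_s, n_sub=n_sub, factor=factor, seed=seed)
    stats = module_timing(report) if report.delivered else None
    return LatencyReport(
        fps=fps,
        shift=shift,
        end_to_end_ms=frames_to_ms(shift.mean_frames, fps),
        end_to_end_sd_ms=frames_to_ms(shift.sd_frames, fps),
        module_stats=stats,
    )
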