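"""Face-state domain model and synthetic motion source.

A *face state* is what the tracker of a virtual mirror produces per frame:
a six-degree-of-freedom head pose plus continuous FACS action-unit (AU)
intensities, with a validity flag and a tracking confidence.  This module
defines those types, deterministic piecewise motion scripts that stand in
for a webcam + markerless tracker (including the periodic head-turn stimulus
used for latency calibration and the near-neutral "rest" sequence replayed
in the baseline condition), a seeded sampler that turns a script into a
timestamped stream, and CSV round-trip I/O for recorded tracks.

Conventions
-----------
* Translations ``tx, ty, tz`` are millimetres in the camera frame.
* Rotations ``rx`` (pitch), ``ry`` (yaw), ``rz`` (roll) are degrees,
  intrinsic pitch-yaw-roll order.  Positive yaw is a turn to the subject's
  left, so the calibration stimulus turn is ``ry = +25``.
* AU intensities use the 17-AU continuous set with range [0, 5]; the
  neutral expression is all zeros.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import TrackFormatError

#: The action units tracked as continuous intensities, in canonical order.
AU_LABELS: tuple[str, ...] = (
    "AU01", "AU02", "AU04", "AU05", "AU06", "AU07", "AU09", "AU10", "AU12",
    "AU14", "AU15", "AU17", "AU20", "AU23", "AU25", "AU26", "AU45",
)
N_AU = len(AU_LABELS)
AU_MIN, AU_MAX = 0.0, 5.0

POSE_FIELDS: tuple[str, ...] = ("tx", "ty", "tz", "rx", "ry", "rz")

#: Columns of the track CSV schema, in order.
TRACK_COLUMNS: tuple[str, ...] = (
    ("frame", "capture_time_ms") + POSE_FIELDS + AU_LABELS + ("valid", "confidence")
)


@dataclass(frozen=True)
class HeadPose:
    """Rigid head pose: translation in mm, rotation in degrees."""

    tx: float = 0.0
    ty: float = 0.0
    tz: float = 0.0
    rx: float = 0.0  # pitch
    ry: float = 0.0  # yaw; + = subject's left
    rz: float = 0.0  # roll

    def as_array(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.tz, self.rx, self.ry, self.rz])

    @classmethod
    def from_array(cls, a: Sequence[float]) -> "HeadPose":
        return cls(*(float(v) for v in a))

    @classmethod
    def neutral(cls) -> "HeadPose":
        return cls()


class ExpressionState:
    """Per-AU intensities, clamped to [0, 5] on construction.

    Stored as a dense float vector in :data:`AU_LABELS` order.  Instances
    are treated as immutable by convention; manipulators build new ones.
    """

    __slots__ = ("au",)

    def __init__(self, au: Sequence[float] | np.ndarray | None = None) -> None:
        if au is None:
            vec = np.zeros(N_AU)
        else:
            vec = np.asarray(au, dtype=float)
            if vec.shape != (N_AU,):
                raise ValueError(f"expected {N_AU} AU intensities, got {vec.shape}")
            vec = np.clip(vec, AU_MIN, AU_MAX)
        self.au = vec

    @classmethod
    def neutral(cls) -> "ExpressionState":
        return cls()

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ExpressionState":
        vec = np.zeros(N_AU)
        for i, label in enumerate(AU_LABELS):
            if label in d:
                vec[i] = d[label]
        return cls(vec)

    def __getitem__(self, label: str) -> float:
        return float(self.au[AU_LABELS.index(label)])

    def with_au(self, label: str, value: float) -> "ExpressionState":
        vec = self.au.copy()
        vec[AU_LABELS.index(label)] = value
        return ExpressionState(vec)

    def as_dict(self) -> dict[str, float]:
        return {label: float(v) for label, v in zip(AU_LABELS, self.au)}

    def is_neutral(self, atol: float = 0.0) -> bool:
        return bool(np.all(np.abs(self.au) <= atol))

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        active = {k: round(v, 3) for k, v in self.as_dict().items() if v != 0.0}
        return f"ExpressionState({active})"


@dataclass(frozen=True)
class FaceState:
    """The tracked quantity: pose + expression + tracking status."""

    pose: HeadPose = field(default_factory=HeadPose)
    expression: ExpressionState = field(default_factory=ExpressionState)
    valid: bool = True
    confidence: float = 1.0

    @classmethod
    def neutral(cls) -> "FaceState":
        return cls()

    def as_vector(self) -> np.ndarray:
        """Pose (6) followed by AU intensities (17)."""
        return np.concatenate([self.pose.as_array(), self.expression.au])


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics carried alongside messages (populated from config)."""

    fx: float
    fy: float
    cx: float
    cy: float
    width: int = 640
    height: int = 480

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError("principal point must lie inside the image")


# ---------------------------------------------------------------------------
# Motion scripts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Segment:
    """One piece of a motion script.

    ``hold`` segments sit at the target for the whole duration; ``linear``
    segments interpolate from the previous segment's target to this one's.
    """

    duration_s: float
    pose: HeadPose = field(default_factory=HeadPose)
    expression: ExpressionState = field(default_factory=ExpressionState)
    transition: str = "hold"

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("segment duration must be > 0")
        if self.transition not in ("hold", "linear"):
            raise ValueError(f"unknown transition {self.transition!r}")


@dataclass(frozen=True)
class MotionScript:
    """Deterministic piecewise head/expression motion.

    For a looped script the motion repeats with period equal to the sum of
    segment durations; sampling an unlooped script past its end holds the
    final segment target.
    """

    segments: tuple[Segment, ...]
    loop: bool = True

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("script needs at least one segment")

    @property
    def period_s(self) -> float:
        return float(sum(s.duration_s for s in self.segments))

    def state_at(self, t_s: float) -> FaceState:
        """Face state at time ``t_s`` seconds from script start."""
        period = self.period_s
        if self.loop:
            t = t_s % period
        else:
            if t_s >= period:
                last = self.segments[-1]
                return FaceState(pose=last.pose, expression=last.expression)
            t = max(t_s, 0.0)
        acc = 0.0
        for i, seg in enumerate(self.segments):
            if t < acc + seg.duration_s or i == len(self.segments) - 1:
                if seg.transition == "hold":
                    return FaceState(pose=seg.pose, expression=seg.expression)
                # linear: interpolate from the previous target
                prev = self.segments[i - 1] if i > 0 else (
                    self.segments[-1] if self.loop else seg
                )
                frac = (t - acc) / seg.duration_s
                frac = min(max(frac, 0.0), 1.0)
                pose = HeadPose.from_array(
                    (1 - frac) * prev.pose.as_array() + frac * seg.pose.as_array()
                )
                expr = ExpressionState(
                    (1 - frac) * prev.expression.au + frac * seg.expression.au
                )
                return FaceState(pose=pose, expression=expr)
            acc += seg.duration_s
        raise AssertionError("unreachable")  # pragma: no cover


def make_calibration_script(
    yaw_deg: float = 25.0,
    frontal_hold_s: float = 1.5,
    turned_hold_s: float = 0.5,
) -> MotionScript:
    """The periodic latency-calibration stimulus.

    The stimulus face is shown frontal (hold 1.5 s), then turns its head
    25 degrees to the subject's left (hold 0.5 s), abruptly — no
    interpolation ramp — and the whole cycle repeats.  The recommended
    analysis sub-sequence is 1.5x the 2 s cycle, i.e. 3 s.
    """
    return MotionScript(
        segments=(
            Segment(frontal_hold_s, HeadPose.neutral(), ExpressionState.neutral(), "hold"),
            Segment(turned_hold_s, HeadPose(ry=yaw_deg), ExpressionState.neutral(), "hold"),
        ),
        loop=True,
    )


def recommended_subsequence_s(script: MotionScript, factor: float = 1.5) -> float:
    """Analysis sub-sequence length: ``factor`` times the stimulus period."""
    return factor * script.period_s


def make_rest_script(
    duration_s: float = 30.0,
    breathing_amplitude: float = 2.0,
    breathing_period_s: float = 4.0,
    knots_per_cycle: int = 32,
) -> MotionScript:
    """A face "at rest": near-neutral with subtle periodic breathing motion.

    Emulates the prerecorded rest sequence replayed to the avatar in the
    baseline condition.  Breathing is modelled as a sinusoid traced by
    ``knots_per_cycle`` linear segments per cycle, modulating ``tz`` with
    peak amplitude ``breathing_amplitude`` (mm) and AU25 (lips-part) with
    one tenth of that amplitude in AU units.  Amplitude 0 yields a strictly
    constant neutral script; the head never turns (yaw stays 0).
    """
    if duration_s <= 0:
        raise ValueError("duration must be > 0")
    if breathing_amplitude < 0:
        raise ValueError("breathing amplitude must be >= 0")
    if breathing_period_s <= 0:
        raise ValueError("breathing period must be > 0")
    a_tz = breathing_amplitude
    a_au = min(breathing_amplitude * 0.1, AU_MAX)
    n_cycles = max(1, round(duration_s / breathing_period_s))
    dt = breathing_period_s / knots_per_cycle
    segments = []
    for _ in range(n_cycles):
        for k in range(1, knots_per_cycle + 1):
            phase = 2.0 * math.pi * k / knots_per_cycle
            tz = a_tz * math.sin(phase)
            au25 = a_au * (1.0 - math.cos(phase)) / 2.0
            segments.append(
                Segment(
                    dt,
                    HeadPose(tz=tz),
                    ExpressionState.neutral().with_au("AU25", au25),
                    "linear",
                )
            )
    return MotionScript(segments=tuple(segments), loop=True)


# ---------------------------------------------------------------------------
# Sampling a script into a timestamped stream
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TimedState:
    """A face state with its frame index and capture timestamp."""

    frame: int
    capture_time_ms: float
    state: FaceState


def sample_states(
    script: MotionScript,
    fps: float,
    n_frames: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    au_noise_sd: float | None = None,
) -> list[TimedState]:
    """Sample a motion script at ``fps`` into a timestamped stream.

    Emulates a markerless tracker's output: frame ``t`` has capture time
    ``t * 1000 / fps`` ms on the (simulated) monotonic clock, with optional
    independent Gaussian jitter per channel.  ``noise_sd`` applies to the
    six pose channels; ``au_noise_sd`` (default: same value) to the AU
    channels, which are re-clamped to [0, 5] after jitter.  Deterministic
    for a given seed.
    """
    if fps <= 0:
        raise ValueError("fps must be > 0")
    if n_frames < 1:
        raise ValueError("need at least one frame")
    if au_noise_sd is None:
        au_noise_sd = noise_sd
    rng = np.random.default_rng(seed)
    out: list[TimedState] = []
    for t in range(n_frames):
        t_ms = t * 1000.0 / fps
        state = script.state_at(t_ms / 1000.0)
        if noise_sd > 0 or au_noise_sd > 0:
            pose_vec = state.pose.as_array() + noise_sd * rng.standard_normal(6)
            au_vec = state.expression.au + au_noise_sd * rng.standard_normal(N_AU)
            state = FaceState(
                pose=HeadPose.from_array(pose_vec),
                expression=ExpressionState(au_vec),
                valid=state.valid,
                confidence=state.confidence,
            )
        out.append(TimedState(frame=t, capture_time_ms=t_ms, state=state))
    return out


# ---------------------------------------------------------------------------
# Track CSV I/O
# ---------------------------------------------------------------------------

def track_to_frame(samples: Iterable[TimedState]) -> pd.DataFrame:
    """Convert a sampled stream to a DataFrame in the track CSV schema."""
    rows = []
    for s in samples:
        row = {"frame": s.frame, "capture_time_ms": s.capture_time_ms}
        row.update(dict(zip(POSE_FIELDS, s.state.pose.as_array())))
        row.update(s.state.expression.as_dict())
        row["valid"] = int(s.state.valid)
        row["confidence"] = s.state.confidence
        rows.append(row)
    return pd.DataFrame(rows, columns=list(TRACK_COLUMNS))


def write_track(samples: Sequence[TimedState], path: str | Path | io.TextIOBase) -> None:
    """Write a sampled stream as CSV (schema: ``frame,capture_time_ms,
    tx..rz,AU01..AU45,valid,confidence``; one header line, '.' decimal)."""
    samples = list(samples)
    if not samples:
        raise ValueError("cannot write an empty track")
    df = track_to_frame(samples)
    df.to_csv(path, index=False, float_format="%.10g")


def read_track(path: str | Path | io.TextIOBase) -> list[TimedState]:
    """Read a track CSV written by :func:`write_track`.

    Columns are matched by header name, so column order is free.  Missing
    required columns raise :class:`TrackFormatError`.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pandas raises a zoo of parse errors
        raise TrackFormatError(f"unreadable track file: {exc}") from exc
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise TrackFormatError(f"track file missing columns: {', '.join(missing)}")
    out: list[TimedState] = []
    for _, row in df.iterrows():
        pose = HeadPose.from_array([row[c] for c in POSE_FIELDS])
        expr = ExpressionState([row[c] for c in AU_LABELS])
        state = FaceState(
            pose=pose,
            expression=expr,
            valid=bool(row["valid"]),
            confidence=float(row["confidence"]),
        )
        out.append(
            TimedState(
                frame=int(row["frame"]),
                capture_time_ms=float(row["capture_time_ms"]),
                state=state,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Message data-map adapters (namespaced keys)
# ---------------------------------------------------------------------------

def state_to_data(state: FaceState, data: dict | None = None) -> dict:
    """Write a face state into a message data map under ``pose.*`` /
    ``au.*`` / ``state.*`` keys (in place if a map is given)."""
    if data is None:
        data = {}
    for name, value in zip(POSE_FIELDS, state.pose.as_array()):
        data[f"pose.{name}"] = float(value)
    for label, value in state.expression.as_dict().items():
        data[f"au.{label}"] = value
    data["state.valid"] = bool(state.valid)
    data["state.confidence"] = float(state.confidence)
    return data


def data_to_state(data: dict) -> FaceState:
    """Reconstruct a face state from a message data map; missing keys fall
    back to the neutral state."""
    pose = HeadPose.from_array([data.get(f"pose.{n}", 0.0) for n in POSE_FIELDS])
    expr = ExpressionState([data.get(f"au.{label}", 0.0) for label in AU_LABELS])
    return FaceState(
        pose=pose,
        expression=expr,
        valid=bool(data.get("state.valid", True)),
        confidence=float(data.get("state.confidence", 1.0)),
    )
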