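"""Experimental-condition machinery.

These are the operations a virtual-mirror study actually manipulates:

* :class:`DelayBuffer` — time-shifts the tracked face state by a configurable
  delay, the classic asynchrony manipulation (delays "in the order of
  seconds" diminish the sense of agency; the synchronous condition runs at
  the pipeline's intrinsic latency).
* :func:`au_scale` — amplifies or attenuates expression intensities
  on-the-fly (e.g. a factor of 1.5 exaggerates every tracked AU).
* :func:`condition_gate` — the condition table of the validation design:
  B (baseline replay), P (pose only), E (expressions only), PE (both).
* :class:`ReplaySource` — continuous replay of a prerecorded rest sequence,
  decoupling the avatar from the participant in the baseline condition.

All operations are pure with respect to their inputs; the delay buffer and
replay source carry explicit state and an injected clock.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigurationError
from .face import (
    AU_MAX,
    ExpressionState,
    FaceState,
    HeadPose,
    TimedState,
)

CONDITIONS = ("B", "P", "E", "PE")

#: Default delay for an asynchronous control condition, in ms.
DEFAULT_ASYNC_DELAY_MS = 2000.0


class DelayBuffer:
    """Timestamp-based delay line for face states.

    States are pushed with their capture time; :meth:`emit` returns the
    newest buffered state captured at or before ``now - delay``.  No
    interpolation is performed, so every emitted state is exactly equal to a
    past input.  Before the buffer covers the delay (the first ``delay`` ms
    of a stream), the neutral state is emitted and flagged as warm-up.
    """

    def __init__(self, delay_ms: float = 0.0) -> None:
        if delay_ms < 0:
            raise ValueError("delay must be >= 0")
        self.delay_ms = float(delay_ms)
        self._times: list[float] = []
        self._states: list[FaceState] = []

    def set_delay(self, delay_ms: float) -> None:
        if delay_ms < 0:
            raise ValueError("delay must be >= 0")
        self.delay_ms = float(delay_ms)

    def push(self, state: FaceState, capture_time_ms: float) -> None:
        if self._times and capture_time_ms < self._times[-1]:
            raise ValueError("capture times must be non-decreasing")
        self._times.append(float(capture_time_ms))
        self._states.append(state)

    def emit(self, now_ms: float) -> tuple[FaceState, float | None]:
        """Return ``(state, emitted_capture_time_ms)`` for the current time.

        While no buffered state is old enough (warm-up), the neutral state
        is returned with ``None`` as its capture time.
        """
        cutoff = now_ms - self.delay_ms
        idx = bisect_right(self._times, cutoff) - 1
        if idx < 0:
            return FaceState.neutral(), None
        state = self._states[idx]
        emitted_t = self._times[idx]
        # Entries before idx can never be selected again (time is monotonic).
        if idx > 0:
            del self._times[:idx]
            del self._states[:idx]
        return state, emitted_t


def au_scale(state: FaceState, factor: float) -> FaceState:
    """Scale every AU intensity by ``factor``, clamped to [0, 5].

    The pose is untouched.  Below the clamp this is linear, so scaling by
    ``s1`` then ``s2`` equals scaling by ``s1 * s2``.
    """
    if factor < 0:
        raise ValueError("AU scale factor must be >= 0")
    scaled = np.minimum(AU_MAX, factor * state.expression.au)
    return FaceState(
        pose=state.pose,
        expression=ExpressionState(scaled),
        valid=state.valid,
        confidence=state.confidence,
    )


def condition_gate(
    state: FaceState,
    mode: str,
    rest_pose: HeadPose | None = None,
    replay_state: FaceState | None = None,
) -> FaceState:
    """Apply the experimental-condition gate.

    ========  =====================================================
    mode      output
    ========  =====================================================
    ``B``     the replay state; the live input is ignored entirely
    ``P``     tracked pose passes, expression forced neutral
    ``E``     tracked expression passes, pose held at ``rest_pose``
    ``PE``    identity — pose and expression both pass
    ========  =====================================================
    """
    if mode not in CONDITIONS:
        raise ValueError(f"unknown condition mode {mode!r}; expected one of {CONDITIONS}")
    if mode == "PE":
        return state
    if mode == "P":
        return FaceState(
            pose=state.pose,
            expression=ExpressionState.neutral(),
            valid=state.valid,
            confidence=state.confidence,
        )
    if mode == "E":
        rest = rest_pose if rest_pose is not None else HeadPose.neutral()
        return FaceState(
            pose=rest,
            expression=state.expression,
            valid=state.valid,
            confidence=state.confidence,
        )
    # mode == "B"
    if replay_state is None:
        raise ConfigurationError("condition B requires a replay source")
    return replay_state


@dataclass
class ReplaySource:
    """Continuous replay of a prerecorded face-state sequence.

    At query time ``t`` the source returns the recorded state with the
    greatest capture time <= ``t mod duration`` (looping) or holds the final
    state once the recording is exhausted (non-looping).  The recording
    duration is the last capture time plus one median frame interval, so
    querying exactly at the duration wraps to the first state.
    """

    samples: Sequence[TimedState]
    loop: bool = True

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        if not self.samples:
            raise ValueError("replay recording must be non-empty")
        self._times = [s.capture_time_ms for s in self.samples]
        if any(b < a for a, b in zip(self._times, self._times[1:])):
            raise ValueError("replay recording must be sorted by capture time")

    @property
    def duration_ms(self) -> float:
        times = self._times
        if len(times) > 1:
            dt = float(np.median(np.diff(times)))
        else:
            dt = 1000.0 / 30.0
        return times[-1] - times[0] + dt

    def state_at(self, t_ms: float) -> FaceState:
        t0 = self._times[0]
        if self.loop:
            t = t0 + (t_ms % self.duration_ms)
        else:
            t = t_ms
            if t >= self._times[-1]:
                return self.samples[-1].state
        idx = bisect_right(self._times, t) - 1
        idx = max(idx, 0)
        return self.samples[idx].state
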