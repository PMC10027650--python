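"""Host-experiment interface and induction-schedule builder.

:class:`MirrorSession` is the surface a stimulus-presentation script (e.g.
a PsychoPy experiment) talks to: the mirror pipeline runs in the
background (or is stepped frame-by-frame under a simulated clock for
deterministic tests), rendered frames are retrieved without blocking, and
delay, condition, avatar, and amplification can be adjusted live, taking
effect on the next frame.

:func:`build_schedule` produces the validation study's induction plan: the
baseline condition B always comes first, the remaining three blocks (P, E,
PE) are counterbalanced across participants over all six permutations, each
block runs instruction 30 s / mirror 180 s / free 30 s (240 s total), and
each participant sees three distinct avatar identities in the synchronous
blocks.
"""

from __future__ import annotations

import itertools
import threading
import time
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .clock import MonotonicClock, SimulatedClock
from .errors import ConfigurationError, SessionStateError
from .pipeline import Message, Pipeline, PipelineSpec, parse_pipeline_spec

PHASES: tuple[tuple[str, float], ...] = (
    ("instruction", 30.0),
    ("mirror", 180.0),
    ("free", 30.0),
)
BLOCK_DURATION_S = sum(d for _, d in PHASES)

DEFAULT_SESSION_SPEC = """
synth_source script=rest fps=30
tracker_stub
delay delay_ms=0
au_scale factor=1.0
gate mode=PE
render avatar=a1 width=128 height=128
sink
"""


class MirrorSession:
    """A running virtual mirror controlled by a host experiment.

    ``mode="stepped"`` advances one frame per :meth:`step` call under a
    simulated clock (deterministic; used in tests and offline work);
    ``mode="live"`` drives the pipeline in a background thread at the
    source's frame rate without ever blocking the host's frame loop.
    """

    def __init__(
        self,
        spec: PipelineSpec | str = DEFAULT_SESSION_SPEC,
        mode: str = "stepped",
        seed: int = 0,
        workdir=None,
    ) -> None:
        if mode not in ("stepped", "live"):
            raise ValueError(f"unknown session mode {mode!r}")
        self.mode = mode
        if isinstance(spec, str):
            spec = parse_pipeline_spec(spec)
        clock = SimulatedClock() if mode == "stepped" else MonotonicClock()
        self.pipeline = Pipeline(spec, clock=clock, seed=seed, workdir=workdir)
        self.clock = clock
        self._running = False
        self._frame_index = 0
        self._thread: Optional[threading.Thread] = None
        self._stop_event = threading.Event()
        self.events: list[tuple[float, str, object]] = []
        self._events_lock = threading.Lock()

    # -- lifecycle ---------------------------------------------------------

    def start(self) -> "MirrorSession":
        if self._running:
            return self
        self._running = True
        self._log("session.start", self.mode)
        if self.mode == "live":
            self._stop_event.clear()
            self._thread = threading.Thread(target=self._live_loop, daemon=True)
            self._thread.start()
        return self

    def stop(self) -> None:
        if not self._running:
            return
        self._running = False
        self._log("session.stop", None)
        if self._thread is not None:
            self._stop_event.set()
            self._thread.join(timeout=5.0)
            self._thread = None

    def __enter__(self) -> "MirrorSession":
        return self.start()

    def __exit__(self, *exc) -> None:
        self.stop()

    @property
    def running(self) -> bool:
        return self._running

    def _require_running(self) -> None:
        if not self._running:
            raise SessionStateError("session is not running")

    def _log(self, event: str, payload) -> None:
        with self._events_lock:
            self.events.append((self.clock.now_ms(), event, payload))

    # -- frame delivery ----------------------------------------------------

    def step(self, n: int = 1) -> None:
        """Advance ``n`` frames (stepped mode only)."""
        self._require_running()
        if self.mode != "stepped":
            raise SessionStateError("step() is only available in stepped mode")
        source = self.pipeline.source
        for _ in range(n):
            i = self._frame_index
            t_ms = source.nominal_time_ms(i)
            self.clock.set(max(t_ms, self.clock.now_ms()))
            msg = source.make_message(i, t_ms)
            data, image = msg.data, msg.image
            for module in self.pipeline.modules[1:]:
                data, image = module.process(dict(data), image)
            out = Message(msg.frame_id, msg.capture_time_ms, image, data)
            self.pipeline.sink.deliver(out)
            self._log("frame.delivered", i)
            self._frame_index += 1

    def _live_loop(self) -> None:
        source = self.pipeline.source
        interval = 1.0 / getattr(source, "fps", 30.0)
        while not self._stop_event.is_set():
            t_start = time.perf_counter()
            i = self._frame_index
            msg = source.make_message(i, self.clock.now_ms())
            data, image = msg.data, msg.image
            for module in self.pipeline.modules[1:]:
                data, image = module.process(dict(data), image)
            self.pipeline.sink.deliver(
                Message(msg.frame_id, msg.capture_time_ms, image, data)
            )
            self._frame_index += 1
            elapsed = time.perf_counter() - t_start
            remaining = interval - elapsed
            if remaining > 0:
                self._stop_event.wait(remaining)

    # -- retrieval ---------------------------------------------------------

    def get_latest(self) -> Optional[Message]:
        """Most recent delivered message, or None before the first frame.
        Non-blocking: returns immediately regardless of pipeline load, and
        repeated calls between frames return the same message."""
        return self.pipeline.sink.latest

    def get_latest_image(self) -> Optional[np.ndarray]:
        """Most recent rendered frame, or None before the first frame."""
        msg = self.get_latest()
        return None if msg is None else msg.image

    # -- live control ------------------------------------------------------

    def set_delay(self, delay_ms: float) -> None:
        self._require_running()
        self.pipeline.find("delay").set_delay(delay_ms)
        self._log("set_delay", delay_ms)

    def set_condition(self, mode: str) -> None:
        self._require_running()
        self.pipeline.find("gate").set_mode(mode)
        self._log("set_condition", mode)

    def set_avatar(self, avatar_id: str) -> None:
        self._require_running()
        self.pipeline.find("render").set_avatar(avatar_id)
        self._log("set_avatar", avatar_id)

    def set_amplification(self, factor: float) -> None:
        self._require_running()
        self.pipeline.find("au_scale").set_factor(factor)
        self._log("set_amplification", factor)

    def control(self, command: str, value) -> None:
        """Generic command dispatch: ``set_delay`` | ``set_condition`` |
        ``set_avatar`` | ``set_amplification``."""
        handler = {
            "set_delay": self.set_delay,
            "set_condition": self.set_condition,
            "set_avatar": self.set_avatar,
            "set_amplification": self.set_amplification,
        }.get(command)
        if handler is None:
            raise ValueError(f"unknown session command {command!r}")
        handler(value)

    def export_events(self, path) -> None:
        """Write the event log as CSV (monotonic time, event, payload)."""
        with self._events_lock:
            df = pd.DataFrame(self.events, columns=["time_ms", "event", "payload"])
        df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Induction schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Block:
    """One induction block of the study schedule."""

    index: int
    condition: str
    avatar_id: str
    phases: tuple[tuple[str, float], ...] = PHASES

    @property
    def duration_s(self) -> float:
        return sum(d for _, d in self.phases)


@dataclass(frozen=True)
class ParticipantSchedule:
    participant: int
    blocks: tuple[Block, ...]


@dataclass
class InductionSchedule:
    """Schedules for all participants, plus export helpers."""

    participants: list[ParticipantSchedule] = field(default_factory=list)
    break_between_blocks_s: float = 300.0  # metadata only, not enforced

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.participants:
            for block in p.blocks:
                onset = 0.0
                for phase, dur in block.phases:
                    rows.append(
                        {
                            "participant": p.participant,
                            "block_index": block.index,
                            "condition": block.condition,
                            "avatar_id": block.avatar_id,
                            "phase": phase,
                            "onset_s": onset,
                            "duration_s": dur,
                        }
                    )
                    onset += dur
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_schedule(
    n_participants: int,
    avatar_ids: list[str],
    seed: int = 0,
) -> InductionSchedule:
    """Build the counterbalanced induction schedule.

    Baseline B is always the first block.  The six permutations of
    (P, E, PE) are assigned in balanced fashion: with ``n_participants`` a
    multiple of 6 each order occurs exactly n/6 times; otherwise the counts
    differ by at most one and a warning is emitted.  Each participant's
    three synchronous blocks use three distinct avatars drawn from the
    pool; the baseline avatar is drawn to differ from those when the pool
    allows.
    """
    if n_participants < 1:
        raise ValueError("need at least one participant")
    if len(set(avatar_ids)) < 3:
        raise ConfigurationError("need at least 3 distinct avatar ids")
    avatar_ids = list(dict.fromkeys(avatar_ids))
    if n_participants % 6 != 0:
        warnings.warn(
            f"{n_participants} participants cannot be exactly counterbalanced "
            "over 6 condition orders; using nearest-balanced assignment",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    orders = sorted(itertools.permutations(("P", "E", "PE")))
    # Balanced multiset of order indices, shuffled across participants.
    reps = [i % 6 for i in range(n_participants)]
    rng.shuffle(reps)

    schedule = InductionSchedule()
    for participant in range(1, n_participants + 1):
        order = orders[reps[participant - 1]]
        if len(avatar_ids) >= 4:
            chosen = rng.choice(len(avatar_ids), size=4, replace=False)
            baseline_avatar = avatar_ids[chosen[3]]
        else:
            chosen = rng.choice(len(avatar_ids), size=3, replace=False)
            baseline_avatar = avatar_ids[int(rng.integers(len(avatar_ids)))]
        sync_avatars = [avatar_ids[c] for c in chosen[:3]]
        blocks = [Block(index=0, condition="B", avatar_id=baseline_avatar)]
        for k, cond in enumerate(order, start=1):
            blocks.append(Block(index=k, condition=cond, avatar_id=sync_avatars[k - 1]))
        schedule.participants.append(
            ParticipantSchedule(participant=participant, blocks=tuple(blocks))
        )
    return schedule
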