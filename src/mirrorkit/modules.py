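"""Built-in pipeline module types.

Each class here is registered under a type name usable in pipeline spec
files (``synth_source``, ``tracker_stub``, ``delay``, ``au_scale``,
``gate``, ``replay``, ``render``, ``identity``, ``sink``).  The synthetic
source replaces the webcam + tracker pair for desk-scale operation: it
samples a deterministic motion script (optionally with Gaussian tracker
jitter) instead of capturing pixels.  A real tracker can be integrated by
conforming to the adapter contract ``(image, CameraIntrinsics) ->
FaceState`` and exposing it as a module like the stub below.
"""

from __future__ import annotations

import threading
from typing import Optional

import numpy as np

from .errors import ConfigurationError
from .face import (
    FaceState,
    HeadPose,
    MotionScript,
    data_to_state,
    make_calibration_script,
    make_rest_script,
    read_track,
    state_to_data,
)
from .manipulators import CONDITIONS, DelayBuffer, ReplaySource, au_scale, condition_gate
from .pipeline import Message, PipelineModule, register_module
from .render import get_avatar, render_state


def _invalid_passthrough(data: dict, image) -> tuple[dict, object]:
    """Flag an invalid-state message and return it unchanged."""
    data["manipulator.skipped"] = True
    return data, image


@register_module
class SynthSource(PipelineModule):
    """Script-driven source emulating a 30-120 Hz tracker output stream.

    Parameters: ``script`` (``calibration`` | ``rest``), ``fps``,
    ``noise_sd``, ``au_noise_sd``, ``seed``, ``yaw`` (calibration turn
    amplitude, degrees).
    """

    type_name = "synth_source"
    is_source = True

    def __init__(self, name, params, ctx):
        super().__init__(name, params, ctx)
        self.fps = self._pfloat("fps", 120.0)
        self.noise_sd = self._pfloat("noise_sd", 0.0)
        self.au_noise_sd = self._pfloat("au_noise_sd", self.noise_sd)
        seed = self._pint("seed", ctx.seed)
        self._rng = np.random.default_rng(seed)
        kind = params.get("script", "calibration")
        if kind == "calibration":
            self.script: MotionScript = make_calibration_script(
                yaw_deg=self._pfloat("yaw", 25.0)
            )
        elif kind == "rest":
            self.script = make_rest_script(
                breathing_amplitude=self._pfloat("amplitude", 2.0),
                breathing_period_s=self._pfloat("period", 4.0),
            )
        else:
            raise ConfigurationError(f"unknown script kind {kind!r}")

    def set_script(self, script: MotionScript) -> None:
        self.script = script

    def nominal_time_ms(self, frame: int) -> float:
        return frame * 1000.0 / self.fps

    def make_message(self, frame: int, t_ms: float) -> Message:
        state = self.script.state_at(t_ms / 1000.0)
        if self.noise_sd > 0 or self.au_noise_sd > 0:
            from .face import ExpressionState  # local to avoid wide import

            pose_vec = state.pose.as_array() + self.noise_sd * self._rng.standard_normal(6)
            au_vec = state.expression.au + self.au_noise_sd * self._rng.standard_normal(
                state.expression.au.size
            )
            state = FaceState(
                pose=HeadPose.from_array(pose_vec),
                expression=ExpressionState(au_vec),
            )
        data = state_to_data(state)
        data["frame.id"] = frame
        data["frame.capture_ms"] = t_ms
        for key in ("fx", "fy", "cx", "cy"):
            if key in self.params:
                data[f"camera.{key}"] = float(self.params[key])
        return Message(frame_id=frame, capture_time_ms=t_ms, image=None, data=data)


@register_module
class TrackerStub(PipelineModule):
    """Stands in for the markerless tracker: guarantees the message carries
    a face state (neutral if the source provided none)."""

    type_name = "tracker_stub"

    def process(self, data, image):
        if "pose.ry" not in data:
            state_to_data(FaceState.neutral(), data)
        return data, image


@register_module
class Identity(PipelineModule):
    """No-op module (plumbing and tests)."""

    type_name = "identity"

    def process(self, data, image):
        return data, image


@register_module
class Delay(PipelineModule):
    """Asynchrony manipulator: emits the tracked state as it was
    ``delay_ms`` ago.  During warm-up (first ``delay_ms`` of the stream)
    the neutral state is emitted and flagged via ``delay.warmup``."""

    type_name = "delay"

    def __init__(self, name, params, ctx):
        super().__init__(name, params, ctx)
        self.buffer = DelayBuffer(self._pfloat("delay_ms", 2000.0))

    def set_delay(self, delay_ms: float) -> None:
        with self._lock:
            self.buffer.set_delay(delay_ms)

    def process(self, data, image):
        state = data_to_state(data)
        capture_ms = float(data.get("frame.capture_ms", self.clock.now_ms()))
        now = self.clock.now_ms()
        with self._lock:
            self.buffer.push(state, capture_ms)
            out, emitted_t = self.buffer.emit(now)
        state_to_data(out, data)
        data["delay.warmup"] = emitted_t is None
        if emitted_t is not None:
            data["delay.age_ms"] = now - emitted_t
        return data, image


@register_module
class AuScale(PipelineModule):
    """Expression amplifier: multiplies every AU intensity by ``factor``
    (default 1.5), clamped to the [0, 5] range."""

    type_name = "au_scale"

    def __init__(self, name, params, ctx):
        super().__init__(name, params, ctx)
        self.factor = self._pfloat("factor", 1.5)

    def set_factor(self, factor: float) -> None:
        if factor < 0:
            raise ValueError("AU scale factor must be >= 0")
        with self._lock:
            self.factor = float(factor)

    def process(self, data, image):
        state = data_to_state(data)
        if not state.valid:
            return _invalid_passthrough(data, image)
        with self._lock:
            factor = self.factor
        state_to_data(au_scale(state, factor), data)
        return data, image


@register_module
class Gate(PipelineModule):
    """Condition gate: ``mode`` in {B, P, E, PE}; ``rest`` currently only
    ``neutral``; ``replay`` names a track CSV (required for mode B)."""

    type_name = "gate"

    def __init__(self, name, params, ctx):
        super().__init__(name, params, ctx)
        self.rest_pose = HeadPose.neutral()
        self.replay: Optional[ReplaySource] = None
        replay_file = params.get("replay")
        if replay_file:
            path = replay_file
            if ctx.workdir is not None:
                path = str(ctx.workdir / replay_file)
            self.replay = ReplaySource(read_track(path), loop=True)
        self.mode = "PE"
        self.set_mode(params.get("mode", "PE"))

    def set_replay(self, replay: ReplaySource) -> None:
        with self._lock:
            self.replay = replay

    def set_mode(self, mode: str) -> None:
        if mode not in CONDITIONS:
            raise ValueError(f"unknown condition mode {mode!r}")
        if mode == "B" and self.replay is None:
            raise ConfigurationError("condition B requires a replay source")
        with self._lock:
            self.mode = mode

    def process(self, data, image):
        state = data_to_state(data)
        if not state.valid:
            return _invalid_passthrough(data, image)
        with self._lock:
            mode, replay = self.mode, self.replay
        replay_state = None
        if mode == "B":
            t = float(data.get("frame.capture_ms", self.clock.now_ms()))
            replay_state = replay.state_at(t)
        out = condition_gate(state, mode, rest_pose=self.rest_pose,
                             replay_state=replay_state)
        state_to_data(out, data)
        data["condition.mode"] = mode
        return data, image


@register_module
class Replay(PipelineModule):
    """Replaces the live state with a prerecorded track (``file=...``,
    ``loop=true``); the standalone form of the baseline manipulation."""

    type_name = "replay"

    def __init__(self, name, params, ctx):
        super().__init__(name, params, ctx)
        replay_file = params.get("file")
        if not replay_file:
            raise ConfigurationError("replay module requires file=...")
        path = replay_file
        if ctx.workdir is not None:
            path = str(ctx.workdir / replay_file)
        self.source = ReplaySource(read_track(path), loop=self._pbool("loop", True))

    def process(self, data, image):
        t = float(data.get("frame.capture_ms", self.clock.now_ms()))
        state_to_data(self.source.state_at(t), data)
        data["condition.mode"] = "B"
        return data, image


@register_module
class Render(PipelineModule):
    """Schematic avatar renderer (``avatar=a1 width=128 height=128``).

    Avatar switches requested via :meth:`set_avatar` take effect on the
    next message; a frame is always rendered with a single identity.
    """

    type_name = "render"

    def __init__(self, name, params, ctx):
        super().__init__(name, params, ctx)
        self.size = (self._pint("width", 128), self._pint("height", 128))
        self._avatar_id = params.get("avatar", "a1")
        get_avatar(self._avatar_id)  # validate eagerly

    @property
    def avatar_id(self) -> str:
        return self._avatar_id

    def set_avatar(self, avatar_id: str) -> None:
        get_avatar(avatar_id)  # raises ValueError listing registered ids
        with self._lock:
            self._avatar_id = avatar_id

    def process(self, data, image):
        with self._lock:
            avatar_id = self._avatar_id
        state = data_to_state(data)
        image = render_state(state, avatar_id, self.size)
        data["avatar.id"] = avatar_id
        return data, image


@register_module
class Sink(PipelineModule):
    """Terminal module: retains the most recent delivered frame for
    non-blocking retrieval by a host experiment."""

    type_name = "sink"
    is_sink = True

    def __init__(self, name, params, ctx):
        super().__init__(name, params, ctx)
        self._latest: Optional[Message] = None
        self._latest_lock = threading.Lock()

    def process(self, data, image):
        return data, image

    def deliver(self, msg: Message) -> None:
        with self._latest_lock:
            self._latest = msg

    @property
    def latest(self) -> Optional[Message]:
        with self._latest_lock:
            return self._latest
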