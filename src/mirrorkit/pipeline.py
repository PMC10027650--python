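"""Feed-forward message-passing pipeline.

A virtual mirror is organised as a linear chain of modules — source,
tracker, manipulators, renderer, sink — through which timestamped messages
flow in one direction.  Modules may operate concurrently on different
messages (one worker thread per module), but each module preserves the
order of the messages it handles, so delivered frame ids are always
strictly increasing.

Because a mirror must show the freshest frame, the default back-pressure
policy is *latest-wins*: when a downstream module is slower than its
upstream, only the most recent pending message per edge is kept and the
rest are counted as dropped.  A *queue-all* policy (unbounded FIFO) is
available for offline processing.  For every run,
``emitted == delivered + dropped``.

Pipelines are described in plain-text spec files, one module per line::

    # capture -> track -> delay -> render -> display
    synth_source script=calibration fps=120
    tracker_stub
    delay delay_ms=2000
    render avatar=a1 width=128 height=128
    sink

Timing instrumentation uses an injected monotonic millisecond clock; each
module writes its processing duration under a ``timing.<module>_ms`` key
that downstream modules never mutate.
"""

from __future__ import annotations

import json
import threading
import time
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Optional

import numpy as np
import pandas as pd

from .clock import MonotonicClock, SimulatedClock
from .errors import PipelineSpecError

DROP_POLICIES = ("latest", "queue")


@dataclass
class Message:
    """One pipeline packet: frame id, capture timestamp, optional image,
    and a key-value data map with namespaced keys (``pose.*``, ``au.*``,
    ``camera.*``, ``timing.*``, ``avatar.*``)."""

    frame_id: int
    capture_time_ms: float
    image: Optional[np.ndarray] = None
    data: dict[str, Any] = field(default_factory=dict)


@dataclass(frozen=True)
class ModuleDescriptor:
    """One line of a pipeline spec: module type plus raw parameters."""

    type: str
    params: dict[str, str] = field(default_factory=dict)
    line_no: int = 0


@dataclass(frozen=True)
class PipelineSpec:
    """Ordered module descriptors forming a linear acyclic chain."""

    descriptors: tuple[ModuleDescriptor, ...]


# ---------------------------------------------------------------------------
# Module registry and base class
# ---------------------------------------------------------------------------

MODULE_TYPES: dict[str, type] = {}


def register_module(cls: type) -> type:
    """Class decorator: make a module type available to spec files."""
    MODULE_TYPES[cls.type_name] = cls
    return cls


@dataclass
class PipelineContext:
    """Dependencies shared by all modules of one pipeline instance."""

    clock: Any
    seed: int = 0
    workdir: Optional[Path] = None


class PipelineModule:
    """Base class for pipeline modules.

    Subclasses implement :meth:`process`, mapping ``(data, image)`` to
    ``(data, image)``.  The surrounding machinery guarantees messages leave
    in the order they entered and records per-message processing durations.
    """

    type_name = "identity"
    is_source = False
    is_sink = False

    def __init__(self, name: str, params: dict[str, str], ctx: PipelineContext) -> None:
        self.name = name
        self.params = params
        self.ctx = ctx
        self.clock = ctx.clock
        # Optional artificial workload, for exercising back-pressure.
        self.work_ms = float(params.get("work_ms", 0.0))
        self._lock = threading.Lock()

    def process(self, data: dict, image):  # noqa: D401 - contract method
        return data, image

    def _busy_work(self) -> None:
        if self.work_ms > 0:
            t_end = time.perf_counter() + self.work_ms / 1000.0
            while time.perf_counter() < t_end:
                pass

    # -- param helpers -----------------------------------------------------
    def _pfloat(self, key: str, default: float) -> float:
        return float(self.params.get(key, default))

    def _pint(self, key: str, default: int) -> int:
        return int(self.params.get(key, default))

    def _pbool(self, key: str, default: bool) -> bool:
        raw = self.params.get(key)
        if raw is None:
            return default
        return raw.lower() in ("1", "true", "yes", "on")


# ---------------------------------------------------------------------------
# Spec parsing
# ---------------------------------------------------------------------------

def parse_pipeline_spec(text: str) -> PipelineSpec:
    """Parse pipeline spec text: one module per line, whitespace-separated
    ``type key=value ...``, ``#`` starts a comment.

    Raises :class:`PipelineSpecError` for empty input or unregistered module
    types (naming the offending line).  Unknown parameter keys are preserved
    verbatim so downstream modules can consume them.
    """
    from . import modules  # noqa: F401 - ensure built-in types are registered

    descriptors: list[ModuleDescriptor] = []
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.split()
        mtype = tokens[0]
        if mtype not in MODULE_TYPES:
            raise PipelineSpecError(
                f"line {line_no}: unknown module type {mtype!r} "
                f"(registered: {sorted(MODULE_TYPES)})"
            )
        params: dict[str, str] = {}
        for tok in tokens[1:]:
            if "=" not in tok:
                raise PipelineSpecError(
                    f"line {line_no}: malformed parameter {tok!r} (expected key=value)"
                )
            key, value = tok.split("=", 1)
            params[key] = value
        descriptors.append(ModuleDescriptor(mtype, params, line_no))
    if not descriptors:
        raise PipelineSpecError("pipeline spec is empty")
    return PipelineSpec(tuple(descriptors))


# ---------------------------------------------------------------------------
# Run report and timing statistics
# ---------------------------------------------------------------------------

@dataclass
class RunReport:
    """Outcome of one pipeline run."""

    emitted: int = 0
    delivered: int = 0
    dropped: int = 0
    delivered_frame_ids: list[int] = field(default_factory=list)
    delivered_data: list[dict] = field(default_factory=list)
    module_durations: dict[str, list[float]] = field(default_factory=dict)
    module_names: list[str] = field(default_factory=list)
    drop_policy: str = "latest"
    failed_module: Optional[str] = None

    @property
    def ok(self) -> bool:
        return self.failed_module is None


def module_timing(report: RunReport) -> pd.DataFrame:
    """Per-module mean and SD of processing duration, plus pipeline total.

    The pipeline total for a delivered message is the sum of the
    ``timing.*`` entries it accumulated on its way to the sink.  SDs are
    population SDs, so a single message yields SD 0.
    """
    if report.delivered < 1:
        raise ValueError("report contains no delivered messages")
    rows = []
    for name in report.module_names:
        durations = np.asarray(report.module_durations.get(name, []), dtype=float)
        if durations.size == 0:
            continue
        rows.append(
            {
                "module": name,
                "n": int(durations.size),
                "mean_ms": float(durations.mean()),
                "sd_ms": float(durations.std(ddof=0)),
            }
        )
    totals = np.array(
        [
            sum(v for k, v in data.items() if k.startswith("timing."))
            for data in report.delivered_data
        ],
        dtype=float,
    )
    rows.append(
        {
            "module": "pipeline",
            "n": int(totals.size),
            "mean_ms": float(totals.mean()) if totals.size else 0.0,
            "sd_ms": float(totals.std(ddof=0)) if totals.size else 0.0,
        }
    )
    return pd.DataFrame(rows, columns=["module", "n", "mean_ms", "sd_ms"])


def export_report(report: RunReport, path: str | Path) -> None:
    """Write timing statistics as CSV (``module,n,mean_ms,sd_ms``) or JSON,
    chosen by file extension."""
    timing = module_timing(report)
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "emitted": report.emitted,
            "delivered": report.delivered,
            "dropped": report.dropped,
            "drop_policy": report.drop_policy,
            "failed_module": report.failed_module,
            "modules": timing.to_dict(orient="records"),
        }
        path.write_text(json.dumps(payload, indent=2))
    else:
        timing.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Edges
# ---------------------------------------------------------------------------

class _Mailbox:
    """One edge between two modules.

    ``latest`` policy keeps only the most recent pending message (older
    pending ones count as dropped); ``queue`` keeps everything.  ``None``
    from :meth:`get` signals end-of-stream.
    """

    def __init__(self, policy: str) -> None:
        if policy not in DROP_POLICIES:
            raise ValueError(f"unknown drop policy {policy!r}")
        self.policy = policy
        self._cond = threading.Condition()
        self._queue: deque[Message] = deque()
        self._closed = False
        self.dropped = 0

    def put(self, msg: Message) -> None:
        with self._cond:
            if self._closed:
                self.dropped += 1
                return
            if self.policy == "latest" and self._queue:
                self.dropped += len(self._queue)
                self._queue.clear()
            self._queue.append(msg)
            self._cond.notify()

    def get(self) -> Optional[Message]:
        with self._cond:
            while not self._queue and not self._closed:
                self._cond.wait(timeout=0.1)
            if self._queue:
                return self._queue.popleft()
            return None

    def close(self) -> None:
        with self._cond:
            self._closed = True
            self._cond.notify_all()

    def drain(self) -> int:
        """Drop any remaining messages (used after a failure) and return
        the number discarded."""
        with self._cond:
            n = len(self._queue)
            self.dropped += n
            self._queue.clear()
            return n


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

class Pipeline:
    """A built pipeline: module instances wired in a chain.

    Supports two execution modes: :meth:`run` (threaded, concurrent modules,
    real or injected clock) and :meth:`run_stepped` (synchronous frame-by-
    frame execution under a simulated clock, for deterministic calibration
    and tests).
    """

    def __init__(
        self,
        spec: PipelineSpec | str,
        clock=None,
        seed: int = 0,
        workdir: Optional[Path] = None,
    ) -> None:
        from . import modules  # noqa: F401 - register built-ins

        if isinstance(spec, str):
            spec = parse_pipeline_spec(spec)
        self.spec = spec
        self.clock = clock if clock is not None else MonotonicClock()
        self.ctx = PipelineContext(clock=self.clock, seed=seed, workdir=workdir)

        descs = spec.descriptors
        first_cls = MODULE_TYPES[descs[0].type]
        if not first_cls.is_source:
            raise PipelineSpecError(
                f"first module must be a source, got {descs[0].type!r}"
            )
        last_cls = MODULE_TYPES[descs[-1].type]
        if not last_cls.is_sink:
            raise PipelineSpecError(f"last module must be a sink, got {descs[-1].type!r}")
        for d in descs[1:-1]:
            cls = MODULE_TYPES[d.type]
            if cls.is_source or cls.is_sink:
                raise PipelineSpecError(
                    f"line {d.line_no}: {d.type!r} may only appear at the chain "
                    f"{'start' if cls.is_source else 'end'}"
                )

        counts: dict[str, int] = {}
        self.modules: list[PipelineModule] = []
        for d in descs:
            counts[d.type] = counts.get(d.type, 0) + 1
            name = d.type if counts[d.type] == 1 else f"{d.type}_{counts[d.type]}"
            self.modules.append(MODULE_TYPES[d.type](name, d.params, self.ctx))

    @property
    def source(self) -> PipelineModule:
        return self.modules[0]

    @property
    def sink(self) -> PipelineModule:
        return self.modules[-1]

    def find(self, type_name: str) -> PipelineModule:
        """First module of the given type; KeyError if absent."""
        for m in self.modules:
            if m.type_name == type_name:
                return m
        raise KeyError(f"no module of type {type_name!r} in pipeline")

    # -- threaded execution ------------------------------------------------

    def run(
        self,
        n_messages: int = 100,
        drop_policy: str = "latest",
        pace_fps: Optional[float] = None,
        duration_s: Optional[float] = None,
    ) -> RunReport:
        """Run the pipeline with one worker thread per module.

        The source emits ``n_messages`` messages (or emits until
        ``duration_s`` of wall time has elapsed), optionally paced at
        ``pace_fps``.  Returns a :class:`RunReport`; a module exception
        halts the run and is recorded in ``failed_module``.
        """
        if drop_policy not in DROP_POLICIES:
            raise ValueError(f"unknown drop policy {drop_policy!r}")
        report = RunReport(
            drop_policy=drop_policy,
            module_names=[m.name for m in self.modules],
            module_durations={m.name: [] for m in self.modules},
        )
        edges = [_Mailbox(drop_policy) for _ in self.modules[1:]]
        abort = threading.Event()
        lock = threading.Lock()

        def source_loop() -> None:
            try:
                deadline = (
                    time.perf_counter() + duration_s if duration_s is not None else None
                )
                i = 0
                while True:
                    if abort.is_set():
                        break
                    if deadline is not None and time.perf_counter() >= deadline:
                        break
                    if deadline is None and i >= n_messages:
                        break
                    t0 = self.clock.now_ms()
                    msg = self.source.make_message(i, t0)
                    self.source._busy_work()
                    t1 = self.clock.now_ms()
                    msg.data[f"timing.{self.source.name}_ms"] = t1 - t0
                    with lock:
                        report.module_durations[self.source.name].append(t1 - t0)
                        report.emitted += 1
                    edges[0].put(msg)
                    i += 1
                    if pace_fps:
                        time.sleep(1.0 / pace_fps)
            except Exception:
                with lock:
                    report.failed_module = self.source.name
                abort.set()
            finally:
                edges[0].close()

        def worker_loop(idx: int) -> None:
            module = self.modules[idx]
            inbox = edges[idx - 1]
            outbox = edges[idx] if idx < len(self.modules) - 1 else None
            try:
                while True:
                    msg = inbox.get()
                    if msg is None:
                        break
                    if abort.is_set():
                        with lock:
                            report.dropped += 1
                        continue
                    try:
                        t0 = self.clock.now_ms()
                        data, image = module.process(dict(msg.data), msg.image)
                        module._busy_work()
                        t1 = self.clock.now_ms()
                    except Exception:
                        with lock:
                            report.failed_module = module.name
                            report.dropped += 1  # the failing message
                        abort.set()
                        break
                    data[f"timing.{module.name}_ms"] = t1 - t0
                    with lock:
                        report.module_durations[module.name].append(t1 - t0)
                    out = Message(msg.frame_id, msg.capture_time_ms, image, data)
                    if module.is_sink:
                        with lock:
                            report.delivered += 1
                            report.delivered_frame_ids.append(out.frame_id)
                            report.delivered_data.append(data)
                        module.deliver(out)
                    else:
                        outbox.put(out)
            finally:
                if outbox is not None:
                    outbox.close()

        threads = [threading.Thread(target=source_loop, daemon=True)]
        threads += [
            threading.Thread(target=worker_loop, args=(i,), daemon=True)
            for i in range(1, len(self.modules))
        ]
        for t in threads:
            t.start()
        for t in threads:
            t.join()
        for edge in edges:
            edge.drain()
            report.dropped += edge.dropped
        return report

    # -- stepped execution -------------------------------------------------

    def run_stepped(
        self,
        n_frames: int,
        on_frame: Optional[Callable[[Message], None]] = None,
    ) -> RunReport:
        """Synchronous deterministic execution under a simulated clock.

        Each frame is generated by the source at its nominal timestamp, the
        clock is advanced to that timestamp, and the message is pushed
        through every module in order.  Used by the latency-calibration
        harness and by stepped experiment sessions.  The pipeline must have
        been built with a :class:`SimulatedClock`.
        """
        if not isinstance(self.clock, SimulatedClock):
            raise ValueError("run_stepped requires a pipeline built with SimulatedClock")
        clock = self.clock
        report = RunReport(
            drop_policy="queue",
            module_names=[m.name for m in self.modules],
            module_durations={m.name: [] for m in self.modules},
        )
        for i in range(n_frames):
            t_ms = self.source.nominal_time_ms(i)
            clock.set(max(t_ms, clock.now_ms()))
            msg = self.source.make_message(i, t_ms)
            msg.data[f"timing.{self.source.name}_ms"] = 0.0
            report.module_durations[self.source.name].append(0.0)
            report.emitted += 1
            data, image = msg.data, msg.image
            failed = False
            for module in self.modules[1:]:
                try:
                    t0 = clock.now_ms()
                    data, image = module.process(dict(data), image)
                    t1 = clock.now_ms()
                except Exception:
                    report.failed_module = module.name
                    report.dropped += 1
                    failed = True
                    break
                data[f"timing.{module.name}_ms"] = t1 - t0
                report.module_durations[module.name].append(t1 - t0)
            if failed:
                break
            out = Message(msg.frame_id, msg.capture_time_ms, image, data)
            report.delivered += 1
            report.delivered_frame_ids.append(out.frame_id)
            report.delivered_data.append(data)
            self.sink.deliver(out)
            if on_frame is not None:
                on_frame(out)
        return report


def run_pipeline(
    spec: PipelineSpec | str,
    n_messages: int = 100,
    drop_policy: str = "latest",
    clock=None,
    seed: int = 0,
    workdir: Optional[Path] = None,
    pace_fps: Optional[float] = None,
) -> RunReport:
    """Build and run a pipeline in one call (threaded mode)."""
    pipeline = Pipeline(spec, clock=clock, seed=seed, workdir=workdir)
    return pipeline.run(n_messages=n_messages, drop_policy=drop_policy, pace_fps=pace_fps)
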