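"""Monotonic millisecond clocks.

Every time-dependent component (delay buffers, replay sources, timing
instrumentation) receives its clock as a dependency.  Production code uses
:class:`MonotonicClock`, a thin wrapper over ``time.perf_counter``; tests and
offline calibration use :class:`SimulatedClock`, which only moves when told
to, making delay arithmetic exactly reproducible.
"""

from __future__ import annotations

import time


class MonotonicClock:
    """Wall clock based on the OS monotonic counter, in milliseconds.

    Immune to NTP adjustments; the zero point is the moment of construction,
    which keeps the numbers small and readable in event logs.
    """

    def __init__(self) -> None:
        self._t0 = time.perf_counter()

    def now_ms(self) -> float:
        return (time.perf_counter() - self._t0) * 1000.0


class SimulatedClock:
    """Deterministic clock for stepped runs.

    Time never advances on its own: drivers call :meth:`set` or
    :meth:`advance`.  Attempting to move backwards raises ``ValueError`` so a
    buggy driver cannot silently violate monotonicity.
    """

    def __init__(self, start_ms: float = 0.0) -> None:
        self._t = float(start_ms)

    def now_ms(self) -> float:
        return self._t

    def set(self, t_ms: float) -> None:
        if t_ms < self._t:
            raise ValueError(
                f"simulated clock cannot move backwards ({t_ms} < {self._t})"
            )
        self._t = float(t_ms)

    def advance(self, dt_ms: float) -> None:
        self.set(self._t + dt_ms)
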