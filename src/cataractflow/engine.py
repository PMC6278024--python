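"""Minimal process-oriented discrete event kernel.

The simulation clock counts minutes from the start of the run.  Three
primitives are provided:

* :class:`EventCalendar` / :class:`Simulator` — a time-ordered event queue
  with a stable tie-break (insertion order), driven by :meth:`Simulator.run_until`.
* :class:`ResourcePool` — a counted resource with a FIFO request queue and a
  busy-time integral used for utilisation reporting.
* :class:`RngStreams` — named independent random substreams, all derived from
  one master seed so that a run is bit-reproducible.

Processes are plain generators that ``yield`` commands created by
:func:`hold`, :func:`acquire` and :func:`release`; the value sent back into
the generator after an ``acquire`` is the grant time in minutes.
"""

from __future__ import annotations

import heapq
import math
from collections import deque
from dataclasses import dataclass
from typing import Callable, Generator, Iterable, Optional, Union

import numpy as np

__all__ = [
    "SchedulingError",
    "ResourceError",
    "EventCalendar",
    "Simulator",
    "ResourcePool",
    "RngStreams",
    "DurationSpec",
    "sample_duration",
    "hold",
    "acquire",
    "release",
]


class SchedulingError(RuntimeError):
    """Raised when an event is scheduled before the current clock."""


class ResourceError(RuntimeError):
    """Raised on resource misuse (e.g. release without a matching acquire)."""


class EventCalendar:
    """Pending events, dispatched in non-decreasing time order.

    Equal times are dispatched in insertion order (a monotone sequence
    counter breaks ties), which makes every run fully deterministic.
    """

    def __init__(self) -> None:
        self._heap: list[tuple[float, int, Callable[[], None]]] = []
        self._seq = 0

    def push(self, time: float, action: Callable[[], None]) -> None:
        heapq.heappush(self._heap, (time, self._seq, action))
        self._seq += 1

    def pop(self) -> tuple[float, int, Callable[[], None]]:
        return heapq.heappop(self._heap)

    def peek_time(self) -> Optional[float]:
        return self._heap[0][0] if self._heap else None

    def __len__(self) -> int:
        return len(self._heap)


class Simulator:
    """Event loop: a clock plus an :class:`EventCalendar`."""

    def __init__(self) -> None:
        self.clock: float = 0.0
        self.calendar = EventCalendar()

    def schedule(self, time: float, action: Callable[[], None]) -> None:
        """Arrange for ``action()`` to run at ``time`` (minutes).

        Scheduling in the past is an error; scheduling exactly at the
        current clock fires before the clock next advances.
        """
        if time < self.clock:
            raise SchedulingError(
                f"cannot schedule at t={time} before current clock t={self.clock}"
            )
        self.calendar.push(time, action)

    def process(self, gen: Generator) -> "Process":
        """Start a generator process immediately (at the current clock)."""
        proc = Process(self, gen)
        proc._advance(None)
        return proc

    def run_until(self, horizon: float) -> float:
        """Dispatch every event with time <= horizon; return the final clock.

        The clock ends at the time of the last dispatched event (it never
        advances past ``horizon``, and does not move at all if the calendar
        holds no eligible event).
        """
        if horizon < 0:
            raise SchedulingError("horizon must be >= 0")
        cal = self.calendar
        while True:
            t = cal.peek_time()
            if t is None or t > horizon:
                break
            t, _, action = cal.pop()
            self.clock = t
            action()
        return self.clock


# -- process commands --------------------------------------------------------

_HOLD, _ACQUIRE, _RELEASE = 0, 1, 2


def hold(minutes: float):
    """Suspend the yielding process for ``minutes`` of simulated time."""
    return (_HOLD, minutes)


def acquire(pool: "ResourcePool"):
    """Request one unit of ``pool``; resumes (FIFO) when granted.

    The value sent back into the generator is the grant time.
    """
    return (_ACQUIRE, pool)


def release(pool: "ResourcePool"):
    """Return one previously acquired unit of ``pool``."""
    return (_RELEASE, pool)


class Process:
    """Driver for one generator process. Internal to the kernel."""

    __slots__ = ("sim", "gen")

    def __init__(self, sim: Simulator, gen: Generator) -> None:
        self.sim = sim
        self.gen = gen

    def _advance(self, value) -> None:
        sim = self.sim
        gen = self.gen
        while True:
            try:
                cmd = gen.send(value)
            except StopIteration:
                return
            kind = cmd[0]
            if kind == _HOLD:
                sim.schedule(sim.clock + cmd[1], self._resume_hold)
                return
            if kind == _ACQUIRE:
                pool: ResourcePool = cmd[1]
                if pool._try_acquire(sim.clock):
                    value = sim.clock
                    continue
                pool.queue.append(self)
                return
            if kind == _RELEASE:
                cmd[1].release(sim.clock)
                value = None
                continue
            raise ValueError(f"unknown process command {cmd!r}")

    def _resume_hold(self) -> None:
        self._advance(self.sim.clock)

    def _resume_grant(self) -> None:
        self._advance(self.sim.clock)


class ResourcePool:
    """A counted resource with a FIFO queue and a busy-time integral.

    ``busy_time_accumulator`` is the time integral of the number of busy
    units, in unit-minutes.  An optional ``monitor(t0, t1, busy)`` callback
    observes every constant-busy interval, which the KPI layer uses to bin
    busy time by calendar month and operating window.
    """

    def __init__(
        self,
        sim: Simulator,
        name: str,
        capacity: int,
        monitor: Optional[Callable[[float, float, int], None]] = None,
    ) -> None:
        if capacity < 0:
            raise ValueError(f"capacity of {name!r} must be >= 0, got {capacity}")
        self.sim = sim
        self.name = name
        self.capacity = capacity
        self.busy = 0
        self.queue: deque[Process] = deque()
        self.busy_time_accumulator = 0.0
        self.monitor = monitor
        self._last_change = sim.clock

    def _integrate(self, now: float) -> None:
        if now > self._last_change:
            if self.busy:
                self.busy_time_accumulator += self.busy * (now - self._last_change)
            if self.monitor is not None:
                self.monitor(self._last_change, now, self.busy)
            self._last_change = now

    def _try_acquire(self, now: float) -> bool:
        if self.busy < self.capacity:
            self._integrate(now)
            self.busy += 1
            return True
        return False

    def release(self, now: float) -> None:
        """Release one unit; the longest-waiting request (if any) is granted
        at the same instant, after the releasing event (stable ordering)."""
        if self.busy <= 0:
            raise ResourceError(f"release of {self.name!r} without a matching acquire")
        self._integrate(now)
        if self.queue:
            # hand the unit straight to the head of the queue: busy count is
            # unchanged, the waiter resumes via the calendar at `now`.
            proc = self.queue.popleft()
            self.sim.schedule(now, proc._resume_grant)
        else:
            self.busy -= 1

    def flush(self, now: float) -> None:
        """Bring the busy-time integral up to ``now`` (end-of-run bookkeeping)."""
        self._integrate(now)


# -- random streams ----------------------------------------------------------

STREAM_NAMES = ("arrivals", "outcomes", "durations", "attendance")


class RngStreams:
    """Named independent random substreams from one master seed.

    One substream per stochastic purpose means that changing, say, a duration
    parameter does not scramble arrival or attendance draws — the standard
    common-random-numbers setup for sharpening scenario contrasts.
    """

    def __init__(self, master_seed: Union[int, np.random.SeedSequence]) -> None:
        if isinstance(master_seed, np.random.SeedSequence):
            ss = master_seed
        else:
            ss = np.random.SeedSequence(int(master_seed))
        self.seed_sequence = ss
        # stateless spawn: deriving children explicitly (rather than via
        # ss.spawn, which mutates ss) means the same SeedSequence object can
        # be reused across scenarios and always yields the same substreams.
        for i, name in enumerate(STREAM_NAMES):
            child = np.random.SeedSequence(
                entropy=ss.entropy, spawn_key=tuple(ss.spawn_key) + (i,)
            )
            setattr(self, name, np.random.default_rng(child))

    arrivals: np.random.Generator
    outcomes: np.random.Generator
    durations: np.random.Generator
    attendance: np.random.Generator


# -- activity durations ------------------------------------------------------

DURATION_FAMILIES = ("constant", "lognormal", "triangular", "exponential")

#: Pathological non-positive draws are truncated to this floor (minutes).
DURATION_FLOOR = 0.1


@dataclass(frozen=True)
class DurationSpec:
    """Distribution of one activity duration, parameterised in minutes.

    ``lognormal`` is parameterised by its real-space mean and standard
    deviation; ``triangular`` by (low, mode, high); ``exponential`` by its
    mean; ``constant`` by its value.
    """

    family: str
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.family not in DURATION_FAMILIES:
            raise ValueError(
                f"unknown duration family {self.family!r}; "
                f"expected one of {DURATION_FAMILIES}"
            )
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        n_expected = {"constant": 1, "lognormal": 2, "triangular": 3, "exponential": 1}
        if len(self.params) != n_expected[self.family]:
            raise ValueError(
                f"{self.family} duration takes {n_expected[self.family]} "
                f"parameter(s), got {self.params}"
            )
        if self.family == "triangular":
            low, mode, high = self.params
            if not (low <= mode <= high):
                raise ValueError(f"triangular needs low <= mode <= high, got {self.params}")

    @property
    def mean(self) -> float:
        if self.family == "constant":
            return self.params[0]
        if self.family == "lognormal":
            return self.params[0]
        if self.family == "triangular":
            return sum(self.params) / 3.0
        return self.params[0]  # exponential

    def scaled(self, factor: float) -> "DurationSpec":
        """Return a copy with every scale parameter multiplied by ``factor``."""
        if factor <= 0:
            raise ValueError(f"duration scale factor must be > 0, got {factor}")
        return DurationSpec(self.family, tuple(p * factor for p in self.params))


def sample_duration(spec: DurationSpec, stream: np.random.Generator) -> float:
    """Draw one activity duration (minutes) from ``spec``.

    Draws are truncated below at :data:`DURATION_FLOOR` so a pathological
    tail draw can never produce a non-positive activity time.
    """
    family = spec.family
    if family == "constant":
        x = spec.params[0]
    elif family == "lognormal":
        mean, sd = spec.params
        if sd <= 0:
            x = mean
        else:
            sigma2 = math.log(1.0 + (sd / mean) ** 2)
            mu = math.log(mean) - 0.5 * sigma2
            x = float(stream.lognormal(mu, math.sqrt(sigma2)))
    elif family == "triangular":
        low, mode, high = spec.params
        x = low if low == high else float(stream.triangular(low, mode, high))
    elif family == "exponential":
        x = float(stream.exponential(spec.params[0]))
    else:  # pragma: no cover - guarded by DurationSpec
        raise ValueError(f"unknown duration family {family!r}")
    return x if x > DURATION_FLOOR else DURATION_FLOOR
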