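"""Calendar mapping for the reporting year.

The simulation clock runs in minutes from the start of the warm-up.  The
reporting year is the 52 weeks (364 days) after the warm-up, mapped onto the
12 calendar months of a non-leap year that starts on a Monday; a session or
event belongs to the month containing its start time.  December is therefore
one day short — the price of a whole number of weeks, which keeps weekly
capacity exact.

Resource utilisation is only meaningful against a scheduled operating
window, not the wall clock: here 08:00-18:00 on working days.  The helpers
at the bottom clip arbitrary busy intervals to that window and split them
across month bins.
"""

from __future__ import annotations

import bisect
import math

import numpy as np

from .config import ServiceConfig

__all__ = [
    "MONTH_DAYS",
    "month_edges",
    "month_of",
    "operating_window_minutes",
    "window_overlap",
    "MonthlyBusyBins",
]

MINUTES_PER_DAY = 24 * 60
MINUTES_PER_WEEK = 7 * MINUTES_PER_DAY

#: Days per calendar month, non-leap year; December truncated to 30 days so
#: the 12 months tile the 364-day (52-week) reporting year exactly.
MONTH_DAYS = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 30)

#: Daily operating window for utilisation denominators: 08:00-18:00.
WINDOW_START = 8 * 60
WINDOW_END = 18 * 60


def month_edges(config: ServiceConfig) -> np.ndarray:
    """13 bin edges (minutes) of the reporting year's months."""
    start = config.reporting_start_minute
    return start + np.concatenate(([0.0], np.cumsum(MONTH_DAYS) * MINUTES_PER_DAY))


def month_of(t: float, config: ServiceConfig) -> int | None:
    """0-based month index of simulation minute ``t``, or None outside the
    reporting year."""
    edges = month_edges(config)
    if t < edges[0] or t >= edges[-1]:
        return None
    return int(np.searchsorted(edges, t, side="right") - 1)


def _is_working_day(day: int, config: ServiceConfig) -> bool:
    # day 0 is a Monday
    return day % 7 < config.working_days_per_week


def operating_window_minutes(config: ServiceConfig) -> np.ndarray:
    """Scheduled operating minutes (window x working days) per month."""
    out = np.zeros(12)
    day = 0
    for m, nd in enumerate(MONTH_DAYS):
        workdays = sum(1 for d in range(day, day + nd) if _is_working_day(d, config))
        out[m] = workdays * (WINDOW_END - WINDOW_START)
        day += nd
    return out


def window_overlap(t0: float, t1: float, config: ServiceConfig) -> float:
    """Minutes of [t0, t1) that fall inside the daily operating window."""
    if t1 <= t0:
        return 0.0
    total = 0.0
    day = int(math.floor(t0 / MINUTES_PER_DAY))
    last_day = int(math.ceil(t1 / MINUTES_PER_DAY))
    for d in range(day, last_day):
        if not _is_working_day(d, config):
            continue
        lo = d * MINUTES_PER_DAY + WINDOW_START
        hi = d * MINUTES_PER_DAY + WINDOW_END
        total += max(0.0, min(t1, hi) - max(t0, lo))
    return total


class MonthlyBusyBins:
    """Busy-time integral of one resource pool, binned by reporting month.

    Plugs into :class:`cataractflow.engine.ResourcePool` as its monitor:
    every constant-busy interval is clipped to the operating window and
    apportioned to the month(s) it falls in.  Time outside the reporting
    year (warm-up, spill-over) is discarded.
    """

    def __init__(self, config: ServiceConfig) -> None:
        self.config = config
        self.edges = month_edges(config)
        self._edge_list = [float(e) for e in self.edges]
        self.minutes = np.zeros(12)  # busy unit-minutes inside the window

    def __call__(self, t0: float, t1: float, busy: int) -> None:
        if busy == 0 or t1 <= t0:
            return
        t0 = max(t0, self._edge_list[0])
        t1 = min(t1, self._edge_list[-1])
        if t1 <= t0:
            return
        m0 = bisect.bisect_right(self._edge_list, t0) - 1
        m1 = bisect.bisect_left(self._edge_list, t1) - 1
        for m in range(m0, m1 + 1):
            lo = max(t0, float(self.edges[m]))
            hi = min(t1, float(self.edges[m + 1]))
            if hi > lo:
                self.minutes[m] += busy * window_overlap(lo, hi, self.config)
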