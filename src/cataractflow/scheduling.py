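"""Yearly theatre timetable, FIFO list booking, and the lost-slot rule.

A *list* (or session) is a half-day theatre slot with a fixed booking
capacity — the "patients per list" parameter that the what-if scenarios
vary.  Patients wait on a strictly first-come-first-served
:class:`WaitingList` and are booked into sessions a fixed lead time ahead.
Because these are elective surgeries planned in advance, a slot vacated on
the day by a cancellation or a no-show is *lost*: it cannot be re-allocated,
which is what makes annual throughput sub-linear in list size.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .config import ServiceConfig, ValidationError

__all__ = [
    "SLOT_OUTCOMES",
    "TheatreSession",
    "WaitingList",
    "build_timetable",
    "book_session",
    "book_sessions",
    "apply_lost_slot_rule",
    "reschedule",
]

MINUTES_PER_DAY = 24 * 60
MINUTES_PER_WEEK = 7 * MINUTES_PER_DAY

#: Half-day session start times: 08:00 and 13:00.
AM_START = 8 * 60
PM_START = 13 * 60

SLOT_OUTCOMES = ("completed", "cancelled_unfit", "no_show", "unused")


@dataclass
class TheatreSession:
    """One half-day surgery list: booked patients and per-slot outcomes."""

    session_id: int
    theatre: int
    start: float
    session_minutes: float
    capacity: int
    booked: list[int] = field(default_factory=list)
    slot_outcomes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.slot_outcomes:
            self.slot_outcomes = ["unused"] * self.capacity

    def book(self, patient_id: int) -> int:
        """Book a patient into the next free slot; returns the slot index."""
        if len(self.booked) >= self.capacity:
            raise ValidationError(
                f"session {self.session_id} already holds {self.capacity} patients"
            )
        self.booked.append(patient_id)
        return len(self.booked) - 1

    @property
    def n_completed(self) -> int:
        return self.slot_outcomes.count("completed")

    @property
    def n_lost(self) -> int:
        return sum(
            1 for o in self.slot_outcomes if o in ("cancelled_unfit", "no_show")
        )


class WaitingList:
    """Surgery waiting list, served strictly in listing-time order.

    Entries carry their listing timestamp; ties (same minute) are broken by
    insertion order.  A patient rescheduled after an on-the-day cancellation
    re-enters with a *future* listing time and only becomes eligible for
    booking once that time has passed.
    """

    def __init__(self) -> None:
        self._heap: list[tuple[float, int, int]] = []
        self._seq = 0
        self._members: set[int] = set()

    def push(self, patient_id: int, listed_time: float) -> None:
        if patient_id in self._members:
            raise ValidationError(f"patient {patient_id} is already on the waiting list")
        heapq.heappush(self._heap, (listed_time, self._seq, patient_id))
        self._seq += 1
        self._members.add(patient_id)

    def pop_eligible(self, cutoff: float, k: int) -> list[int]:
        """Remove and return up to ``k`` patients listed at or before ``cutoff``."""
        out: list[int] = []
        while len(out) < k and self._heap and self._heap[0][0] <= cutoff:
            _, _, pid = heapq.heappop(self._heap)
            self._members.discard(pid)
            out.append(pid)
        return out

    def __len__(self) -> int:
        return len(self._heap)

    def __contains__(self, patient_id: int) -> bool:
        return patient_id in self._members


def build_timetable(
    config: ServiceConfig, weeks: Optional[int] = None
) -> list[TheatreSession]:
    """Lay out every half-day session for ``weeks`` weeks (default: warm-up
    plus the reporting year).

    Lists are spread across working days first (one morning session per day),
    then across afternoons, so e.g. 3 lists/week sit on Monday, Tuesday and
    Wednesday mornings.  Total sessions = theatres x lists/week x weeks.
    """
    if weeks is None:
        weeks = config.warmup_weeks + config.weeks_per_year
    lists = config.lists_per_theatre_per_week
    wd = config.working_days_per_week
    if lists > 2 * wd:
        raise ValidationError(
            f"lists_per_theatre_per_week={lists} exceeds {2 * wd} half-day "
            f"sessions available on {wd} working days"
        )
    slots = []  # (day, start-of-day offset) per list, mornings first
    for k in range(lists):
        day, half = k % wd, k // wd
        slots.append((day, AM_START if half == 0 else PM_START))
    slots.sort()
    sessions: list[TheatreSession] = []
    sid = 0
    for week in range(weeks):
        for day, start_of_day in slots:
            for theatre in range(config.theatres):
                sessions.append(
                    TheatreSession(
                        session_id=sid,
                        theatre=theatre,
                        start=week * MINUTES_PER_WEEK + day * MINUTES_PER_DAY + start_of_day,
                        session_minutes=config.session_minutes,
                        capacity=config.patients_per_list,
                    )
                )
                sid += 1
    sessions.sort(key=lambda s: (s.start, s.theatre))
    return sessions


def book_session(
    session: TheatreSession, waiting_list: WaitingList, booking_time: float
) -> list[int]:
    """Fill one session FIFO from patients already listed at ``booking_time``.

    Unfilled slots stay marked ``unused``.  Returns the booked patient ids.
    """
    pids = waiting_list.pop_eligible(booking_time, session.capacity - len(session.booked))
    for pid in pids:
        session.book(pid)
    return pids


def book_sessions(
    waiting_list: WaitingList,
    sessions: Sequence[TheatreSession],
    booking_lead_days: float,
) -> dict[int, list[int]]:
    """Batch-book a sequence of time-ordered sessions.

    Each session is filled from patients listed at least ``booking_lead_days``
    before its start; each patient is booked at most once (removal from the
    list guarantees it).
    """
    bookings: dict[int, list[int]] = {}
    for session in sessions:
        cutoff = session.start - booking_lead_days * MINUTES_PER_DAY
        bookings[session.session_id] = book_session(session, waiting_list, cutoff)
    return bookings


def apply_lost_slot_rule(
    session: TheatreSession, slot_index: int, outcome: str
) -> TheatreSession:
    """Record a slot outcome; cancelled/no-show slots are lost for good.

    No same-day backfill ever happens, so completed surgeries per session
    can never exceed capacity minus lost slots.
    """
    if outcome not in SLOT_OUTCOMES[:3]:
        raise ValidationError(f"invalid slot outcome {outcome!r}")
    if not 0 <= slot_index < session.capacity:
        raise ValidationError(
            f"slot index {slot_index} out of range for capacity {session.capacity}"
        )
    session.slot_outcomes[slot_index] = outcome
    return session


def reschedule(
    patient_id: int,
    outcome: str,
    waiting_list: WaitingList,
    config: ServiceConfig,
    now: float,
    rebook_draw: Optional[float] = None,
) -> bool:
    """Handle a patient whose slot was lost; returns True if they re-join.

    Patients found unfit on the day re-join the list automatically after
    ``unfit_reschedule_delay_weeks``.  No-shows re-join (immediately) with
    probability ``p_noshow_rebooked`` — ``rebook_draw`` is the uniform draw
    to compare against — and otherwise leave the pathway for good.
    """
    if outcome == "cancelled_unfit":
        waiting_list.push(
            patient_id, now + config.unfit_reschedule_delay_weeks * MINUTES_PER_WEEK
        )
        return True
    if outcome == "no_show":
        if rebook_draw is None:
            rebook_draw = 1.0  # deterministic: only rebook when p == 1 impossible
        if rebook_draw < config.p_noshow_rebooked:
            waiting_list.push(patient_id, now)
            return True
        return False
    raise ValidationError(f"reschedule only applies to lost slots, got {outcome!r}")
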