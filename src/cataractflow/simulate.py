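"""Run one full service year: wiring of engine, pathway and scheduling.

:func:`run_simulation` assembles the resource pools, primes the waiting list
(the service is modelled as capacity-saturated, so the list starts full),
generates the referral arrivals, lays out the theatre timetable, schedules
the booking and session events, and drives the event loop over warm-up plus
one reporting year.  The returned :class:`SimulationResult` carries
everything the KPI and finance layers need: per-patient records, per-session
slot outcomes, timed activity records for staff hours, timed events for
counts and revenue, and windowed busy-time bins for utilisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .config import ServiceConfig, planned_weekly_capacity
from .engine import ResourcePool, RngStreams, Simulator
from .pathway import Patient, generate_referrals, patient_journey, patient_surgery_day
from .scheduling import (
    MINUTES_PER_DAY,
    TheatreSession,
    WaitingList,
    book_session,
    build_timetable,
)
from .timebase import MonthlyBusyBins

__all__ = ["SimulationContext", "SimulationResult", "run_simulation"]

#: Pools whose utilisation is reported monthly (theatres are pinned at 100%
#: during their sessions and are excluded from the utilisation report).
MONITORED_POOLS = ("presurgery_rooms", "recovery_chairs", "recovery_beds")


@dataclass
class SimulationContext:
    """Live state shared by all processes during a run."""

    config: ServiceConfig
    sim: Simulator
    rngs: RngStreams
    pools: dict[str, ResourcePool]
    theatre_pools: list[ResourcePool]
    waiting_list: WaitingList
    patients: dict[int, Patient]
    sessions: list[TheatreSession]
    activity_records: list[tuple[float, float, str, str, int]] = field(default_factory=list)
    events: list[tuple[float, str, int]] = field(default_factory=list)
    trace: Optional[list[tuple[float, int, str]]] = None

    def record_activity(
        self, start: float, duration: float, role: str, activity: str, patient_id: int
    ) -> None:
        self.activity_records.append((start, duration, role, activity, patient_id))

    def record_event(self, time: float, kind: str, patient_id: int) -> None:
        self.events.append((time, kind, patient_id))

    def trace_event(self, patient_id: int, event: str) -> None:
        if self.trace is not None:
            self.trace.append((self.sim.clock, patient_id, event))

    def list_patient(self, patient: Patient) -> None:
        patient.listed_time = self.sim.clock
        self.waiting_list.push(patient.id, self.sim.clock)
        self.trace_event(patient.id, "listed")


@dataclass
class SimulationResult:
    """Everything observable from one completed run."""

    config: ServiceConfig
    patients: dict[int, Patient]
    sessions: list[TheatreSession]
    activity_records: list[tuple[float, float, str, str, int]]
    events: list[tuple[float, str, int]]
    busy_bins: dict[str, MonthlyBusyBins]
    pools: dict[str, ResourcePool]
    waiting_list: WaitingList
    horizon: float
    trace: Optional[list[tuple[float, int, str]]] = None

    def count_events(self, kind: str, t0: float = 0.0, t1: float = float("inf")) -> int:
        return sum(1 for t, k, _ in self.events if k == kind and t0 <= t < t1)

    def status_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for p in self.patients.values():
            out[p.status] = out.get(p.status, 0) + 1
        return out


def _prime_waiting_list(ctx: SimulationContext, id_start: int) -> int:
    """Seed the waiting list with a saturated-service backlog at t=0.

    The backlog holds warm-up weeks x planned weekly capacity patients, so
    every session can be fully booked from the first week.  Primed patients
    are historical: their examination happened before the run, so they incur
    no outpatient workload here and are excluded from referral-to-discharge
    statistics.
    """
    cfg = ctx.config
    n = cfg.warmup_weeks * planned_weekly_capacity(cfg)
    for i in range(n):
        pid = id_start + i
        p = Patient(
            id=pid,
            elderly=bool(ctx.rngs.arrivals.random() < cfg.p_elderly),
            source="optometrist",
            referral_time=0.0,
            primed=True,
            listed_time=0.0,
        )
        ctx.patients[pid] = p
        ctx.waiting_list.push(pid, 0.0)
    return n


def run_simulation(
    config: ServiceConfig,
    seed: Union[int, RngStreams, np.random.SeedSequence],
    referrals: Optional[Sequence[Patient]] = None,
    collect_trace: bool = False,
) -> SimulationResult:
    """Simulate warm-up plus one reporting year and return the raw results.

    ``referrals`` overrides the stochastic arrival process with an explicit
    patient sequence (used for hand-traceable and degenerate runs).  The same
    seed always produces the bit-identical trajectory.
    """
    rngs = seed if isinstance(seed, RngStreams) else RngStreams(seed)
    sim = Simulator()
    horizon = config.horizon_minutes

    busy_bins = {name: MonthlyBusyBins(config) for name in MONITORED_POOLS}
    pools = {
        "doctors": ResourcePool(sim, "doctors", config.doctors),
        "nurses": ResourcePool(sim, "nurses", config.nurses),
        "consult_rooms": ResourcePool(sim, "consult_rooms", config.consult_rooms),
        "presurgery_rooms": ResourcePool(
            sim, "presurgery_rooms", config.presurgery_rooms,
            monitor=busy_bins["presurgery_rooms"],
        ),
        "recovery_chairs": ResourcePool(
            sim, "recovery_chairs", config.recovery_chairs,
            monitor=busy_bins["recovery_chairs"],
        ),
        "recovery_beds": ResourcePool(
            sim, "recovery_beds", config.recovery_beds,
            monitor=busy_bins["recovery_beds"],
        ),
    }
    theatre_pools = [
        ResourcePool(sim, f"theatre_{i}", 1) for i in range(config.theatres)
    ]

    sessions = build_timetable(config)
    ctx = SimulationContext(
        config=config,
        sim=sim,
        rngs=rngs,
        pools=pools,
        theatre_pools=theatre_pools,
        waiting_list=WaitingList(),
        patients={},
        sessions=sessions,
        trace=[] if collect_trace else None,
    )

    n_primed = _prime_waiting_list(ctx, id_start=0)

    if referrals is None:
        referrals = generate_referrals(
            config, horizon, rngs.arrivals, id_start=n_primed
        )
    for p in referrals:
        ctx.patients[p.id] = p
        sim.schedule(
            p.referral_time,
            (lambda pat: (lambda: sim.process(patient_journey(ctx, pat))))(p),
        )

    for session in sessions:
        booking_time = max(0.0, session.start - config.booking_lead_days * MINUTES_PER_DAY)
        sim.schedule(
            booking_time,
            (lambda s, bt: (lambda: _booking_event(ctx, s, bt)))(session, booking_time),
        )
        sim.schedule(
            session.start,
            (lambda s: (lambda: _session_start(ctx, s)))(session),
        )

    sim.run_until(horizon)
    for pool in list(pools.values()) + theatre_pools:
        pool.flush(horizon)

    return SimulationResult(
        config=config,
        patients=ctx.patients,
        sessions=sessions,
        activity_records=ctx.activity_records,
        events=ctx.events,
        busy_bins=busy_bins,
        pools=pools,
        waiting_list=ctx.waiting_list,
        horizon=horizon,
        trace=ctx.trace,
    )


def _booking_event(ctx: SimulationContext, session: TheatreSession, now: float) -> None:
    for pid in book_session(session, ctx.waiting_list, now):
        patient = ctx.patients[pid]
        patient.surgery_booked_time = now
        ctx.record_event(now, "booked", pid)
        ctx.trace_event(pid, "booked")


def _session_start(ctx: SimulationContext, session: TheatreSession) -> None:
    for slot, pid in enumerate(session.booked):
        ctx.sim.process(
            patient_surgery_day(ctx, ctx.patients[pid], session, slot)
        )
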