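"""The patient journey, from referral to same-day discharge.

Referrals arrive from community optometrists and from other hospital
services (e.g. Diabetes clinics spotting a suspected cataract); both enter
the same outpatient eye examination, which has four possible outcomes:
not suitable for surgery, listed directly, listed after a pre-operative
clinic assessment, or listed after a pre-operative phone assessment.

On the day of surgery a specialised nurse runs pre-surgery tests (dilating,
blood pressure, eye scan and lens measurements); a patient can still be
found unfit and cancelled, or may simply not show up — in either case the
theatre slot is lost.  Surgery itself takes around twenty minutes under
(usually local) anaesthesia.  Local-anaesthetic patients recover on a
chair, general-anaesthetic patients on a bed, and elderly local patients
sometimes on a bed too; almost everyone goes home the same day.

The generator functions at the bottom are processes over the
:mod:`cataractflow.engine` kernel; the ``ctx`` argument is the live
simulation state assembled by :mod:`cataractflow.simulate`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .config import ServiceConfig
from .engine import RngStreams, acquire, hold, release, sample_duration
from .scheduling import (
    MINUTES_PER_DAY,
    MINUTES_PER_WEEK,
    TheatreSession,
    apply_lost_slot_rule,
    reschedule,
)

__all__ = [
    "EXAM_OUTCOMES",
    "Patient",
    "generate_referrals",
    "draw_exam_outcome",
    "draw_slot_loss",
    "route_recovery",
    "patient_journey",
    "patient_surgery_day",
]

EXAM_OUTCOMES = ("not_suitable", "listed_direct", "preop_clinic", "preop_phone")

#: Referrals arrive during outpatient hours, 08:00-17:00.
ARRIVAL_WINDOW = (8 * 60, 17 * 60)


@dataclass
class Patient:
    """One simulated individual and their pathway timestamps (minutes)."""

    id: int
    elderly: bool
    source: str  # "optometrist" | "internal"
    referral_time: float
    primed: bool = False  # pre-existing waiting-list member (warm start)
    anaesthesia: Optional[str] = None  # "local" | "general"
    exam_time: Optional[float] = None
    listed_time: Optional[float] = None
    surgery_booked_time: Optional[float] = None
    surgery_done_time: Optional[float] = None
    discharge_time: Optional[float] = None
    recovery_location: Optional[str] = None  # "chair" | "bed"
    status: str = "in_pathway"

    @property
    def completed(self) -> bool:
        return self.status in ("completed", "overnight_then_discharged")

    def timestamps_in_order(self) -> bool:
        seq = [
            self.referral_time,
            self.exam_time,
            self.listed_time,
            self.surgery_booked_time,
            self.surgery_done_time,
            self.discharge_time,
        ]
        known = [t for t in seq if t is not None]
        return all(a <= b for a, b in zip(known, known[1:]))


def generate_referrals(
    config: ServiceConfig,
    horizon: float,
    stream: np.random.Generator,
    id_start: int = 0,
) -> list[Patient]:
    """Draw the full referral arrival sequence up to ``horizon``.

    Two superposed Poisson streams (optometrist and internal-hospital), with
    arrivals landing on working days during outpatient hours.  Each patient's
    elderly flag is drawn with probability ``p_elderly``.
    """
    n_days = int(math.ceil(horizon / MINUTES_PER_DAY))
    lo, hi = ARRIVAL_WINDOW
    arrivals: list[tuple[float, str]] = []
    for source, weekly_rate in (
        ("optometrist", config.referral_rate_optometrist),
        ("internal", config.referral_rate_internal),
    ):
        if weekly_rate <= 0:
            continue
        daily_rate = weekly_rate / config.working_days_per_week
        for day in range(n_days):
            if day % 7 >= config.working_days_per_week:
                continue
            n = int(stream.poisson(daily_rate))
            if n == 0:
                continue
            times = day * MINUTES_PER_DAY + lo + stream.random(n) * (hi - lo)
            arrivals.extend((float(t), source) for t in times if t < horizon)
    arrivals.sort(key=lambda x: x[0])
    patients = []
    for i, (t, source) in enumerate(arrivals):
        patients.append(
            Patient(
                id=id_start + i,
                elderly=bool(stream.random() < config.p_elderly),
                source=source,
                referral_time=t,
            )
        )
    return patients


def draw_exam_outcome(config: ServiceConfig, stream: np.random.Generator) -> str:
    """Four-way examination outcome, drawn from ``exam_outcome_probs``."""
    u = stream.random()
    acc = 0.0
    for outcome, p in zip(EXAM_OUTCOMES, config.exam_outcome_probs):
        acc += p
        if u < acc:
            return outcome
    return EXAM_OUTCOMES[-1]  # guard against rounding at u ~ 1

def draw_slot_loss(
    patient: Patient,
    config: ServiceConfig,
    attendance_stream: np.random.Generator,
    outcome_stream: np.random.Generator,
) -> str:
    """Day-of-surgery slot fate before anaesthesia: did the slot survive?

    Returns ``no_show`` (age-band attendance behaviour), ``cancelled_unfit``
    (failed pre-surgery assessment) or ``proceed``.  The two draws use their
    dedicated streams so attendance behaviour is comparable across scenarios.
    """
    p_ns = config.p_noshow_elderly if patient.elderly else config.p_noshow_other
    if attendance_stream.random() < p_ns:
        return "no_show"
    if outcome_stream.random() < config.p_unfit_on_day:
        return "cancelled_unfit"
    return "proceed"


def route_recovery(
    patient: Patient, config: ServiceConfig, stream: np.random.Generator
) -> str:
    """Post-surgery recovery resource: chair or bed.

    General anaesthesia always needs a bed; local-anaesthetic patients take a
    chair, except elderly ones who get a bed with ``p_bed_local_elderly``.
    """
    if patient.anaesthesia == "general":
        return "bed"
    if patient.elderly and stream.random() < config.p_bed_local_elderly:
        return "bed"
    return "chair"


# -- engine processes --------------------------------------------------------


def patient_journey(ctx, patient: Patient):
    """Referral -> eye examination -> (four outcomes) -> waiting list."""
    cfg: ServiceConfig = ctx.config
    sim = ctx.sim
    ctx.trace_event(patient.id, "referral")
    # outpatient eye examination: one doctor and one consultation room
    yield acquire(ctx.pools["doctors"])
    yield acquire(ctx.pools["consult_rooms"])
    start = sim.clock
    ctx.trace_event(patient.id, "exam_start")
    dur = sample_duration(cfg.durations["eye_exam"], ctx.rngs.durations)
    yield hold(dur)
    yield release(ctx.pools["consult_rooms"])
    yield release(ctx.pools["doctors"])
    patient.exam_time = sim.clock
    ctx.record_activity(start, dur, "doctor", "eye_exam", patient.id)
    ctx.record_event(sim.clock, "first_appointment", patient.id)
    ctx.trace_event(patient.id, "exam_end")

    outcome = draw_exam_outcome(cfg, ctx.rngs.outcomes)
    if outcome == "not_suitable":
        patient.status = "not_suitable"
        ctx.trace_event(patient.id, "not_suitable")
        return
    if outcome == "preop_clinic":
        # face-to-face pre-operative assessment: nurse + pre-surgery room
        yield acquire(ctx.pools["nurses"])
        yield acquire(ctx.pools["presurgery_rooms"])
        start = sim.clock
        dur = sample_duration(cfg.durations["preop_clinic"], ctx.rngs.durations)
        yield hold(dur)
        yield release(ctx.pools["presurgery_rooms"])
        yield release(ctx.pools["nurses"])
        ctx.record_activity(start, dur, "nurse", "preop_clinic", patient.id)
        ctx.record_event(sim.clock, "preop_clinic", patient.id)
    elif outcome == "preop_phone":
        # phone assessment: nurse time only, no room
        yield acquire(ctx.pools["nurses"])
        start = sim.clock
        dur = sample_duration(cfg.durations["preop_phone"], ctx.rngs.durations)
        yield hold(dur)
        yield release(ctx.pools["nurses"])
        ctx.record_activity(start, dur, "nurse", "preop_phone", patient.id)
        ctx.record_event(sim.clock, "preop_phone", patient.id)
    ctx.list_patient(patient)


def patient_surgery_day(ctx, patient: Patient, session: TheatreSession, slot: int):
    """One booked patient's day of surgery, recovery and discharge."""
    cfg: ServiceConfig = ctx.config
    sim = ctx.sim
    fate = draw_slot_loss(patient, cfg, ctx.rngs.attendance, ctx.rngs.outcomes)
    if fate == "no_show":
        apply_lost_slot_rule(session, slot, "no_show")
        patient.status = "no_show"
        ctx.record_event(sim.clock, "no_show", patient.id)
        ctx.trace_event(patient.id, "no_show")
        if reschedule(
            patient.id, "no_show", ctx.waiting_list, cfg, sim.clock,
            ctx.rngs.outcomes.random(),
        ):
            patient.status = "in_pathway"
            ctx.record_event(sim.clock, "rebooked_after_no_show", patient.id)
        return

    # pre-surgery assessment by a specialised nurse in a pre-surgery room
    yield acquire(ctx.pools["nurses"])
    yield acquire(ctx.pools["presurgery_rooms"])
    start = sim.clock
    dur = sample_duration(cfg.durations["presurgery_tests"], ctx.rngs.durations)
    yield hold(dur)
    yield release(ctx.pools["presurgery_rooms"])
    yield release(ctx.pools["nurses"])
    ctx.record_activity(start, dur, "nurse", "presurgery_tests", patient.id)

    if fate == "cancelled_unfit":
        apply_lost_slot_rule(session, slot, "cancelled_unfit")
        patient.status = "cancelled_unfit"
        ctx.record_event(sim.clock, "cancelled_unfit", patient.id)
        ctx.trace_event(patient.id, "cancelled_unfit")
        reschedule(patient.id, "cancelled_unfit", ctx.waiting_list, cfg, sim.clock)
        patient.status = "in_pathway"  # will be re-listed after the delay
        return

    # anaesthesia (mostly local), then surgery by a doctor in the theatre
    patient.anaesthesia = (
        "general"
        if ctx.rngs.outcomes.random() < cfg.p_general_anaesthesia
        else "local"
    )
    an_name = "anaesthesia_general" if patient.anaesthesia == "general" else "anaesthesia_local"
    an_dur = sample_duration(cfg.durations[an_name], ctx.rngs.durations)
    yield acquire(ctx.theatre_pools[session.theatre])
    yield hold(an_dur)
    yield acquire(ctx.pools["doctors"])
    start = sim.clock
    ctx.trace_event(patient.id, "surgery_start")
    dur = sample_duration(cfg.durations["surgery"], ctx.rngs.durations)
    yield hold(dur)
    yield release(ctx.pools["doctors"])
    yield release(ctx.theatre_pools[session.theatre])
    patient.surgery_done_time = sim.clock
    session.slot_outcomes[slot] = "completed"
    ctx.record_activity(start, dur, "doctor", "surgery", patient.id)
    ctx.record_event(sim.clock, "surgery", patient.id)
    ctx.trace_event(patient.id, "surgery_end")

    # recovery: chair for local anaesthetic, bed for general (and for some
    # elderly local-anaesthetic patients)
    location = route_recovery(patient, cfg, ctx.rngs.outcomes)
    patient.recovery_location = location
    pool = ctx.pools["recovery_chairs" if location == "chair" else "recovery_beds"]
    dur_name = "recovery_chair" if location == "chair" else "recovery_bed"
    yield acquire(pool)
    ctx.trace_event(patient.id, f"recovery_start_{location}")
    yield hold(sample_duration(cfg.durations[dur_name], ctx.rngs.durations))

    overnight = ctx.rngs.outcomes.random() < cfg.p_overnight
    if overnight:
        # kept for observation, discharged at 08:00 the next morning
        next_morning = (math.floor(sim.clock / MINUTES_PER_DAY) + 1) * MINUTES_PER_DAY + 8 * 60
        yield hold(next_morning - sim.clock)
        patient.status = "overnight_then_discharged"
    else:
        patient.status = "completed"
    yield release(pool)
    patient.discharge_time = sim.clock
    ctx.record_event(sim.clock, "followup", patient.id)
    ctx.record_event(sim.clock, "discharge", patient.id)
    ctx.trace_event(patient.id, "discharge")
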