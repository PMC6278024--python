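"""Timetable construction, FIFO booking, lost slots and rescheduling."""

from __future__ import annotations

import pytest

from cataractflow.config import ValidationError, planned_weekly_capacity
from cataractflow.scheduling import (
    MINUTES_PER_DAY,
    MINUTES_PER_WEEK,
    TheatreSession,
    WaitingList,
    apply_lost_slot_rule,
    book_session,
    book_sessions,
    build_timetable,
    reschedule,
)

from conftest import make_config


class TestBuildTimetable:
    def test_session_count_three_lists_over_year(self):
        cfg = make_config()
        sessions = build_timetable(cfg, weeks=52)
        assert len(sessions) == 3 * 52

    def test_default_span_covers_warmup_plus_year(self):
        cfg = make_config(warmup_weeks=2)
        sessions = build_timetable(cfg)
        assert len(sessions) == 3 * (52 + 2)

    def test_zero_lists_empty_timetable(self):
        cfg = make_config(lists_per_theatre_per_week=0)
        assert build_timetable(cfg) == []

    def test_capacity_propagates_to_every_session(self):
        cfg = make_config(patients_per_list=9)
        assert all(s.capacity == 9 for s in build_timetable(cfg, weeks=4))

    def test_sessions_spread_over_mornings_first(self):
        cfg = make_config()  # 3 lists/week
        week0 = [s for s in build_timetable(cfg, weeks=1)]
        starts = sorted((s.start for s in week0))
        # Monday, Tuesday, Wednesday at 08:00
        assert starts == [8 * 60, MINUTES_PER_DAY + 8 * 60, 2 * MINUTES_PER_DAY + 8 * 60]

    def test_afternoons_used_beyond_five_lists(self):
        cfg = make_config(lists_per_theatre_per_week=6)
        week0 = build_timetable(cfg, weeks=1)
        starts = {s.start % MINUTES_PER_DAY for s in week0}
        assert starts == {8 * 60, 13 * 60}

    def test_sessions_in_time_order(self):
        cfg = make_config(theatres=2, lists_per_theatre_per_week=5)
        sessions = build_timetable(cfg, weeks=3)
        assert [s.start for s in sessions] == sorted(s.start for s in sessions)


class TestWaitingList:
    def test_fifo_by_listing_time_then_insertion(self):
        wl = WaitingList()
        wl.push(1, 100.0)
        wl.push(2, 50.0)
        wl.push(3, 50.0)
        assert wl.pop_eligible(1000.0, 10) == [2, 3, 1]

    def test_future_listings_not_eligible(self):
        wl = WaitingList()
        wl.push(1, 10.0)
        wl.push(2, 500.0)
        assert wl.pop_eligible(100.0, 10) == [1]
        assert len(wl) == 1

    def test_duplicate_membership_rejected(self):
        wl = WaitingList()
        wl.push(1, 0.0)
        with pytest.raises(ValidationError):
            wl.push(1, 5.0)


class TestBooking:
    def _session(self, start=10_000.0, capacity=6):
        return TheatreSession(
            session_id=0, theatre=0, start=start, session_minutes=240, capacity=capacity
        )

    def test_underfilled_session_leaves_unused_slots(self):
        wl = WaitingList()
        for pid in range(4):
            wl.push(pid, 0.0)
        s = self._session()
        booked = book_session(s, wl, booking_time=s.start)
        assert len(booked) == 4
        assert s.slot_outcomes.count("unused") == 6  # outcomes resolved on the day
        assert len(s.booked) == 4

    def test_overfull_list_books_first_six_fifo(self):
        wl = WaitingList()
        for pid in range(10):
            wl.push(pid, float(pid))
        s = self._session()
        booked = book_session(s, wl, booking_time=s.start)
        assert booked == [0, 1, 2, 3, 4, 5]
        assert len(wl) == 4

    def test_lead_time_rule_excludes_late_listings(self):
        wl = WaitingList()
        lead_days = 7.0
        s = self._session(start=20 * MINUTES_PER_DAY)
        cutoff = s.start - lead_days * MINUTES_PER_DAY
        wl.push(1, cutoff - 1.0)  # in time
        wl.push(2, cutoff + 1.0)  # too late for this session
        bookings = book_sessions(wl, [s], booking_lead_days=lead_days)
        assert bookings[0] == [1]
        assert 2 in wl

    def test_each_patient_booked_at_most_once(self):
        wl = WaitingList()
        for pid in range(8):
            wl.push(pid, 0.0)
        sessions = [self._session(), self._session()]
        sessions[1].session_id = 1
        bookings = book_sessions(wl, sessions, booking_lead_days=0.0)
        flat = bookings[0] + bookings[1]
        assert len(flat) == len(set(flat)) == 8


class TestLostSlotRule:
    def test_lost_slots_cap_completions(self):
        s = TheatreSession(0, 0, 0.0, 240, capacity=6)
        for pid in range(6):
            s.book(pid)
        apply_lost_slot_rule(s, 0, "no_show")
        apply_lost_slot_rule(s, 1, "cancelled_unfit")
        for slot in range(2, 6):
            s.slot_outcomes[slot] = "completed"
        assert s.n_lost == 2
        assert s.n_completed == 4
        assert s.n_completed <= s.capacity - s.n_lost

    def test_no_cancellations_all_booked_complete(self):
        s = TheatreSession(0, 0, 0.0, 240, capacity=6)
        for pid in range(6):
            s.book(pid)
            s.slot_outcomes[pid] = "completed"
        assert s.n_completed == len(s.booked) == 6

    def test_invalid_outcome_rejected(self):
        s = TheatreSession(0, 0, 0.0, 240, capacity=6)
        with pytest.raises(ValidationError):
            apply_lost_slot_rule(s, 0, "vanished")
        with pytest.raises(ValidationError):
            apply_lost_slot_rule(s, 6, "no_show")


class TestReschedule:
    def test_unfit_relisted_after_exact_delay(self):
        cfg = make_config(unfit_reschedule_delay_weeks=2.0)
        wl = WaitingList()
        now = 1000.0
        assert reschedule(7, "cancelled_unfit", wl, cfg, now)
        relist = now + 2 * MINUTES_PER_WEEK
        assert wl.pop_eligible(relist - 1.0, 10) == []
        assert wl.pop_eligible(relist, 10) == [7]

    def test_no_show_never_rebooked_at_probability_zero(self):
        cfg = make_config(p_noshow_rebooked=0.0)
        wl = WaitingList()
        assert not reschedule(7, "no_show", wl, cfg, 0.0, rebook_draw=0.5)
        assert len(wl) == 0

    def test_no_show_always_rebooked_at_probability_one(self):
        cfg = make_config(p_noshow_rebooked=1.0)
        wl = WaitingList()
        assert reschedule(7, "no_show", wl, cfg, 0.0, rebook_draw=0.999)
        assert 7 in wl

    def test_only_lost_slot_outcomes_accepted(self):
        wl = WaitingList()
        with pytest.raises(ValidationError):
            reschedule(7, "completed", wl, make_config(), 0.0)


class TestCapacityBounds:
    def test_annual_surgeries_never_exceed_hard_capacity(self, default_run):
        cfg = default_run.config
        hard_cap = planned_weekly_capacity(cfg) * cfg.weeks_per_year
        r0 = cfg.reporting_start_minute
        r1 = r0 + cfg.weeks_per_year * MINUTES_PER_WEEK
        assert default_run.count_events("surgery", r0, r1) <= hard_cap

    def test_saturated_lossfree_sessions_all_complete(self, saturated_run):
        # zero no-shows, zero unfit, demand above capacity: every session in
        # the reporting year completes exactly its capacity
        cfg = saturated_run.config
        r0 = cfg.reporting_start_minute
        year_sessions = [s for s in saturated_run.sessions if s.start >= r0]
        assert year_sessions
        for s in year_sessions:
            assert len(s.booked) == s.capacity
            assert s.n_completed == s.capacity
            assert s.n_lost == 0
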