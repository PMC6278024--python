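"""Patient journey: referrals, examination outcomes, day of surgery, recovery."""

from __future__ import annotations

import math

import numpy as np
import pytest

from cataractflow.pathway import (
    EXAM_OUTCOMES,
    Patient,
    draw_exam_outcome,
    draw_slot_loss,
    generate_referrals,
    route_recovery,
)
from cataractflow.simulate import run_simulation
from cataractflow.synthetic import estimate_loss_probabilities

from conftest import make_config

WEEK = 7 * 24 * 60


class TestGenerateReferrals:
    def test_zero_rates_give_no_patients(self):
        cfg = make_config(referral_rate_optometrist=0.0, referral_rate_internal=0.0)
        assert generate_referrals(cfg, 52 * WEEK, np.random.default_rng(0)) == []

    def test_poisson_count_at_expected_scale(self):
        # rate 100/week over 52 weeks: count within 3 standard deviations
        # of the Poisson mean 5200
        cfg = make_config(referral_rate_optometrist=100.0)
        pts = generate_referrals(cfg, 52 * WEEK, np.random.default_rng(11))
        assert abs(len(pts) - 5200) < 3 * math.sqrt(5200)

    def test_all_elderly_when_probability_one(self):
        cfg = make_config(referral_rate_optometrist=20.0, p_elderly=1.0)
        pts = generate_referrals(cfg, 4 * WEEK, np.random.default_rng(2))
        assert pts and all(p.elderly for p in pts)

    def test_arrivals_on_working_days_in_time_order(self):
        cfg = make_config(referral_rate_optometrist=50.0, referral_rate_internal=10.0)
        pts = generate_referrals(cfg, 8 * WEEK, np.random.default_rng(3))
        times = [p.referral_time for p in pts]
        assert times == sorted(times)
        for t in times:
            day = int(t // (24 * 60))
            assert day % 7 < cfg.working_days_per_week
            minute = t % (24 * 60)
            assert 8 * 60 <= minute < 17 * 60

    def test_both_sources_present(self):
        cfg = make_config(referral_rate_optometrist=30.0, referral_rate_internal=30.0)
        pts = generate_referrals(cfg, 8 * WEEK, np.random.default_rng(4))
        sources = {p.source for p in pts}
        assert sources == {"optometrist", "internal"}


class TestExamOutcome:
    def test_degenerate_not_suitable(self):
        cfg = make_config(exam_outcome_probs=(1.0, 0.0, 0.0, 0.0))
        rng = np.random.default_rng(0)
        assert all(draw_exam_outcome(cfg, rng) == "not_suitable" for _ in range(50))

    def test_degenerate_phone_route(self):
        cfg = make_config(exam_outcome_probs=(0.0, 0.0, 0.0, 1.0))
        rng = np.random.default_rng(0)
        assert all(draw_exam_outcome(cfg, rng) == "preop_phone" for _ in range(50))

    def test_empirical_frequencies_match_configured_probabilities(self):
        probs = (0.2, 0.3, 0.3, 0.2)
        cfg = make_config(exam_outcome_probs=probs)
        rng = np.random.default_rng(5)
        n = 10_000
        counts = {o: 0 for o in EXAM_OUTCOMES}
        for _ in range(n):
            counts[draw_exam_outcome(cfg, rng)] += 1
        for outcome, p in zip(EXAM_OUTCOMES, probs):
            sd = math.sqrt(n * p * (1 - p))
            assert abs(counts[outcome] - n * p) < 3 * sd


class TestPreopAssessment:
    def test_phone_route_never_touches_presurgery_room(self):
        # all patients take the phone pre-op; with no theatre lists the
        # pre-surgery rooms are never used at all, while nurses are
        cfg = make_config(
            exam_outcome_probs=(0.0, 0.0, 0.0, 1.0),
            lists_per_theatre_per_week=0,
            referral_rate_optometrist=5.0,
            warmup_weeks=0,
        )
        result = run_simulation(cfg, seed=1)
        assert result.count_events("preop_phone") > 0
        assert result.pools["presurgery_rooms"].busy_time_accumulator == 0.0
        assert result.pools["nurses"].busy_time_accumulator > 0.0

    def test_clinic_route_room_time_matches_constant_duration(self):
        # every pre-op clinic visit holds a room for exactly the constant
        # 30-minute assessment
        cfg = make_config(
            exam_outcome_probs=(0.0, 0.0, 1.0, 0.0),
            lists_per_theatre_per_week=0,
            referral_rate_optometrist=5.0,
            warmup_weeks=0,
        )
        result = run_simulation(cfg, seed=1)
        n = result.count_events("preop_clinic")
        assert n > 0
        assert result.pools["presurgery_rooms"].busy_time_accumulator == pytest.approx(
            30.0 * n
        )


class TestDayOfSurgery:
    def test_no_losses_means_every_slot_proceeds(self):
        cfg = make_config()
        rng_a, rng_o = np.random.default_rng(1), np.random.default_rng(2)
        p = Patient(id=0, elderly=False, source="optometrist", referral_time=0)
        assert all(
            draw_slot_loss(p, cfg, rng_a, rng_o) == "proceed" for _ in range(100)
        )

    def test_expected_completions_per_session_binomial_thinning(self):
        # mean completed per 6-slot session = 6 (1-p_ns)(1-p_unfit) over
        # 10^4 simulated sessions of a single age band
        p_ns, p_unfit, cap = 0.1, 0.05, 6
        cfg = make_config(p_noshow_other=p_ns, p_unfit_on_day=p_unfit)
        rng_a, rng_o = np.random.default_rng(8), np.random.default_rng(9)
        n_sessions = 10_000
        completed = 0
        for _ in range(n_sessions * cap):
            p = Patient(id=0, elderly=False, source="optometrist", referral_time=0)
            if draw_slot_loss(p, cfg, rng_a, rng_o) == "proceed":
                completed += 1
        expected = cap * (1 - p_ns) * (1 - p_unfit)
        p_c = (1 - p_ns) * (1 - p_unfit)
        sd_mean = cap * math.sqrt(p_c * (1 - p_c) / (n_sessions * cap))
        assert abs(completed / n_sessions - expected) < 3 * sd_mean

    def test_elderly_no_show_rate_exceeds_other(self, default_run):
        est = estimate_loss_probabilities(default_run)
        assert est["n_booked_elderly"] > 1000
        assert est["p_noshow_elderly"] > est["p_noshow_other"]


class TestRecoveryRouting:
    def _patient(self, elderly, anaesthesia):
        p = Patient(id=0, elderly=elderly, source="optometrist", referral_time=0)
        p.anaesthesia = anaesthesia
        return p

    def test_general_anaesthesia_always_bed(self):
        cfg = make_config(p_bed_local_elderly=0.0)
        rng = np.random.default_rng(0)
        p = self._patient(elderly=False, anaesthesia="general")
        assert all(route_recovery(p, cfg, rng) == "bed" for _ in range(20))

    def test_local_non_elderly_always_chair(self):
        cfg = make_config(p_bed_local_elderly=1.0)
        rng = np.random.default_rng(0)
        p = self._patient(elderly=False, anaesthesia="local")
        assert all(route_recovery(p, cfg, rng) == "chair" for _ in range(20))

    def test_local_elderly_bed_when_probability_one(self):
        cfg = make_config(p_bed_local_elderly=1.0)
        rng = np.random.default_rng(0)
        p = self._patient(elderly=True, anaesthesia="local")
        assert all(route_recovery(p, cfg, rng) == "bed" for _ in range(20))


class TestDischarge:
    def test_no_overnight_means_same_day_discharge(self, saturated_run):
        completed = [p for p in saturated_run.patients.values() if p.completed]
        assert completed
        for p in completed:
            assert p.status == "completed"  # never overnight_then_discharged
            assert int(p.discharge_time // (24 * 60)) == int(
                p.surgery_done_time // (24 * 60)
            )

    def test_all_overnight_discharged_next_morning(self):
        cfg = make_config(
            p_overnight=1.0,
            referral_rate_optometrist=10.0,
            warmup_weeks=1,
            recovery_beds=8,  # bed held until 08:00, so give slack
            recovery_chairs=8,
        )
        result = run_simulation(cfg, seed=3)
        completed = [p for p in result.patients.values() if p.completed]
        assert completed
        for p in completed:
            assert p.status == "overnight_then_discharged"
            assert p.discharge_time % (24 * 60) == 8 * 60
            assert int(p.discharge_time // (24 * 60)) == int(
                p.surgery_done_time // (24 * 60)
            ) + 1

    def test_overnight_fraction_at_configured_rate(self):
        p_on = 0.3
        cfg = make_config(
            p_overnight=p_on,
            referral_rate_optometrist=25.0,
            recovery_beds=8,
            recovery_chairs=8,
        )
        result = run_simulation(cfg, seed=4)
        completed = [p for p in result.patients.values() if p.completed]
        n = len(completed)
        k = sum(1 for p in completed if p.status == "overnight_then_discharged")
        assert n > 500
        assert abs(k / n - p_on) < 3 * math.sqrt(p_on * (1 - p_on) / n)


class TestPathwayInvariants:
    def test_flow_conservation_by_final_status(self, default_run):
        counts = default_run.status_counts()
        allowed = {
            "in_pathway",
            "not_suitable",
            "completed",
            "overnight_then_discharged",
            "no_show",
        }
        assert set(counts) <= allowed
        assert sum(counts.values()) == len(default_run.patients)
        n_completed = counts.get("completed", 0) + counts.get(
            "overnight_then_discharged", 0
        )
        assert n_completed == default_run.count_events("surgery")

    def test_timestamps_non_decreasing_in_pathway_order(self, default_run):
        assert all(p.timestamps_in_order() for p in default_run.patients.values())

    def test_referral_to_discharge_positive(self, default_run):
        for p in default_run.patients.values():
            if p.completed and not p.primed:
                assert p.discharge_time > p.referral_time
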