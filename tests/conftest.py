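"""Shared fixtures: deterministic micro-configs and one cached default run."""

from __future__ import annotations

import pytest

from cataractflow.config import ServiceConfig
from cataractflow.engine import DurationSpec
from cataractflow.simulate import run_simulation
from cataractflow.synthetic import default_parameters

#: Constant (degenerate) activity durations for hand-traceable runs.
CONSTANT_DURATIONS = {
    "eye_exam": DurationSpec("constant", (30.0,)),
    "preop_clinic": DurationSpec("constant", (30.0,)),
    "preop_phone": DurationSpec("constant", (10.0,)),
    "presurgery_tests": DurationSpec("constant", (20.0,)),
    "anaesthesia_local": DurationSpec("constant", (10.0,)),
    "anaesthesia_general": DurationSpec("constant", (15.0,)),
    "surgery": DurationSpec("constant", (20.0,)),
    "recovery_chair": DurationSpec("constant", (30.0,)),
    "recovery_bed": DurationSpec("constant", (60.0,)),
}


def make_config(**overrides) -> ServiceConfig:
    """A small, fully deterministic service: every branching probability is
    degenerate and every duration constant, so outcomes are hand-computable.

    Defaults describe a saturated single-theatre service (3 lists/week of 6)
    with demand of 40 listed patients/week against 18 slots/week.
    """
    base = dict(
        referral_rate_optometrist=40.0,
        referral_rate_internal=0.0,
        exam_outcome_probs=(0.0, 1.0, 0.0, 0.0),
        p_unfit_on_day=0.0,
        p_noshow_elderly=0.0,
        p_noshow_other=0.0,
        p_elderly=0.0,
        p_general_anaesthesia=0.0,
        p_bed_local_elderly=0.0,
        p_overnight=0.0,
        durations=dict(CONSTANT_DURATIONS),
        theatres=1,
        lists_per_theatre_per_week=3,
        patients_per_list=6,
        consult_rooms=2,
        presurgery_rooms=2,
        recovery_chairs=2,
        recovery_beds=1,
        doctors=2,
        nurses=2,
        tariff_surgery=700.0,
        tariff_first_appointment=25.0,
        tariff_followup=18.0,
        hourly_cost_doctor=100.0,
        hourly_cost_nurse=40.0,
        warmup_weeks=2,
    )
    base.update(overrides)
    return ServiceConfig(**base)


@pytest.fixture(scope="session")
def default_config() -> ServiceConfig:
    return default_parameters()


@pytest.fixture(scope="session")
def saturated_config() -> ServiceConfig:
    """Saturated, loss-free single-theatre service (capacity-identity case)."""
    return make_config()


@pytest.fixture(scope="session")
def default_run(default_config):
    """One full baseline year with the shipped synthetic defaults."""
    return run_simulation(default_config, seed=123)


@pytest.fixture(scope="session")
def saturated_run(saturated_config):
    """One full year of the deterministic saturated service."""
    return run_simulation(saturated_config, seed=7)
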