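"""Service parameters, validation, file I/O and what-if scenarios.

A :class:`ServiceConfig` holds every numerical parameter of the cataract
service model: referral demand, examination-outcome branching, day-of-surgery
attendance behaviour, activity-duration distributions, resource counts, the
theatre timetable shape, and the tariff/cost rates used by the finance layer.

Configurations live in a flat YAML file (one key per field; durations as a
small nested mapping).  The four published what-if scenarios — 6, 7, 8 or 9
patients per half-day theatre list, with process-time reductions that make
the larger lists feasible — are expressed as :class:`ScenarioSpec` deltas and
applied with :func:`apply_scenario`, which never mutates its input.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Union

import yaml

from .engine import DurationSpec

__all__ = [
    "SchemaError",
    "ValidationError",
    "DURATION_NAMES",
    "ServiceConfig",
    "ScenarioSpec",
    "SCENARIO_NAMES",
    "builtin_scenario",
    "apply_scenario",
    "planned_weekly_capacity",
    "load_config",
    "save_config",
]


class SchemaError(KeyError):
    """A required key is missing or a key is unknown in a config file."""


class ValidationError(ValueError):
    """A parameter value is outside its documented bounds."""


#: Activities whose durations must be specified, in pathway order.
DURATION_NAMES = (
    "eye_exam",
    "preop_clinic",
    "preop_phone",
    "presurgery_tests",
    "anaesthesia_local",
    "anaesthesia_general",
    "surgery",
    "recovery_chair",
    "recovery_bed",
)

_PROB_FIELDS = (
    "p_unfit_on_day",
    "p_noshow_elderly",
    "p_noshow_other",
    "p_elderly",
    "p_general_anaesthesia",
    "p_bed_local_elderly",
    "p_overnight",
    "p_noshow_rebooked",
)

_COUNT_FIELDS = (
    "theatres",
    "lists_per_theatre_per_week",
    "patients_per_list",
    "consult_rooms",
    "presurgery_rooms",
    "recovery_chairs",
    "recovery_beds",
    "doctors",
    "nurses",
    "working_days_per_week",
    "weeks_per_year",
    "warmup_weeks",
)

_NONNEG_REAL_FIELDS = (
    "referral_rate_optometrist",
    "referral_rate_internal",
    "tariff_surgery",
    "tariff_first_appointment",
    "tariff_followup",
    "tariff_preop_clinic",
    "hourly_cost_doctor",
    "hourly_cost_nurse",
    "cost_per_surgery_other",
    "unfit_reschedule_delay_weeks",
    "booking_lead_days",
)


@dataclass(frozen=True)
class ServiceConfig:
    """All numerical parameters of the cataract service model.

    Rates are per week, durations in minutes, money in GBP (converted to
    integer pence inside the finance layer).  ``exam_outcome_probs`` is the
    four-way branching after the outpatient eye examination, in the order
    (not_suitable, listed_direct, preop_clinic, preop_phone) and must sum
    to 1.
    """

    # demand
    referral_rate_optometrist: float
    referral_rate_internal: float
    # branching probabilities
    exam_outcome_probs: tuple[float, float, float, float]
    p_unfit_on_day: float
    p_noshow_elderly: float
    p_noshow_other: float
    p_elderly: float
    p_general_anaesthesia: float
    p_bed_local_elderly: float
    p_overnight: float
    # activity durations (minutes)
    durations: Mapping[str, DurationSpec]
    # theatre capacity
    theatres: int
    lists_per_theatre_per_week: int
    patients_per_list: int
    # other resources
    consult_rooms: int
    presurgery_rooms: int
    recovery_chairs: int
    recovery_beds: int
    doctors: int
    nurses: int
    # money
    tariff_surgery: float
    tariff_first_appointment: float
    tariff_followup: float
    hourly_cost_doctor: float
    hourly_cost_nurse: float
    # timetable & run shape (documented defaults)
    session_minutes: float = 240.0
    working_days_per_week: int = 5
    weeks_per_year: int = 52
    warmup_weeks: int = 6
    booking_lead_days: float = 7.0
    # rebooking behaviour
    unfit_reschedule_delay_weeks: float = 2.0
    p_noshow_rebooked: float = 0.8
    # optional money terms
    tariff_preop_clinic: float = 0.0
    cost_per_surgery_other: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "exam_outcome_probs", tuple(float(p) for p in self.exam_outcome_probs)
        )
        object.__setattr__(self, "durations", dict(self.durations))
        validate_config(self)

    # convenience -----------------------------------------------------------
    @property
    def p_not_suitable(self) -> float:
        return self.exam_outcome_probs[0]

    @property
    def minutes_per_week(self) -> float:
        return 7 * 24 * 60.0

    @property
    def horizon_minutes(self) -> float:
        """Warm-up plus reporting year, in minutes."""
        return (self.warmup_weeks + self.weeks_per_year) * self.minutes_per_week

    @property
    def reporting_start_minute(self) -> float:
        return self.warmup_weeks * self.minutes_per_week


def validate_config(config: ServiceConfig) -> None:
    """Raise :class:`ValidationError` naming the offending field and bound."""
    probs = config.exam_outcome_probs
    if len(probs) != 4:
        raise ValidationError("exam_outcome_probs must have exactly 4 entries")
    for i, p in enumerate(probs):
        if not 0.0 <= p <= 1.0:
            raise ValidationError(f"exam_outcome_probs[{i}]={p} not in [0, 1]")
    if abs(sum(probs) - 1.0) > 1e-9:
        raise ValidationError(
            f"exam_outcome_probs must sum to 1 (got {sum(probs)!r})"
        )
    for name in _PROB_FIELDS:
        p = getattr(config, name)
        if not 0.0 <= p <= 1.0:
            raise ValidationError(f"{name}={p} not in [0, 1]")
    for name in _COUNT_FIELDS:
        v = getattr(config, name)
        if not isinstance(v, int) or v < 0:
            raise ValidationError(f"{name}={v!r} must be a count >= 0")
    for name in _NONNEG_REAL_FIELDS:
        v = getattr(config, name)
        if v < 0:
            raise ValidationError(f"{name}={v} must be >= 0")
    if config.session_minutes <= 0:
        raise ValidationError(f"session_minutes={config.session_minutes} must be > 0")
    if not 1 <= config.working_days_per_week <= 7:
        raise ValidationError(
            f"working_days_per_week={config.working_days_per_week} not in [1, 7]"
        )
    if config.lists_per_theatre_per_week > 2 * config.working_days_per_week:
        raise ValidationError(
            "lists_per_theatre_per_week="
            f"{config.lists_per_theatre_per_week} exceeds "
            f"{2 * config.working_days_per_week} half-day sessions available on "
            f"{config.working_days_per_week} working days"
        )
    missing = [n for n in DURATION_NAMES if n not in config.durations]
    if missing:
        raise ValidationError(f"durations missing entries for: {', '.join(missing)}")
    for name, spec in config.durations.items():
        if name not in DURATION_NAMES:
            raise ValidationError(f"unknown duration name {name!r}")
        if not isinstance(spec, DurationSpec):
            raise ValidationError(f"durations[{name!r}] must be a DurationSpec")
        if spec.mean <= 0:
            raise ValidationError(f"durations[{name!r}] mean {spec.mean} must be > 0")


# -- scenarios ---------------------------------------------------------------

SCENARIO_NAMES = ("baseline", "scenario1", "scenario2", "scenario3")

#: Patients per half-day list under each published scenario.
_SCENARIO_LIST_SIZE = {"baseline": 6, "scenario1": 7, "scenario2": 8, "scenario3": 9}

#: Shipped process-time reductions that make the larger lists feasible:
#: earlier admission shortens the day-of-surgery tests (scenario 1), the 3D
#: eye-imaging machine shortens them further (scenarios 2-3), and preparing
#: the lens during surgery shortens the surgery itself (scenario 3).
_SCENARIO_MULTIPLIERS: dict[str, dict[str, float]] = {
    "baseline": {},
    "scenario1": {"presurgery_tests": 0.85},
    "scenario2": {"presurgery_tests": 0.6},
    "scenario3": {"presurgery_tests": 0.6, "surgery": 0.9},
}


@dataclass(frozen=True)
class ScenarioSpec:
    """A named configuration delta: list size plus duration multipliers."""

    name: str
    patients_per_list: int
    duration_multipliers: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "duration_multipliers", dict(self.duration_multipliers)
        )
        if self.patients_per_list <= 0:
            raise ValidationError(
                f"patients_per_list={self.patients_per_list} must be > 0"
            )
        if self.name in _SCENARIO_LIST_SIZE and self.patients_per_list not in (6, 7, 8, 9):
            raise ValidationError(
                f"{self.name}: patients_per_list must be one of 6, 7, 8, 9"
            )
        for dur, m in self.duration_multipliers.items():
            if m <= 0:
                raise ValidationError(f"duration multiplier {dur}={m} must be > 0")


def builtin_scenario(name: str) -> ScenarioSpec:
    """Return one of the four shipped scenarios by name."""
    if name not in _SCENARIO_LIST_SIZE:
        raise KeyError(f"unknown scenario {name!r}; expected one of {SCENARIO_NAMES}")
    return ScenarioSpec(
        name=name,
        patients_per_list=_SCENARIO_LIST_SIZE[name],
        duration_multipliers=_SCENARIO_MULTIPLIERS[name],
    )


def apply_scenario(config: ServiceConfig, scenario: ScenarioSpec) -> ServiceConfig:
    """Return a new config with the scenario's list size and time savings.

    Pure: the input config is left untouched; each named duration's scale
    parameters are multiplied by the scenario's multiplier.
    """
    durations = dict(config.durations)
    for name, factor in scenario.duration_multipliers.items():
        if name not in durations:
            raise SchemaError(f"scenario {scenario.name!r} scales unknown duration {name!r}")
        durations[name] = durations[name].scaled(factor)
    return replace(
        config, patients_per_list=scenario.patients_per_list, durations=durations
    )


def planned_weekly_capacity(config: ServiceConfig) -> int:
    """Surgeries planned per week: theatres x lists/theatre/week x patients/list."""
    return (
        config.theatres
        * config.lists_per_theatre_per_week
        * config.patients_per_list
    )


# -- file I/O ----------------------------------------------------------------

_OPTIONAL_DEFAULTS = {
    f.name: f.default
    for f in dataclasses.fields(ServiceConfig)
    if f.default is not dataclasses.MISSING
}
_REQUIRED_KEYS = [
    f.name
    for f in dataclasses.fields(ServiceConfig)
    if f.default is dataclasses.MISSING
]


def _duration_from_mapping(name: str, raw: Mapping) -> DurationSpec:
    if not isinstance(raw, Mapping) or "family" not in raw:
        raise SchemaError(f"durations.{name} must be a mapping with a 'family' key")
    family = raw["family"]
    try:
        if family == "constant":
            params = (raw["value"],)
        elif family == "lognormal":
            params = (raw["mean"], raw["sd"])
        elif family == "triangular":
            params = (raw["low"], raw["mode"], raw["high"])
        elif family == "exponential":
            params = (raw["mean"],)
        else:
            raise ValidationError(f"durations.{name}: unknown family {family!r}")
    except KeyError as exc:
        raise SchemaError(f"durations.{name} missing parameter {exc.args[0]!r}") from None
    try:
        return DurationSpec(family, params)
    except ValueError as exc:
        raise ValidationError(f"durations.{name}: {exc}") from None


def _duration_to_mapping(spec: DurationSpec) -> dict:
    if spec.family == "constant":
        return {"family": "constant", "value": spec.params[0]}
    if spec.family == "lognormal":
        return {"family": "lognormal", "mean": spec.params[0], "sd": spec.params[1]}
    if spec.family == "triangular":
        low, mode, high = spec.params
        return {"family": "triangular", "low": low, "mode": mode, "high": high}
    return {"family": "exponential", "mean": spec.params[0]}


def config_from_mapping(raw: Mapping) -> ServiceConfig:
    """Build and validate a :class:`ServiceConfig` from a parsed mapping."""
    known = set(_REQUIRED_KEYS) | set(_OPTIONAL_DEFAULTS)
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    missing = [k for k in _REQUIRED_KEYS if k not in raw]
    if missing:
        raise SchemaError(f"missing required config key(s): {', '.join(missing)}")
    kwargs: dict = {}
    for key in known:
        if key not in raw:
            continue
        value = raw[key]
        if key == "durations":
            if not isinstance(value, Mapping):
                raise SchemaError("durations must be a mapping of activity -> spec")
            value = {
                name: _duration_from_mapping(name, spec) for name, spec in value.items()
            }
        elif key == "exam_outcome_probs":
            value = tuple(value)
        kwargs[key] = value
    return ServiceConfig(**kwargs)


def config_to_mapping(config: ServiceConfig) -> dict:
    """Inverse of :func:`config_from_mapping` (round-trips exactly)."""
    out: dict = {}
    for f in dataclasses.fields(ServiceConfig):
        value = getattr(config, f.name)
        if f.name == "durations":
            value = {k: _duration_to_mapping(v) for k, v in value.items()}
        elif f.name == "exam_outcome_probs":
            value = list(value)
        out[f.name] = value
    return out


def load_config(path: Union[str, Path]) -> ServiceConfig:
    """Load and validate a service configuration from a YAML (or JSON) file."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, Mapping):
        raise SchemaError(f"{path}: expected a mapping of config keys")
    return config_from_mapping(raw)


def save_config(config: ServiceConfig, path: Union[str, Path]) -> None:
    """Write a config as YAML; ``load_config`` reads it back identically."""
    Path(path).write_text(
        yaml.safe_dump(config_to_mapping(config), sort_keys=False)
    )
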