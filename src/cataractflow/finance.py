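"""Tariff revenue, staff-hour cost, and surplus — in exact integer pence.

Revenue follows the national-tariff logic: every activity of a reimbursable
type (surgery, first outpatient appointment, post-operative follow-up,
pre-operative clinic assessment) earns its fixed tariff.  Cost is staff time
at fully-absorbed hourly rates, plus an optional per-surgery non-staff term
(lens, consumables) that defaults to zero.  All arithmetic is done in
integer pence so that monthly surpluses sum to the annual surplus with zero
rounding drift.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .config import ServiceConfig

__all__ = [
    "TARIFF_ACTIVITIES",
    "to_pence",
    "revenue",
    "cost",
    "surplus",
    "finance_table",
]

#: Reimbursable activity types -> the config field holding their tariff.
TARIFF_ACTIVITIES = {
    "surgery": "tariff_surgery",
    "first_appointment": "tariff_first_appointment",
    "followup": "tariff_followup",
    "preop_clinic": "tariff_preop_clinic",
}


def to_pence(gbp: float) -> int:
    """Convert a GBP amount to integer pence (round half away from zero)."""
    return int(round(gbp * 100))


def revenue(activity_counts: Mapping[str, int], config: ServiceConfig) -> int:
    """Tariff income in pence: sum over activities of count x tariff."""
    total = 0
    for activity, count in activity_counts.items():
        if activity not in TARIFF_ACTIVITIES:
            raise KeyError(f"no tariff configured for activity {activity!r}")
        if count < 0:
            raise ValueError(f"negative count for {activity!r}: {count}")
        total += count * to_pence(getattr(config, TARIFF_ACTIVITIES[activity]))
    return total


def cost(doctor_hours: float, nurse_hours: float, config: ServiceConfig,
         n_surgeries: int = 0) -> int:
    """Service cost in pence: staff hours at hourly rates, plus the optional
    per-surgery non-staff term."""
    if doctor_hours < 0 or nurse_hours < 0:
        raise ValueError(
            f"staff hours must be >= 0, got doctor={doctor_hours}, nurse={nurse_hours}"
        )
    if n_surgeries < 0:
        raise ValueError(f"n_surgeries must be >= 0, got {n_surgeries}")
    return (
        to_pence(doctor_hours * config.hourly_cost_doctor)
        + to_pence(nurse_hours * config.hourly_cost_nurse)
        + n_surgeries * to_pence(config.cost_per_surgery_other)
    )


def surplus(revenue_pence: int, cost_pence: int) -> int:
    """Revenue minus cost, in pence; may be negative."""
    return revenue_pence - cost_pence


def finance_table(
    monthly_counts: pd.DataFrame,
    doctor_hours: pd.Series,
    nurse_hours: pd.Series,
    config: ServiceConfig,
) -> pd.DataFrame:
    """Monthly revenue/cost/surplus in GBP from monthly activity counts.

    ``monthly_counts`` columns are activity types (12 rows, one per month);
    the hour series are indexed the same way.  Surplus is computed row-wise
    in pence, so the identity surplus = revenue - cost is exact on every row
    and on the annual sum.
    """
    rev, cst, srp = [], [], []
    for m in monthly_counts.index:
        counts = {a: int(monthly_counts.loc[m, a]) for a in monthly_counts.columns}
        r = revenue(counts, config)
        c = cost(
            float(doctor_hours.loc[m]),
            float(nurse_hours.loc[m]),
            config,
            n_surgeries=counts.get("surgery", 0),
        )
        rev.append(r)
        cst.append(c)
        srp.append(surplus(r, c))
    return pd.DataFrame(
        {
            "revenue": [p / 100 for p in rev],
            "cost": [p / 100 for p in cst],
            "surplus": [p / 100 for p in srp],
        },
        index=monthly_counts.index,
    )
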