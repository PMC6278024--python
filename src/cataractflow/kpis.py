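"""The nine service performance indicators, monthly and annual.

Indicators: completed surgeries; doctor and nurse hours; utilisation of
pre-surgery rooms, recovery chairs and recovery beds (percent of the
scheduled operating window); revenue, cost and surplus.  Diagnostics carried
alongside: on-the-day cancellations, no-shows, and the mean
referral-to-discharge time in weeks (the model's validation metric).

Annual values are the sums of the monthly values — except utilisations,
which are window-weighted means, i.e. total busy time over total scheduled
capacity-minutes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd
from scipy import stats

from .config import ScenarioSpec, ServiceConfig, apply_scenario, builtin_scenario
from .engine import ResourcePool
from .finance import finance_table
from .pathway import Patient
from .timebase import MINUTES_PER_WEEK, month_edges, operating_window_minutes

__all__ = [
    "KPIReport",
    "utilisation",
    "staff_hours",
    "monthly_report",
    "mean_referral_to_discharge",
    "replicate_and_summarise",
    "scenario_sweep",
]

#: Monthly report columns, in output order.
KPI_COLUMNS = (
    "surgeries",
    "doctor_hours",
    "nurse_hours",
    "utilisation_presurgery_room",
    "utilisation_recovery_chair",
    "utilisation_recovery_bed",
    "revenue",
    "cost",
    "surplus",
    "cancellations",
    "no_shows",
)

_UTIL_POOL = {
    "utilisation_presurgery_room": "presurgery_rooms",
    "utilisation_recovery_chair": "recovery_chairs",
    "utilisation_recovery_bed": "recovery_beds",
}

_COUNTED_EVENTS = ("surgery", "first_appointment", "followup", "preop_clinic",
                   "cancelled_unfit", "no_show")


@dataclass
class KPIReport:
    """Monthly (12 rows) and annual indicator values for one run."""

    monthly: pd.DataFrame
    annual: pd.Series

    def write(self, out_dir: Union[str, Path]) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.monthly.to_csv(out / "kpi_monthly.csv", index_label="month")
        self.annual.to_frame("annual").to_csv(out / "kpi_annual.csv")


def utilisation(pool: ResourcePool, window: float) -> float:
    """Percent of ``window`` minutes the pool's capacity was in use.

    100 x busy-time integral / (capacity x window), clamped to [0, 100].
    """
    if window <= 0:
        raise ValueError(f"utilisation window must be > 0, got {window}")
    if pool.capacity == 0:
        return 0.0
    return float(np.clip(100.0 * pool.busy_time_accumulator / (pool.capacity * window), 0, 100))


def staff_hours(
    activity_records: Iterable[tuple[float, float, str, str, int]],
    role: str,
    period: tuple[float, float],
) -> float:
    """Hours of ``role`` activity starting within ``period`` (minutes)."""
    t0, t1 = period
    return sum(d for s, d, r, _, _ in activity_records if r == role and t0 <= s < t1) / 60.0


def mean_referral_to_discharge(patients: Iterable[Patient]) -> float:
    """Mean referral-to-discharge time over completed patients, in weeks.

    Primed (warm-start backlog) patients are excluded: their referral
    predates the simulation, so their clock does not start at a real event.
    """
    spans = [
        p.discharge_time - p.referral_time
        for p in patients
        if p.completed and not p.primed and p.discharge_time is not None
    ]
    if not spans:
        raise ValueError("no completed patients to average over")
    return float(np.mean(spans)) / MINUTES_PER_WEEK


def monthly_report(result, config: Optional[ServiceConfig] = None) -> KPIReport:
    """Build the full indicator table from one :class:`SimulationResult`."""
    config = config or result.config
    edges = month_edges(config)
    if result.horizon < edges[-1]:
        raise ValueError(
            f"run horizon {result.horizon} min is shorter than the reporting "
            f"year ending at {edges[-1]} min"
        )
    months = pd.RangeIndex(1, 13, name="month")

    # event counts per month
    counts = pd.DataFrame(0, index=months, columns=list(_COUNTED_EVENTS))
    for t, kind, _ in result.events:
        if kind not in counts.columns or not edges[0] <= t < edges[-1]:
            continue
        m = int(np.searchsorted(edges, t, side="right"))  # 1-based month
        counts.loc[m, kind] += 1

    # staff hours per month, by activity start time
    doctor_hours = pd.Series(0.0, index=months)
    nurse_hours = pd.Series(0.0, index=months)
    for start, dur, role, _, _ in result.activity_records:
        if not edges[0] <= start < edges[-1]:
            continue
        m = int(np.searchsorted(edges, start, side="right"))
        if role == "doctor":
            doctor_hours.loc[m] += dur / 60.0
        else:
            nurse_hours.loc[m] += dur / 60.0

    # utilisation per month against the scheduled operating window
    window = operating_window_minutes(config)
    util = pd.DataFrame(0.0, index=months, columns=list(_UTIL_POOL))
    for col, pool_name in _UTIL_POOL.items():
        cap = result.pools[pool_name].capacity
        if cap == 0:
            continue
        busy = result.busy_bins[pool_name].minutes
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(window > 0, 100.0 * busy / (cap * window), 0.0)
        util[col] = np.clip(vals, 0.0, 100.0)

    fin = finance_table(
        counts[["surgery", "first_appointment", "followup", "preop_clinic"]],
        doctor_hours,
        nurse_hours,
        config,
    )

    monthly = pd.DataFrame(
        {
            "surgeries": counts["surgery"],
            "doctor_hours": doctor_hours,
            "nurse_hours": nurse_hours,
            "utilisation_presurgery_room": util["utilisation_presurgery_room"],
            "utilisation_recovery_chair": util["utilisation_recovery_chair"],
            "utilisation_recovery_bed": util["utilisation_recovery_bed"],
            "revenue": fin["revenue"],
            "cost": fin["cost"],
            "surplus": fin["surplus"],
            "cancellations": counts["cancelled_unfit"],
            "no_shows": counts["no_show"],
        }
    )

    annual = monthly.sum()
    total_window = float(window.sum())
    for col, pool_name in _UTIL_POOL.items():
        cap = result.pools[pool_name].capacity
        if cap == 0 or total_window == 0:
            annual[col] = 0.0
        else:
            busy_total = float(result.busy_bins[pool_name].minutes.sum())
            annual[col] = float(np.clip(100.0 * busy_total / (cap * total_window), 0, 100))
    try:
        annual["mean_referral_to_discharge_weeks"] = mean_referral_to_discharge(
            result.patients.values()
        )
    except ValueError:
        annual["mean_referral_to_discharge_weeks"] = np.nan

    return KPIReport(monthly=monthly, annual=annual)


def _replication_seed(master_seed: int, rep: int) -> np.random.SeedSequence:
    """Deterministic, reusable per-replication seed (stateless spawn)."""
    return np.random.SeedSequence(entropy=int(master_seed), spawn_key=(rep,))


def replicate_and_summarise(
    config: ServiceConfig,
    scenario: Optional[Union[str, ScenarioSpec]],
    n_reps: int,
    master_seed: int,
) -> pd.DataFrame:
    """Mean, SD and t-based 95% interval of every annual indicator.

    Runs ``n_reps`` independent replications (seeds derived from
    ``master_seed``); the same master seed gives the same replication seeds
    for every scenario, so scenario contrasts share random numbers.
    """
    if n_reps < 2:
        raise ValueError(f"n_reps must be >= 2, got {n_reps}")
    from .simulate import run_simulation  # local import avoids a cycle

    if isinstance(scenario, str):
        scenario = builtin_scenario(scenario)
    cfg = apply_scenario(config, scenario) if scenario is not None else config

    rows = []
    for rep in range(n_reps):
        result = run_simulation(cfg, _replication_seed(master_seed, rep))
        rows.append(monthly_report(result).annual)
    reps = pd.DataFrame(rows).reset_index(drop=True)

    mean = reps.mean()
    sd = reps.std(ddof=1)
    se = sd / np.sqrt(n_reps)
    tcrit = float(stats.t.ppf(0.975, df=n_reps - 1))
    summary = pd.DataFrame(
        {
            "mean": mean,
            "sd": sd,
            "ci_low": mean - tcrit * se,
            "ci_high": mean + tcrit * se,
        }
    )
    summary.attrs["n_reps"] = n_reps
    return summary


def scenario_sweep(
    config: ServiceConfig,
    n_reps: int,
    master_seed: int,
    scenarios: tuple[str, ...] = ("baseline", "scenario1", "scenario2", "scenario3"),
) -> dict[str, pd.DataFrame]:
    """Replicated what-if sweep over the published scenarios (shared seeds)."""
    return {
        name: replicate_and_summarise(config, name, n_reps, master_seed)
        for name in scenarios
    }
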