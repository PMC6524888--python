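"""Discounted cost and QALY accounting, ICER and net monetary benefit.

Costs follow the societal perspective by default: healthcare costs (events,
drugs, monitoring, chronic-state maintenance) plus travel expenses and
friction-cost productivity losses.  The healthcare-payer perspective drops
the travel and productivity categories and changes nothing else.

Discounting is discrete at cycle start, with separate annual rates for
costs and effects.  All per-patient figures divide by the cohort size at
entry, so dead patients dilute the average exactly as in the published
per-patient tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .engine import (
    TH_APIX, TH_NONE, TH_NONE_PERM, TH_VKA, CohortTrace, HealthState,
)
from .parameters import CostRegistry, ParameterError, ParameterSet, UtilityRegistry

logger = logging.getLogger("vtecea")

DAYS_PER_CYCLE = 365.25 / 4.0


class Perspective(Enum):
    SOCIETAL = "societal"
    HEALTHCARE_PAYER = "healthcare_payer"


#: cost categories reported per patient
COST_CATEGORIES = (
    "vte_death", "recurrent_pe", "recurrent_dvt",
    "fatal_mb", "nonfatal_ic_mb", "nonfatal_extracranial_mb",
    "crnmb", "cteph", "pts", "drug_and_administration", "monitoring",
    "productivity_loss", "transportation",
)
#: categories outside the healthcare sector, dropped under the payer view
OUTSIDE_HEALTHCARE = ("productivity_loss", "transportation")


@dataclass(frozen=True)
class CostBreakdown:
    """Discounted euros per patient by category."""

    per_patient: dict[str, float]
    perspective: Perspective

    @property
    def total(self) -> float:
        return float(sum(self.per_patient.values()))

    def as_series(self) -> pd.Series:
        series = pd.Series(self.per_patient)
        series["total"] = self.total
        return series


@dataclass(frozen=True)
class EffectResult:
    """Discounted QALYs and life-years per patient."""

    qalys: float
    life_years: float

    def __post_init__(self) -> None:
        if self.qalys < 0 or self.life_years < 0:
            raise ParameterError("negative effect totals")
        if self.qalys > self.life_years + 1e-9:
            raise ParameterError("QALYs cannot exceed life-years")


@dataclass(frozen=True)
class IcerResult:
    """Incremental cost-effectiveness of the new strategy vs the reference."""

    delta_cost: float
    delta_effect: float
    icer: float | None
    classification: str  # "trade-off" | "dominant" | "dominated" | "no difference"

    def __str__(self) -> str:
        if self.icer is None:
            return self.classification
        return f"{self.icer:,.0f} EUR/QALY ({self.classification})"


def discount_factor(t_years: float, rate: float) -> float:
    """Discrete annual discount factor ``(1 + rate)**(-t)``."""
    if t_years < 0 or rate < 0:
        raise ParameterError("time and rate must be non-negative")
    return (1.0 + rate) ** (-t_years)


def _discount_vector(n_cycles: int, cycle_years: float, rate: float) -> np.ndarray:
    times = np.arange(n_cycles) * cycle_years
    return (1.0 + rate) ** (-times)


def accumulate_costs(
    trace: CohortTrace,
    costs: CostRegistry,
    perspective: Perspective = Perspective.SOCIETAL,
    discount_rate: float | None = None,
    params: ParameterSet | None = None,
) -> CostBreakdown:
    """Accumulate discounted per-patient costs from a cohort trace.

    Event costs accrue in the cycle the event occurs; drug, monitoring and
    chronic-state (CTEPH, PTS) costs accrue per occupied person-cycle.
    Treatment interruptions after bleeds reduce drug-cost accrual by their
    configured durations.  ``params`` supplies the interruption risks and
    the discount rate default.
    """
    if params is None:
        raise ParameterError("parameter set required for cost accrual rules")
    rate = params.discount_rate_costs if discount_rate is None else discount_rate
    cohort = trace.cohort_size
    if cohort == 0:
        return CostBreakdown({k: 0.0 for k in COST_CATEGORIES}, perspective)
    n = len(trace.events)
    cycle_years = params.cycle_months / 12.0
    df = _discount_vector(n, cycle_years, rate)
    ev = trace.events

    out: dict[str, float] = {}

    # one-off event costs
    event_cost_map = {
        "vte_death": "vte_death", "recurrent_pe": "recurrent_pe",
        "recurrent_dvt": "recurrent_dvt", "fatal_mb": "fatal_mb",
        "nonfatal_ic_mb": "nonfatal_ic_mb",
        "nonfatal_extracranial_mb": "nonfatal_extracranial_mb",
        "crnmb": "crnmb",
    }
    for category, key in event_cost_map.items():
        try:
            unit = costs.event[key]
        except KeyError as exc:
            raise ParameterError(f"cost registry missing event key {key!r}") from exc
        out[category] = float((ev[category].to_numpy() * df).sum() * unit / cohort)

    # CTEPH: onset cost plus per-cycle maintenance for occupants
    cteph_occ = trace.occupancy[:n, HealthState.CTEPH]
    out["cteph"] = float(
        ((ev["cteph_onset"].to_numpy() * costs.event["cteph_onset"]
          + cteph_occ * costs.per_cycle["cteph_maintenance"]) * df).sum() / cohort
    )
    # PTS background pool maintenance
    out["pts"] = float(
        (trace.pts_persons[:n] * costs.per_cycle["pts"] * df).sum() / cohort
    )

    # drug + administration, net of interruption days after bleeds
    tt = trace.person_cycles_on_therapy
    drug_days = {
        "apixaban": tt["apixaban"].to_numpy() * DAYS_PER_CYCLE,
        "vka": tt["vka"].to_numpy() * DAYS_PER_CYCLE,
    }
    treated_frac = np.zeros(n)
    alive_on = tt["apixaban"].to_numpy() + tt["vka"].to_numpy()
    np.divide(
        alive_on, alive_on + tt["none"].to_numpy() + tt["none_permanent"].to_numpy(),
        out=treated_frac, where=(alive_on > 0),
    )
    interruption_days = (
        ev["nonfatal_extracranial_mb"].to_numpy() * params.interruption_mb.mean
        * params.interruption_mb_days
        + ev["crnmb"].to_numpy() * params.interruption_crnmb.mean
        * params.interruption_crnmb_days
    ) * treated_frac
    # interruption days are split across drugs by their person-time share
    total_on_days = drug_days["apixaban"] + drug_days["vka"]
    drug_cost = np.zeros(n)
    for drug, key in (("apixaban", "apixaban_extended"), ("vka", "vka")):
        share = np.zeros(n)
        np.divide(drug_days[drug], total_on_days, out=share, where=total_on_days > 0)
        net_days = np.maximum(drug_days[drug] - share * interruption_days, 0.0)
        drug_cost += net_days * costs.drug_per_day[key]
    out["drug_and_administration"] = float((drug_cost * df).sum() / cohort)

    # INR monitoring for VKA-treated person-time
    inr_visits = tt["vka"].to_numpy() * costs.inr_visits_per_cycle
    out["monitoring"] = float(
        (inr_visits * costs.per_cycle["inr_monitoring_visit"] * df).sum() / cohort
    )

    # travel: hospital-visit events plus INR monitoring visits
    visit_events = (
        ev["recurrent_pe"] + ev["recurrent_dvt"] + ev["nonfatal_ic_mb"]
        + ev["nonfatal_extracranial_mb"] + ev["cteph_onset"]
    ).to_numpy()
    out["transportation"] = float(
        ((visit_events + inr_visits) * costs.travel_per_visit * df).sum() / cohort
    )

    # friction-cost productivity losses
    prod = costs.productivity
    loss_per_day = prod["hourly_wage"] * prod["workday_hours"] * prod["employment_probability"]
    prod_loss = np.zeros(n)
    for event_col, days in costs.absence_days.items():
        if event_col not in ev.columns:
            continue
        capped = min(days, prod["friction_period_days"])
        prod_loss += ev[event_col].to_numpy() * capped * loss_per_day
    out["productivity_loss"] = float((prod_loss * df).sum() / cohort)

    if perspective is Perspective.HEALTHCARE_PAYER:
        for category in OUTSIDE_HEALTHCARE:
            out[category] = 0.0
    return CostBreakdown(out, perspective)


def accumulate_qalys(
    trace: CohortTrace,
    utilities: UtilityRegistry,
    discount_rate: float | None = None,
    params: ParameterSet | None = None,
) -> EffectResult:
    """Accumulate discounted QALYs and life-years per patient.

    Per cycle: alive occupancy earns the baseline utility minus applicable
    decrements (additive, floored at zero), times the cycle length in
    years, times the effect discount factor.  Event decrements apply for
    the event's cycle; CTEPH, PTS and post-IC decrements recur while the
    state persists.
    """
    if params is None:
        raise ParameterError("parameter set required for QALY accrual rules")
    rate = params.discount_rate_effects if discount_rate is None else rate_guard(discount_rate)
    cohort = trace.cohort_size
    if cohort == 0:
        return EffectResult(0.0, 0.0)
    n = len(trace.events)
    cycle_years = params.cycle_months / 12.0
    df = _discount_vector(n, cycle_years, rate)

    alive = trace.occupancy[:n, : int(HealthState.VTE_DEATH)].sum(axis=1)
    base = np.clip(utilities.baseline, 0.0, 1.0)
    utility_mass = alive * base

    # event decrements in the cycle of occurrence (tunnel occupancy at next
    # cycle start equals the event flow, so use the flows directly)
    ev = trace.events
    for event_col, decrement in utilities.event_decrements.items():
        if event_col not in ev.columns:
            continue
        utility_mass -= ev[event_col].to_numpy() * decrement
    # recurring state decrements
    state_pool = {
        "cteph": trace.occupancy[:n, HealthState.CTEPH],
        "pts": trace.pts_persons[:n],
    }
    for state_key, decrement in utilities.state_decrements.items():
        pool = state_pool.get(state_key)
        if pool is None:
            continue
        utility_mass -= pool * decrement

    floored = np.maximum(utility_mass, 0.0)
    if np.any(utility_mass < 0):
        logger.warning("utility decrements drove cycle utility below 0; clamped")
    qalys = float((floored * cycle_years * df).sum() / cohort)
    life_years = float((alive * cycle_years * df).sum() / cohort)
    return EffectResult(qalys=qalys, life_years=life_years)


def rate_guard(rate: float) -> float:
    if rate < 0:
        raise ParameterError("discount rate must be >= 0")
    return rate


def icer(c_new: float, c_ref: float, e_new: float, e_ref: float) -> IcerResult:
    """Incremental cost-effectiveness ratio with quadrant classification."""
    d_cost = c_new - c_ref
    d_effect = e_new - e_ref
    if d_effect == 0.0:
        label = "no difference" if d_cost == 0 else (
            "dominated" if d_cost > 0 else "dominant"
        )
        return IcerResult(d_cost, d_effect, None, label)
    ratio = d_cost / d_effect
    if d_effect > 0 and d_cost <= 0:
        label = "dominant"
    elif d_effect < 0 and d_cost >= 0:
        label = "dominated"
    else:
        label = "trade-off"
    return IcerResult(d_cost, d_effect, ratio, label)


def net_monetary_benefit(d_cost: float, d_effect: float, wtp: float) -> float:
    """Net monetary benefit ``wtp * dE - dC`` at a willingness-to-pay."""
    if wtp < 0:
        raise ParameterError("willingness-to-pay must be >= 0")
    return wtp * d_effect - d_cost


def evaluate_arm(
    trace: CohortTrace,
    params: ParameterSet,
    perspective: Perspective = Perspective.SOCIETAL,
) -> tuple[CostBreakdown, EffectResult]:
    """Convenience: cost breakdown and effects for one arm's trace."""
    breakdown = accumulate_costs(
        trace, params.costs, perspective=perspective, params=params
    )
    effects = accumulate_qalys(trace, params.utilities, params=params)
    return breakdown, effects
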