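"""Model inputs and probability mathematics for the extended-VTE-treatment model.

This module owns every quantitative input of the cost-effectiveness model:
the transition-probability estimates for the extended anticoagulation phase
(per-arm interval risks of recurrent VTE, bleeding risks, discontinuation,
chronic complications), the mortality hazard ratios, the post-cessation
cumulative-incidence curve for recurrence, the discount rates and cohort
demographics, and the cost/utility registries.  It also provides the
probability/rate conversion primitives every downstream module relies on:
period-basis rescaling, hazard-ratio application, the bleeding aging
adjustment, and the piecewise-constant-hazard recurrence conversion.

All risk transformations act on the rate (complement-log) scale, never by
direct probability multiplication, so results remain valid probabilities.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import yaml

logger = logging.getLogger("vtecea")

ARMS = ("apixaban", "no_treatment")
#: labels of the four 3-month intervals of the extended treatment phase
#: (months since the index event)
RECURRENCE_INTERVALS = ("6-9", "9-12", "12-15", "15-18")

DISTRIBUTION_FAMILIES = ("beta", "gamma", "lognormal", "dirichlet_component", "fixed")


class ParameterError(ValueError):
    """Raised when a model input violates its declared invariants."""


# ---------------------------------------------------------------------------
# Estimate types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbabilityEstimate:
    """A probability with its 95% CI, sampling family and period basis.

    ``period_basis_months`` states the duration the probability refers to
    (3 for per-cycle risks, 12 for annual risks, 60 for the 5-year PTS risk).
    """

    mean: float
    ci_low: float
    ci_high: float
    distribution_family: str = "beta"
    period_basis_months: float = 3.0

    def __post_init__(self) -> None:
        if self.distribution_family not in DISTRIBUTION_FAMILIES:
            raise ParameterError(
                f"unknown distribution family {self.distribution_family!r}"
            )
        if not (0.0 <= self.ci_low <= self.mean <= self.ci_high <= 1.0):
            raise ParameterError(
                f"CI ordering violated: 0 <= {self.ci_low} <= {self.mean}"
                f" <= {self.ci_high} <= 1 must hold"
            )
        if self.period_basis_months <= 0:
            raise ParameterError("period basis must be positive")
        if self.distribution_family == "fixed" and not (
            self.ci_low == self.mean == self.ci_high
        ):
            raise ParameterError("fixed estimates must have ci_low = mean = ci_high")

    @classmethod
    def fixed(cls, value: float, basis: float = 3.0) -> "ProbabilityEstimate":
        return cls(value, value, value, "fixed", basis)


@dataclass(frozen=True)
class HazardRatioEstimate:
    """A hazard ratio (> 0) with its 95% CI and sampling family."""

    mean: float
    ci_low: float
    ci_high: float
    distribution_family: str = "gamma"

    def __post_init__(self) -> None:
        if self.distribution_family not in ("gamma", "lognormal", "fixed"):
            raise ParameterError(
                f"hazard ratios use gamma/lognormal/fixed, got "
                f"{self.distribution_family!r}"
            )
        if not (0.0 < self.ci_low <= self.mean <= self.ci_high):
            raise ParameterError(
                f"HR CI ordering violated: 0 < {self.ci_low} <= {self.mean}"
                f" <= {self.ci_high} must hold"
            )


@dataclass(frozen=True)
class CumulativeIncidenceCurve:
    """Cumulative incidence of recurrent VTE after treatment cessation.

    ``knots`` are (time in years, cumulative probability) pairs anchored at
    (0, 0).  Between knots the hazard is assumed piecewise constant; beyond
    the last knot the final segment's hazard persists.
    """

    knots: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.knots or self.knots[0] != (0.0, 0.0):
            raise ParameterError("curve must be anchored at (0, 0)")
        times = [t for t, _ in self.knots]
        cis = [c for _, c in self.knots]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ParameterError("knot times must be strictly increasing")
        if any(c2 < c1 for c1, c2 in zip(cis, cis[1:])):
            raise ParameterError("cumulative incidence must be non-decreasing")
        if any(not (0.0 <= c <= 1.0) for c in cis):
            raise ParameterError("cumulative incidence must lie in [0, 1]")

    def segment_at(self, t: float) -> tuple[float, float, float, float]:
        """Return (t1, ci1, t2, ci2) of the segment whose hazard applies at t.

        Times at or beyond the last knot fall into the final segment.
        """
        if t < 0:
            raise ParameterError("time must be non-negative")
        for (t1, c1), (t2, c2) in zip(self.knots, self.knots[1:]):
            if t < t2:
                return t1, c1, t2, c2
        t1, c1 = self.knots[-2]
        t2, c2 = self.knots[-1]
        return t1, c1, t2, c2


# ---------------------------------------------------------------------------
# Conversion primitives
# ---------------------------------------------------------------------------

def to_cycle_probability(p: float, basis_months: float, cycle_months: float) -> float:
    """Rescale a probability from one period basis to another.

    Uses the constant-rate identity ``1 - (1 - p)**(cycle/basis)``, i.e. the
    underlying event rate is assumed constant over the basis period.
    """
    if basis_months <= 0 or cycle_months <= 0:
        raise ParameterError("period durations must be positive")
    if not 0.0 <= p <= 1.0:
        raise ParameterError(f"probability {p} outside [0, 1]")
    if basis_months == cycle_months:
        return p
    if p == 1.0:
        raise ParameterError("cannot rescale a certain event (infinite rate)")
    # exp/log1p formulation keeps precision for tiny risks
    return -math.expm1((cycle_months / basis_months) * math.log1p(-p))


def from_cycle_probability(p_cycle: float, cycle_months: float, basis_months: float) -> float:
    """Inverse of :func:`to_cycle_probability` (round-trips to ~1e-16)."""
    return to_cycle_probability(p_cycle, cycle_months, basis_months)


def apply_hazard_ratio(p: float, hr: float) -> float:
    """Scale a probability by a hazard ratio on the rate scale.

    Returns ``1 - (1 - p)**hr``; identity for hr = 1 and zero base risk.
    """
    if hr <= 0:
        raise ParameterError(f"hazard ratio must be positive, got {hr}")
    if not 0.0 <= p < 1.0:
        raise ParameterError(f"probability {p} outside [0, 1)")
    return -math.expm1(hr * math.log1p(-p))


def age_adjust_bleeding(
    p_base: float, age: float, base_age: float, factor_per_decade: float
) -> float:
    """Adjust a per-cycle bleeding probability for aging.

    The per-decade risk-adjustment factor acts multiplicatively on the
    hazard: the adjusted probability is
    ``1 - (1 - p_base)**(factor**((age - base_age) / 10))``.
    Probabilities driven above 0.999 are clamped with a warning.
    """
    if age < base_age:
        raise ParameterError("age must be at or above the reference age")
    if not 0.0 <= p_base < 1.0:
        raise ParameterError(f"base probability {p_base} outside [0, 1)")
    exponent = factor_per_decade ** ((age - base_age) / 10.0)
    out = -math.expm1(exponent * math.log1p(-p_base))
    if out > 0.999:
        logger.warning(
            "aging adjustment drove bleeding probability to %.4f at age %.1f;"
            " clamped to 0.999", out, age,
        )
        return 0.999
    return out


def piecewise_recurrence_probability(
    curve: CumulativeIncidenceCurve, t_start: float, cycle_months: float
) -> float:
    """Per-cycle recurrence probability from a cumulative-incidence curve.

    Under a piecewise-constant hazard, a cycle starting at ``t_start`` inside
    segment (t1, t2] has conditional probability
    ``1 - ((1 - CI(t2)) / (1 - CI(t1)))**((cycle_months/12) / (t2 - t1))``.
    The hazard of the final segment persists beyond the last knot.
    """
    if cycle_months <= 0:
        raise ParameterError("cycle length must be positive")
    t1, c1, t2, c2 = curve.segment_at(t_start)
    if c2 < c1:
        raise ParameterError("cumulative incidence decreases within segment")
    if c1 >= 1.0:
        raise ParameterError("cumulative incidence saturated at 1")
    frac = (cycle_months / 12.0) / (t2 - t1)
    # survival ratio over the segment, raised to the cycle's share of it
    log_surv_ratio = math.log1p(-c2) - math.log1p(-c1)
    return -math.expm1(frac * log_surv_ratio)


def treatment_effect_rr(arm_risks: dict[str, list[float]]) -> float:
    """Hazard-scale relative treatment effect from the extended-phase risks.

    Computes the ratio of cumulative log-survival over the 6-18-month window:
    ``log(1 - cum_treated) / log(1 - cum_untreated)``.  This ratio scales the
    post-cessation baseline recurrence hazard for patients who remain
    anticoagulated beyond the trial window.
    """
    try:
        treated = arm_risks["apixaban"]
        untreated = arm_risks["no_treatment"]
    except KeyError as exc:
        raise ParameterError(f"arm risks missing {exc}") from exc
    if len(treated) != len(untreated) or not treated:
        raise ParameterError("both arms need the same, non-empty interval risks")
    log_s_treated = sum(math.log1p(-p) for p in treated)
    log_s_untreated = sum(math.log1p(-p) for p in untreated)
    if log_s_untreated == 0.0:
        raise ParameterError("zero untreated risk: treatment effect undefined")
    return log_s_treated / log_s_untreated


# ---------------------------------------------------------------------------
# Cost and utility registries
# ---------------------------------------------------------------------------

EVENT_COST_KEYS = (
    "recurrent_dvt", "recurrent_pe", "vte_death", "fatal_mb",
    "nonfatal_ic_mb", "nonfatal_extracranial_mb", "crnmb", "cteph_onset",
)
CYCLE_COST_KEYS = ("cteph_maintenance", "pts", "inr_monitoring_visit")
DRUG_KEYS = ("apixaban_extended", "apixaban_initial", "vka", "lmwh")
PRODUCTIVITY_KEYS = (
    "hourly_wage", "employment_probability", "friction_period_days",
    "workday_hours",
)
#: events that trigger a hospital visit, hence a travel tariff
TRAVEL_EVENT_KEYS = (
    "recurrent_dvt", "recurrent_pe", "nonfatal_ic_mb",
    "nonfatal_extracranial_mb", "cteph_onset",
)


@dataclass(frozen=True)
class CostRegistry:
    """Unit costs in euros (2015 price year).

    ``event`` holds one-off acute costs per event; ``per_cycle`` holds
    recurring 3-monthly state costs; ``drug_per_day`` daily drug plus
    administration cost by regimen; ``absence_days`` productivity-loss days
    per event type for the friction-cost method; ``inr_visits_per_cycle``
    is the INR-monitoring frequency for VKA-treated patients.
    """

    event: dict[str, float]
    per_cycle: dict[str, float]
    drug_per_day: dict[str, float]
    travel_per_visit: float
    inr_visits_per_cycle: float
    productivity: dict[str, float]
    absence_days: dict[str, float]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for group, keys in (
            (self.event, EVENT_COST_KEYS),
            (self.per_cycle, CYCLE_COST_KEYS),
            (self.drug_per_day, DRUG_KEYS),
            (self.productivity, PRODUCTIVITY_KEYS),
        ):
            for key in keys:
                if key not in group:
                    raise ParameterError(f"cost registry missing key {key!r}")
            for key, value in group.items():
                if value < 0:
                    raise ParameterError(f"cost {key!r} is negative")
        if self.travel_per_visit < 0 or self.inr_visits_per_cycle < 0:
            raise ParameterError("travel tariff and INR frequency must be >= 0")
        if not 0 <= self.productivity["employment_probability"] <= 1:
            raise ParameterError("employment probability outside [0, 1]")


@dataclass(frozen=True)
class UtilityRegistry:
    """Baseline utility and event/state decrements (additive, floored at 0)."""

    baseline: float
    event_decrements: dict[str, float]
    state_decrements: dict[str, float]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.baseline <= 1.0:
            raise ParameterError("baseline utility outside [0, 1]")
        for key, value in {**self.event_decrements, **self.state_decrements}.items():
            if value < 0:
                raise ParameterError(f"utility decrement {key!r} is negative")


# ---------------------------------------------------------------------------
# The full parameter set
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterSet:
    """Complete registry of model inputs for the extended treatment phase.

    Transition probabilities carry their published 95% CIs, distribution
    families and period bases; costs and utilities live in the attached
    registries.  Instances are immutable; scenario overrides produce copies.
    """

    recurrence: dict[str, tuple[ProbabilityEstimate, ...]]
    event_split: dict[str, ProbabilityEstimate]
    mb_risk: dict[str, ProbabilityEstimate]
    crnmb_risk: dict[str, ProbabilityEstimate]
    fatal_mb_fraction: ProbabilityEstimate
    nonfatal_ic_fraction: ProbabilityEstimate
    bleeding_age_factor: HazardRatioEstimate
    interruption_mb: ProbabilityEstimate
    interruption_mb_days: float
    interruption_crnmb: ProbabilityEstimate
    interruption_crnmb_days: float
    other_discontinuation: ProbabilityEstimate
    cteph_annual: ProbabilityEstimate
    pts_5yr: ProbabilityEstimate
    mortality_hr: dict[str, HazardRatioEstimate]
    post_cessation: CumulativeIncidenceCurve
    post_cessation_estimates: tuple[ProbabilityEstimate, ...]
    discount_rate_costs: float
    discount_rate_effects: float
    start_age: float
    male_fraction: float
    index_pe_fraction: float
    max_age: float
    cycle_months: float
    costs: CostRegistry
    utilities: UtilityRegistry
    #: dotted-name -> "paper_table1" | "placeholder"
    provenance: dict[str, str] = field(default_factory=dict)
    #: post-18-month bleeding source: "arm_specific" keeps each arm's trial
    #: risks while on treatment; "placebo_all" applies the untreated-arm
    #: risks to everyone
    late_bleeding_source: str = "arm_specific"

    def __post_init__(self) -> None:
        for arm in ARMS:
            if arm not in self.recurrence or len(self.recurrence[arm]) != 4:
                raise ParameterError(f"arm {arm!r} needs 4 interval recurrence risks")
            if arm not in self.mb_risk or arm not in self.crnmb_risk:
                raise ParameterError(f"arm {arm!r} missing bleeding risks")
        split_total = sum(e.mean for e in self.event_split.values())
        if abs(split_total - 1.0) > 1e-9:
            raise ParameterError(
                f"event-split proportions sum to {split_total}, expected 1"
            )
        if self.discount_rate_costs < 0 or self.discount_rate_effects < 0:
            raise ParameterError("discount rates must be >= 0")
        if not 0 <= self.index_pe_fraction <= 1:
            raise ParameterError("index-PE fraction outside [0, 1]")
        if not 0 <= self.male_fraction <= 1:
            raise ParameterError("male fraction outside [0, 1]")
        if self.cycle_months <= 0 or self.max_age <= self.start_age:
            raise ParameterError("invalid cycle length or age span")
        if self.late_bleeding_source not in ("arm_specific", "placebo_all"):
            raise ParameterError("unknown late-bleeding source")

    # -- convenience accessors -------------------------------------------

    def recurrence_cycle_risks(self, arm: str) -> list[float]:
        """Per-cycle interval recurrence risks (already on the 3-month basis)."""
        return [
            to_cycle_probability(e.mean, e.period_basis_months, self.cycle_months)
            for e in self.recurrence[arm]
        ]

    def cycle_risk(self, estimate: ProbabilityEstimate) -> float:
        """Convert any estimate to the model's cycle basis."""
        return to_cycle_probability(
            estimate.mean, estimate.period_basis_months, self.cycle_months
        )

    def treatment_effect(self) -> float:
        return treatment_effect_rr(
            {arm: self.recurrence_cycle_risks(arm) for arm in ARMS}
        )

    def with_overrides(self, **kwargs) -> "ParameterSet":
        return replace(self, **kwargs)

    def iter_uncertain(self) -> Iterator[tuple[str, ProbabilityEstimate | HazardRatioEstimate]]:
        """Yield (dotted name, estimate) for every parameter with sampling
        uncertainty (fixed entries are skipped by the sampler, not here)."""
        for arm in ARMS:
            for label, est in zip(RECURRENCE_INTERVALS, self.recurrence[arm]):
                yield f"recurrence.{arm}.{label}", est
            yield f"mb_risk.{arm}", self.mb_risk[arm]
            yield f"crnmb_risk.{arm}", self.crnmb_risk[arm]
        for name, est in self.event_split.items():
            yield f"event_split.{name}", est
        yield "fatal_mb_fraction", self.fatal_mb_fraction
        yield "nonfatal_ic_fraction", self.nonfatal_ic_fraction
        yield "bleeding_age_factor", self.bleeding_age_factor
        yield "interruption_mb", self.interruption_mb
        yield "interruption_crnmb", self.interruption_crnmb
        yield "other_discontinuation", self.other_discontinuation
        yield "cteph_annual", self.cteph_annual
        yield "pts_5yr", self.pts_5yr
        for name, est in self.mortality_hr.items():
            yield f"mortality_hr.{name}", est
        for i, est in enumerate(self.post_cessation_estimates):
            yield f"post_cessation.knot{i + 1}", est

    def placeholder_names(self) -> list[str]:
        return sorted(k for k, v in self.provenance.items() if v == "placeholder")

    def require_authoritative_economics(self) -> None:
        """Refuse to treat placeholder costs/utilities as authoritative.

        Published economic endpoints (ICERs, QALY totals, CEAC points) can
        only be replicated with unit values transcribed from their
        supplementary source; this guard raises while any cost or utility
        entry is still flagged as a placeholder.
        """
        placeholders = self.placeholder_names()
        if placeholders:
            raise ParameterError(
                "economic outputs are gated on an authoritative cost/utility "
                f"file; {len(placeholders)} placeholder values present "
                f"(first: {placeholders[0]})"
            )


# ---------------------------------------------------------------------------
# YAML loading
# ---------------------------------------------------------------------------

def _estimate_from_mapping(mapping: dict, path: str, basis_default: float = 3.0) -> ProbabilityEstimate:
    try:
        return ProbabilityEstimate(
            mean=float(mapping["mean"]),
            ci_low=float(mapping.get("ci_low", mapping["mean"])),
            ci_high=float(mapping.get("ci_high", mapping["mean"])),
            distribution_family=mapping.get("distribution", "beta"),
            period_basis_months=float(mapping.get("basis_months", basis_default)),
        )
    except (KeyError, TypeError, ParameterError) as exc:
        raise ParameterError(f"{path}: {exc}") from exc


def _hr_from_mapping(mapping: dict, path: str) -> HazardRatioEstimate:
    try:
        return HazardRatioEstimate(
            mean=float(mapping["mean"]),
            ci_low=float(mapping.get("ci_low", mapping["mean"])),
            ci_high=float(mapping.get("ci_high", mapping["mean"])),
            distribution_family=mapping.get("distribution", "gamma"),
        )
    except (KeyError, TypeError, ParameterError) as exc:
        raise ParameterError(f"{path}: {exc}") from exc


def load_parameters(path: str | Path) -> ParameterSet:
    """Load and validate a ParameterSet from a YAML parameter file.

    Validation errors name the offending key path.  Placeholder-flagged
    cost/utility entries are collected and logged as warnings so that a run
    against the shipped non-authoritative registry is clearly marked.
    """
    with open(path) as handle:
        raw = yaml.safe_load(handle)
    return parameters_from_dict(raw)


def parameters_from_dict(raw: dict) -> ParameterSet:
    if not isinstance(raw, dict):
        raise ParameterError("parameter file must be a mapping")
    try:
        return _build_parameters(raw)
    except KeyError as exc:
        raise ParameterError(f"parameter file missing key {exc}") from exc


def _build_parameters(raw: dict) -> ParameterSet:
    model = raw["model"]
    tp = raw["transition_probabilities"]
    costs_raw = raw["costs"]
    utils_raw = raw["utilities"]

    recurrence: dict[str, tuple[ProbabilityEstimate, ...]] = {}
    for arm in ARMS:
        rows = tp["recurrence"][arm]
        if len(rows) != len(RECURRENCE_INTERVALS):
            raise ParameterError(
                f"transition_probabilities.recurrence.{arm}: expected "
                f"{len(RECURRENCE_INTERVALS)} interval rows, got {len(rows)}"
            )
        recurrence[arm] = tuple(
            _estimate_from_mapping(
                row, f"transition_probabilities.recurrence.{arm}[{i}]", 3.0
            )
            for i, row in enumerate(rows)
        )

    event_split = {
        name: _estimate_from_mapping(
            {**row, "distribution": "dirichlet_component"},
            f"transition_probabilities.event_split.{name}",
        )
        for name, row in tp["event_split"].items()
    }

    def arm_block(key: str, basis: float) -> dict[str, ProbabilityEstimate]:
        return {
            arm: _estimate_from_mapping(
                tp[key][arm], f"transition_probabilities.{key}.{arm}", basis
            )
            for arm in ARMS
        }

    knots_raw = tp["post_cessation_curve"]
    knot_estimates = tuple(
        _estimate_from_mapping(
            row, f"transition_probabilities.post_cessation_curve[{i}]", 12.0
        )
        for i, row in enumerate(knots_raw)
    )
    knots = [(0.0, 0.0)] + [
        (float(row["time_years"]), est.mean)
        for row, est in zip(knots_raw, knot_estimates)
    ]
    curve = CumulativeIncidenceCurve(tuple(knots))

    mortality_hr = {
        name: _hr_from_mapping(row, f"transition_probabilities.mortality_hr.{name}")
        for name, row in tp["mortality_hr"].items()
    }

    provenance: dict[str, str] = {}

    def registry_values(section: dict, prefix: str) -> dict[str, float]:
        out = {}
        for key, entry in section.items():
            if isinstance(entry, dict):
                out[key] = float(entry["value"])
                provenance[f"{prefix}.{key}"] = entry.get("provenance", "placeholder")
            else:
                out[key] = float(entry)
                provenance[f"{prefix}.{key}"] = "placeholder"
        return out

    costs = CostRegistry(
        event=registry_values(costs_raw["event"], "costs.event"),
        per_cycle=registry_values(costs_raw["per_cycle"], "costs.per_cycle"),
        drug_per_day=registry_values(costs_raw["drug_per_day"], "costs.drug_per_day"),
        travel_per_visit=float(costs_raw["travel_per_visit"]),
        inr_visits_per_cycle=float(costs_raw["inr_visits_per_cycle"]),
        productivity=registry_values(costs_raw["productivity"], "costs.productivity"),
        absence_days=registry_values(costs_raw["absence_days"], "costs.absence_days"),
        provenance={k: v for k, v in provenance.items() if k.startswith("costs.")},
    )
    provenance["costs.travel_per_visit"] = costs_raw.get(
        "travel_provenance", "placeholder"
    )

    utilities = UtilityRegistry(
        baseline=float(utils_raw["baseline"]),
        event_decrements=registry_values(
            utils_raw["event_decrements"], "utilities.event_decrements"
        ),
        state_decrements=registry_values(
            utils_raw["state_decrements"], "utilities.state_decrements"
        ),
        provenance={k: v for k, v in provenance.items() if k.startswith("utilities.")},
    )
    provenance["utilities.baseline"] = utils_raw.get(
        "baseline_provenance", "placeholder"
    )

    for name in ("recurrence", "event_split", "mb", "crnmb"):
        provenance.setdefault(f"transition_probabilities.{name}", "paper_table1")

    params = ParameterSet(
        recurrence=recurrence,
        event_split=event_split,
        mb_risk=arm_block("mb", 12.0),
        crnmb_risk=arm_block("crnmb", 12.0),
        fatal_mb_fraction=_estimate_from_mapping(
            tp["fatal_mb_fraction"], "transition_probabilities.fatal_mb_fraction"
        ),
        nonfatal_ic_fraction=_estimate_from_mapping(
            tp["nonfatal_ic_fraction"], "transition_probabilities.nonfatal_ic_fraction"
        ),
        bleeding_age_factor=_hr_from_mapping(
            tp["bleeding_age_factor"], "transition_probabilities.bleeding_age_factor"
        ),
        interruption_mb=_estimate_from_mapping(
            tp["interruption_mb"], "transition_probabilities.interruption_mb"
        ),
        interruption_mb_days=float(tp.get("interruption_mb_days", 14)),
        interruption_crnmb=_estimate_from_mapping(
            tp["interruption_crnmb"], "transition_probabilities.interruption_crnmb"
        ),
        interruption_crnmb_days=float(tp.get("interruption_crnmb_days", 2)),
        other_discontinuation=_estimate_from_mapping(
            tp["other_discontinuation"],
            "transition_probabilities.other_discontinuation",
            12.0,
        ),
        cteph_annual=_estimate_from_mapping(
            tp["cteph_annual"], "transition_probabilities.cteph_annual", 12.0
        ),
        pts_5yr=_estimate_from_mapping(
            tp["pts_5yr"], "transition_probabilities.pts_5yr", 60.0
        ),
        mortality_hr=mortality_hr,
        post_cessation=curve,
        post_cessation_estimates=knot_estimates,
        discount_rate_costs=float(model["discount_rate_costs"]),
        discount_rate_effects=float(model["discount_rate_effects"]),
        start_age=float(model["start_age"]),
        male_fraction=float(model["male_fraction"]),
        index_pe_fraction=float(model["index_pe_fraction"]),
        max_age=float(model.get("max_age", 100)),
        cycle_months=float(model.get("cycle_months", 3)),
        costs=costs,
        utilities=utilities,
        provenance=provenance,
        late_bleeding_source=model.get("late_bleeding_source", "arm_specific"),
    )

    placeholders = params.placeholder_names()
    if placeholders:
        logger.warning(
            "parameter set contains %d placeholder (non-authoritative) values: %s",
            len(placeholders), ", ".join(placeholders),
        )
    return params
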