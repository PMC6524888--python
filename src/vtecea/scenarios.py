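"""Scenario definitions, trial-validation harness and interval-risk estimator.

Five scenario variants of the base case are encoded: (1) inclusion of the
initial 6-month treatment phase with an LMWH/VKA comparator — available
only when acute-phase parameters are supplied, since those inputs live in
a separate publication; (2) the healthcare-payer perspective; (3)–(5)
equalised major-bleeding and/or CRNMB risks between arms.

The validation harness re-runs the cohort engine at the source trials'
arm sizes and horizons and compares modelled event counts and relative
risks against the published trial counts, which ship here as reference
constants.

The censored interval-risk estimator reconstructs per-interval risks from
trial event counts: interval j's denominator is the intention-to-treat
population minus all patients with an event in earlier intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .economics import Perspective
from .engine import ArmSpec, LifeTable, run_cohort
from .parameters import ParameterError, ParameterSet, ProbabilityEstimate

SCENARIO_IDS = ("base", "s1", "s2", "s3", "s4", "s5")

#: published trial event counts used as validation references
#: (extension trial: apixaban 2.5 mg N=804 vs placebo N=829, 12 months)
EXTENSION_TRIAL_REFERENCE = {
    "n": {"apixaban": 804, "no_treatment": 829},
    "horizon_cycles": 4,
    "counts": {
        "recurrent_vte_and_death": {"apixaban": 14, "no_treatment": 73},
        "major_bleeding": {"apixaban": 2, "no_treatment": 4},
        "crnmb": {"apixaban": 25, "no_treatment": 19},
        "all_cause_death": {"apixaban": 32, "no_treatment": 96},
    },
    # RRs as printed in the trial report (exposure-adjusted; stored as
    # reference constants rather than recomputed from the counts above)
    "rr": {
        "recurrent_vte_and_death": 0.19,
        "major_bleeding": 0.49,
        "crnmb": 1.29,
        "all_cause_death": 0.33,
    },
}
#: initial-phase trial (apixaban N=2691 vs LMWH/VKA N=2704, 6 months);
#: replication requires user-supplied acute-phase parameters
INITIAL_TRIAL_REFERENCE = {
    "n": {"apixaban": 2691, "lmwh_vka": 2704},
    "horizon_cycles": 2,
    "counts": {
        "recurrent_vte_and_death": {"apixaban": 59, "lmwh_vka": 71},
        "major_bleeding": {"apixaban": 15, "lmwh_vka": 49},
        "crnmb": {"apixaban": 103, "lmwh_vka": 215},
    },
    "rr": {
        "recurrent_vte_and_death": 0.83,
        "major_bleeding": 0.31,
        "crnmb": 0.48,
    },
}

VALIDATION_OUTCOMES = ("recurrent_vte_and_death", "major_bleeding", "crnmb")


@dataclass(frozen=True)
class ScenarioConfig:
    """One analysis scenario: perspective, phase span and risk overrides."""

    scenario_id: str
    perspective: Perspective = Perspective.SOCIETAL
    include_initial_phase: bool = False
    override_mb: bool = False
    override_crnmb: bool = False

    def __post_init__(self) -> None:
        if self.scenario_id not in SCENARIO_IDS:
            raise ParameterError(f"unknown scenario {self.scenario_id!r}")

    @classmethod
    def from_id(cls, scenario_id: str) -> "ScenarioConfig":
        table = {
            "base": cls("base"),
            "s1": cls("s1", include_initial_phase=True),
            "s2": cls("s2", perspective=Perspective.HEALTHCARE_PAYER),
            "s3": cls("s3", override_mb=True),
            "s4": cls("s4", override_crnmb=True),
            "s5": cls("s5", override_mb=True, override_crnmb=True),
        }
        try:
            return table[scenario_id]
        except KeyError as exc:
            raise ParameterError(f"unknown scenario {scenario_id!r}") from exc


def apply_scenario(
    base: ParameterSet,
    scenario: ScenarioConfig | str,
    acute_params: object | None = None,
) -> ParameterSet:
    """Return a new ParameterSet with the scenario's overrides applied.

    Scenarios 3-5 copy the apixaban-arm bleeding risks onto the untreated
    arm.  Scenario 1 needs acute-phase parameters (a separate publication's
    inputs); without them an explicit error is raised.  The base parameter
    set is never mutated.
    """
    if isinstance(scenario, str):
        scenario = ScenarioConfig.from_id(scenario)
    if scenario.include_initial_phase and acute_params is None:
        raise ParameterError(
            "scenario 1 requires acute-phase parameters; supply the initial "
            "6-month treatment inputs transcribed from the prior publication"
        )
    params = base
    if scenario.override_mb:
        params = params.with_overrides(
            mb_risk={
                "apixaban": params.mb_risk["apixaban"],
                "no_treatment": params.mb_risk["apixaban"],
            }
        )
    if scenario.override_crnmb:
        params = params.with_overrides(
            crnmb_risk={
                "apixaban": params.crnmb_risk["apixaban"],
                "no_treatment": params.crnmb_risk["apixaban"],
            }
        )
    return params


# ---------------------------------------------------------------------------
# Trial validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrialSettings:
    """Arm sizes and horizon of a validation run."""

    n_apixaban: int
    n_reference: int
    horizon_cycles: int
    phase: str = "extended"

    def __post_init__(self) -> None:
        if self.n_apixaban <= 0 or self.n_reference <= 0:
            raise ParameterError("trial arm sizes must be positive")
        if self.horizon_cycles < 1:
            raise ParameterError("horizon must be at least one cycle")
        if self.phase not in ("extended", "initial"):
            raise ParameterError(f"unknown phase {self.phase!r}")

    @classmethod
    def extension_trial(cls) -> "TrialSettings":
        ref = EXTENSION_TRIAL_REFERENCE
        return cls(
            n_apixaban=ref["n"]["apixaban"],
            n_reference=ref["n"]["no_treatment"],
            horizon_cycles=ref["horizon_cycles"],
        )


@dataclass(frozen=True)
class ValidationReport:
    """Modelled vs trial event counts with relative risks per outcome."""

    table: pd.DataFrame           # outcome rows
    settings: TrialSettings

    def modelled(self, outcome: str, arm: str) -> float:
        row = self.table.set_index("outcome").loc[outcome]
        return float(row[f"model_{arm}"])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def relative_risk(a_events: float, a_n: float, b_events: float, b_n: float) -> float:
    """Risk ratio (a_events/a_n) / (b_events/b_n); NaN when b has no events."""
    if a_n <= 0 or b_n <= 0:
        raise ParameterError("denominators must be positive")
    if b_events == 0:
        return float("nan")
    return (a_events / a_n) / (b_events / b_n)


def validate_trial(
    settings: TrialSettings,
    params: ParameterSet,
    life_table: LifeTable,
    acute_params: object | None = None,
) -> ValidationReport:
    """Run both arms at trial size and horizon; compare against trial counts.

    Counts are reported both unrounded and integer-rounded; relative risks
    are computed on the unrounded modelled counts.  All-cause death is
    reported for completeness but depends on the configured life table.
    """
    if settings.phase == "initial":
        if acute_params is None:
            raise ParameterError(
                "initial-phase validation requires acute-phase parameters"
            )
        raise NotImplementedError(
            "initial-phase engine activates only with supplied acute inputs"
        )
    reference = EXTENSION_TRIAL_REFERENCE
    arms = {
        "apixaban": ArmSpec(
            "apixaban", settings.horizon_cycles, settings.n_apixaban,
            params.start_age, params.male_fraction, params.index_pe_fraction,
        ),
        "no_treatment": ArmSpec(
            "no_treatment", settings.horizon_cycles, settings.n_reference,
            params.start_age, params.male_fraction, params.index_pe_fraction,
        ),
    }
    raw: dict[str, pd.Series] = {}
    for arm_name, spec in arms.items():
        trace = run_cohort(spec, params, life_table)
        totals = trace.events.sum()
        raw[arm_name] = pd.Series(
            {
                "recurrent_vte_and_death": totals["vte_death"]
                + totals["recurrent_pe"] + totals["recurrent_dvt"],
                "major_bleeding": totals["fatal_mb"] + totals["nonfatal_ic_mb"]
                + totals["nonfatal_extracranial_mb"],
                "crnmb": totals["crnmb"],
                "all_cause_death": totals["vte_death"] + totals["fatal_mb"]
                + totals["other_death"],
            }
        )

    rows = []
    for outcome in (*VALIDATION_OUTCOMES, "all_cause_death"):
        trial = reference["counts"].get(outcome, {})
        model_a = raw["apixaban"][outcome]
        model_b = raw["no_treatment"][outcome]
        trial_a = trial.get("apixaban")
        trial_b = trial.get("no_treatment")
        rows.append(
            {
                "outcome": outcome,
                "trial_apixaban": trial_a,
                "trial_no_treatment": trial_b,
                "trial_rr": reference["rr"].get(outcome),
                "model_apixaban": model_a,
                "model_no_treatment": model_b,
                "model_apixaban_rounded": int(round(model_a)),
                "model_no_treatment_rounded": int(round(model_b)),
                "model_rr": round(relative_risk(
                    model_a, settings.n_apixaban, model_b, settings.n_reference
                ), 2),
            }
        )
    return ValidationReport(pd.DataFrame(rows), settings)


# ---------------------------------------------------------------------------
# Censored interval-risk estimator
# ---------------------------------------------------------------------------

def interval_risk_from_counts(
    events_by_interval: list[int] | list[float],
    n_itt: int,
    basis_months: float = 3.0,
) -> list[ProbabilityEstimate]:
    """Interval-specific risks from event counts under event censoring.

    The first interval divides by the full intention-to-treat population;
    each later interval removes patients with events in preceding intervals
    from the denominator.  Wald 95% CIs accompany each estimate.
    """
    if n_itt <= 0:
        raise ParameterError("ITT denominator must be positive")
    if any(e < 0 for e in events_by_interval):
        raise ParameterError("event counts must be non-negative")
    if sum(events_by_interval) > n_itt:
        raise ParameterError("more events than patients")
    out = []
    remaining = float(n_itt)
    for events in events_by_interval:
        if remaining <= 0:
            raise ParameterError("denominator exhausted by prior events")
        risk = events / remaining
        se = (risk * (1 - risk) / remaining) ** 0.5
        out.append(
            ProbabilityEstimate(
                mean=risk,
                ci_low=max(risk - 1.96 * se, 0.0),
                ci_high=min(risk + 1.96 * se, 1.0),
                distribution_family="beta" if se > 0 else "fixed",
                period_basis_months=basis_months,
            )
        )
        remaining -= events
    return out
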