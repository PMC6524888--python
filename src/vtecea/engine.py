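"""Cohort state-transition engine for the extended-VTE-treatment model.

The model follows a closed cohort of VTE patients through 12 health states
in 3-month cycles from entry into the extended treatment phase (6 months
after the index event) until death or age 100.  Event states (recurrent
DVT/PE, major bleed, CRNMB, treatment discontinuation, intracranial bleed)
are one-cycle tunnel states: the transition into them is counted once for
cost/utility purposes, after which survivors rejoin their treatment track.
While in a tunnel, patients remain exposed to their track's risks — a
patient who discontinues mid-cycle, for instance, still carries
on-treatment risk for that transition cycle and assumes the untreated risk
profile from the next cycle on.

Competing risks within a cycle are composed multiplicatively on the
survival scale and each cause's share of the total event mass is allocated
proportionally to its hazard, which is order-independent.

Internally the cohort is stratified beyond the 12 public states: by current
therapy (extended apixaban, resumed LMWH/VKA, untreated, permanently
untreated after intracranial bleed), by PE history (eligibility for CTEPH)
and by DVT history (eligibility for the postthrombotic-syndrome background
process).  The public trace aggregates these strata onto the 12 states.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import IntEnum
from pathlib import Path

import numpy as np
import pandas as pd

from .parameters import (
    ParameterError,
    ParameterSet,
    age_adjust_bleeding,
    apply_hazard_ratio,
    piecewise_recurrence_probability,
    to_cycle_probability,
)

logger = logging.getLogger("vtecea")

#: number of 3-month cycles covered by the trial-derived interval risks
TRIAL_WINDOW_CYCLES = 4


class HealthState(IntEnum):
    """The 12 public health states of the model."""

    INDEX_DVT = 0
    INDEX_PE = 1
    ON_TREATMENT_NO_EVENT = 2
    RECURRENT_DVT = 3
    RECURRENT_PE = 4
    MB_NON_IC = 5
    IC_BLEED = 6
    CRNMB = 7
    CTEPH = 8
    OFF_TREATMENT_NO_EVENT = 9
    VTE_DEATH = 10
    OTHER_DEATH = 11


ABSORBING_STATES = (HealthState.VTE_DEATH, HealthState.OTHER_DEATH)

# internal therapy strata
TH_APIX, TH_VKA, TH_NONE, TH_NONE_PERM = range(4)
THERAPY_LABELS = ("apixaban", "vka", "none", "none_permanent")
# internal cycle markers
(
    MK_TRACK, MK_REC_DVT, MK_REC_PE, MK_MB, MK_CRNMB, MK_DISC, MK_IC, MK_CTEPH,
) = range(8)

EVENT_COLUMNS = (
    "vte_death", "recurrent_pe", "recurrent_dvt", "fatal_mb", "nonfatal_ic_mb",
    "nonfatal_extracranial_mb", "crnmb", "cteph_onset", "discontinuation",
    "other_death",
)


# ---------------------------------------------------------------------------
# Life table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LifeTable:
    """Annual death probabilities by integer age and sex, ages 0-100."""

    qx_male: np.ndarray
    qx_female: np.ndarray

    def __post_init__(self) -> None:
        for qx in (self.qx_male, self.qx_female):
            if len(qx) != 101:
                raise ParameterError("life table must cover ages 0-100")
            if np.any((qx < 0) | (qx > 1)):
                raise ParameterError("life-table q outside [0, 1]")
            if qx[100] != 1.0:
                raise ParameterError("terminal q(100) must equal 1")

    def q_mixed(self, age: float, male_fraction: float) -> float:
        """Sex-mixed annual death probability at (floored) attained age."""
        if age >= 100:
            return 1.0
        idx = int(age)
        return float(
            male_fraction * self.qx_male[idx]
            + (1.0 - male_fraction) * self.qx_female[idx]
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        frame = pd.read_csv(path, comment="#")
        expected = {"age", "qx_male", "qx_female"}
        if not expected.issubset(frame.columns):
            raise ParameterError(f"life table CSV needs columns {sorted(expected)}")
        frame = frame.sort_values("age").reset_index(drop=True)
        if list(frame["age"]) != list(range(101)):
            raise ParameterError("life table must list every integer age 0-100")
        return cls(
            qx_male=frame["qx_male"].to_numpy(float),
            qx_female=frame["qx_female"].to_numpy(float),
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"age": np.arange(101), "qx_male": self.qx_male,
             "qx_female": self.qx_female}
        ).to_csv(path, index=False)


def background_mortality(
    age: float,
    male_fraction: float,
    life_table: LifeTable,
    hr: float = 1.0,
    cycle_months: float = 3.0,
) -> float:
    """Per-cycle death probability from the life table with a mortality HR.

    The sex-mixed annual probability is converted to the cycle length and
    the hazard ratio applied on the rate scale:
    ``1 - (1 - q)**((cycle/12) * hr)``.
    """
    if hr <= 0:
        raise ParameterError("mortality HR must be positive")
    q = life_table.q_mixed(age, male_fraction)
    if q >= 1.0:
        return 1.0
    return -math.expm1((cycle_months / 12.0) * hr * math.log1p(-q))


# ---------------------------------------------------------------------------
# Arm specification and trace
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArmSpec:
    """One strategy arm of a cohort run.

    ``arm`` selects the risk profile ("apixaban" = extended 2.5 mg twice
    daily, "no_treatment" = cessation after the initial 6 months);
    ``horizon_cycles`` the number of 3-month cycles; ``start_age`` the
    cohort age at entry into the run.
    """

    arm: str
    horizon_cycles: int
    cohort_size: float = 1000.0
    start_age: float = 56.9
    male_fraction: float = 0.58
    index_pe_fraction: float = 0.34

    def __post_init__(self) -> None:
        if self.arm not in ("apixaban", "no_treatment"):
            raise ParameterError(f"unknown arm {self.arm!r}")
        if self.horizon_cycles < 1:
            raise ParameterError("horizon must be at least one cycle")
        if self.cohort_size < 0:
            raise ParameterError("cohort size must be non-negative")
        if not 0 < self.start_age < 100:
            raise ParameterError("start age outside the life-table span")

    @classmethod
    def lifetime(cls, arm: str, params: ParameterSet, cohort_size: float = 1000.0) -> "ArmSpec":
        """Lifetime horizon: run until the cohort reaches the maximum age."""
        cycles_per_year = 12.0 / params.cycle_months
        horizon = int(math.ceil((params.max_age - params.start_age) * cycles_per_year))
        return cls(
            arm=arm,
            horizon_cycles=horizon,
            cohort_size=cohort_size,
            start_age=params.start_age,
            male_fraction=params.male_fraction,
            index_pe_fraction=params.index_pe_fraction,
        )


@dataclass
class CohortTrace:
    """Per-cycle state occupancy and event flows of one cohort run.

    ``occupancy`` holds persons per public state at each cycle start
    (``horizon + 1`` rows); ``events`` the per-cycle event flows;
    ``person_cycles_on_therapy`` person-time by therapy stratum;
    ``pts_persons`` the postthrombotic-syndrome background pool.
    """

    arm: ArmSpec
    occupancy: np.ndarray           # (horizon+1, 12)
    events: pd.DataFrame            # (horizon, EVENT_COLUMNS)
    person_cycles_on_therapy: pd.DataFrame   # (horizon, 4)
    pts_persons: np.ndarray         # (horizon+1,)
    ages: np.ndarray                # (horizon+1,)
    truncated: bool = False

    @property
    def cohort_size(self) -> float:
        return float(self.occupancy[0].sum())

    @property
    def cumulative_events(self) -> pd.DataFrame:
        return self.events.cumsum()

    def to_csv(self, path: str | Path) -> None:
        frame = pd.DataFrame(
            self.occupancy, columns=[state.name for state in HealthState]
        )
        frame.insert(0, "cycle", np.arange(len(frame)))
        frame.insert(1, "age", self.ages)
        frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Per-cycle cause-specific risks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CycleRisks:
    """Cause-specific per-cycle probabilities for one stratum and cycle."""

    recurrence: float
    mb: float
    crnmb: float
    cteph: float
    discontinuation: float
    death: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.recurrence, self.mb, self.crnmb, self.cteph,
             self.discontinuation, self.death]
        )


def compose_competing(probs: np.ndarray) -> np.ndarray:
    """Compose independent cause-specific probabilities within one cycle.

    Returns each cause's share of the total transition mass: survival
    complements are multiplied, and the combined event probability is
    allocated proportionally to the cause-specific hazards.
    """
    probs = np.asarray(probs, dtype=float)
    if np.any((probs < 0) | (probs >= 1)):
        if np.any(probs == 1.0):
            # a certain competing event absorbs everything in proportion
            sure = probs == 1.0
            out = np.zeros_like(probs)
            out[sure] = 1.0 / sure.sum()
            return out
        raise ParameterError(f"cause-specific probabilities invalid: {probs}")
    rates = -np.log1p(-probs)
    total = rates.sum()
    if total == 0.0:
        return np.zeros_like(probs)
    p_any = -math.expm1(-total)
    return p_any * rates / total


class _RiskModel:
    """Precomputed per-cycle risk lookups for one (arm, params) pair."""

    def __init__(self, arm: ArmSpec, params: ParameterSet, life_table: LifeTable):
        self.arm = arm
        self.params = params
        self.life_table = life_table
        self.cycle_months = params.cycle_months
        self.cycle_years = params.cycle_months / 12.0
        self.rec_cycle = {
            a: params.recurrence_cycle_risks(a) for a in ("apixaban", "no_treatment")
        }
        self.mb_cycle = {
            a: params.cycle_risk(params.mb_risk[a])
            for a in ("apixaban", "no_treatment")
        }
        self.crnmb_cycle = {
            a: params.cycle_risk(params.crnmb_risk[a])
            for a in ("apixaban", "no_treatment")
        }
        self.disc_cycle = params.cycle_risk(params.other_discontinuation)
        self.cteph_cycle = params.cycle_risk(params.cteph_annual)
        try:
            self.effect_ratio = params.treatment_effect()
        except ParameterError:
            # degenerate zero-risk inputs: no recurrence to scale
            self.effect_ratio = 1.0
        self.age_factor = params.bleeding_age_factor.mean
        self.hr_base = params.mortality_hr["index_dvt"].mean
        self.hr_post_ic = params.mortality_hr["post_ic"].mean
        self.hr_post_cteph = params.mortality_hr["post_cteph"].mean

    # -- components ------------------------------------------------------

    def age_at(self, cycle: int) -> float:
        return self.arm.start_age + cycle * self.cycle_years

    def _decade_anchor_age(self, cycle: int) -> float:
        """Attained age floored to whole elapsed decades since entry.

        The bleeding aging factor is applied in decade steps, so risks stay
        at their trial values throughout the first decade of the run.
        """
        decades = math.floor((self.age_at(cycle) - self.arm.start_age) / 10.0)
        return self.arm.start_age + 10.0 * decades

    def recurrence_risk(self, cycle: int, therapy: int, marker: int) -> float:
        if marker == MK_CTEPH:
            return 0.0
        anticoagulated = therapy in (TH_APIX, TH_VKA)
        if cycle < TRIAL_WINDOW_CYCLES:
            # trial window: anticoagulated patients of the treated arm keep
            # the treated interval risk; everyone else carries the untreated
            # arm's ITT interval risk
            if self.arm.arm == "apixaban" and anticoagulated:
                return self.rec_cycle["apixaban"][cycle]
            return self.rec_cycle["no_treatment"][cycle]
        # beyond the trial window: baseline post-cessation hazard, scaled by
        # the treatment effect for patients still anticoagulated
        t_years = cycle * self.cycle_years
        base = piecewise_recurrence_probability(
            self.params.post_cessation, t_years, self.cycle_months
        )
        if anticoagulated:
            return apply_hazard_ratio(base, self.effect_ratio) if base > 0 else 0.0
        return base

    def bleeding_risks(self, cycle: int, therapy: int) -> tuple[float, float]:
        late = cycle >= TRIAL_WINDOW_CYCLES
        if self.params.late_bleeding_source == "placebo_all" and late:
            source = "no_treatment"
        elif therapy == TH_APIX:
            source = "apixaban"
        else:
            # resumed VKA and untreated patients carry the untreated-arm
            # trial bleeding risks (no extended-phase VKA data exist)
            source = "no_treatment"
        anchor = self._decade_anchor_age(cycle)
        mb = age_adjust_bleeding(
            self.mb_cycle[source], anchor, self.arm.start_age, self.age_factor
        )
        crnmb = age_adjust_bleeding(
            self.crnmb_cycle[source], anchor, self.arm.start_age, self.age_factor
        )
        return mb, crnmb

    def mortality(self, cycle: int, therapy: int, marker: int) -> float:
        hr = self.hr_base
        if therapy == TH_NONE_PERM:
            hr *= self.hr_post_ic
        if marker == MK_CTEPH:
            hr *= self.hr_post_cteph
        return background_mortality(
            self.age_at(cycle), self.arm.male_fraction, self.life_table,
            hr, self.cycle_months,
        )

    def risks(self, cycle: int, therapy: int, pe_hist: int, marker: int) -> CycleRisks:
        mb, crnmb = (0.0, 0.0) if marker == MK_CTEPH else self.bleeding_risks(cycle, therapy)
        disc = (
            self.disc_cycle
            if therapy in (TH_APIX, TH_VKA) and marker not in (MK_DISC, MK_CTEPH)
            else 0.0
        )
        cteph = self.cteph_cycle if (pe_hist and marker != MK_CTEPH) else 0.0
        return CycleRisks(
            recurrence=self.recurrence_risk(cycle, therapy, marker),
            mb=mb,
            crnmb=crnmb,
            cteph=cteph,
            discontinuation=disc,
            death=self.mortality(cycle, therapy, marker),
        )

    def resume_therapy(self, therapy: int) -> int:
        """Therapy of a recurrence survivor: untreated patients resume
        LMWH/VKA (both the never-extended arm and apixaban discontinuers,
        who left apixaban for cause); patients still on drug continue it;
        post-IC patients never resume."""
        if therapy == TH_NONE_PERM:
            return TH_NONE_PERM
        if therapy == TH_NONE:
            return TH_VKA
        return therapy

    def marker_exit_therapy(self, therapy: int, marker: int) -> int:
        if marker == MK_DISC:
            return TH_NONE
        if marker == MK_IC:
            return TH_NONE_PERM
        return therapy


# ---------------------------------------------------------------------------
# Matrix construction (public 12-state view)
# ---------------------------------------------------------------------------

_STATE_TO_INTERNAL = {
    HealthState.INDEX_DVT: (MK_TRACK, 0, 1),
    HealthState.INDEX_PE: (MK_TRACK, 1, 0),
    HealthState.ON_TREATMENT_NO_EVENT: (MK_TRACK, 0, 1),
    HealthState.RECURRENT_DVT: (MK_REC_DVT, 0, 1),
    HealthState.RECURRENT_PE: (MK_REC_PE, 1, 0),
    HealthState.MB_NON_IC: (MK_MB, 0, 1),
    HealthState.IC_BLEED: (MK_IC, 0, 1),
    HealthState.CRNMB: (MK_CRNMB, 0, 1),
    HealthState.CTEPH: (MK_CTEPH, 1, 0),
    HealthState.OFF_TREATMENT_NO_EVENT: (MK_TRACK, 0, 1),
}


def build_matrix(
    arm: ArmSpec,
    cycle: int,
    params: ParameterSet,
    life_table: LifeTable,
) -> np.ndarray:
    """Build the 12x12 row-stochastic transition matrix for one cycle.

    Each public state's row is derived from its representative internal
    stratum: on-treatment rows use the arm's active therapy, off-treatment
    rows the untreated stratum.  Event states are one-cycle tunnels whose
    no-event mass empties back into the treatment track, so their rows are
    not self-loops.  Rows always sum to one.
    """
    model = _RiskModel(arm, params, life_table)
    active = TH_APIX if arm.arm == "apixaban" else TH_NONE
    matrix = np.zeros((12, 12))
    for state in HealthState:
        if state in ABSORBING_STATES:
            matrix[state, state] = 1.0
            continue
        marker, pe_hist, _ = _STATE_TO_INTERNAL[state]
        treated = TH_APIX if arm.arm == "apixaban" else TH_VKA
        if state == HealthState.OFF_TREATMENT_NO_EVENT:
            therapy = TH_NONE
        elif state == HealthState.ON_TREATMENT_NO_EVENT:
            therapy = treated
        else:
            therapy = active
        row = _internal_row(model, cycle, therapy, pe_hist, marker)
        matrix[state] = row
        residual = 1.0 - row.sum()
        if residual < -1e-12:
            bad = HealthState(int(np.argmax(row))).name
            raise ParameterError(
                f"negative transition mass in row {state.name} (largest flow "
                f"to {bad})"
            )
    if np.any(matrix < -1e-15):
        src, dst = np.unravel_index(int(np.argmin(matrix)), matrix.shape)
        raise ParameterError(
            f"negative transition probability "
            f"{HealthState(src).name} -> {HealthState(dst).name}"
        )
    return np.clip(matrix, 0.0, 1.0)


def _internal_row(
    model: _RiskModel, cycle: int, therapy: int, pe_hist: int, marker: int,
) -> np.ndarray:
    """One public-state row: event shares plus the no-event successor flow."""
    risks = model.risks(cycle, therapy, pe_hist, marker)
    shares = compose_competing(risks.as_array())
    p_rec, p_mb, p_crnmb, p_cteph, p_disc, p_die = shares
    split = model.params.event_split
    fatal_mb = model.params.fatal_mb_fraction.mean
    ic_frac = model.params.nonfatal_ic_fraction.mean

    row = np.zeros(12)
    row[HealthState.VTE_DEATH] += p_rec * split["vte_death"].mean
    row[HealthState.RECURRENT_PE] += p_rec * split["recurrent_pe"].mean
    row[HealthState.RECURRENT_DVT] += p_rec * split["recurrent_dvt"].mean
    row[HealthState.OTHER_DEATH] += p_mb * fatal_mb + p_die
    row[HealthState.IC_BLEED] += p_mb * (1 - fatal_mb) * ic_frac
    row[HealthState.MB_NON_IC] += p_mb * (1 - fatal_mb) * (1 - ic_frac)
    row[HealthState.CRNMB] += p_crnmb
    row[HealthState.CTEPH] += p_cteph
    # no-event remainder flows to the marker's successor track
    remainder = 1.0 - shares.sum()
    exit_therapy = model.marker_exit_therapy(therapy, marker)
    if marker == MK_CTEPH:
        successor = HealthState.CTEPH
    elif exit_therapy in (TH_APIX, TH_VKA):
        successor = HealthState.ON_TREATMENT_NO_EVENT
    else:
        successor = HealthState.OFF_TREATMENT_NO_EVENT
    row[successor] += remainder
    # discontinuation flow enters the off-treatment state
    row[HealthState.OFF_TREATMENT_NO_EVENT] += p_disc
    return row


# ---------------------------------------------------------------------------
# Cohort run
# ---------------------------------------------------------------------------

def run_cohort(
    arm: ArmSpec, params: ParameterSet, life_table: LifeTable
) -> CohortTrace:
    """Run the deterministic cohort through its horizon.

    Returns a :class:`CohortTrace` with per-cycle public-state occupancy,
    event flows, person-time by therapy and the PTS background pool.  The
    horizon is truncated (with a warning) if it would carry the cohort past
    the maximum age of 100 years.
    """
    cycle_years = params.cycle_months / 12.0
    horizon = arm.horizon_cycles
    max_cycles = int(math.ceil((params.max_age - arm.start_age) / cycle_years))
    truncated = False
    if horizon > max_cycles:
        logger.warning(
            "horizon of %d cycles exceeds age %.0f; truncated to %d",
            horizon, params.max_age, max_cycles,
        )
        horizon = max_cycles
        truncated = True

    model = _RiskModel(arm, params, life_table)
    active = TH_APIX if arm.arm == "apixaban" else TH_NONE

    # occupancy[therapy, pe_hist, dvt_hist, marker]
    occ = np.zeros((4, 2, 2, 8))
    occ[active, 1, 0, MK_TRACK] = arm.cohort_size * arm.index_pe_fraction
    occ[active, 0, 1, MK_TRACK] = arm.cohort_size * (1 - arm.index_pe_fraction)
    dead_vte = 0.0
    dead_other = 0.0
    pts = 0.0

    split = params.event_split
    p_death_split = split["vte_death"].mean
    p_pe_split = split["recurrent_pe"].mean
    p_dvt_split = split["recurrent_dvt"].mean
    fatal_mb_frac = params.fatal_mb_fraction.mean
    ic_frac = params.nonfatal_ic_fraction.mean
    pts_cycle = params.cycle_risk(params.pts_5yr)

    n_states = len(HealthState)
    occupancy = np.zeros((horizon + 1, n_states))
    events = np.zeros((horizon, len(EVENT_COLUMNS)))
    therapy_time = np.zeros((horizon, 4))
    pts_series = np.zeros(horizon + 1)
    ages = arm.start_age + np.arange(horizon + 1) * cycle_years

    occupancy[0] = _public_occupancy(occ, dead_vte, dead_other, entry=True)
    pts_series[0] = pts
    col = {name: i for i, name in enumerate(EVENT_COLUMNS)}

    for cycle in range(horizon):
        new_occ = np.zeros_like(occ)
        flows = np.zeros(len(EVENT_COLUMNS))
        alive_dvt_before = occ[:, :, 1, :].sum()
        deaths_dvt = 0.0

        for therapy in range(4):
            for pe_hist in (0, 1):
                for dvt_hist in (0, 1):
                    for marker in range(8):
                        mass = occ[therapy, pe_hist, dvt_hist, marker]
                        if mass <= 0.0:
                            continue
                        therapy_time[cycle, therapy] += mass
                        risks = model.risks(cycle, therapy, pe_hist, marker)
                        shares = compose_competing(risks.as_array())
                        e_rec, e_mb, e_cr, e_ct, e_di, e_dd = shares * mass

                        rec_dead = e_rec * p_death_split
                        rec_pe = e_rec * p_pe_split
                        rec_dvt = e_rec * p_dvt_split
                        mb_dead = e_mb * fatal_mb_frac
                        mb_ic = e_mb * (1 - fatal_mb_frac) * ic_frac
                        mb_ecr = e_mb * (1 - fatal_mb_frac) * (1 - ic_frac)

                        flows[col["vte_death"]] += rec_dead
                        flows[col["recurrent_pe"]] += rec_pe
                        flows[col["recurrent_dvt"]] += rec_dvt
                        flows[col["fatal_mb"]] += mb_dead
                        flows[col["nonfatal_ic_mb"]] += mb_ic
                        flows[col["nonfatal_extracranial_mb"]] += mb_ecr
                        flows[col["crnmb"]] += e_cr
                        flows[col["cteph_onset"]] += e_ct
                        flows[col["discontinuation"]] += e_di
                        flows[col["other_death"]] += e_dd

                        dead_vte += rec_dead
                        dead_other += mb_dead + e_dd
                        if dvt_hist:
                            deaths_dvt += rec_dead + mb_dead + e_dd

                        resume = model.resume_therapy(therapy)
                        new_occ[resume, pe_hist, 1, MK_REC_DVT] += rec_dvt
                        new_occ[resume, 1, dvt_hist, MK_REC_PE] += rec_pe
                        new_occ[therapy, pe_hist, dvt_hist, MK_MB] += mb_ecr
                        new_occ[therapy, pe_hist, dvt_hist, MK_IC] += mb_ic
                        new_occ[therapy, pe_hist, dvt_hist, MK_CRNMB] += e_cr
                        new_occ[therapy, pe_hist, dvt_hist, MK_CTEPH] += e_ct
                        if therapy in (TH_APIX, TH_VKA):
                            new_occ[therapy, pe_hist, dvt_hist, MK_DISC] += e_di
                        else:  # defensive: untreated strata cannot discontinue
                            new_occ[therapy, pe_hist, dvt_hist, MK_TRACK] += e_di

                        remainder = mass - shares.sum() * mass
                        exit_th = model.marker_exit_therapy(therapy, marker)
                        exit_marker = MK_CTEPH if marker == MK_CTEPH else MK_TRACK
                        new_occ[exit_th, pe_hist, dvt_hist, exit_marker] += remainder

        # postthrombotic-syndrome background pool among DVT-history patients
        death_frac_dvt = deaths_dvt / alive_dvt_before if alive_dvt_before > 0 else 0.0
        pts = pts * (1.0 - death_frac_dvt)
        alive_dvt_after = new_occ[:, :, 1, :].sum()
        pts += max(alive_dvt_after - pts, 0.0) * pts_cycle
        pts = min(pts, alive_dvt_after)

        occ = new_occ
        events[cycle] = flows
        occupancy[cycle + 1] = _public_occupancy(occ, dead_vte, dead_other)
        pts_series[cycle + 1] = pts

    return CohortTrace(
        arm=arm,
        occupancy=occupancy,
        events=pd.DataFrame(events, columns=list(EVENT_COLUMNS)),
        person_cycles_on_therapy=pd.DataFrame(
            therapy_time, columns=list(THERAPY_LABELS)
        ),
        pts_persons=pts_series,
        ages=ages,
        truncated=truncated,
    )


def _public_occupancy(
    occ: np.ndarray, dead_vte: float, dead_other: float, entry: bool = False
) -> np.ndarray:
    """Aggregate internal strata onto the 12 public states."""
    out = np.zeros(len(HealthState))
    track_treated = occ[(TH_APIX, TH_VKA), :, :, MK_TRACK].sum()
    track_untreated = occ[(TH_NONE, TH_NONE_PERM), :, :, MK_TRACK].sum()
    if entry:
        out[HealthState.INDEX_PE] = occ[:, 1, :, MK_TRACK].sum()
        out[HealthState.INDEX_DVT] = occ[:, 0, :, MK_TRACK].sum()
    else:
        out[HealthState.ON_TREATMENT_NO_EVENT] = track_treated
        out[HealthState.OFF_TREATMENT_NO_EVENT] = track_untreated
    out[HealthState.RECURRENT_DVT] = occ[:, :, :, MK_REC_DVT].sum()
    out[HealthState.RECURRENT_PE] = occ[:, :, :, MK_REC_PE].sum()
    out[HealthState.MB_NON_IC] = occ[:, :, :, MK_MB].sum()
    out[HealthState.IC_BLEED] = occ[:, :, :, MK_IC].sum()
    out[HealthState.CRNMB] = occ[:, :, :, MK_CRNMB].sum()
    out[HealthState.CTEPH] = occ[:, :, :, MK_CTEPH].sum()
    out[HealthState.OFF_TREATMENT_NO_EVENT] += occ[:, :, :, MK_DISC].sum()
    out[HealthState.VTE_DEATH] = dead_vte
    out[HealthState.OTHER_DEATH] = dead_other
    return out


def count_events(trace: CohortTrace) -> pd.Series:
    """Integer-rounded cumulative event counts by category.

    Major bleeding is also reported as a total alongside its fatal,
    intracranial and extracranial components.
    """
    total = trace.events.sum()
    counts = {
        "vte_death": total["vte_death"],
        "recurrent_pe": total["recurrent_pe"],
        "recurrent_dvt": total["recurrent_dvt"],
        "recurrent_vte_and_death": (
            total["vte_death"] + total["recurrent_pe"] + total["recurrent_dvt"]
        ),
        "fatal_mb": total["fatal_mb"],
        "nonfatal_ic_mb": total["nonfatal_ic_mb"],
        "nonfatal_extracranial_mb": total["nonfatal_extracranial_mb"],
        "major_bleeding": (
            total["fatal_mb"] + total["nonfatal_ic_mb"]
            + total["nonfatal_extracranial_mb"]
        ),
        "crnmb": total["crnmb"],
        "cteph": total["cteph_onset"],
        "discontinuation": total["discontinuation"],
        "other_death": total["other_death"],
    }
    return pd.Series(counts).round().astype(int)
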