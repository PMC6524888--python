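"""Synthetic inputs and simulation oracles.

Provides everything the model needs without external downloads: a
Gompertz-Makeham period life table standing in for a national table, a
patient-level trial simulator used as the oracle for the censored
interval-risk estimator, a microsimulation of the cohort engine's own
transition dynamics (expected-value cross-check), and the packaged
base-case parameter fixture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .engine import (
    MK_CTEPH, MK_DISC, MK_TRACK, TH_APIX, TH_NONE, TH_NONE_PERM, TH_VKA,
    ArmSpec, LifeTable, _RiskModel, compose_competing,
)
from .parameters import ParameterError, ParameterSet, load_parameters

#: Gompertz-Makeham defaults per sex, loosely calibrated to a recent Dutch
#: period table: ~0.5% annual mortality in the late 50s and a remaining life
#: expectancy of roughly 27 years at age 57 for the 58% male mix.
DEFAULT_GM_PARAMS = {
    "male": {"makeham": 2.0e-4, "scale": 2.0e-5, "shape": 0.100},
    "female": {"makeham": 1.5e-4, "scale": 1.1e-5, "shape": 0.100},
}


@dataclass(frozen=True)
class GompertzMakeham:
    """Annual mortality hazard ``makeham + scale * exp(shape * age)``."""

    makeham: float
    scale: float
    shape: float

    def __post_init__(self) -> None:
        if self.makeham < 0 or self.scale < 0 or self.shape <= 0:
            raise ParameterError("Gompertz-Makeham parameters must be positive")

    def annual_q(self, age: float) -> float:
        hazard = self.makeham + self.scale * math.exp(self.shape * age)
        return min(-math.expm1(-hazard), 1.0)


def make_life_table(
    male: GompertzMakeham | None = None,
    female: GompertzMakeham | None = None,
) -> LifeTable:
    """Tabulate a synthetic period life table to age 100.

    Annual death probabilities follow the Gompertz-Makeham law per sex;
    q(100) is forced to 1 so the engine's maximum-age rule holds.
    """
    male = male or GompertzMakeham(**DEFAULT_GM_PARAMS["male"])
    female = female or GompertzMakeham(**DEFAULT_GM_PARAMS["female"])
    ages = np.arange(101)
    qm = np.array([male.annual_q(a) for a in ages])
    qf = np.array([female.annual_q(a) for a in ages])
    qm[100] = qf[100] = 1.0
    return LifeTable(qx_male=qm, qx_female=qf)


def life_expectancy(table: LifeTable, age: float, male_fraction: float) -> float:
    """Remaining life expectancy by summed annual survival (trapezoid)."""
    survival = 1.0
    total = 0.0
    for a in range(int(age), 101):
        q = table.q_mixed(a, male_fraction)
        total += survival * (1 - q / 2.0)
        survival *= 1 - q
        if survival <= 0:
            break
    return total


# ---------------------------------------------------------------------------
# Patient-level trial simulator (estimator oracle)
# ---------------------------------------------------------------------------

@dataclass
class SimulatedCohort:
    """Per-patient first-event records from a simulated trial arm.

    ``event_cycle[i]`` is the 0-based cycle of patient i's first recurrent
    event, or -1 if censored; ``discontinuation_cycle`` and ``death_cycle``
    analogous.  At most one efficacy event is recorded per patient, matching
    the censoring design of the interval-risk estimator.
    """

    event_cycle: np.ndarray
    discontinuation_cycle: np.ndarray
    death_cycle: np.ndarray
    seed: int

    @property
    def n(self) -> int:
        return len(self.event_cycle)

    def events_by_interval(self, n_intervals: int) -> np.ndarray:
        return np.array(
            [(self.event_cycle == j).sum() for j in range(n_intervals)]
        )


def simulate_patients(
    n: int,
    interval_hazards: list[float],
    discontinuation_risk: float = 0.0,
    death_risk: float = 0.0,
    seed: int = 0,
) -> SimulatedCohort:
    """Simulate patient-level event histories over the trial intervals.

    Each cycle, event / discontinuation / death compete by the same
    survival-scale composition rule the cohort engine uses.  Patients are
    censored after their first recurrent event.
    """
    hazards = np.asarray(interval_hazards, dtype=float)
    if np.any((hazards < 0) | (hazards >= 1)):
        raise ParameterError("interval hazards must lie in [0, 1)")
    if not 0 <= discontinuation_risk < 1 or not 0 <= death_risk < 1:
        raise ParameterError("competing risks must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    event = np.full(n, -1, dtype=int)
    disc = np.full(n, -1, dtype=int)
    death = np.full(n, -1, dtype=int)
    at_risk = np.ones(n, dtype=bool)

    for j, hazard in enumerate(hazards):
        shares = compose_competing(
            np.array([hazard, discontinuation_risk, death_risk])
        )
        p_event, p_disc, p_death = shares
        u = rng.random(n)
        idx = np.flatnonzero(at_risk)
        u = u[idx]
        hit_event = idx[u < p_event]
        hit_disc = idx[(u >= p_event) & (u < p_event + p_disc)]
        hit_death = idx[(u >= p_event + p_disc) & (u < p_event + p_disc + p_death)]
        event[hit_event] = j
        death[hit_death] = j
        newly_disc = hit_disc[disc[hit_disc] < 0]
        disc[newly_disc] = j
        # efficacy events and deaths censor; discontinuation does not
        at_risk[hit_event] = False
        at_risk[hit_death] = False
    return SimulatedCohort(event, disc, death, seed)


# ---------------------------------------------------------------------------
# Engine microsimulation (expected-value oracle)
# ---------------------------------------------------------------------------

def microsimulate_cohort(
    arm: ArmSpec,
    params: ParameterSet,
    life_table: LifeTable,
    n_walkers: int,
    seed: int,
    return_se: bool = False,
) -> pd.Series | tuple[pd.Series, pd.Series]:
    """Monte Carlo walkers through the cohort engine's own transition rules.

    Uses the identical per-stratum cause-specific risks and composition as
    :func:`vtecea.engine.run_cohort`, so expected counts from the two must
    agree up to Monte Carlo error.  Returns unrounded event counts scaled
    to the arm's cohort size; with ``return_se`` also the empirical Monte
    Carlo standard error of each count (computed from the per-walker count
    variance, which exceeds the Poisson value when events can repeat).
    """
    rng = np.random.default_rng(seed)
    model = _RiskModel(arm, params, life_table)
    split = params.event_split
    p_split = np.array(
        [split["vte_death"].mean, split["recurrent_pe"].mean,
         split["recurrent_dvt"].mean]
    )
    fatal_mb = params.fatal_mb_fraction.mean
    ic_frac = params.nonfatal_ic_fraction.mean
    active = TH_APIX if arm.arm == "apixaban" else TH_NONE

    # walker state: therapy, pe_hist, marker (dvt_hist not needed for counts)
    n_pe = rng.binomial(n_walkers, arm.index_pe_fraction)
    therapy = np.full(n_walkers, active, dtype=np.int8)
    pe_hist = np.zeros(n_walkers, dtype=np.int8)
    pe_hist[:n_pe] = 1
    marker = np.full(n_walkers, MK_TRACK, dtype=np.int8)
    alive = np.ones(n_walkers, dtype=bool)

    outcome_keys = (
        "vte_death", "recurrent_pe", "recurrent_dvt", "fatal_mb",
        "nonfatal_ic_mb", "nonfatal_extracranial_mb", "crnmb",
        "cteph_onset", "discontinuation", "other_death",
    )
    # per-walker counts so the Monte Carlo SE can be estimated empirically
    per_walker = {key: np.zeros(n_walkers, dtype=np.uint16) for key in outcome_keys}

    for cycle in range(arm.horizon_cycles):
        if not alive.any():
            break
        # group walkers by identical (therapy, pe_hist, marker) strata
        key = therapy.astype(int) * 100 + pe_hist.astype(int) * 10 + marker
        key[~alive] = -1
        for stratum in np.unique(key):
            if stratum < 0:
                continue
            members = np.flatnonzero(key == stratum)
            th, ph, mk = stratum // 100, (stratum // 10) % 10, stratum % 10
            risks = model.risks(cycle, th, ph, mk)
            shares = compose_competing(risks.as_array())
            cum = np.cumsum(shares)
            u = rng.random(len(members))
            cause = np.searchsorted(cum, u)  # 6 == no event

            rec = members[cause == 0]
            if len(rec):
                sub = rng.choice(3, size=len(rec), p=p_split)
                dead = rec[sub == 0]
                pe = rec[sub == 1]
                dvt = rec[sub == 2]
                per_walker["vte_death"][dead] += 1
                per_walker["recurrent_pe"][pe] += 1
                per_walker["recurrent_dvt"][dvt] += 1
                alive[dead] = False
                resume = np.array(
                    [model.resume_therapy(t) for t in therapy[pe]]
                    , dtype=np.int8) if len(pe) else None
                if len(pe):
                    therapy[pe] = resume
                    pe_hist[pe] = 1
                    marker[pe] = 2  # MK_REC_PE
                if len(dvt):
                    therapy[dvt] = [model.resume_therapy(t) for t in therapy[dvt]]
                    marker[dvt] = 1  # MK_REC_DVT
            mb = members[cause == 1]
            if len(mb):
                u2 = rng.random(len(mb))
                dead = mb[u2 < fatal_mb]
                rest = mb[u2 >= fatal_mb]
                u3 = rng.random(len(rest))
                ic = rest[u3 < ic_frac]
                ecr = rest[u3 >= ic_frac]
                per_walker["fatal_mb"][dead] += 1
                per_walker["nonfatal_ic_mb"][ic] += 1
                per_walker["nonfatal_extracranial_mb"][ecr] += 1
                alive[dead] = False
                marker[ic] = 6   # MK_IC
                marker[ecr] = 3  # MK_MB
            cr = members[cause == 2]
            per_walker["crnmb"][cr] += 1
            marker[cr] = 4       # MK_CRNMB
            ct = members[cause == 3]
            per_walker["cteph_onset"][ct] += 1
            marker[ct] = MK_CTEPH
            di = members[cause == 4]
            per_walker["discontinuation"][di] += 1
            marker[di] = MK_DISC
            dd = members[cause == 5]
            per_walker["other_death"][dd] += 1
            alive[dd] = False
            # no-event walkers exit their tunnel
            none = members[cause == 6]
            tunnel = none[(marker[none] != MK_TRACK) & (marker[none] != MK_CTEPH)]
            for w in tunnel:
                therapy[w] = model.marker_exit_therapy(therapy[w], marker[w])
            marker[tunnel] = MK_TRACK

    scale = arm.cohort_size / n_walkers
    series = pd.Series(
        {key: float(values.sum()) for key, values in per_walker.items()}
    ) * scale
    series["recurrent_vte_and_death"] = (
        series["vte_death"] + series["recurrent_pe"] + series["recurrent_dvt"]
    )
    series["major_bleeding"] = (
        series["fatal_mb"] + series["nonfatal_ic_mb"]
        + series["nonfatal_extracranial_mb"]
    )
    if not return_se:
        return series
    se = {}
    for key, values in per_walker.items():
        se[key] = float(values.std(ddof=1)) * math.sqrt(n_walkers) * scale
    grouped = {
        "recurrent_vte_and_death": ("vte_death", "recurrent_pe", "recurrent_dvt"),
        "major_bleeding": (
            "fatal_mb", "nonfatal_ic_mb", "nonfatal_extracranial_mb",
        ),
    }
    for name, keys in grouped.items():
        combined = sum(
            per_walker[k].astype(np.int64) for k in keys
        )
        se[name] = float(combined.std(ddof=1)) * math.sqrt(n_walkers) * scale
    return series, pd.Series(se)


# ---------------------------------------------------------------------------
# Packaged fixture
# ---------------------------------------------------------------------------

def default_fixture_parameters() -> ParameterSet:
    """The packaged base-case ParameterSet.

    Transition probabilities are the published base-case values; every cost
    and utility entry is a flagged synthetic placeholder (check
    ``ParameterSet.placeholder_names()``).
    """
    source = resources.files("vtecea").joinpath("data/base_parameters.yaml")
    with resources.as_file(source) as path:
        return load_parameters(path)


def default_life_table() -> LifeTable:
    """The default synthetic life table (Gompertz-Makeham, both sexes)."""
    return make_life_table()
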