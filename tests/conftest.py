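"""Shared fixtures: the packaged parameter set, synthetic life table, and
degenerate (zero-risk) variants used for closed-form checks."""

import logging

import numpy as np
import pytest

from vtecea import (
    ArmSpec, CumulativeIncidenceCurve, LifeTable, ParameterSet,
    ProbabilityEstimate, default_fixture_parameters, default_life_table,
)

logging.getLogger("vtecea").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def params() -> ParameterSet:
    return default_fixture_parameters()


@pytest.fixture(scope="session")
def life_table() -> LifeTable:
    return default_life_table()


@pytest.fixture(scope="session")
def zero_life_table() -> LifeTable:
    """No background mortality below the forced terminal age."""
    qx = np.zeros(101)
    qx[100] = 1.0
    return LifeTable(qx_male=qx.copy(), qx_female=qx.copy())


def make_inert_params(base: ParameterSet) -> ParameterSet:
    """All event risks zero, no discounting: the cohort just ages."""
    zero = ProbabilityEstimate.fixed(0.0)
    zero12 = ProbabilityEstimate.fixed(0.0, basis=12.0)
    zero60 = ProbabilityEstimate.fixed(0.0, basis=60.0)
    flat = CumulativeIncidenceCurve(((0.0, 0.0), (1.0, 0.0), (10.0, 0.0)))
    zero_knots = (
        ProbabilityEstimate.fixed(0.0, basis=12.0),
        ProbabilityEstimate.fixed(0.0, basis=12.0),
    )
    return base.with_overrides(
        recurrence={arm: (zero,) * 4 for arm in ("apixaban", "no_treatment")},
        mb_risk={arm: zero12 for arm in ("apixaban", "no_treatment")},
        crnmb_risk={arm: zero12 for arm in ("apixaban", "no_treatment")},
        other_discontinuation=zero12,
        cteph_annual=zero12,
        pts_5yr=zero60,
        post_cessation=flat,
        post_cessation_estimates=zero_knots,
        discount_rate_costs=0.0,
        discount_rate_effects=0.0,
    )


@pytest.fixture(scope="session")
def inert_params(params) -> ParameterSet:
    return make_inert_params(params)


@pytest.fixture()
def short_arm():
    def _make(arm: str = "apixaban", cycles: int = 4, n: float = 1000.0) -> ArmSpec:
        return ArmSpec(arm, cycles, n)
    return _make
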