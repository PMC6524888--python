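"""Cohort engine: matrix stochasticity, mass conservation, event dynamics."""

import numpy as np
import pandas as pd
import pytest

from vtecea import (
    ArmSpec, HealthState, ProbabilityEstimate, background_mortality,
    build_matrix, count_events, run_cohort,
)
from vtecea.engine import ABSORBING_STATES, _RiskModel
from vtecea.parameters import ParameterError

from conftest import make_inert_params


class TestBackgroundMortality:
    def test_zero_risk(self, zero_life_table):
        assert background_mortality(60, 0.58, zero_life_table, hr=1.0) == 0.0

    def test_hr_on_rate_scale(self, zero_life_table):
        qx = np.full(101, 0.01)
        qx[100] = 1.0
        from vtecea import LifeTable
        table = LifeTable(qx_male=qx.copy(), qx_female=qx.copy())
        assert background_mortality(60, 0.58, table, hr=4.41) == pytest.approx(
            0.0110193327, abs=1e-9
        )

    def test_terminal_age_is_certain_death(self, life_table):
        assert background_mortality(100, 0.58, life_table, hr=1.0) == 1.0

    def test_invalid_hr(self, life_table):
        with pytest.raises(ParameterError):
            background_mortality(60, 0.58, life_table, hr=0.0)


class TestBuildMatrix:
    @pytest.mark.parametrize("arm_name", ["apixaban", "no_treatment"])
    @pytest.mark.parametrize("cycle", [0, 3, 4, 40])
    def test_rows_sum_to_one(self, params, life_table, arm_name, cycle, short_arm):
        arm = short_arm(arm_name, cycles=60)
        matrix = build_matrix(arm, cycle, params, life_table)
        assert matrix.shape == (12, 12)
        assert np.allclose(matrix.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(matrix >= 0)

    def test_absorbing_states(self, params, life_table, short_arm):
        matrix = build_matrix(short_arm(), 0, params, life_table)
        for state in ABSORBING_STATES:
            row = np.zeros(12)
            row[state] = 1.0
            assert np.array_equal(matrix[state], row)

    def test_untreated_interval_mass_before_composition(self, params, life_table):
        """The untreated arm's months 6-9 recurrence risk is carried into
        the matrix uncomposited at its published per-cycle value."""
        arm = ArmSpec("no_treatment", 4, 829)
        model = _RiskModel(arm, params, life_table)
        from vtecea.engine import MK_TRACK, TH_NONE
        risks = model.risks(0, TH_NONE, 0, MK_TRACK)
        assert risks.recurrence == pytest.approx(0.0277, abs=1e-12)

    def test_zero_risk_zero_mortality_track_rows_identity(
        self, params, zero_life_table, short_arm
    ):
        """With all risks off, live track states and the absorbing states
        are identity rows; one-cycle event tunnels still empty back into
        the treatment track by construction."""
        inert = make_inert_params(params)
        matrix = build_matrix(short_arm(), 0, inert, zero_life_table)
        for state in (
            HealthState.ON_TREATMENT_NO_EVENT, HealthState.CTEPH,
            HealthState.OFF_TREATMENT_NO_EVENT, *ABSORBING_STATES,
        ):
            assert matrix[state, state] == pytest.approx(1.0, abs=1e-12)
        for tunnel in (
            HealthState.RECURRENT_DVT, HealthState.RECURRENT_PE,
            HealthState.MB_NON_IC, HealthState.CRNMB,
        ):
            assert matrix[tunnel, HealthState.ON_TREATMENT_NO_EVENT] == (
                pytest.approx(1.0, abs=1e-12)
            )
        assert matrix[
            HealthState.IC_BLEED, HealthState.OFF_TREATMENT_NO_EVENT
        ] == pytest.approx(1.0, abs=1e-12)


class TestRunCohort:
    def test_mass_conservation(self, params, life_table):
        arm = ArmSpec("apixaban", 40, 1000)
        trace = run_cohort(arm, params, life_table)
        totals = trace.occupancy.sum(axis=1)
        assert np.allclose(totals, 1000.0, atol=1e-9)

    def test_counters_non_decreasing(self, params, life_table):
        trace = run_cohort(ArmSpec("no_treatment", 20, 1000), params, life_table)
        cumulative = trace.cumulative_events.to_numpy()
        assert np.all(np.diff(cumulative, axis=0) >= -1e-12)

    def test_empty_cohort_gives_zero_trace(self, params, life_table):
        trace = run_cohort(ArmSpec("apixaban", 8, 0.0), params, life_table)
        assert trace.occupancy.sum() == 0.0
        assert trace.events.to_numpy().sum() == 0.0

    def test_zero_risk_run_counts_nothing(self, params, zero_life_table):
        inert = make_inert_params(params)
        trace = run_cohort(ArmSpec("apixaban", 8, 500), inert, zero_life_table)
        assert count_events(trace).sum() == 0
        # everyone survives in the no-event states
        assert trace.occupancy[-1, HealthState.ON_TREATMENT_NO_EVENT] == (
            pytest.approx(500.0, abs=1e-9)
        )

    def test_horizon_truncated_at_max_age(self, params, life_table):
        arm = ArmSpec("apixaban", 10_000, 100)
        trace = run_cohort(arm, params, life_table)
        assert trace.truncated
        assert trace.ages[-1] <= params.max_age + 0.25

    def test_raising_mb_risk_raises_mb_count(self, params, life_table):
        """Monotonicity under finite perturbation of a single event risk."""
        arm = ArmSpec("apixaban", 12, 1000)
        base_count = run_cohort(arm, params, life_table).events["nonfatal_extracranial_mb"].sum()
        bumped = params.with_overrides(
            mb_risk={
                "apixaban": ProbabilityEstimate(0.02, 0.02, 0.02, "beta", 12.0),
                "no_treatment": params.mb_risk["no_treatment"],
            }
        )
        bumped_count = run_cohort(arm, bumped, life_table).events["nonfatal_extracranial_mb"].sum()
        assert bumped_count > base_count

    def test_equalised_arms_produce_identical_traces(self, params, life_table):
        """With every treatment-specific risk copied across arms and the
        discontinuation channel closed, the two strategies coincide."""
        shared = params.with_overrides(
            recurrence={
                "apixaban": params.recurrence["apixaban"],
                "no_treatment": params.recurrence["apixaban"],
            },
            mb_risk={
                "apixaban": params.mb_risk["apixaban"],
                "no_treatment": params.mb_risk["apixaban"],
            },
            crnmb_risk={
                "apixaban": params.crnmb_risk["apixaban"],
                "no_treatment": params.crnmb_risk["apixaban"],
            },
            other_discontinuation=ProbabilityEstimate.fixed(0.0, basis=12.0),
        )
        t_apix = run_cohort(ArmSpec("apixaban", 4, 1000), shared, life_table)
        t_none = run_cohort(ArmSpec("no_treatment", 4, 1000), shared, life_table)
        pd.testing.assert_frame_equal(t_apix.events, t_none.events)

    def test_pts_pool_bounded(self, params, life_table):
        trace = run_cohort(ArmSpec("no_treatment", 80, 1000), params, life_table)
        alive = trace.occupancy[:, : int(HealthState.VTE_DEATH)].sum(axis=1)
        assert np.all(trace.pts_persons >= 0)
        assert np.all(trace.pts_persons <= alive + 1e-9)

    def test_discontinuation_lag_one_cycle(self, params, life_table):
        """Discontinuers spend one transition cycle at on-treatment risk:
        the off-treatment state only starts accumulating at cycle 2."""
        trace = run_cohort(ArmSpec("apixaban", 4, 1000), params, life_table)
        off = trace.occupancy[:, HealthState.OFF_TREATMENT_NO_EVENT]
        disc = trace.events["discontinuation"]
        assert off[0] == 0.0
        assert off[1] == pytest.approx(disc.iloc[0], abs=1e-9)


class TestCountEvents:
    def test_rounding_to_integers(self, params, life_table):
        trace = run_cohort(ArmSpec("apixaban", 4, 804), params, life_table)
        counts = count_events(trace)
        assert counts.dtype.kind == "i"
        assert counts["major_bleeding"] == (
            counts["fatal_mb"] + counts["nonfatal_ic_mb"]
            + counts["nonfatal_extracranial_mb"]
        ) or abs(
            counts["major_bleeding"]
            - (counts["fatal_mb"] + counts["nonfatal_ic_mb"]
               + counts["nonfatal_extracranial_mb"])
        ) <= 1  # component-wise rounding may differ by one
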