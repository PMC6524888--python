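"""Distribution fitting, parameter sampling, PSA reproducibility, CEAC and
tornado behaviour."""

import numpy as np
import pytest

from vtecea import (
    ArmSpec, HazardRatioEstimate, ProbabilityEstimate, ceac, fit_distribution,
    run_psa, sample_parameter_set, univariate_sweep,
)
from vtecea.uncertainty import (
    PSAResult, _override_parameter, _spec_mean, iteration_seed,
)
from vtecea.parameters import ParameterError


class TestFitDistribution:
    def test_symmetric_beta_preserves_mean(self):
        est = ProbabilityEstimate(0.5, 0.46, 0.54, "beta")
        spec = fit_distribution(est)
        assert spec.family == "beta"
        assert _spec_mean(spec) == pytest.approx(0.5, rel=1e-9)

    def test_published_mb_row_percentiles_bracket_ci(self):
        from scipy import stats
        est = ProbabilityEstimate(0.0048, 0.0001, 0.0096, "beta", 12.0)
        spec = fit_distribution(est)
        a, b = spec.params
        lo, hi = stats.beta.ppf([0.025, 0.975], a, b)
        width = est.ci_high - est.ci_low
        assert lo == pytest.approx(est.ci_low, abs=0.2 * width)
        assert hi == pytest.approx(est.ci_high, abs=0.2 * width)

    def test_gamma_and_lognormal_match_moments(self):
        est = HazardRatioEstimate(4.41, 3.63, 5.36, "gamma")
        spec = fit_distribution(est)
        assert _spec_mean(spec) == pytest.approx(4.41, rel=1e-9)
        est_ln = HazardRatioEstimate(1.97, 1.79, 2.16, "lognormal")
        spec_ln = fit_distribution(est_ln)
        assert _spec_mean(spec_ln) == pytest.approx(1.97, rel=1e-9)

    def test_fixed_entry_degenerate(self):
        est = ProbabilityEstimate.fixed(1.0)
        spec = fit_distribution(est)
        assert spec.family == "fixed"
        assert spec.sample(np.random.default_rng(0)) == 1.0

    def test_missing_ci_falls_back_to_cv(self):
        est = ProbabilityEstimate(0.1, 0.1, 0.1, "beta")
        spec = fit_distribution(est)
        # SE = 0.3 * mean by the fallback rule
        a, b = spec.params
        var = a * b / ((a + b) ** 2 * (a + b + 1))
        assert np.sqrt(var) == pytest.approx(0.03, rel=1e-6)

    def test_infeasible_beta_variance_rejected(self):
        est = ProbabilityEstimate(0.001, 0.0, 0.9, "beta")
        with pytest.raises(ParameterError):
            fit_distribution(est)

    def test_sampling_recovers_mean(self, params):
        """Large-sample moments recover the input mean for a spread of the
        packaged rows (the full sweep lives in the acceptance suite)."""
        rng = np.random.default_rng(12345)
        for est in (
            params.recurrence["no_treatment"][0],
            params.mb_risk["apixaban"],
            params.bleeding_age_factor,
            params.mortality_hr["index_dvt"],
        ):
            spec = fit_distribution(est)
            draws = np.array([spec.sample(rng) for _ in range(100_000)])
            se = draws.std() / np.sqrt(len(draws))
            assert abs(draws.mean() - est.mean) < 3 * se + 1e-12


class TestSampling:
    def test_same_seed_same_draw(self, params):
        a = sample_parameter_set(params, seed=7)
        b = sample_parameter_set(params, seed=7)
        assert a == b

    def test_different_seeds_differ(self, params):
        a = sample_parameter_set(params, seed=7)
        b = sample_parameter_set(params, seed=8)
        assert a != b

    def test_fixed_entries_never_move(self, params):
        for seed in range(5):
            drawn = sample_parameter_set(params, seed=seed)
            assert drawn.interruption_crnmb == params.interruption_crnmb

    def test_event_split_stays_on_simplex(self, params):
        for seed in range(5):
            drawn = sample_parameter_set(params, seed=seed)
            total = sum(e.mean for e in drawn.event_split.values())
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_draw_means_center_on_base(self, params):
        """Across draws each sampled parameter's mean stays within Monte
        Carlo error of its base value."""
        n = 400
        draws = [sample_parameter_set(params, seed=s) for s in range(n)]
        checks = {
            "recurrence": lambda p: p.recurrence["no_treatment"][0].mean,
            "mb": lambda p: p.mb_risk["no_treatment"].mean,
            "hr": lambda p: p.mortality_hr["index_dvt"].mean,
        }
        for label, getter in checks.items():
            values = np.array([getter(d) for d in draws])
            se = values.std() / np.sqrt(n)
            assert abs(values.mean() - getter(params)) < 4 * se, label


class TestPSA:
    def _arms(self):
        return (ArmSpec("apixaban", 8, 1000), ArmSpec("no_treatment", 8, 1000))

    def test_bit_reproducible(self, params, life_table):
        r1 = run_psa(self._arms(), params, life_table, n=3, master_seed=11)
        r2 = run_psa(self._arms(), params, life_table, n=3, master_seed=11)
        assert np.array_equal(r1.delta_costs, r2.delta_costs)
        assert np.array_equal(r1.delta_effects, r2.delta_effects)

    def test_iteration_seed_stable_and_small(self):
        assert iteration_seed(5, 3) == iteration_seed(5, 3)
        assert iteration_seed(5, 3) != iteration_seed(5, 4)
        assert 0 <= iteration_seed(123, 1999) < 2 ** 32

    def test_result_shape(self, params, life_table):
        res = run_psa(self._arms(), params, life_table, n=4, master_seed=1)
        assert res.n_iterations == 4
        assert res.as_frame().shape == (4, 2)


class TestCEAC:
    def test_wtp_zero_counts_cost_saving_draws(self):
        res = PSAResult(
            delta_costs=np.array([-10.0, 5.0, 20.0, -1.0]),
            delta_effects=np.array([0.1, 0.2, 0.3, -0.4]),
            master_seed=0,
        )
        point = ceac(res, [0.0])[0]
        assert point.probability_cost_effective == 0.5

    def test_identical_draws_step_at_icer(self):
        res = PSAResult(
            delta_costs=np.full(10, 900.0),
            delta_effects=np.full(10, 0.1),
            master_seed=0,
        )
        below, above = ceac(res, [8000.0, 10_000.0])
        assert below.probability_cost_effective == 0.0
        assert above.probability_cost_effective == 1.0

    def test_monotone_when_all_effects_positive(self, params, life_table):
        res = run_psa(
            (ArmSpec("apixaban", 8, 1000), ArmSpec("no_treatment", 8, 1000)),
            params, life_table, n=12, master_seed=3,
        )
        grid = [0, 5_000, 10_000, 20_000, 50_000, 100_000]
        if np.all(res.delta_effects > 0):
            probs = [p.probability_cost_effective for p in ceac(res, grid)]
            assert all(b >= a for a, b in zip(probs, probs[1:]))


class TestTornado:
    def test_zero_width_bounds_give_zero_width_entry(self, params, life_table):
        arms = (ArmSpec("apixaban", 8, 1000), ArmSpec("no_treatment", 8, 1000))
        entries = univariate_sweep(
            arms, params, life_table,
            bounds={"cteph_annual": (0.0125, 0.0125)},
        )
        assert len(entries) == 1
        assert entries[0].width == pytest.approx(0.0, abs=1e-9)

    def test_icer_monotone_in_drug_cost(self, params, life_table):
        """Incremental cost is linear in the apixaban unit price with the
        effect fixed, so the ICER rises with the price."""
        arms = (ArmSpec("apixaban", 12, 1000), ArmSpec("no_treatment", 12, 1000))
        name = "costs.drug_per_day.apixaban_extended"
        entries = univariate_sweep(
            arms, params, life_table, bounds={name: (1.0, 4.0)}
        )
        assert entries[0].icer_low < entries[0].icer_base < entries[0].icer_high

    def test_unknown_parameter_rejected(self, params):
        with pytest.raises(ParameterError):
            _override_parameter(params, "no.such.parameter", 1.0)
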