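"""Probability conversions, estimate invariants and the parameter loader."""

import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from vtecea import (
    CumulativeIncidenceCurve, ParameterError, ProbabilityEstimate,
    age_adjust_bleeding, apply_hazard_ratio, piecewise_recurrence_probability,
    to_cycle_probability, treatment_effect_rr,
)
from vtecea.parameters import from_cycle_probability, parameters_from_dict


class TestCycleConversion:
    @pytest.mark.parametrize(
        "p, basis, cycle, expected",
        [
            (0.0300, 12, 3, 0.0075858827),   # annual risk to 3-month cycle
            (0.0, 12, 3, 0.0),
            (0.0277, 3, 3, 0.0277),          # already per-cycle: identity
            (0.0812, 60, 3, 1 - (1 - 0.0812) ** (3 / 60)),
        ],
    )
    def test_known_values(self, p, basis, cycle, expected):
        assert to_cycle_probability(p, basis, cycle) == pytest.approx(
            expected, abs=1e-9
        )

    @pytest.mark.parametrize(
        "p, basis, cycle",
        [(1.0, 12, 3), (-0.1, 12, 3), (0.5, 0, 3), (0.5, 12, -1)],
    )
    def test_invalid_inputs_rejected(self, p, basis, cycle):
        with pytest.raises(ParameterError):
            to_cycle_probability(p, basis, cycle)

    def test_certain_event_identity_when_bases_match(self):
        assert to_cycle_probability(1.0, 3, 3) == 1.0

    @given(
        p=st.floats(0.0, 0.99),
        basis=st.sampled_from([3.0, 12.0, 60.0, 120.0]),
        cycle=st.floats(0.5, 3.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_round_trip(self, p, basis, cycle):
        """Converting a risk down to a shorter cycle and back is lossless
        (the direction every model conversion uses)."""
        assume(cycle <= basis)
        down = to_cycle_probability(p, basis, cycle)
        assert from_cycle_probability(down, cycle, basis) == pytest.approx(
            p, abs=1e-12
        )


class TestHazardRatio:
    def test_identity_and_zero(self):
        assert apply_hazard_ratio(0.37, 1.0) == pytest.approx(0.37, abs=1e-15)
        assert apply_hazard_ratio(0.0, 2.60) == 0.0

    def test_mortality_hr_value(self):
        assert apply_hazard_ratio(0.01, 4.41) == pytest.approx(
            0.0433541140, abs=1e-9
        )

    def test_invalid_hr(self):
        with pytest.raises(ParameterError):
            apply_hazard_ratio(0.1, 0.0)

    @given(
        p=st.floats(1e-6, 0.9),
        hr1=st.floats(0.1, 5.0),
        hr2=st.floats(0.1, 5.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_strictly_increasing_in_hr(self, p, hr1, hr2):
        lo, hi = sorted((hr1, hr2))
        if hi - lo > 1e-9:
            assert apply_hazard_ratio(p, lo) < apply_hazard_ratio(p, hi)


class TestAgingAdjustment:
    def test_no_elapsed_decades_is_identity(self):
        assert age_adjust_bleeding(0.0123, 60.0, 60.0, 1.97) == pytest.approx(
            0.0123, abs=1e-15
        )

    @pytest.mark.parametrize(
        "decades, expected",
        [(1, 0.0094339854), (2, 0.0184999080)],
    )
    def test_decade_steps(self, decades, expected):
        out = age_adjust_bleeding(0.0048, 56.9 + 10 * decades, 56.9, 1.97)
        assert out == pytest.approx(expected, abs=1e-9)

    def test_runaway_probability_clamped(self):
        # 5 decades at factor 1.97 on a large base risk exceeds the cap
        assert age_adjust_bleeding(0.5, 100.0, 50.0, 1.97) == 0.999

    def test_age_below_reference_rejected(self):
        with pytest.raises(ParameterError):
            age_adjust_bleeding(0.01, 55.0, 60.0, 1.97)


class TestPiecewiseRecurrence:
    CURVE = CumulativeIncidenceCurve(
        ((0.0, 0.0), (1.0, 0.110), (3.0, 0.196), (5.0, 0.291), (10.0, 0.399))
    )

    def test_mid_segment_value(self):
        assert piecewise_recurrence_probability(self.CURVE, 2.0, 3) == pytest.approx(
            0.0126224345, abs=1e-9
        )

    def test_first_segment_value(self):
        assert piecewise_recurrence_probability(self.CURVE, 0.25, 3) == pytest.approx(
            0.0287131664, abs=1e-9
        )

    def test_flat_curve_gives_zero(self):
        flat = CumulativeIncidenceCurve(((0.0, 0.0), (1.0, 0.0), (5.0, 0.0)))
        assert piecewise_recurrence_probability(flat, 2.0, 3) == 0.0

    def test_last_segment_hazard_persists(self):
        inside = piecewise_recurrence_probability(self.CURVE, 9.0, 3)
        beyond = piecewise_recurrence_probability(self.CURVE, 25.0, 3)
        assert beyond == pytest.approx(inside, abs=1e-15)

    def test_compounding_reproduces_knots(self):
        """Brute-force compounding across every segment recovers the input
        cumulative incidences."""
        survival = 1.0
        t = 0.0
        for knot_t, knot_ci in self.CURVE.knots[1:]:
            while t < knot_t - 1e-9:
                p = piecewise_recurrence_probability(self.CURVE, t, 3)
                survival *= 1 - p
                t += 0.25
            assert 1 - survival == pytest.approx(knot_ci, abs=1e-9)

    def test_decreasing_curve_rejected(self):
        with pytest.raises(ParameterError):
            CumulativeIncidenceCurve(((0.0, 0.0), (1.0, 0.2), (2.0, 0.1)))


class TestTreatmentEffect:
    BASE = {
        "apixaban": [0.0048, 0.0059, 0.0012, 0.0036],
        "no_treatment": [0.0277, 0.0265, 0.0217, 0.0121],
    }

    def test_base_case_ratio(self):
        assert treatment_effect_rr(self.BASE) == pytest.approx(0.17444, abs=1e-4)

    def test_identical_arms_give_unity(self):
        same = {"apixaban": [0.01, 0.02], "no_treatment": [0.01, 0.02]}
        assert treatment_effect_rr(same) == pytest.approx(1.0, abs=1e-12)

    def test_full_protection_gives_zero(self):
        arms = {"apixaban": [0.0, 0.0], "no_treatment": [0.02, 0.02]}
        assert treatment_effect_rr(arms) == 0.0

    def test_zero_untreated_risk_rejected(self):
        with pytest.raises(ParameterError):
            treatment_effect_rr(
                {"apixaban": [0.01], "no_treatment": [0.0]}
            )


class TestEstimateInvariants:
    def test_ci_ordering_enforced(self):
        with pytest.raises(ParameterError):
            ProbabilityEstimate(0.0110, 0.0950, 0.1250)

    def test_fixed_requires_degenerate_ci(self):
        with pytest.raises(ParameterError):
            ProbabilityEstimate(0.5, 0.4, 0.6, "fixed")

    def test_loader_rejects_bad_ci(self):
        """A transcription error that breaks CI ordering is refused with
        the offending key path named."""
        import yaml
        from importlib import resources
        source = resources.files("vtecea").joinpath("data/base_parameters.yaml")
        raw = yaml.safe_load(source.read_text())
        raw["transition_probabilities"]["recurrence"]["apixaban"][0]["ci_low"] = 0.9
        with pytest.raises(ParameterError, match="recurrence.apixaban"):
            parameters_from_dict(raw)

    def test_loader_rejects_missing_section(self):
        with pytest.raises(ParameterError):
            parameters_from_dict({"model": {}, "transition_probabilities": {},
                                  "costs": {}, "utilities": {}})


class TestFixture:
    """The packaged parameter fixture carries the published base case."""

    def test_recurrence_values(self, params):
        assert params.recurrence["apixaban"][0].mean == 0.0048
        assert params.recurrence["no_treatment"][3].mean == 0.0121

    def test_cteph_and_split(self, params):
        assert params.cteph_annual.mean == 0.0125
        total = sum(e.mean for e in params.event_split.values())
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_first_year_knot_stored_corrected(self, params):
        # the published table prints 0.0110; the CI identifies 0.110
        assert params.post_cessation.knots[1] == (1.0, 0.110)

    def test_every_cost_and_utility_is_flagged_placeholder(self, params):
        flagged = set(params.placeholder_names())
        assert all(k.startswith(("costs.", "utilities.")) for k in flagged)
        for key in params.costs.provenance:
            assert key in flagged

    def test_demographics(self, params):
        assert params.start_age == 56.9
        assert params.male_fraction == 0.58
        assert params.index_pe_fraction == 0.34
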