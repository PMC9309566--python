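"""Parameter container, schedule conversion, cost averaging, distribution fits."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hboc_cea import (cumulative_to_conditional, fit_distribution, get_path,
                      load_parameters, set_path, validate)
from hboc_cea import test_cost_per_woman as family_test_cost
from hboc_cea.params import CumulativeSchedule, conditional_schedule


def reaccumulate(cond):
    """Independent oracle: push a unit cohort through conditional probabilities."""
    alive, cum = 1.0, []
    for c in cond:
        alive *= 1.0 - c
        cum.append(1.0 - alive)
    return cum


class TestCumulativeToConditional:
    @pytest.mark.parametrize("cum, expected", [
        # metastatic breast-cancer mortality, years 1..5
        ([0.37, 0.61, 0.76, 0.85, 0.90],
         [0.37, 0.38095238, 0.38461538, 0.375, 0.33333333]),
        # ovarian-cancer mortality
        ([0.10, 0.18, 0.25, 0.32, 0.39],
         [0.10, 0.08888889, 0.08536585, 0.09333333, 0.10294118]),
        ([0, 0, 0, 0, 0], [0, 0, 0, 0, 0]),
    ])
    def test_examples(self, cum, expected):
        cond = cumulative_to_conditional(CumulativeSchedule(cum=list(cum))).cond
        assert cond == pytest.approx(expected, abs=1e-6)
        assert reaccumulate(cond) == pytest.approx(cum, abs=1e-12)

    def test_first_year_equals_cumulative(self):
        sched = CumulativeSchedule(cum=[0.2, 0.3, 0.5, 0.6, 0.8])
        assert cumulative_to_conditional(sched).cond[0] == 0.2

    @given(st.lists(st.floats(0.0, 1.0), min_size=5, max_size=5))
    @settings(derandomize=True, max_examples=200)
    def test_round_trip_property(self, raw):
        cum = sorted(min(x, 0.999999) for x in raw)
        cond = cumulative_to_conditional(CumulativeSchedule(cum=cum)).cond
        assert reaccumulate(cond) == pytest.approx(cum, abs=1e-12)

    def test_non_monotone_raises_with_year(self):
        with pytest.raises(ValueError, match="year 3"):
            cumulative_to_conditional(CumulativeSchedule(cum=[0.3, 0.5, 0.4, 0.6, 0.7]))

    def test_saturated_schedule_warns_and_fills_ones(self):
        with pytest.warns(UserWarning):
            out = cumulative_to_conditional(
                CumulativeSchedule(cum=[0.5, 1.0, 1.0, 1.0, 1.0]))
        assert out.cond[2:] == [1.0, 1.0, 1.0]

    def test_tail_policies(self):
        hold = conditional_schedule(CumulativeSchedule(cum=[0.1] * 5, tail="hold"),
                                    "conditional")
        none = conditional_schedule(CumulativeSchedule(cum=[0.1] * 5, tail="none"),
                                    "conditional")
        assert hold.tail == 0.1 and none.tail == 0.0
        assert hold.at_year(9) == 0.1 and none.at_year(9) == 0.0

    def test_conditional_form_uses_values_verbatim(self):
        sched = CumulativeSchedule(cum=[0.37, 0.61, 0.76, 0.85, 0.90])
        assert conditional_schedule(sched, "conditional").cond == sched.cum
        assert conditional_schedule(sched, "cumulative").cond[1] == \
            pytest.approx((0.61 - 0.37) / (1 - 0.37))


class TestTestCost:
    @pytest.mark.parametrize("n, expected", [(2, 1135.0), (1, 2035.0), (4, 685.0)])
    def test_family_averaging(self, n, expected):
        assert family_test_cost(1800, 235, n) == pytest.approx(expected)

    def test_zero_relatives_rejected(self):
        with pytest.raises(ValueError):
            family_test_cost(1800, 235, 0)

    def test_strictly_decreasing_to_relative_cost(self):
        costs = [family_test_cost(1800, 235, n) for n in range(1, 200)]
        assert all(a > b for a, b in zip(costs, costs[1:]))
        assert costs[-1] == pytest.approx(235, rel=0.05)


class TestFitDistribution:
    def test_beta_moments_closed_form(self):
        spec = fit_distribution(0.5, sd=0.1, family="beta")
        assert spec.params["a"] == pytest.approx(12.0)
        assert spec.params["b"] == pytest.approx(12.0)

    def test_gamma_moments_closed_form(self):
        spec = fit_distribution(1135, sd=454, family="gamma")
        assert spec.params["shape"] == pytest.approx(6.25)
        assert spec.params["scale"] == pytest.approx(181.6)

    def test_range_to_sd(self):
        spec = fit_distribution(0.03, lo=0.02, hi=0.04, family="beta")
        assert spec.sd == pytest.approx((0.04 - 0.02) / 3.92)
        assert spec.sd == pytest.approx(0.00510204, abs=1e-8)

    @pytest.mark.parametrize("mean, sd, family", [
        (0.013, 0.052, "beta"), (0.34, 0.30, "beta"), (0.92, 0.0072, "beta"),
        (428.85, 171.54, "gamma"),
    ])
    def test_analytic_mean_reproduced(self, mean, sd, family):
        spec = fit_distribution(mean, sd=sd, family=family)
        assert spec.analytic_mean() == pytest.approx(mean, abs=1e-9)

    def test_monte_carlo_moments(self):
        rng = np.random.default_rng(7)
        for spec in (fit_distribution(0.5, sd=0.1, family="beta"),
                     fit_distribution(1135, sd=454, family="gamma")):
            x = spec.sample(rng, 10**6)
            assert abs(x.mean() - spec.mean) < 3 * spec.sd / 1000
            assert x.std() == pytest.approx(spec.sd, rel=0.02)

    def test_infeasible_beta_sd_shrunk(self):
        with pytest.warns(UserWarning, match="infeasible"):
            spec = fit_distribution(0.9, sd=0.5, family="beta")
        assert spec.sd < math.sqrt(0.9 * 0.1)
        assert spec.analytic_mean() == pytest.approx(0.9, abs=1e-9)

    def test_support_errors(self):
        with pytest.raises(ValueError):
            fit_distribution(1.5, sd=0.1, family="beta")
        with pytest.raises(ValueError):
            fit_distribution(-3.0, sd=1.0, family="gamma")


class TestValidateAndGolden:
    def test_shipped_basecase_validates_clean(self, base_params):
        assert validate(base_params) == []

    def test_uptake_sum_flagged(self, params):
        params.probabilities.uptake.mastectomy = 0.5
        params.probabilities.uptake.oophorectomy = 0.4
        params.probabilities.uptake.both = 0.3
        assert any("uptake sum > 1" in f.message for f in validate(params))

    def test_negative_discount_flagged(self, params):
        params.model.discount_rate = -0.01
        assert any(f.path == "model.discount_rate" for f in validate(params))

    def test_bad_schedule_length_flagged(self, params):
        params.costs.oc_yearly = [1.0, 2.0]
        assert any("oc_yearly" in f.path for f in validate(params))

    def test_golden_values_match_published_tables(self, base_params):
        """The shipped config is the published input tables, verbatim."""
        expected = {
            "probabilities.p_positive_test": 0.18,
            "probabilities.uptake.mastectomy": 0.03,
            "probabilities.uptake.oophorectomy": 0.12,
            "probabilities.uptake.both": 0.12,
            "probabilities.well_to_bc_carrier.bands.0.p": 0.012,
            "probabilities.well_to_bc_carrier.bands.5.p": 0.037,
            "probabilities.well_to_bc_noncarrier.bands.0.p": 0.0011,
            "probabilities.well_to_oc_carrier": 0.013,
            "probabilities.well_to_oc_noncarrier": 0.00008728,
            "probabilities.all_cause_mortality.bands.0.p": 0.004,
            "probabilities.all_cause_mortality.bands.11.p": 1.0,
            "probabilities.recurrence_bc_carrier": 0.069,
            "probabilities.recurrence_bc_noncarrier": 0.003,
            "probabilities.bc_mortality": 0.006,
            "probabilities.bc_to_metastatic": 0.0134,
            "probabilities.bc_to_oc": 0.007,
            "probabilities.metastatic_death.cum": [0.37, 0.61, 0.76, 0.85, 0.90],
            "probabilities.oc_death.cum": [0.10, 0.18, 0.25, 0.32, 0.39],
            "probabilities.post_surgery.bc_after_oophorectomy.bands.0.p": 0.014,
            "probabilities.post_surgery.oc_after_oophorectomy": 0.01,
            "utilities.baseline_age30": 0.920,
            "utilities.annual_age_decrement": 0.00029,
            "utilities.mastectomy.multiplier": 0.88,
            "utilities.oophorectomy.multiplier": 0.95,
            "utilities.both.multiplier": 0.83,
            "utilities.bc.multiplier": 0.77,
            "utilities.bc.post_multiplier": 0.79,
            "utilities.metastatic": 0.64,
            "utilities.oc.multiplier": 0.34,
            "utilities.oc.post_multiplier": 0.83,
            "costs.index_test": 1800.0,
            "costs.relative_test": 235.0,
            "costs.n_relatives_per_index": 2,
            "costs.intensive_screening_annual": 428.85,
            "costs.standard_care_annual": 55.00,
            "costs.surgery.mastectomy": 3484.26,
            "costs.surgery.oophorectomy": 621.00,
            "costs.surgery.both": 4105.26,
            "costs.bc_index_yearly": [17813.11, 958.95, 719.03, 719.03, 719.03],
            "costs.bc_relative_yearly": [16540.09, 934.27, 719.03, 719.03, 719.03],
            "costs.metastatic_yearly": [18392.61, 17285.58, 14949.91, 15914.02, 15914.02],
            "costs.oc_yearly": [14224.92, 1654.11, 6487.23, 240.68, 240.68],
            "model.discount_rate": 0.05,
            "model.horizon_years": 70,
            "model.start_age": 30,
        }
        for path, value in expected.items():
            assert get_path(base_params, path) == value, path
        # the published high-risk well utility (0.92) coincides with the
        # published age-30 baseline (0.920): no net decrement
        u = base_params.utilities
        assert u.baseline_age30 * u.multiplier_high_risk == pytest.approx(0.92)
        assert base_params.costs.test_cost == pytest.approx(1135.0)

    def test_dotted_path_roundtrip_and_casting(self, params):
        set_path(params, "model.discount_rate", "0.1")
        assert params.model.discount_rate == 0.1
        set_path(params, "costs.bc_index_yearly.0", 100.0)
        assert get_path(params, "costs.bc_index_yearly.0") == 100.0
        set_path(params, "costs.n_relatives_per_index", "4")
        assert params.costs.n_relatives_per_index == 4

    def test_load_with_override_strings(self):
        p = load_parameters(overrides=["model.discount_rate=0.0"])
        assert p.model.discount_rate == 0.0

    def test_copy_isolates_base_case(self, base_params):
        clone = base_params.copy()
        clone.probabilities.uptake.mastectomy = 0.9
        assert base_params.probabilities.uptake.mastectomy == 0.03
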