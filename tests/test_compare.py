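"""Tests of feeding-rate fitting, cross-scenario projection and bias stats."""

import math

import numpy as np
import pytest
from scipy import stats

from thermoniche import (
    WeightAtAge,
    age_specific_consumption,
    compare,
    fit_p_schedule,
    fit_p_year,
    paired_t,
    project_with_p,
    simulate,
)
from thermoniche.errors import DomainError, FitError
from thermoniche.scenarios import TemperatureScenario


@pytest.fixture(scope="module")
def cs_scenario(cs_params):
    """Constant 12 degC year (below the Thornton-Lessem optimum)."""
    return TemperatureScenario.from_nodes("flat12", cs_params.sim_start, [12.0] * 13)


class TestPairedT:
    def test_matches_independent_implementation(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 40))
            a = rng.normal(0, 2, n)
            b = a + rng.normal(0.3, 1, n)
            mine = paired_t(a, b)
            ref = stats.ttest_rel(a, b)
            assert mine.t == pytest.approx(ref.statistic, abs=1e-10)
            assert mine.df == n - 1
            assert mine.pvalue == pytest.approx(ref.pvalue, abs=1e-10)

    def test_closed_form_ten_pairs(self):
        a = np.arange(10.0)
        b = a + np.array([1.0, 0.5, 2.0, 1.5, 0.0, 1.0, 2.5, 0.5, 1.0, 1.5])
        d = a - b
        t_expected = d.mean() / (d.std(ddof=1) / math.sqrt(10))
        res = paired_t(a, b)
        assert res.t == pytest.approx(t_expected, abs=1e-12)
        assert res.df == 9

    def test_constant_difference_is_degenerate(self):
        res = paired_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert res.degenerate
        assert res.mean_diff == pytest.approx(-1.0)

    def test_identical_samples_degenerate_with_zero_t(self):
        res = paired_t([1.0, 2.0], [1.0, 2.0])
        assert res.degenerate and res.t == 0.0


class TestFitPYear:
    def test_round_trip_recovers_p(self, cs_params, cs_diet, ed_models, cs_scenario):
        ed = ed_models["chinook_salmon"]
        for p_true in (0.25, 0.6, 0.95):
            end = simulate(300.0, cs_scenario.daily, [p_true], cs_diet, ed,
                           cs_params).final_weight
            p_fit = fit_p_year(300.0, end, cs_scenario.daily, cs_diet, ed, cs_params)
            assert p_fit == pytest.approx(p_true, abs=1e-4)
            refit_end = simulate(300.0, cs_scenario.daily, [p_fit], cs_diet, ed,
                                 cs_params).final_weight
            assert abs(refit_end - end) <= 0.01

    def test_target_at_starvation_weight_gives_zero(
        self, lt_params, lt_diet, ed_models, lt_observed_scenario
    ):
        ed = ed_models["lake_trout"]
        w0 = simulate(5000.0, lt_observed_scenario.daily, [0.0], lt_diet, ed,
                      lt_params).final_weight
        assert fit_p_year(5000.0, w0, lt_observed_scenario.daily, lt_diet, ed,
                          lt_params) == 0.0

    def test_unreachable_target_raises(self, cs_params, cs_diet, ed_models, cs_scenario):
        with pytest.raises(FitError, match="unreachable"):
            fit_p_year(300.0, 5e6, cs_scenario.daily, cs_diet,
                       ed_models["chinook_salmon"], cs_params)

    def test_target_below_starvation_raises(
        self, lt_params, lt_diet, ed_models, lt_observed_scenario
    ):
        with pytest.raises(FitError, match="starvation"):
            fit_p_year(5000.0, 100.0, lt_observed_scenario.daily, lt_diet,
                       ed_models["lake_trout"], lt_params)


class TestFitPSchedule:
    def test_two_year_round_trip(self, cs_params, cs_diet, ed_models, cs_scenario):
        ed = ed_models["chinook_salmon"]
        p_true = [0.7, 0.55]
        traj = simulate(200.0, cs_scenario.daily, p_true, cs_diet, ed, cs_params)
        waa = WeightAtAge(
            ages=(0, 1, 2),
            weights=(200.0, traj.age_summaries[0].end_weight, traj.final_weight),
        )
        fitted = fit_p_schedule(waa, cs_scenario, cs_diet, ed, cs_params)
        assert fitted == pytest.approx(p_true, abs=1e-4)

    def test_single_year_span(self, cs_params, cs_diet, ed_models, cs_scenario):
        ed = ed_models["chinook_salmon"]
        end = simulate(400.0, cs_scenario.daily, [0.5], cs_diet, ed,
                       cs_params).final_weight
        waa = WeightAtAge(ages=(1, 2), weights=(400.0, end))
        fitted = fit_p_schedule(waa, cs_scenario, cs_diet, ed, cs_params)
        assert fitted.shape == (1,)
        assert fitted[0] == pytest.approx(0.5, abs=1e-4)

    def test_fit_error_names_age(self, cs_params, cs_diet, ed_models, cs_scenario):
        waa = WeightAtAge(ages=(0, 1, 2), weights=(200.0, 300.0, 5e6))
        with pytest.raises(FitError, match="age 1 -> 2"):
            fit_p_schedule(waa, cs_scenario, cs_diet, ed_models["chinook_salmon"],
                           cs_params)


class TestProjection:
    def test_same_scenario_round_trip(self, cs_params, cs_diet, ed_models, cs_scenario):
        ed = ed_models["chinook_salmon"]
        p_true = [0.7, 0.55]
        traj = simulate(200.0, cs_scenario.daily, p_true, cs_diet, ed, cs_params)
        waa = WeightAtAge(
            ages=(0, 1, 2),
            weights=(200.0, traj.age_summaries[0].end_weight, traj.final_weight),
        )
        fitted = fit_p_schedule(waa, cs_scenario, cs_diet, ed, cs_params)
        proj = project_with_p(fitted, cs_scenario, 200.0, cs_diet, ed, cs_params)
        assert proj.final_weight == pytest.approx(traj.final_weight, abs=0.05)

    def test_warmer_scenario_below_optimum_grows_more(
        self, cs_params, cs_diet, ed_models
    ):
        ed = ed_models["chinook_salmon"]
        cool = TemperatureScenario.from_nodes("cool", cs_params.sim_start, [9.0] * 13)
        warm = TemperatureScenario.from_nodes("warm", cs_params.sim_start, [12.0] * 13)
        w_cool = project_with_p([0.6], cool, 300.0, cs_diet, ed, cs_params).final_weight
        w_warm = project_with_p([0.6], warm, 300.0, cs_diet, ed, cs_params).final_weight
        assert w_warm > w_cool


class TestAgeSpecificConsumption:
    def test_starvation_endpoint_gives_zero_series(
        self, lt_params, lt_diet, ed_models, lt_observed_scenario
    ):
        ed = ed_models["lake_trout"]
        end = simulate(5000.0, lt_observed_scenario.daily, [0.0], lt_diet, ed,
                       lt_params).final_weight
        series, total, p = age_specific_consumption(
            5000.0, end, lt_observed_scenario, lt_diet, ed, lt_params
        )
        assert p == 0.0
        assert np.all(series == 0.0)
        assert total == 0.0

    def test_bisection_matches_grid_search(
        self, lt_params, lt_diet, ed_models, lt_observed_scenario
    ):
        """Brute-force search over a fine p grid brackets the bisection fit."""
        ed = ed_models["lake_trout"]
        _, _, p_fit = age_specific_consumption(
            6573.0, 6980.0, lt_observed_scenario, lt_diet, ed, lt_params
        )
        grid = np.arange(0.0, 1.5, 0.005)
        ends = np.array([
            simulate(6573.0, lt_observed_scenario.daily, [p], lt_diet, ed,
                     lt_params).final_weight
            for p in grid
        ])
        best = grid[np.argmin(np.abs(ends - 6980.0))]
        assert abs(p_fit - best) <= 0.005

    def test_annual_total_is_daily_sum(
        self, lt_params, lt_diet, ed_models, lt_observed_scenario
    ):
        ed = ed_models["lake_trout"]
        series, total, p = age_specific_consumption(
            6573.0, 6980.0, lt_observed_scenario, lt_diet, ed, lt_params
        )
        traj = simulate(6573.0, lt_observed_scenario.daily, [p], lt_diet, ed, lt_params)
        assert total == pytest.approx(float((series * traj.weights[:-1]).sum()), rel=1e-9)

    def test_richer_diet_halves_ration_grams(
        self, lt_params, ed_models, lt_observed_scenario, simple_diet
    ):
        """Doubling prey energy density with the same growth endpoints leaves
        annual energy intake nearly unchanged, so grams roughly halve."""
        from thermoniche.params import DietItem, DietSchedule

        rich = DietSchedule(items=(DietItem("prey", 1.0, 10000.0, 0.0),))
        ed = ed_models["lake_trout"]
        _, total_lean, _ = age_specific_consumption(
            6573.0, 6980.0, lt_observed_scenario, simple_diet, ed, lt_params
        )
        _, total_rich, _ = age_specific_consumption(
            6573.0, 6980.0, lt_observed_scenario, rich, ed, lt_params
        )
        energy_lean = total_lean * 5000.0
        energy_rich = total_rich * 10000.0
        assert energy_rich == pytest.approx(energy_lean, rel=0.05)
        assert total_rich == pytest.approx(total_lean / 2.0, rel=0.05)


class TestCompare:
    def test_identical_scenarios_zero_bias(
        self, cs_params, cs_diet, ed_models, cs_scenario
    ):
        ed = ed_models["chinook_salmon"]
        traj = simulate(200.0, cs_scenario.daily, [0.7, 0.6, 0.55, 0.5], cs_diet, ed,
                        cs_params)
        waa = WeightAtAge(
            ages=tuple(range(0, 5)),
            weights=(200.0, *(s.end_weight for s in traj.age_summaries)),
        )
        comp = compare(cs_scenario, cs_scenario, waa, cs_diet, ed, cs_params)
        assert comp.final_weight_pct_bias == pytest.approx(0.0, abs=1e-3)
        assert comp.daily_C_pct_bias == pytest.approx(0.0, abs=1e-6)
        assert comp.lifetime_consumption_pct_bias == pytest.approx(0.0, abs=1e-3)
        assert comp.p_ttest.degenerate or abs(comp.p_ttest.t) < 1e-6

    def test_requires_age_endpoints(self, cs_params, cs_diet, ed_models, cs_scenario):
        from dataclasses import replace

        stripped = replace(cs_params, age_specific_endpoints=None)
        waa = WeightAtAge(ages=(0, 1), weights=(200.0, 900.0))
        with pytest.raises(DomainError):
            compare(cs_scenario, cs_scenario, waa, cs_diet,
                    ed_models["chinook_salmon"], stripped)
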