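"""Unit and property tests of the daily mass-balance engine."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermoniche import (
    ConsumptionParams,
    consumption_ft,
    max_consumption,
    realized_consumption,
    respiration,
    simulate,
    step_day,
    waste,
)
from thermoniche.engine import thornton_lessem_factors
from thermoniche.errors import (
    ConfigurationError,
    DomainError,
    NumericalRangeError,
    SimulationError,
)
from thermoniche.params import DietItem, DietSchedule

from conftest import make_toy_params


# ---------------------------------------------------------------------------
# consumption temperature dependence

class TestConsumptionFt:
    def test_dome_is_one_at_optimum_and_zero_at_maximum(self, toy_params):
        c = toy_params.consumption
        assert consumption_ft(c.CTO, toy_params) == 1.0
        assert consumption_ft(c.CTM, toy_params) == 0.0

    def test_dome_clamps_to_zero_above_maximum(self, toy_params):
        assert consumption_ft(toy_params.consumption.CTM + 5.0, toy_params) == 0.0

    def test_double_sigmoid_fixed_points(self, cs_params):
        c = cs_params.consumption
        KA, _ = thornton_lessem_factors(c.CTO, c)
        _, KB = thornton_lessem_factors(c.CTM, c)
        assert KA == pytest.approx(0.98, abs=1e-12)
        assert KB == pytest.approx(0.98, abs=1e-12)

    def test_exponential_form(self, lt_params):
        c = lt_params.consumption
        assert consumption_ft(7.0, lt_params) == pytest.approx(math.exp(c.CQ * 7.0))

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        cq=st.floats(1.5, 4.0),
        cto=st.floats(5.0, 20.0),
        span=st.floats(1.0, 15.0),
        t_frac=st.floats(0.0, 1.0),
    )
    def test_dome_bounded_by_one(self, cq, cto, span, t_frac):
        c = ConsumptionParams(
            CA=0.05, CB=0.0, CEQ=2, CQ=cq, CTO=cto, CTM=cto + span
        )
        params = replace(make_toy_params(), consumption=c)
        T = cto + t_frac * span
        f = consumption_ft(T, params)
        assert 0.0 <= f <= 1.0 + 1e-12
        assert consumption_ft(cto, params) == 1.0

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        ck1=st.floats(0.01, 0.99),
        ck4=st.floats(0.01, 0.99),
        cq=st.floats(1.0, 8.0),
        d1=st.floats(0.5, 10.0),
        d2=st.floats(0.5, 10.0),
    )
    def test_double_sigmoid_fixed_points_for_random_parameters(
        self, ck1, ck4, cq, d1, d2
    ):
        """The ascending factor equals 0.98 at CTO and the descending factor
        0.98 at CTM, for any valid steepness constants."""
        c = ConsumptionParams(
            CA=0.3, CB=0.0, CEQ=3, CQ=cq,
            CTO=cq + d1, CTM=cq + d1 + d2, CTL=cq + d1 + 2 * d2,
            CK1=ck1, CK4=ck4,
        )
        c.validate()
        KA, _ = thornton_lessem_factors(c.CTO, c)
        _, KB = thornton_lessem_factors(c.CTM, c)
        assert abs(KA - 0.98) < 1e-9
        assert abs(KB - 0.98) < 1e-9

    def test_invalid_selector_rejected(self):
        with pytest.raises(ConfigurationError):
            ConsumptionParams(CA=0.1, CB=0.0, CEQ=4, CQ=1.0).validate()

    def test_cto_below_cq_rejected_for_double_sigmoid(self):
        with pytest.raises(ConfigurationError):
            ConsumptionParams(
                CA=0.1, CB=0.0, CEQ=3, CQ=10.0, CTO=5.0, CTM=18.0, CTL=24.0,
                CK1=0.3, CK4=0.01,
            ).validate()


class TestMaxConsumption:
    def test_unit_weight_gives_intercept(self, lt_params):
        assert max_consumption(1.0, lt_params) == lt_params.consumption.CA

    def test_zero_exponent_is_weight_independent(self, toy_params):
        assert max_consumption(3.0, toy_params) == max_consumption(3000.0, toy_params)

    def test_log_space_oracle(self, lt_params):
        # independent evaluation of CA * 1000^CB in log space
        expected = math.exp(math.log(0.0589) - 0.307 * math.log(1000.0))
        assert max_consumption(1000.0, lt_params) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_weight_rejected(self, lt_params):
        with pytest.raises(DomainError):
            max_consumption(0.0, lt_params)


class TestRealizedConsumption:
    def test_zero_p_gives_zero(self, lt_params):
        assert realized_consumption(500.0, 8.0, 0.0, lt_params) == 0.0

    def test_full_ration_at_optimum_equals_cmax(self, toy_params):
        W = 700.0
        c = realized_consumption(W, toy_params.consumption.CTO, 1.0, toy_params)
        assert c == pytest.approx(max_consumption(W, toy_params))

    def test_linear_in_p(self, cs_params):
        c1 = realized_consumption(800.0, 12.0, 0.3, cs_params)
        c2 = realized_consumption(800.0, 12.0, 0.6, cs_params)
        assert c2 == pytest.approx(2.0 * c1, rel=1e-12)

    def test_negative_p_rejected(self, cs_params):
        with pytest.raises(DomainError):
            realized_consumption(800.0, 12.0, -0.1, cs_params)


# ---------------------------------------------------------------------------
# waste and respiration

class TestWaste:
    def test_zero_consumption_gives_zero_losses(self, lt_params, lt_diet):
        assert waste(0.0, 8.0, 0.5, lt_diet, lt_params) == (0.0, 0.0)

    def test_proportional_form_direct_product(self, simple_diet):
        params = make_toy_params(FA=0.2, UA=0.0)
        EF, EU = waste(0.01, 10.0, 0.5, simple_diet, params)
        assert EF == pytest.approx(10.0)  # 0.2 * 0.01 * 5000 J/g/d
        assert EU == 0.0

    def test_elliott_form_with_fully_digestible_diet(self, lt_params, simple_diet):
        """With all indigestible fractions zero, the corrected egestion
        proportion reduces to (PE - 0.1) / 0.9."""
        w = lt_params.waste
        C, T, p = 0.02, 6.0, 0.6
        PE = w.FA * T ** w.FB * math.exp(w.FG * p)
        expected_F = ((PE - 0.1) / 0.9) * C
        EF, _ = waste(C, T, p, simple_diet, lt_params)
        assert EF == pytest.approx(expected_F * simple_diet.mean_energy_density, rel=1e-12)

    def test_egestion_proportion_out_of_range_raises(self, lt_params, lt_diet):
        # very high feeding rate in cold water blows the Elliott proportion
        with pytest.raises(NumericalRangeError):
            waste(0.05, 1.0, 5.0, lt_diet, lt_params)

    def test_losses_bounded_by_intake(self, lt_params, lt_diet):
        C, T, p = 0.015, 7.0, 0.7
        EC = C * lt_diet.mean_energy_density
        EF, EU = waste(C, T, p, lt_diet, lt_params)
        assert 0.0 <= EF <= EC
        assert 0.0 <= EU <= EC - EF


class TestRespiration:
    def test_no_consumption_means_no_sda(self, lt_params, lt_diet):
        ER, ES = respiration(900.0, 6.0, 0.5, 0.0, lt_diet, lt_params)
        assert ER > 0.0
        assert ES == 0.0

    def test_dome_peak_value(self, simple_diet):
        """At the dome's optimum fR = 1, so ER = RA * W^RB * ACT * oxycal."""
        params = make_toy_params(RA=0.003, RB=-0.2)
        r = params.respiration
        W = 400.0
        ER, _ = respiration(W, r.RTO, 0.0, 0.0, simple_diet, params)
        assert ER == pytest.approx(r.RA * W ** r.RB * r.ACT * params.oxycal, rel=1e-12)

    def test_monotone_below_cutoff(self, lt_params, lt_diet):
        # exponential form with positive BACT: warmer water costs more
        ER1, _ = respiration(900.0, 4.0, 0.0, 0.0, lt_diet, lt_params)
        ER2, _ = respiration(900.0, 9.0, 0.0, 0.0, lt_diet, lt_params)
        assert ER1 < ER2

    def test_sda_is_fraction_of_assimilated_energy(self, cs_params, cs_diet):
        C, T, p, W = 0.02, 12.0, 0.6, 800.0
        EC = C * cs_diet.mean_energy_density
        EF, _ = waste(C, T, p, cs_diet, cs_params)
        _, ES = respiration(W, T, p, C, cs_diet, cs_params)
        assert ES == pytest.approx(cs_params.respiration.SDA * (EC - EF), rel=1e-12)


# ---------------------------------------------------------------------------
# daily step and simulation

class TestStepDay:
    def test_energy_closure(self, lt_params, lt_diet, ed_models):
        budget, w_next = step_day(
            900.0, 7.0, 0.6, lt_diet, ed_models["lake_trout"], lt_params
        )
        ed = ed_models["lake_trout"]
        E0 = ed.body_energy(900.0)
        E1 = ed.body_energy(w_next)
        assert abs((E1 - E0) - budget.dE * 900.0) < 1e-6 * max(1.0, E0)
        assert budget.dE == budget.EC - budget.EF - budget.EU - budget.ER - budget.ES

    def test_zero_flux_is_a_fixed_point(self, simple_diet, flat_ed):
        # vanishing metabolism and no food: the weight must not move
        params = make_toy_params(RA=1e-300)
        _, w_next = step_day(250.0, 10.0, 0.0, simple_diet, flat_ed, params)
        assert w_next == 250.0

    def test_flat_ed_closed_form(self, simple_diet, flat_ed, toy_params):
        """With ED = alpha (slope 0), next weight = W + dE * W / (1000 alpha)."""
        W = 300.0
        budget, w_next = step_day(W, 10.0, 0.5, simple_diet, flat_ed, toy_params)
        assert w_next == pytest.approx(W + budget.dE * W / 6000.0, rel=1e-12)

    def test_starvation_collapse_names_day(self, simple_diet, flat_ed):
        params = make_toy_params(RA=0.3)  # absurd metabolic rate
        with pytest.raises(SimulationError, match="day 7"):
            step_day(0.5, 10.0, 0.0, simple_diet, flat_ed, params, day=7)


class TestSimulate:
    def test_geometric_recursion_oracle(self, simple_diet, flat_ed, toy_params):
        """Weight-independent rates at constant temperature with a flat ED
        model grow exactly geometrically."""
        p, T, W0 = 0.6, 10.0, 100.0
        c = toy_params.consumption
        C = c.CA * p  # f(T)=1 at the dome optimum, CB=0
        EC = C * simple_diet.mean_energy_density
        EF = toy_params.waste.FA * C * simple_diet.mean_energy_density
        EU = toy_params.waste.UA * (C - toy_params.waste.FA * C) * simple_diet.mean_energy_density
        r = toy_params.respiration
        ER = r.RA * r.ACT * toy_params.oxycal
        ES = r.SDA * (EC - EF)
        g = (EC - EF - EU - ER - ES) / 6000.0
        temps = np.full(365, T)
        traj = simulate(W0, temps, [p], simple_diet, flat_ed, toy_params)
        expected = W0 * (1.0 + g) ** np.arange(366)
        assert np.allclose(
            np.concatenate([traj.weights[:-1], [traj.final_weight]]),
            expected, rtol=1e-9, atol=0.0,
        )

    def test_deterministic(self, lt_params, lt_diet, ed_models, lt_observed_scenario):
        a = simulate(142.0, lt_observed_scenario.daily, [0.5, 0.6], lt_diet,
                     ed_models["lake_trout"], lt_params)
        b = simulate(142.0, lt_observed_scenario.daily, [0.5, 0.6], lt_diet,
                     ed_models["lake_trout"], lt_params)
        assert np.array_equal(a.weights, b.weights)
        assert np.array_equal(a.C, b.C)

    def test_total_consumption_accumulation_oracle(
        self, lt_params, lt_diet, ed_models, lt_observed_scenario
    ):
        traj = simulate(142.0, lt_observed_scenario.daily, [0.55] * 3, lt_diet,
                        ed_models["lake_trout"], lt_params)
        total = 0.0
        for c, w in zip(traj.C, traj.weights[:-1]):
            total += c * w
        assert traj.total_consumption_g == pytest.approx(total, rel=1e-6)
        # prey split follows diet proportions
        for item in lt_diet.items:
            assert traj.prey_consumption_g[item.prey] == pytest.approx(
                total * item.proportion, rel=1e-6
            )

    def test_age_summaries_chain(self, lt_params, lt_diet, ed_models, lt_observed_scenario):
        traj = simulate(142.0, lt_observed_scenario.daily, [0.5, 0.55, 0.6], lt_diet,
                        ed_models["lake_trout"], lt_params)
        assert traj.n_days == 3 * 365
        for a, b in zip(traj.age_summaries, traj.age_summaries[1:]):
            assert b.start_weight == pytest.approx(a.end_weight, rel=1e-12)
        assert traj.age_summaries[-1].end_weight == pytest.approx(traj.final_weight)
        assert np.all(traj.weights > 0)
        assert np.all(np.diff(np.cumsum(traj.daily_consumption_g)) >= 0)

    def test_energy_closure_every_day(
        self, lt_params, lt_diet, ed_models, lt_observed_scenario
    ):
        traj = simulate(142.0, lt_observed_scenario.daily, [0.55] * 3, lt_diet,
                        ed_models["lake_trout"], lt_params)
        resid = np.abs(np.diff(traj.energy) - traj.dE * traj.weights[:-1])
        assert np.all(resid < 1e-6 * np.maximum(1.0, traj.energy[:-1]))

    @pytest.mark.parametrize("p_pair", [(0.3, 0.5), (0.5, 0.7), (0.7, 0.9)])
    def test_final_weight_monotone_in_p_below_optimum(
        self, cs_params, cs_diet, ed_models, p_pair
    ):
        temps = np.full(365, 10.0)  # below the Thornton-Lessem optimum
        lo, hi = p_pair
        w_lo = simulate(300.0, temps, [lo], cs_diet, ed_models["chinook_salmon"],
                        cs_params).final_weight
        w_hi = simulate(300.0, temps, [hi], cs_diet, ed_models["chinook_salmon"],
                        cs_params).final_weight
        assert w_hi >= w_lo

    def test_rejects_wrong_temperature_length(self, cs_params, cs_diet, ed_models):
        with pytest.raises(DomainError):
            simulate(300.0, np.full(200, 10.0), [0.5], cs_diet,
                     ed_models["chinook_salmon"], cs_params)
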