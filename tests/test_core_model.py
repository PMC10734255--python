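"""Damage dynamics, hazard and survival: examples, oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thermguts import (
    ModelParameters,
    TemperatureScenario,
    accrual_target,
    damage_rate,
    hazard_from_damage,
    constant_damage_closed_form,
    constant_survival_closed_form,
    simulate_damage,
    simulate_survival,
)
from thermguts.core_model import survival_at_times, hazard_series


class TestPointwiseFunctions:
    def test_accrual_target_examples(self, ref_params):
        # at the critical temperature the target is exactly the baseline
        assert accrual_target(284.15, ref_params) == pytest.approx(1.0)
        # 25 degC, alpha = 0.033/K: exp(0.033 * 14) = exp(0.462)
        assert accrual_target(298.15, ref_params) == pytest.approx(
            np.exp(0.462), rel=1e-12)
        # below T_c the target clamps at the repair baseline
        assert accrual_target(280.0, ref_params) == 1.0

    def test_accrual_target_continuous_at_tc(self, ref_params):
        eps = 1e-9
        below = accrual_target(ref_params.T_c - eps, ref_params)
        above = accrual_target(ref_params.T_c + eps, ref_params)
        assert abs(above - below) < 1e-9

    @pytest.mark.parametrize("bad_T", [np.nan, np.inf, -5.0, 0.0])
    def test_accrual_target_rejects_bad_temperature(self, ref_params, bad_T):
        with pytest.raises(ValueError):
            accrual_target(bad_T, ref_params)

    def test_damage_rate_examples(self, ref_params):
        # no damage and no thermal forcing: nothing to accrue or repair
        assert damage_rate(1.0, 283.15, ref_params) == 0.0
        # steady state at the accrual target
        F = accrual_target(298.15, ref_params)
        assert damage_rate(F, 298.15, ref_params) == pytest.approx(0.0, abs=1e-12)
        # fresh cohort at 25 degC: k_T * (F - 1) = 5.76 * 0.5872
        assert damage_rate(1.0, 298.15, ref_params) == pytest.approx(
            5.76 * (np.exp(0.462) - 1.0), rel=1e-12)

    def test_damage_rate_rejects_sub_baseline_damage(self, ref_params):
        with pytest.raises(ValueError):
            damage_rate(0.5, 298.15, ref_params)

    def test_hazard_examples(self, ref_params):
        assert hazard_from_damage(1.0, ref_params) == 0.0
        assert hazard_from_damage(1.5872, ref_params) == pytest.approx(
            0.127 * 0.5872, rel=1e-12)
        assert hazard_from_damage(2.0, ref_params.with_(b_T=0.0)) == 0.0


class TestClosedForms:
    def test_initial_condition(self, ref_params):
        assert constant_damage_closed_form(298.15, 0.0, ref_params) == 1.0
        assert constant_survival_closed_form(298.15, 0.0, ref_params) == 1.0

    def test_fast_kinetics_limit(self, ref_params):
        fast = ref_params.with_(k_T=1e6)
        F = accrual_target(298.15, fast)
        assert constant_damage_closed_form(298.15, 1.0, fast) == pytest.approx(
            F, rel=1e-12)

    def test_damage_at_8_days_15C(self, ref_params):
        # F = exp(0.033 * 4) = 1.14111...; the transient is long gone
        D = constant_damage_closed_form(288.15, 8.0, ref_params)
        assert D == pytest.approx(np.exp(0.132), rel=1e-9)

    def test_survival_25C_8days_no_background(self, ref_params_no_background):
        # cumulative hazard b_T (F-1) [t - (1 - e^{-kt})/k] at 25 degC
        p = ref_params_no_background
        F = np.exp(0.462)
        lag = (1 - np.exp(-p.k_T * 8.0)) / p.k_T
        expected = np.exp(-p.b_T * (F - 1) * (8.0 - lag))
        S = constant_survival_closed_form(298.15, 8.0, p)
        assert S == pytest.approx(expected, rel=1e-12)
        assert S == pytest.approx(0.558, abs=5e-4)

    def test_zero_k_means_damage_stays_at_baseline(self, ref_params):
        p = ref_params.with_(k_T=0.0)
        assert constant_damage_closed_form(298.15, 5.0, p) == 1.0
        # only background hazard remains
        assert constant_survival_closed_form(298.15, 5.0, p) == pytest.approx(
            np.exp(-p.h_b * 5.0), rel=1e-12)


class TestSimulationAgainstOracles:
    @pytest.mark.parametrize("temp_C", [5.0, 11.0, 15.0, 20.0, 25.0, 30.0])
    def test_damage_matches_closed_form(self, ref_params, constant_scenario,
                                        temp_C):
        scenario = constant_scenario(temp_C, t_end=8.0)
        grid = np.linspace(0.0, 8.0, 33)
        traj = simulate_damage(scenario, ref_params, output_grid=grid)
        expected = constant_damage_closed_form(temp_C + 273.15, grid, ref_params)
        np.testing.assert_allclose(traj.damage, expected, rtol=1e-6)

    @pytest.mark.parametrize("temp_C", [5.0, 15.0, 25.0, 30.0])
    def test_survival_matches_closed_form(self, ref_params, constant_scenario,
                                          temp_C):
        scenario = constant_scenario(temp_C, t_end=8.0)
        grid = np.linspace(0.0, 8.0, 33)
        curve = simulate_survival(scenario, ref_params, output_grid=grid)
        expected = constant_survival_closed_form(temp_C + 273.15, grid,
                                                 ref_params)
        np.testing.assert_allclose(curve.survival, expected, rtol=1e-5)

    def test_below_tc_is_inert(self, ref_params_no_background,
                               constant_scenario):
        scenario = constant_scenario(10.0, t_end=200.0)
        traj = simulate_damage(scenario, ref_params_no_background)
        curve = simulate_survival(scenario, ref_params_no_background)
        np.testing.assert_array_equal(traj.damage, 1.0)
        np.testing.assert_array_equal(curve.survival, 1.0)

    def test_background_only_below_tc(self, ref_params, constant_scenario):
        scenario = constant_scenario(8.0, t_end=50.0)
        grid = np.linspace(0.0, 50.0, 26)
        curve = simulate_survival(scenario, ref_params, output_grid=grid)
        np.testing.assert_allclose(curve.survival,
                                   np.exp(-ref_params.h_b * grid), rtol=1e-7)

    def test_no_killing_no_background_means_no_death(self, ref_params,
                                                     fig3_heatwave):
        p = ref_params.with_(b_T=0.0, h_b=0.0)
        curve = simulate_survival(fig3_heatwave, p,
                                  output_grid=np.linspace(0, 200, 101))
        np.testing.assert_allclose(curve.survival, 1.0, atol=1e-9)

    def test_survival_nonincreasing_in_temperature(self, ref_params,
                                                   constant_scenario):
        temps = [11.0, 14.0, 18.0, 22.0, 26.0, 30.0]
        finals = []
        for T in temps:
            curve = simulate_survival(constant_scenario(T, t_end=8.0),
                                      ref_params,
                                      output_grid=np.array([0.0, 8.0]))
            finals.append(curve.survival[-1])
        assert np.all(np.diff(finals) <= 1e-12)

    def test_damage_recovers_below_tc(self, ref_params):
        # after a hot pulse the forcing drops below T_c: damage must relax
        # back towards 1 with rate k_T
        hot = TemperatureScenario(kind="heatwave", base_mean=10.0,
                                  amplitude=0.0, hw_start=0.0,
                                  hw_duration=2.0, hw_intensity=15.0,
                                  t_end=6.0)
        grid = np.array([0.0, 2.0, 2.5, 3.0, 4.0, 6.0])
        traj = simulate_damage(hot, ref_params, output_grid=grid)
        D_peak = traj.damage[1]
        assert D_peak > 1.5
        # exponential relaxation: D(2 + dt) - 1 = (D(2) - 1) e^{-k dt}
        for i, dt in [(2, 0.5), (3, 1.0), (4, 2.0)]:
            expected = 1.0 + (D_peak - 1.0) * np.exp(-ref_params.k_T * dt)
            assert traj.damage[i] == pytest.approx(expected, rel=1e-4)
        assert traj.damage[-1] == pytest.approx(1.0, abs=1e-6)

    def test_fluctuating_survival_between_trough_and_peak_bounds(
            self, ref_params_no_background):
        # survival under a 12 +/- 4 sinusoid must lie between the survivals
        # of the constant trough (8 degC) and constant peak (16 degC)
        p = ref_params_no_background
        scenario = TemperatureScenario(kind="daily_fluctuation",
                                       base_mean=12.0, amplitude=4.0,
                                       t_end=30.0)
        S_fluct = simulate_survival(scenario, p,
                                    output_grid=np.array([0.0, 30.0])).survival[-1]
        S_peak = constant_survival_closed_form(16.0 + 273.15, 30.0, p)
        assert S_peak < S_fluct < 1.0


class TestContainersAndGrids:
    def test_trajectory_requires_grid_from_zero(self):
        from thermguts import DamageTrajectory
        with pytest.raises(ValueError):
            DamageTrajectory(times=[1.0, 2.0], damage=[1.0, 1.0])
        with pytest.raises(ValueError):
            DamageTrajectory(times=[0.0, 2.0, 1.0], damage=[1.0, 1.0, 1.0])

    def test_output_grid_beyond_t_end_rejected(self, ref_params,
                                               constant_scenario):
        scenario = constant_scenario(15.0, t_end=8.0)
        with pytest.raises(ValueError):
            simulate_damage(scenario, ref_params, t_end=4.0,
                            output_grid=np.array([0.0, 5.0]))

    def test_hazard_series_is_total_hazard(self, ref_params,
                                           constant_scenario):
        scenario = constant_scenario(25.0, t_end=4.0)
        grid = np.linspace(0.0, 4.0, 9)
        series = hazard_series(scenario, ref_params, output_grid=grid)
        D = constant_damage_closed_form(298.15, grid, ref_params)
        expected = ref_params.b_T * (D - 1.0) + ref_params.h_b
        np.testing.assert_allclose(series.hazard, expected, rtol=1e-6)

    def test_survival_at_times_dispatch_agrees(self, ref_params,
                                               fig3_heatwave,
                                               constant_scenario):
        times = np.array([0.0, 5.0, 12.0, 25.0])
        ode = survival_at_times(fig3_heatwave, ref_params, times)
        assert np.all(np.diff(ode) < 0)
        # constant dispatch equals the closed form exactly
        const = survival_at_times(constant_scenario(20.0, t_end=25.0),
                                  ref_params, times)
        np.testing.assert_array_equal(
            const, constant_survival_closed_form(293.15, times, ref_params))


class TestParameterValidation:
    @pytest.mark.parametrize("field,value", [
        ("k_T", -1.0), ("alpha", np.nan), ("T_c", 0.0), ("h_b", -0.1),
        ("b_T", np.inf),
    ])
    def test_invalid_parameters_rejected(self, field, value):
        kwargs = dict(k_T=5.76, alpha=0.033, T_c=284.15, h_b=0.004, b_T=0.127)
        kwargs[field] = value
        with pytest.raises(ValueError):
            ModelParameters(**kwargs)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    k_T=st.floats(0.01, 50.0),
    alpha=st.floats(1e-4, 0.3),
    b_T=st.floats(0.0, 5.0),
    h_b=st.floats(0.0, 0.1),
    temp=st.floats(0.0, 35.0),
)
def test_survival_curves_always_monotone_unit_interval(k_T, alpha, b_T, h_b,
                                                       temp):
    """For any nonnegative parameter set and constant forcing, survival
    starts at 1, never leaves [0, 1], and never increases."""
    params = ModelParameters(k_T=k_T, alpha=alpha, T_c=284.15, h_b=h_b,
                             b_T=b_T)
    scenario = TemperatureScenario(kind="constant", base_mean=temp, t_end=20.0)
    curve = simulate_survival(scenario, params,
                              output_grid=np.linspace(0.0, 20.0, 41))
    assert curve.survival[0] == 1.0
    assert np.all(curve.survival >= 0.0) and np.all(curve.survival <= 1.0)
    assert np.all(np.diff(curve.survival) <= 1e-12)
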