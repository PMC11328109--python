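"""Two-state forward model and thermogram processing."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad

from thermoshell import (
    BaselineModel,
    DSCTrace,
    FitError,
    TwoStateParams,
    analyze_trace,
    calorimetric_enthalpy,
    cooperativity_ratio,
    delta_g,
    denatured_fraction,
    excess_cp,
    find_td,
    fit_two_state,
    simulate_trace,
    subtract_baseline,
    suggested_grid,
    vant_hoff_enthalpy,
)
from thermoshell.constants import R_KJ
from thermoshell.dsc import estimate_baseline, peak_height


class TestDeltaG:
    def test_zero_at_td(self, buffer_params):
        assert delta_g(buffer_params.td, buffer_params) == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_without_dcp(self):
        # dCp = 0: dG(Td - 10) = dH * 10 / Td
        p = TwoStateParams(375.75, 470.0, 0.0)
        expected = 470.0 * 10.0 / 375.75  # = 12.508...
        assert delta_g(p.td - 10.0, p) == pytest.approx(expected, rel=1e-12)

    def test_matches_entropy_integration_oracle(self):
        # dG(T) = -integral of dS from Td to T, dS(T) = dH/Td + dCp ln(T/Td)
        p = TwoStateParams(375.75, 470.0, 5.2)

        def neg_entropy(t):
            return -(p.dh / p.td + p.dcp * np.log(t / p.td))

        for t in (333.15, 360.0, 390.0):
            oracle, _ = quad(neg_entropy, p.td, t)
            assert delta_g(t, p) == pytest.approx(oracle, rel=1e-10)

    def test_slope_at_td_is_minus_dh_over_td(self, buffer_params):
        p = buffer_params
        h = 1e-4
        slope = (delta_g(p.td + h, p) - delta_g(p.td - h, p)) / (2 * h)
        assert slope == pytest.approx(-p.dh / p.td, rel=1e-6)

    def test_rejects_nonpositive_temperature(self, buffer_params):
        with pytest.raises(ValueError):
            delta_g(-1.0, buffer_params)


class TestDenaturedFraction:
    def test_half_at_td(self, buffer_params):
        assert denatured_fraction(buffer_params.td, buffer_params) == pytest.approx(0.5)

    def test_cold_limit_folded(self, sharp_params):
        assert denatured_fraction(10.0, sharp_params) == pytest.approx(0.0, abs=1e-30)

    def test_matches_mass_action_root(self):
        # brute-force root of K = f/(1-f) with K = exp(-dG/RT)
        p = TwoStateParams(375.75, 470.0, 0.0)
        t = p.td + 20.0
        k = np.exp(-delta_g(t, p) / (R_KJ * t))
        f_grid = np.linspace(0.0, 1.0 - 1e-12, 2_000_001)
        i = np.argmin(np.abs(f_grid / (1.0 - f_grid) - k))
        assert denatured_fraction(t, p) == pytest.approx(f_grid[i], abs=1e-6)

    @given(st.floats(min_value=320.0, max_value=380.0),
           st.floats(min_value=200.0, max_value=500.0),
           st.floats(min_value=0.0, max_value=6.0))
    def test_strictly_increasing_in_temperature(self, td, dh, dcp):
        p = TwoStateParams(td, dh, dcp)
        t = np.linspace(td - 25.0, td + 25.0, 200)
        f = denatured_fraction(t, p)
        assert np.all(np.diff(f) > 0)


class TestExcessCp:
    def test_peak_height_closed_form(self):
        # Cp_ex(Td) = dH^2 / (4 R Td^2) when dCp = 0
        p = TwoStateParams(375.75, 470.0, 0.0)
        expected = 470.0**2 / (4.0 * R_KJ * 375.75**2)  # ~47.04 kJ/K/mol
        assert excess_cp(p.td, p) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(47.0, abs=0.1)

    def test_vanishes_far_from_transition(self, sharp_params):
        assert excess_cp(sharp_params.td - 60.0, sharp_params) < 1e-8

    @pytest.mark.parametrize("t_offset", [-20.0, -5.0, 0.0, 5.0, 20.0])
    def test_matches_finite_difference_of_f_dh(self, buffer_params, t_offset):
        p = buffer_params
        t = p.td + t_offset
        h = 1e-3

        def f_dh(x):
            return denatured_fraction(x, p) * (p.dh + p.dcp * (x - p.td))

        oracle = (f_dh(t + h) - f_dh(t - h)) / (2 * h)
        assert excess_cp(t, p) == pytest.approx(oracle, rel=1e-6)


class TestSimulateTrace:
    def test_noiseless_equals_forward_model(self, sharp_params):
        grid = suggested_grid(sharp_params)
        trace = simulate_trace(sharp_params, grid)
        assert np.allclose(trace.cp_excess, excess_cp(grid, sharp_params))

    def test_seeded_reproducibility(self, sharp_params):
        grid = suggested_grid(sharp_params)
        a = simulate_trace(sharp_params, grid, noise_sd=0.5, seed=7)
        b = simulate_trace(sharp_params, grid, noise_sd=0.5, seed=7)
        c = simulate_trace(sharp_params, grid, noise_sd=0.5, seed=8)
        assert np.array_equal(a.cp_excess, b.cp_excess)
        assert not np.array_equal(a.cp_excess, c.cp_excess)

    def test_noise_amplitude(self, sharp_params):
        grid = np.arange(300.0, 450.0, 0.01)  # large grid for tight sd estimate
        noisy = simulate_trace(sharp_params, grid, noise_sd=0.5, seed=3)
        clean = simulate_trace(sharp_params, grid)
        resid = noisy.cp_excess - clean.cp_excess
        assert np.std(resid) == pytest.approx(0.5, rel=0.05)

    def test_empty_grid_rejected(self, sharp_params):
        with pytest.raises(ValueError):
            simulate_trace(sharp_params, np.array([]))


class TestBaseline:
    def test_known_linear_baseline_exact_inverse(self, sharp_trace):
        model = BaselineModel.linear(intercept=-30.0, slope=0.1)
        shifted = DSCTrace(sharp_trace.temperatures,
                           sharp_trace.cp_excess + model.evaluate(sharp_trace.temperatures))
        back = subtract_baseline(shifted, model)
        assert np.allclose(back.cp_excess, sharp_trace.cp_excess, atol=1e-8)

    def test_null_baseline_is_identity(self, sharp_trace):
        out = subtract_baseline(sharp_trace, BaselineModel.null())
        assert np.array_equal(out.cp_excess, sharp_trace.cp_excess)

    def test_conservation_with_progress_baseline(self, buffer_params):
        # instrument baseline + dCp step; subtracted area must return dHd
        grid = suggested_grid(buffer_params)
        instrument = BaselineModel(pre=(12.0, -0.03), post=(15.0, -0.03), progress=True)
        trace = simulate_trace(buffer_params, grid, baseline=instrument)
        ex = subtract_baseline(trace)
        assert calorimetric_enthalpy(ex) == pytest.approx(buffer_params.dh, rel=5e-3)

    def test_estimated_windows_flatten_edges(self, buffer_trace):
        ex = subtract_baseline(buffer_trace)
        n = len(ex)
        w = int(0.1 * n)
        peak = ex.cp_excess.max()
        assert np.abs(ex.cp_excess[:w]).max() < 0.02 * peak
        assert np.abs(ex.cp_excess[-w:]).max() < 0.02 * peak

    def test_trace_without_baseline_windows_rejected(self, sharp_params):
        grid = np.arange(sharp_params.td - 1.0, sharp_params.td + 1.0, 0.1)
        trace = simulate_trace(sharp_params, grid)
        with pytest.raises(ValueError):
            estimate_baseline(trace)


class TestFindTd:
    def test_noiseless_recovery(self, sharp_trace, sharp_params):
        assert find_td(sharp_trace) == pytest.approx(sharp_params.td, abs=0.1)

    def test_invariant_to_additive_offset(self, sharp_trace):
        shifted = DSCTrace(sharp_trace.temperatures, sharp_trace.cp_excess + 5.0)
        assert find_td(shifted) == pytest.approx(find_td(sharp_trace), abs=1e-9)

    def test_truncated_transition_flagged(self, sharp_params):
        grid = np.arange(sharp_params.td - 40.0, sharp_params.td - 0.5, 0.1)
        trace = simulate_trace(sharp_params, grid)
        with pytest.raises(ValueError):
            find_td(trace)

    def test_noisy_recovery_within_0p2_K(self, sharp_params):
        grid = suggested_grid(sharp_params)
        peak = excess_cp(sharp_params.td, sharp_params)
        errs = []
        for seed in range(100):
            noisy = simulate_trace(sharp_params, grid, noise_sd=0.01 * peak, seed=seed)
            smooth = subtract_baseline(noisy)
            errs.append(find_td(smooth) - sharp_params.td)
        assert np.mean(np.abs(errs)) < 0.2


class TestEnthalpies:
    def test_calorimetric_enthalpy_conserves_dh(self, sharp_trace, sharp_params):
        assert calorimetric_enthalpy(sharp_trace) == pytest.approx(sharp_params.dh, rel=1e-3)

    def test_linearity_in_cp(self, sharp_trace):
        doubled = DSCTrace(sharp_trace.temperatures, 2.0 * sharp_trace.cp_excess)
        assert calorimetric_enthalpy(doubled) == pytest.approx(
            2.0 * calorimetric_enthalpy(sharp_trace), rel=1e-12)

    def test_half_grid_density_richardson(self, sharp_params):
        fine = simulate_trace(sharp_params, suggested_grid(sharp_params, step=0.1))
        coarse = simulate_trace(sharp_params, suggested_grid(sharp_params, step=0.2))
        a = calorimetric_enthalpy(fine)
        b = calorimetric_enthalpy(coarse)
        assert b == pytest.approx(a, rel=1e-4)  # trapezoid error O(h^2)

    def test_negative_area_flagged(self, sharp_trace):
        inverted = DSCTrace(sharp_trace.temperatures, -sharp_trace.cp_excess)
        with pytest.raises(ValueError):
            calorimetric_enthalpy(inverted)

    def test_vant_hoff_self_consistency(self, sharp_trace, sharp_params):
        vh = vant_hoff_enthalpy(sharp_trace)
        assert vh == pytest.approx(sharp_params.dh, rel=5e-3)

    def test_two_separated_transitions_lower_vant_hoff(self):
        p1 = TwoStateParams(340.0, 400.0, 0.0)
        p2 = TwoStateParams(385.0, 400.0, 0.0)
        grid = np.arange(300.0, 425.0, 0.1)
        cp = excess_cp(grid, p1) + excess_cp(grid, p2)
        trace = DSCTrace(grid, cp)
        dh_cal = calorimetric_enthalpy(trace)
        dh_vh = vant_hoff_enthalpy(trace)
        assert dh_cal == pytest.approx(800.0, rel=1e-2)
        assert cooperativity_ratio(dh_cal, dh_vh) > 1.5

    def test_peak_height_proportionality(self, sharp_trace):
        dh_cal = calorimetric_enthalpy(sharp_trace)
        vh_full = vant_hoff_enthalpy(sharp_trace, dh_cal=dh_cal)
        halved = DSCTrace(sharp_trace.temperatures, 0.5 * sharp_trace.cp_excess)
        vh_half = vant_hoff_enthalpy(halved, dh_cal=dh_cal)
        assert vh_half == pytest.approx(0.5 * vh_full, rel=1e-9)


class TestCooperativityRatio:
    @pytest.mark.parametrize("dh_cal,dh_vh,expected", [
        (470.0, 490.0, 0.96),  # aqueous buffer condition
        (425.0, 435.0, 0.98),  # 2 M KSCN condition
    ])
    def test_published_condition_ratios(self, dh_cal, dh_vh, expected):
        assert cooperativity_ratio(dh_cal, dh_vh) == pytest.approx(expected, abs=5e-3)

    def test_identity(self):
        assert cooperativity_ratio(123.4, 123.4) == 1.0

    def test_zero_divisor(self):
        with pytest.raises((ZeroDivisionError, ValueError)):
            cooperativity_ratio(470.0, 0.0)


class TestFitTwoState:
    def test_noiseless_recovery(self, buffer_params, buffer_trace):
        fit, diag = fit_two_state(buffer_trace)
        assert fit.td == pytest.approx(buffer_params.td, rel=1e-3)
        assert fit.dh == pytest.approx(buffer_params.dh, rel=1e-3)
        assert fit.dcp == pytest.approx(buffer_params.dcp, rel=1e-3)
        assert diag.rss < 1e-10

    def test_noisy_recovery_unbiased(self, buffer_params):
        grid = suggested_grid(buffer_params)
        peak = excess_cp(buffer_params.td, buffer_params)
        tds, dhs = [], []
        for seed in range(100):
            noisy = simulate_trace(buffer_params, grid, noise_sd=0.01 * peak, seed=seed)
            fit, _ = fit_two_state(noisy)
            tds.append(fit.td)
            dhs.append(fit.dh)
        assert np.mean(tds) == pytest.approx(buffer_params.td, abs=0.1)
        assert np.mean(dhs) == pytest.approx(buffer_params.dh, rel=0.02)
        # bias within Monte-Carlo standard error (plus discretisation slack)
        assert abs(np.mean(tds) - buffer_params.td) < max(
            np.std(tds, ddof=1) / 10.0, 5e-3)

    def test_flat_trace_rejected(self):
        grid = np.arange(300.0, 400.0, 0.5)
        with pytest.raises(FitError):
            fit_two_state(DSCTrace(grid, np.zeros_like(grid)))


class TestAnalyzeTrace:
    def test_full_workup_on_buffer_conditions(self, buffer_trace, buffer_params):
        res = analyze_trace(buffer_trace)
        assert res.dh_cal == pytest.approx(buffer_params.dh, rel=5e-3)
        assert 0.99 < res.ratio < 1.01
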