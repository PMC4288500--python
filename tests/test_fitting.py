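"""Hill / Boltzmann / linear fits: closed-form values, exact noiseless
round trips, grid-search oracle agreement, and degenerate-input flags."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from sklearn.base import clone

from kmburst.fitting import (
    BoltzmannCurve,
    BoltzmannFit,
    HillCurve,
    HillFit,
    boltzmann,
    conductance_slope,
    eval_boltzmann,
    eval_hill,
    fit_boltzmann,
    fit_hill,
    hill,
    single_channel_conductance,
)
from kmburst.synth import NoiseSpec, gen_dose_response

STEPS = np.arange(-50.0, 10.1, 10.0)


class TestHillEvaluation:
    @pytest.mark.parametrize("n_h", [0.5, 1.0, 2.0, 3.7])
    def test_half_maximal_at_ec50_for_any_coefficient(self, n_h):
        assert hill(9.8, 100.0, 9.8, n_h) == pytest.approx(50.0)

    def test_reported_ec50_evaluation(self):
        assert hill(9.8, 100.0, 9.8, 1.0) == pytest.approx(50.0)

    def test_cooperative_evaluation(self):
        # 100 * 30^2 / (10^2 + 30^2) = 90
        assert hill(30.0, 100.0, 10.0, 2.0) == pytest.approx(90.0)

    def test_printed_denominator_variant_matches_standard_at_nh_1(self):
        c = np.array([0.5, 5.0, 50.0])
        np.testing.assert_allclose(hill(c, 100, 9.8, 1.0, "standard"),
                                   hill(c, 100, 9.8, 1.0, "as_printed"))

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            hill(-1.0, 100.0, 9.8, 1.0)

    @given(st.floats(0.1, 300.0), st.floats(0.5, 3.0))
    def test_monotone_in_concentration(self, c, n_h):
        assert hill(c * 1.01, 100.0, 9.8, n_h) >= hill(c, 100.0, 9.8, n_h)


class TestBoltzmannEvaluation:
    def test_half_activation_at_v_half(self):
        assert boltzmann(-26.8, -26.8, 1.86) == pytest.approx(0.5)

    def test_control_curve_at_minus_10(self):
        # RT/F = 25.42 mV at 295 K -> 0.774
        assert boltzmann(-10.0, -26.8, 1.86, 295.0) == pytest.approx(0.774, abs=1e-3)

    def test_shifted_curve_dominates_control_everywhere(self):
        v = np.linspace(-50.0, 10.0, 61)
        ctrl = boltzmann(v, -26.8, 1.86)
        ngen = boltzmann(v, -44.3, 2.01)
        assert np.all(ngen > ctrl)

    @given(st.floats(-80.0, 20.0), st.floats(0.5, 4.0))
    def test_strictly_increasing_in_voltage(self, v, q):
        assert boltzmann(v + 0.5, -26.8, q) > boltzmann(v, -26.8, q)


def _hill_grid_oracle(c, y, ec50_range, nh_range):
    """Coarse-to-fine brute-force least squares over an (EC50, n_H) grid
    with the linear E_max profiled out in closed form."""
    def scan(ecs, nhs):
        best = (np.inf, None, None, None)
        for ec in ecs:
            for nh in nhs:
                f = c ** nh / (ec ** nh + c ** nh)
                e_max = float(f @ y) / float(f @ f)
                sse = float(np.sum((y - e_max * f) ** 2))
                if sse < best[0]:
                    best = (sse, e_max, ec, nh)
        return best

    _, e, ec, nh = scan(np.arange(*ec50_range, 0.01), np.arange(*nh_range, 0.01))
    # the (EC50, n_H) SSE valley is correlated: refine around the coarse
    # optimum with a generous window before the final fine pass
    _, e, ec, nh = scan(np.arange(ec - 0.3, ec + 0.3, 0.005),
                        np.arange(nh - 0.05, nh + 0.05, 0.002))
    _, e, ec, nh = scan(np.arange(ec - 0.02, ec + 0.02, 0.0005),
                        np.arange(nh - 0.01, nh + 0.01, 0.0005))
    return e, ec, nh


class TestHillFit:
    def test_noiseless_recovery_of_reported_ec50(self):
        truth = HillFit(100.0, 9.8, 1.0)
        c = np.array([0.1, 1, 3, 10, 30, 100, 300], dtype=float)
        fit = fit_hill((c, eval_hill(truth, c)))
        assert fit.converged
        assert fit.ec50 == pytest.approx(9.8, rel=1e-6)
        assert fit.n_h == pytest.approx(1.0, rel=1e-6)

    def test_constant_responses_flagged_not_raised(self):
        c = np.array([1.0, 3.0, 10.0, 30.0, 100.0])
        fit = fit_hill((c, np.full(5, 42.0)))
        assert not fit.converged
        assert fit.message

    def test_noisy_fit_agrees_with_grid_search_oracle(self, rng):
        truth = HillFit(100.0, 9.8, 1.0)
        c = np.repeat([1.0, 3.0, 10.0, 30.0, 100.0], 8)
        y = eval_hill(truth, c) + rng.normal(0, 3.0, c.size)
        fit = fit_hill((c, y))
        _, ec_o, nh_o = _hill_grid_oracle(c, y, (8.0, 12.0), (0.7, 1.3))
        assert fit.ec50 == pytest.approx(ec_o, abs=0.01)
        assert fit.n_h == pytest.approx(nh_o, abs=0.01)

    def test_stochastic_table_recovery_within_3_se(self):
        table = gen_dose_response(HillFit(100.0, 9.8, 1.0),
                                  [0.1, 1, 3, 10, 30, 100, 300],
                                  NoiseSpec(seed=1), n_cells=200)
        fit = fit_hill(table)
        assert abs(fit.ec50 - 9.8) < 3 * max(fit.se["ec50"], 0.1)


def _boltz_grid_oracle(v, g, vh_range, q_range, res=0.01):
    best = (np.inf, None, None)
    for vh in np.arange(*vh_range, res):
        for q in np.arange(*q_range, res):
            f = boltzmann(v, vh, q)
            g_max = float(f @ g) / float(f @ f)
            sse = float(np.sum((g - g_max * f) ** 2))
            if sse < best[0]:
                best = (sse, vh, q)
    return best[1:]


class TestBoltzmannFit:
    @pytest.mark.parametrize("v_half,q", [(-26.8, 1.86), (-44.3, 2.01)])
    def test_noiseless_recovery_of_reported_activation(self, v_half, q):
        truth = BoltzmannFit(1.0, v_half, q)
        pts = np.column_stack([STEPS, eval_boltzmann(truth, STEPS)])
        fit = fit_boltzmann(pts)
        assert fit.converged
        assert fit.v_half == pytest.approx(v_half, rel=1e-6)
        assert fit.q == pytest.approx(q, rel=1e-6)

    def test_constant_conductances_flagged(self):
        pts = np.column_stack([STEPS, np.full(STEPS.size, 0.5)])
        fit = fit_boltzmann(pts)
        assert not fit.converged

    def test_noisy_fit_agrees_with_grid_search_oracle(self, rng):
        truth = BoltzmannFit(1.0, -26.8, 1.86)
        g = eval_boltzmann(truth, STEPS) + rng.normal(0, 0.02, STEPS.size)
        fit = fit_boltzmann(np.column_stack([STEPS, g]))
        vh_o, q_o = _boltz_grid_oracle(STEPS, g, (-29.0, -24.0), (1.5, 2.3))
        assert fit.v_half == pytest.approx(vh_o, abs=0.02)
        assert fit.q == pytest.approx(q_o, abs=0.02)

    @given(st.floats(-45.0, -15.0), st.floats(1.0, 3.0))
    def test_roundtrip_property(self, v_half, q):
        truth = BoltzmannFit(2.0, v_half, q)
        pts = np.column_stack([STEPS, 2.0 * eval_boltzmann(truth, STEPS)])
        fit = fit_boltzmann(pts)
        assert fit.v_half == pytest.approx(v_half, rel=1e-4, abs=1e-3)
        assert fit.q == pytest.approx(q, rel=1e-4)


class TestLinearFits:
    def test_exact_line_recovers_reported_slope(self):
        v = np.array([-30.0, -20.0, -10.0])
        pts = np.column_stack([v, 2.11 * (v + 91.0)])
        fit = conductance_slope(pts, window=(-30.0, -10.0))
        assert fit.slope_nS == pytest.approx(2.11, rel=1e-12)

    def test_two_points_exact_line(self):
        fit = conductance_slope([[-30.0, 10.0], [-10.0, 30.0]], window=(-30.0, -10.0))
        assert fit.slope_nS == pytest.approx(1.0)
        assert fit.intercept_pA == pytest.approx(40.0)

    def test_window_excludes_outside_points(self):
        pts = [[-50.0, 999.0], [-30.0, 0.0], [-20.0, 10.0], [-10.0, 20.0], [10.0, -999.0]]
        fit = conductance_slope(pts, window=(-30.0, -10.0))
        assert fit.slope_nS == pytest.approx(1.0)
        assert fit.n_points == 3

    def test_noisy_slope_equals_normal_equations(self, rng):
        v = np.arange(-30.0, -9.0, 2.0)
        i = 2.0 * v + 5.0 + rng.normal(0, 1.0, v.size)
        fit = conductance_slope(np.column_stack([v, i]), window=(-30.0, -10.0))
        # closed-form OLS
        sxx = np.sum((v - v.mean()) ** 2)
        sxy = np.sum((v - v.mean()) * (i - i.mean()))
        assert fit.slope_nS == pytest.approx(sxy / sxx, rel=1e-12)

    def test_too_few_in_window_rejected(self):
        with pytest.raises(ValueError):
            conductance_slope([[-20.0, 1.0], [-60.0, 2.0]], window=(-30.0, -10.0))

    @pytest.mark.parametrize("g", [178.0, 180.0])
    def test_single_channel_conductance_exact(self, g):
        v = np.arange(-60.0, 61.0, 20.0)
        pts = np.column_stack([v, g * v / 1e3])
        assert single_channel_conductance(pts) == pytest.approx(g, rel=1e-12)
        assert single_channel_conductance(pts, reversal=0.0) == pytest.approx(g, rel=1e-12)

    def test_duplicated_potential_rejected(self):
        with pytest.raises(ValueError):
            single_channel_conductance([[60.0, 10.8], [60.0, 10.8]])


class TestEstimatorApi:
    def test_get_set_params_and_clone(self):
        est = HillCurve(denominator="as_printed")
        assert clone(est).get_params()["denominator"] == "as_printed"
        est2 = BoltzmannCurve(temperature=300.0)
        assert clone(est2).get_params()["temperature"] == 300.0

    def test_predict_matches_closed_form(self):
        c = np.array([1.0, 3.0, 10.0, 30.0, 100.0])
        truth = HillFit(80.0, 12.0, 1.3)
        est = HillCurve().fit(c, eval_hill(truth, c))
        np.testing.assert_allclose(est.predict(c), eval_hill(truth, c), rtol=1e-5)
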