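"""Casson constitutive law, curve fitting, and the analytic pipe-flow solution."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from hemoflow.rheology import (
    CassonParams,
    ViscosityCurve,
    casson_tube_flow_rate,
    cp_to_pa_s,
    effective_viscosity,
    fit_casson,
    pa_s_to_cp,
    synth_viscosity_curve,
)


class TestEffectiveViscosity:
    def test_newtonian_limit_is_plateau(self):
        p = CassonParams(tau_y=0.0, k=0.0035)
        for g in (1.0, 10.0, 1000.0):
            assert effective_viscosity(g, p) == pytest.approx(0.0035)

    def test_matches_hand_evaluation(self):
        p = CassonParams(tau_y=0.005, k=0.0035)
        g = 1000.0
        expected = (np.sqrt(0.005 / 1000.0) + np.sqrt(0.0035)) ** 2
        assert effective_viscosity(g, p) == pytest.approx(expected, rel=1e-14)

    def test_shear_thinning_monotonicity(self):
        p = CassonParams(tau_y=0.01, k=0.004)
        m10, m100, m1000 = (effective_viscosity(g, p) for g in (10.0, 100.0, 1000.0))
        assert m10 > m100 > m1000

    def test_low_shear_clamped_at_floor(self):
        p = CassonParams(tau_y=0.01, k=0.004, gamma_min=1.0)
        assert effective_viscosity(0.0, p) == effective_viscosity(1.0, p)
        assert effective_viscosity(0.5, p) == effective_viscosity(1.0, p)

    def test_negative_shear_rate_rejected(self):
        with pytest.raises(ValueError):
            effective_viscosity(-1.0, CassonParams(0.0, 0.0035))

    @given(
        tau_y=st.floats(0.0, 0.05),
        k=st.floats(1e-4, 0.05),
        g1=st.floats(1.0, 1e4),
        g2=st.floats(1.0, 1e4),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_positive_bounded_and_nonincreasing(self, tau_y, k, g1, g2):
        p = CassonParams(tau_y=tau_y, k=k)
        lo, hi = sorted((g1, g2))
        mu_lo, mu_hi = effective_viscosity(lo, p), effective_viscosity(hi, p)
        assert mu_hi > 0
        assert mu_lo >= mu_hi  # non-increasing
        assert mu_hi >= k * (1.0 - 1e-12)  # plateau bound (float epsilon)


class TestViscosityCurve:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            ViscosityCurve("x", [1.0, 1.0, 2.0], [3.0, 3.0, 3.0])  # not increasing
        with pytest.raises(ValueError):
            ViscosityCurve("x", [1.0, 2.0, 3.0], [3.0, -1.0, 3.0])  # negative viscosity

    def test_csv_round_trip(self):
        curve = synth_viscosity_curve(CassonParams(0.005, 0.004), 10, 0.0, seed=0)
        buf = io.StringIO()
        curve.to_csv(buf)
        buf.seek(0)
        back = ViscosityCurve.from_csv(buf, patient_id=curve.patient_id)
        np.testing.assert_array_equal(back.shear_rates, curve.shear_rates)
        np.testing.assert_array_equal(back.viscosities, curve.viscosities)

    def test_unit_conversion_round_trip(self):
        vals = np.array([1.0, 3.5, 56.0])
        np.testing.assert_allclose(pa_s_to_cp(cp_to_pa_s(vals)), vals, rtol=1e-15)
        assert cp_to_pa_s(3.5) == pytest.approx(0.0035)


class TestFitCasson:
    def test_noiseless_round_trip_is_exact(self):
        true = CassonParams(tau_y=0.004, k=0.0032)
        fit = fit_casson(synth_viscosity_curve(true, 50, 0.0, seed=0))
        assert fit.params.tau_y == pytest.approx(0.004, abs=1e-12)
        assert fit.params.k == pytest.approx(0.0032, abs=1e-12)
        assert fit.residual == pytest.approx(0.0, abs=1e-9)

    def test_flat_newtonian_curve(self):
        gamma = np.logspace(0, 3, 30)
        curve = ViscosityCurve("flat", gamma, np.full(30, 3.5))
        fit = fit_casson(curve)
        assert fit.params.tau_y == pytest.approx(0.0, abs=1e-10)
        assert fit.params.k == pytest.approx(0.0035, rel=1e-10)

    def test_noisy_fit_error_distribution(self):
        # 2% multiplicative noise, 100 seeds: mean relative parameter error < 5%
        true = CassonParams(tau_y=0.004, k=0.0032)
        err_tau, err_k = [], []
        for seed in range(100):
            f = fit_casson(synth_viscosity_curve(true, 50, 0.02, seed=seed))
            err_tau.append(abs(f.params.tau_y - true.tau_y) / true.tau_y)
            err_k.append(abs(f.params.k - true.k) / true.k)
        assert np.mean(err_tau) < 0.05
        assert np.mean(err_k) < 0.05

    def test_insufficient_points_rejected(self):
        curve = ViscosityCurve("x", [1.0, 10.0], [4.0, 3.6])
        with pytest.raises(ValueError, match="at least 3"):
            fit_casson(curve)

    def test_negative_intercept_clamped_to_zero_yield(self):
        # super-Newtonian (shear-thickening-looking) data force a negative intercept
        gamma = np.logspace(0, 3, 20)
        mu = 3.0 + 0.002 * gamma  # viscosity increasing with shear
        fit = fit_casson(ViscosityCurve("x", gamma, mu))
        assert fit.clamped
        assert fit.params.tau_y == 0.0


class TestCassonTubeFlow:
    def test_newtonian_limit_is_poiseuille(self):
        R, G, k = 0.002, 500.0, 0.0035
        q = casson_tube_flow_rate(R, G, CassonParams(0.0, k))
        assert q == pytest.approx(np.pi * G * R**4 / (8 * k), rel=1e-14)

    def test_unyielded_plug_gives_zero_flow(self):
        p = CassonParams(tau_y=1.0, k=0.0035)
        assert casson_tube_flow_rate(0.002, 500.0, p) == 0.0  # tau_w = 0.5 < tau_y

    def test_matches_numerical_quadrature(self):
        R, G = 0.002, 800.0
        p = CassonParams(tau_y=0.005, k=0.0035)

        def gdot(tau):
            return (np.sqrt(tau) - np.sqrt(p.tau_y)) ** 2 / p.k if tau > p.tau_y else 0.0

        def u(r):
            return quad(lambda rr: gdot(G * rr / 2.0), r, R, limit=200)[0]

        q_quad = quad(lambda r: 2 * np.pi * r * u(r), 0.0, R, limit=200)[0]
        assert casson_tube_flow_rate(R, G, p) == pytest.approx(q_quad, rel=1e-6)

    @given(
        r=st.floats(5e-4, 5e-3),
        g=st.floats(10.0, 2000.0),
        tau_y=st.floats(0.0, 0.05),
        k=st.floats(1e-3, 0.02),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_in_drivers_and_resistances(self, r, g, tau_y, k):
        p = CassonParams(tau_y=tau_y, k=k)
        q = casson_tube_flow_rate(r, g, p)
        assert q >= 0
        assert casson_tube_flow_rate(r, g * 1.1, p) >= q
        assert casson_tube_flow_rate(r * 1.1, g, p) >= q
        assert casson_tube_flow_rate(r, g, CassonParams(tau_y + 0.01, k)) <= q
        assert casson_tube_flow_rate(r, g, CassonParams(tau_y, k * 1.1)) <= q


class TestSynthCurve:
    def test_noiseless_equals_model(self):
        p = CassonParams(0.006, 0.004)
        curve = synth_viscosity_curve(p, 20, 0.0, seed=3)
        np.testing.assert_allclose(
            cp_to_pa_s(curve.viscosities), effective_viscosity(curve.shear_rates, p), rtol=1e-13
        )
        assert curve.shear_rates[0] == pytest.approx(1.0)
        assert curve.shear_rates[-1] == pytest.approx(1000.0)

    def test_deterministic_given_seed(self):
        p = CassonParams(0.006, 0.004)
        c1 = synth_viscosity_curve(p, 30, 0.05, seed=42)
        c2 = synth_viscosity_curve(p, 30, 0.05, seed=42)
        np.testing.assert_array_equal(c1.viscosities, c2.viscosities)

    def test_noise_magnitude_calibrated(self):
        p = CassonParams(0.006, 0.004)
        ref = cp_to_pa_s(synth_viscosity_curve(p, 50, 0.0, seed=0).viscosities)
        devs = []
        for seed in range(200):
            c = synth_viscosity_curve(p, 50, 0.02, seed=seed)
            devs.extend(cp_to_pa_s(c.viscosities) / ref - 1.0)
        assert np.std(devs) == pytest.approx(0.02, rel=0.1)
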