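"""Flow-solver validation against closed-form channel solutions.

The solver contract is the analytic-oracle suite: plane Poiseuille for the
Newtonian limit, the two-zone plane-Casson solution for the yield-stress
case, quasi-steady agreement with instantaneous steady solves, mass
conservation, no-slip walls, and cycle periodicity.
"""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import brentq

from hemoflow import (
    CassonParams,
    SolverConfig,
    build_2d_domain,
    inlet_profile,
    inlet_waveform,
    solve_unsteady,
    steady_solve,
)
from hemoflow.hemodynamics import dome_average, wall_shear_stress
from hemoflow.solver import boundary_flux_imbalance, shear_rate_centers
from tests.conftest import CASSON, NEWTONIAN


class TestInletWaveform:
    def test_cycle_mean_is_published_flow_rate(self):
        cfg = SolverConfig()
        t = np.linspace(0, cfg.cycle_period, 10001)
        assert np.trapezoid(inlet_waveform(t, cfg), t) / cfg.cycle_period == pytest.approx(2.6, rel=1e-6)

    def test_steady_when_amplitude_zero(self):
        cfg = SolverConfig(waveform_amplitude=0.0)
        assert inlet_waveform(0.37, cfg) == pytest.approx(2.6)

    def test_extrema_at_quarter_cycles(self):
        cfg = SolverConfig(waveform_amplitude=0.5)
        assert inlet_waveform(0.25, cfg) == pytest.approx(2.6 * 1.5)
        assert inlet_waveform(0.75, cfg) == pytest.approx(2.6 * 0.5)


class TestInletProfile:
    def test_mean_speed_from_inlet_area(self):
        # 2.6 mL/s over a 13 mm^2 inlet -> 0.2 m/s mean speed
        y = np.linspace(0, 4e-3, 4001)
        u = inlet_profile(2.6, y, 4e-3, inlet_area_mm2=13.0)
        assert np.trapezoid(u, y) / 4e-3 == pytest.approx(0.2, rel=1e-6)

    def test_zero_flow_gives_zero_profile(self):
        y = np.linspace(0, 4e-3, 11)
        assert np.all(inlet_profile(0.0, y, 4e-3) == 0.0)

    def test_parabola_peak_is_1p5_mean(self):
        y = np.linspace(0, 4e-3, 4001)
        u = inlet_profile(2.6, y, 4e-3, inlet_area_mm2=13.0)
        assert u.max() == pytest.approx(1.5 * 0.2, rel=1e-6)

    def test_zero_extent_rejected(self):
        with pytest.raises(ValueError):
            inlet_profile(2.6, np.array([0.0]), 0.0)


class TestSteadyChannel:
    def test_newtonian_poiseuille_within_one_percent(self, channel_domain, poiseuille_solution):
        dom = channel_domain
        y = dom.face_y()
        ana = inlet_profile(2.6, y, dom.channel_height)
        num = poiseuille_solution.u[0][dom.nx // 2, :]
        err = np.linalg.norm(num - ana) / np.linalg.norm(ana)
        assert err < 0.01

    def test_mass_conservation(self, poiseuille_solution):
        assert boundary_flux_imbalance(poiseuille_solution) < 0.005

    def test_no_slip_walls(self, channel_domain, poiseuille_solution):
        # wall-adjacent tangential speed stays below the parabola's near-wall value
        u = poiseuille_solution.u[0]
        v = poiseuille_solution.v[0]
        assert np.abs(v[:, 0]).max() == 0.0  # no penetration through the wall
        assert np.abs(v[:, -1]).max() == 0.0
        wall_gap_speed = np.abs(u[:, 0]).max()
        assert wall_gap_speed < 0.2 * u.max()

    def test_stokes_linearity_under_flow_doubling(self, small_dome_shape):
        dom = build_2d_domain(small_dome_shape, mesh_size=0.3)
        creeping = CassonParams(tau_y=0.0, k=0.05)
        s1 = steady_solve(dom, creeping, 0.05)
        s2 = steady_solve(dom, creeping, 0.10)
        resid = np.linalg.norm(s2.u[0] - 2.0 * s1.u[0]) / np.linalg.norm(s2.u[0])
        assert resid < 0.01

    def test_newtonian_viscosity_field_is_constant(self, channel_domain, poiseuille_solution):
        from hemoflow.rheology import effective_viscosity

        g = shear_rate_centers(channel_domain, poiseuille_solution.u[0], poiseuille_solution.v[0])
        mu = effective_viscosity(g[channel_domain.fluid], NEWTONIAN)
        assert np.all(mu == 0.0035)


def plane_casson_wall_stress(params, q2d, half_gap):
    """Analytic two-zone plane-Casson wall stress for 2D flow rate q2d."""

    def gdot(tau):
        return (np.sqrt(tau) - np.sqrt(params.tau_y)) ** 2 / params.k if tau > params.tau_y else 0.0

    def q_of_tw(tw):
        G = tw / half_gap

        def u(y):
            return quad(lambda s: gdot(G * s), y, half_gap, limit=200)[0]

        return 2.0 * quad(u, 0.0, half_gap, limit=200)[0]

    return brentq(lambda t: q_of_tw(t) - q2d, 1e-6, 100.0, xtol=1e-12)


class TestCassonChannel:
    def test_wall_stress_matches_two_zone_solution(self):
        params = CassonParams(tau_y=0.01, k=0.0035)
        q_ml = 0.6
        dom = build_2d_domain(None, mesh_size=0.2)
        H = dom.channel_height
        u_mean = q_ml / (0.25 * np.pi * (H * 1e3) ** 2)
        tw_ref = plane_casson_wall_stress(params, u_mean * H, H / 2.0)
        sol = steady_solve(dom, params, q_ml)
        wf = wall_shear_stress(sol, params)
        mask = (
            (wf.positions[:, 1] < 1e-12)
            & (wf.positions[:, 0] > 0.6 * dom.length)
            & (wf.positions[:, 0] < 0.9 * dom.length)
        )
        wss = wf.wss[mask, 0].mean()
        assert wss == pytest.approx(tw_ref, rel=0.02)


class TestUnsteady:
    def test_quasi_steady_limit_matches_steady_sequence(self, dome_domain):
        # period 50 s: each stored snapshot should match the steady solution
        # at the instantaneous inflow within 2%
        T = 50.0
        cfg = SolverConfig(
            cycle_period=T, n_cycles=1, report_cycle=1, time_step=T / 160.0,
            waveform_amplitude=0.4, store_every=4,
        )
        sol = solve_unsteady(dome_domain, CASSON, cfg)
        for k in range(6, len(sol.times), 12):
            ssol = steady_solve(dome_domain, CASSON, inlet_waveform(sol.times[k], cfg))
            err = np.linalg.norm(sol.u[k] - ssol.u[0]) / np.linalg.norm(ssol.u[0])
            assert err < 0.02

    def test_cycles_three_and_four_are_periodic(self, dome_domain):
        cfg = SolverConfig(n_cycles=4, report_cycle=2, time_step=1.0 / 60.0)
        sol = solve_unsteady(dome_domain, CASSON, cfg, store_cycles=(3, 4))
        i3, i4 = sol.cycle_indices(3), sol.cycle_indices(4)
        g3 = np.array(
            [dome_average(shear_rate_centers(dome_domain, sol.u[i], sol.v[i]), dome_domain) for i in i3]
        )
        g4 = np.array(
            [dome_average(shear_rate_centers(dome_domain, sol.u[i], sol.v[i]), dome_domain) for i in i4]
        )
        n = min(g3.size, g4.size)
        assert np.max(np.abs(g3[:n] - g4[:n])) / np.max(g4[:n]) < 0.02

    def test_mass_conserved_at_every_stored_time(self, dome_solution):
        for k in range(len(dome_solution.times)):
            assert boundary_flux_imbalance(dome_solution, k) < 0.005

    def test_ps_ed_flagged_at_waveform_extrema(self, dome_solution):
        cfg = dome_solution.config
        T = cfg.cycle_period
        assert dome_solution.times[dome_solution.ps_index] % T == pytest.approx(T / 4.0, abs=T / 50)
        assert dome_solution.times[dome_solution.ed_index] % T == pytest.approx(3 * T / 4.0, abs=T / 50)

    def test_dome_shear_rate_mesh_convergence(self, small_dome_shape):
        # one uniform refinement from the default spacing changes the
        # dome-averaged shear rate by < 5%
        vals = {}
        for ms in (0.2, 0.1):
            dom = build_2d_domain(small_dome_shape, mesh_size=ms)
            sol = steady_solve(dom, CASSON, 2.6)
            vals[ms] = dome_average(shear_rate_centers(dom, sol.u[0], sol.v[0]), dom)
        assert abs(vals[0.2] - vals[0.1]) / vals[0.1] < 0.05
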