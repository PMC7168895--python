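"""Shear rate, viscosity, WSS, TAWSS and the per-patient summary."""

import numpy as np
import pytest

from hemoflow import CassonParams, SolverConfig, build_2d_domain
from hemoflow.hemodynamics import (
    WallField,
    dome_average,
    scalar_shear_rate,
    summarize,
    time_averaged_wss,
    wall_shear_stress,
    wss_extrema,
)
from hemoflow.rheology import effective_viscosity, pa_s_to_cp
from hemoflow.solver import FlowSolution, shear_rate_centers
from tests.conftest import CASSON, NEWTONIAN


class TestScalarShearRate:
    def test_simple_shear(self):
        gamma = 7.3
        G = np.array([[0.0, gamma], [0.0, 0.0]])  # u = (gamma*y, 0)
        assert scalar_shear_rate(G) == pytest.approx(gamma)

    def test_rigid_rotation_is_zero(self):
        w = 11.0
        G = np.array([[0.0, -w], [w, 0.0]])
        assert scalar_shear_rate(G) == pytest.approx(0.0, abs=1e-14)

    def test_poiseuille_wall_value(self, channel_domain, poiseuille_solution):
        # plane Poiseuille: wall shear rate 6 U / h, centreline ~ 0
        dom = channel_domain
        g = shear_rate_centers(dom, poiseuille_solution.u[0], poiseuille_solution.v[0])
        H = dom.channel_height
        u_mean = 2.6 / (0.25 * np.pi * (H * 1e3) ** 2)
        expected_wall = 6.0 * u_mean / H
        i = dom.nx // 2
        # cell-centre value half a cell off the wall: compare to the analytic
        # profile's gradient at y = h/2
        y_half = dom.h / 2.0
        ana = expected_wall * (1.0 - 2.0 * y_half / H)
        assert g[i, 0] == pytest.approx(ana, rel=0.02)
        centre = g[i, dom.ny // 2 - 1 : dom.ny // 2 + 1].min()
        assert centre < 0.1 * expected_wall


class TestDomeAverage:
    def test_constant_field(self, dome_domain):
        f = np.full((dome_domain.nx, dome_domain.ny), 3.7)
        assert dome_average(f, dome_domain) == pytest.approx(3.7)

    def test_linearity(self, dome_domain, rng):
        f = rng.random((dome_domain.nx, dome_domain.ny))
        g = rng.random((dome_domain.nx, dome_domain.ny))
        lhs = dome_average(2.0 * f + 3.0 * g, dome_domain)
        rhs = 2.0 * dome_average(f, dome_domain) + 3.0 * dome_average(g, dome_domain)
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_explicit_weighted_mean(self, dome_domain, rng):
        f = rng.random((dome_domain.nx, dome_domain.ny))
        manual = f[dome_domain.dome].sum() / dome_domain.dome.sum()
        assert dome_average(f, dome_domain) == pytest.approx(manual, rel=1e-14)

    def test_empty_dome_rejected(self, channel_domain):
        with pytest.raises(ValueError):
            dome_average(np.zeros((channel_domain.nx, channel_domain.ny)), channel_domain)


def _wall_field(times, wss, period=1.0):
    n = wss.shape[0]
    return WallField(
        positions=np.zeros((n, 2)),
        on_dome=np.ones(n, dtype=bool),
        times=times,
        wss=wss,
        period=period,
    )


class TestTAWSS:
    def test_constant_field_is_identity(self):
        t = np.linspace(0, 1, 51)
        wf = _wall_field(t, np.full((3, 51), 2.5))
        np.testing.assert_allclose(time_averaged_wss(wf), 2.5, rtol=1e-12)

    def test_rectified_sine_integral(self):
        # TAWSS of c*|sin(2 pi t/T)| -> (2/pi) c within 0.5% at 200 samples
        c = 4.0
        t = np.linspace(0, 1, 201)
        wf = _wall_field(t, c * np.abs(np.sin(2 * np.pi * t))[None, :])
        assert time_averaged_wss(wf)[0] == pytest.approx(2.0 * c / np.pi, rel=0.005)

    def test_matches_independent_quadrature(self, rng):
        t = np.sort(rng.uniform(0, 1, 97))
        t[0], t[-1] = 0.0, 1.0
        w = rng.random((4, 97))
        wf = _wall_field(t, w)
        expected = np.array([np.trapezoid(w[i], t) for i in range(4)])
        np.testing.assert_allclose(time_averaged_wss(wf), expected, rtol=1e-12)

    def test_incomplete_cycle_rejected(self):
        t = np.linspace(0, 0.5, 20)
        wf = _wall_field(t, np.ones((2, 20)))
        with pytest.raises(ValueError, match="cycle"):
            time_averaged_wss(wf)


class TestExtrema:
    def test_constant_field(self):
        wf = _wall_field(np.linspace(0, 1, 5), np.full((2, 5), 1.3))
        assert wss_extrema(wf) == (pytest.approx(1.3), pytest.approx(1.3))

    def test_planted_extremes_recovered(self, rng):
        w = rng.uniform(1.0, 2.0, (6, 9))
        w[3, 4] = 0.0
        w[1, 7] = 9.9
        wf = _wall_field(np.linspace(0, 1, 9), w)
        lo, hi = wss_extrema(wf)
        assert lo == 0.0
        assert hi == 9.9


class TestWallShearStress:
    def test_newtonian_poiseuille_wall_stress(self, channel_domain, poiseuille_solution):
        # WSS = 6 mu U / h uniformly along both flat walls
        dom = channel_domain
        H = dom.channel_height
        u_mean = 2.6 / (0.25 * np.pi * (H * 1e3) ** 2)
        expected = 6.0 * 0.0035 * u_mean / H
        wf = wall_shear_stress(poiseuille_solution, NEWTONIAN)
        interior = (wf.positions[:, 0] > 0.2 * dom.length) & (wf.positions[:, 0] < 0.8 * dom.length)
        np.testing.assert_allclose(wf.wss[interior, 0], expected, rtol=0.01)

    def test_zero_flow_gives_zero_wss(self, channel_domain):
        sol = FlowSolution(
            domain=channel_domain,
            config=SolverConfig(),
            times=np.array([0.0]),
            u=np.zeros((1, channel_domain.nx + 1, channel_domain.ny)),
            v=np.zeros((1, channel_domain.nx, channel_domain.ny + 1)),
            p=np.zeros((1, channel_domain.nx, channel_domain.ny)),
        )
        wf = wall_shear_stress(sol, CASSON)
        assert np.all(wf.wss == 0.0)

    def test_casson_wall_stress_exceeds_plateau_value(self):
        # at low wall shear rate the Casson apparent viscosity exceeds k, so
        # the Casson WSS must exceed the Newtonian-with-k WSS for the same flow
        params = CassonParams(tau_y=0.02, k=0.0035)
        dom = build_2d_domain(None, mesh_size=0.2)
        q = 0.2  # low flow -> low wall shear rate
        sol_c = __import__("hemoflow").steady_solve(dom, params, q)
        sol_n = __import__("hemoflow").steady_solve(dom, CassonParams(0.0, 0.0035), q)
        wf_c = wall_shear_stress(sol_c, params)
        wf_n = wall_shear_stress(sol_n, CassonParams(0.0, 0.0035))
        mid = (wf_c.positions[:, 0] > 0.6 * dom.length) & (wf_c.positions[:, 0] < 0.9 * dom.length)
        assert wf_c.wss[mid, 0].mean() > wf_n.wss[mid, 0].mean()


class TestSummarize:
    def test_quiescent_solution_is_zero_except_plateau_viscosity(self, dome_domain):
        sol = FlowSolution(
            domain=dome_domain,
            config=SolverConfig(n_cycles=1, report_cycle=1),
            times=np.linspace(0, 1, 5),
            u=np.zeros((5, dome_domain.nx + 1, dome_domain.ny)),
            v=np.zeros((5, dome_domain.nx, dome_domain.ny + 1)),
            p=np.zeros((5, dome_domain.nx, dome_domain.ny)),
        )
        s = summarize(sol, CASSON)
        assert s.avg_shear_rate_ps == 0.0
        assert s.wss_min == s.wss_tavg == s.wss_max == 0.0
        plateau = pa_s_to_cp(effective_viscosity(CASSON.gamma_min, CASSON))
        assert s.avg_viscosity_ps == pytest.approx(plateau)

    def test_extrema_ordering_invariant(self, dome_solution):
        s = summarize(dome_solution, CASSON)
        assert 0.0 <= s.wss_min <= s.wss_tavg <= s.wss_max

    def test_viscosity_within_plateau_bounds(self, dome_solution):
        s = summarize(dome_solution, CASSON)
        lo = pa_s_to_cp(CASSON.k)
        hi = pa_s_to_cp(effective_viscosity(CASSON.gamma_min, CASSON))
        for val in (s.avg_viscosity_ps, s.avg_viscosity_ed):
            assert lo <= val <= hi

    def test_spatial_mean_extrema_mode_is_tighter(self, dome_solution):
        g = summarize(dome_solution, CASSON, extrema_mode="global")
        m = summarize(dome_solution, CASSON, extrema_mode="spatial_mean")
        assert m.wss_min >= g.wss_min
        assert m.wss_max <= g.wss_max


class TestSizeEffect:
    def test_dome_shear_decreases_and_viscosity_increases_with_size(self):
        # the central qualitative effect: larger domes -> lower dome-average
        # shear rate -> higher dome-average viscosity (shear-thinning coupling)
        from hemoflow import ShapeParams, steady_solve

        shears, viscs = [], []
        for height, ostium in ((2.5, 4.0), (4.0, 4.8), (6.2, 5.9)):
            shape = ShapeParams.from_height_and_ostium(height, ostium)
            dom = build_2d_domain(shape, mesh_size=0.3)
            sol = steady_solve(dom, CASSON, 2.6)
            g = shear_rate_centers(dom, sol.u[0], sol.v[0])
            shears.append(dome_average(g, dom))
            viscs.append(
                float(np.mean(pa_s_to_cp(effective_viscosity(g[dom.dome], CASSON))))
            )
        assert shears[0] > shears[1] > shears[2]
        assert viscs[0] < viscs[1] < viscs[2]
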