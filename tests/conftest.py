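"""Shared fixtures: domains and (expensive) reference solves, computed once."""

import numpy as np
import pytest

from hemoflow import (
    CassonParams,
    ShapeParams,
    SolverConfig,
    build_2d_domain,
    solve_unsteady,
    steady_solve,
)

NEWTONIAN = CassonParams(tau_y=0.0, k=0.0035)
CASSON = CassonParams(tau_y=0.008, k=0.0035)


@pytest.fixture(scope="session")
def channel_domain():
    """Plain parent-vessel channel, default spacing (0.2 mm, 20 cells across)."""
    return build_2d_domain(None, mesh_size=0.2)


@pytest.fixture(scope="session")
def small_dome_shape():
    """Spherical-cap dome at the small-group mean morphology."""
    return ShapeParams.from_height_and_ostium(3.4, 4.5)


@pytest.fixture(scope="session")
def dome_domain(small_dome_shape):
    return build_2d_domain(small_dome_shape, mesh_size=0.3)


@pytest.fixture(scope="session")
def poiseuille_solution(channel_domain):
    """Steady Newtonian channel solve at the mean physiological flow rate."""
    return steady_solve(channel_domain, NEWTONIAN, q_ml_s=2.6)


@pytest.fixture(scope="session")
def dome_solution(dome_domain):
    """Pulsatile two-cycle dome solve at the fast preset (report cycle 2)."""
    cfg = SolverConfig(n_cycles=2, report_cycle=2, time_step=1.0 / 100.0)
    return solve_unsteady(dome_domain, CASSON, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
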