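"""Unsteady incompressible generalized-Newtonian flow on the 2D domain.

Physics: conservation of mass and momentum for a laminar, incompressible,
shear-thinning fluid,

    div(u) = 0
    rho (du/dt + u . grad u) = -grad p + div( 2 mu(gamma_dot) D(u) )

with the apparent viscosity mu(gamma_dot) given by the Casson law
(:func:`hemoflow.rheology.effective_viscosity`) evaluated at the local
scalar shear rate gamma_dot = sqrt(2 D:D).

Discretization: uniform staggered (MAC) grid over the masked domain of
:class:`hemoflow.domain.SimDomain2D`.  Each time step solves the two
momentum components implicitly (first-order upwind advection, variable-
viscosity diffusion, both in the matrix; the transpose part of the stress
divergence is lagged) and projects onto the divergence-free space with an
incremental pressure-correction Poisson solve.  The nonlinear coupling of
viscosity and advection to the velocity is resolved by Picard iteration
stopped at a relative increment below ``relative_tolerance`` (default 0.01)
or ``max_nonlinear_iterations`` (default 50).

Boundary conditions: prescribed parabolic inlet velocity (pulsatile flow
rate), no-slip rigid walls, and an outflow boundary implemented as
zero-streamwise-gradient velocity with exact flux matching (the desk-scale
stand-in for a traction-free outlet).

The protocol mirrors clinical CFD practice: the waveform runs for
``n_cycles`` cardiac cycles (default 4) and only ``report_cycle`` (default
the second) is stored, after start-up transients have decayed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .domain import SimDomain2D
from .rheology import CassonParams, effective_viscosity

_TYPE_UNKNOWN, _TYPE_KNOWN, _TYPE_GHOST, _TYPE_ZEROGRAD = 0, 1, 2, 3


@dataclass(frozen=True)
class SolverConfig:
    """Numerical and physiological settings for a simulation.

    density [kg/m^3]; cycle_period [s]; mean_flow_rate [mL/s] with a
    single-harmonic waveform of relative amplitude ``waveform_amplitude``;
    ``time_step=None`` means T/200.
    """

    density: float = 1060.0
    cycle_period: float = 1.0
    n_cycles: int = 4
    report_cycle: int = 2
    time_step: float | None = None
    relative_tolerance: float = 0.01
    max_nonlinear_iterations: int = 50
    mean_flow_rate: float = 2.6  # mL/s
    waveform_amplitude: float = 0.5
    store_every: int = 1

    def __post_init__(self):
        if self.density <= 0 or self.cycle_period <= 0:
            raise ValueError("density and cycle_period must be positive")
        if not (1 <= self.report_cycle <= self.n_cycles):
            raise ValueError("report_cycle must lie in [1, n_cycles]")
        if not (0 <= self.waveform_amplitude < 1):
            raise ValueError("waveform_amplitude must be in [0, 1)")
        if not (0 < self.relative_tolerance < 1):
            raise ValueError("relative_tolerance must be in (0, 1)")

    def to_dict(self):
        return {
            "density_kg_m3": self.density,
            "cycle_period_s": self.cycle_period,
            "n_cycles": self.n_cycles,
            "report_cycle": self.report_cycle,
            "time_step_s": self.time_step,
            "relative_tolerance": self.relative_tolerance,
            "max_nonlinear_iterations": self.max_nonlinear_iterations,
            "mean_flow_rate_ml_s": self.mean_flow_rate,
            "waveform_amplitude": self.waveform_amplitude,
            "store_every": self.store_every,
        }

    @classmethod
    def from_dict(cls, d):
        key_map = {
            "density_kg_m3": "density",
            "cycle_period_s": "cycle_period",
            "time_step_s": "time_step",
            "mean_flow_rate_ml_s": "mean_flow_rate",
        }
        kwargs = {key_map.get(k, k): v for k, v in d.items()}
        return cls(**kwargs)


class SolverFailure(RuntimeError):
    """Velocity norm diverged; the solve cannot continue."""


def inlet_waveform(t, config: SolverConfig):
    """Pulsatile inlet flow rate [mL/s] at time ``t`` [s].

    Q(t) = Q_mean (1 + A sin(2 pi t / T)): the cycle mean is the published
    mean flow rate, peak systole falls at t = T/4 (mod T) and end diastole
    at t = 3T/4 (mod T).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    q = config.mean_flow_rate * (
        1.0 + config.waveform_amplitude * np.sin(2.0 * np.pi * t / config.cycle_period)
    )
    return q if q.ndim else float(q)


def inlet_profile(q_ml_s: float, y, channel_width: float, inlet_area_mm2: float | None = None):
    """Parabolic (fully developed) inlet velocity [m/s] at positions ``y``.

    The 2D channel stands in for a circular artery: the prescribed
    area-mean speed is Q / A_inlet with A_inlet the patient's inlet area
    (default the circular area of the parent diameter), so reported speeds
    stay on the physiological scale.  The profile maximum is 1.5x the mean,
    and the profile vanishes at both walls.
    """
    if q_ml_s < 0:
        raise ValueError("flow rate must be >= 0")
    if channel_width <= 0:
        raise ValueError("inlet extent must be positive")
    if inlet_area_mm2 is None:
        inlet_area_mm2 = 0.25 * np.pi * (channel_width * 1e3) ** 2
    if inlet_area_mm2 <= 0:
        raise ValueError("inlet area must be positive")
    u_mean = q_ml_s / inlet_area_mm2  # mL/s per mm^2 == m/s
    y = np.asarray(y, dtype=float)
    xi = 2.0 * (y - channel_width / 2.0) / channel_width
    return 1.5 * u_mean * np.clip(1.0 - xi**2, 0.0, None)


@dataclass
class FlowSolution:
    """Stored velocity/pressure snapshots plus cycle bookkeeping.

    ``u`` has shape (n_times, nx+1, ny), ``v`` (n_times, nx, ny+1), ``p``
    (n_times, nx, ny); ``times`` are the snapshot times in seconds.
    ``ps_index``/``ed_index`` flag the peak-systole and end-diastole
    snapshots of the report cycle.
    """

    domain: SimDomain2D
    config: SolverConfig
    times: np.ndarray
    u: np.ndarray = field(repr=False)
    v: np.ndarray = field(repr=False)
    p: np.ndarray = field(repr=False)
    ps_index: int = 0
    ed_index: int = 0
    nonlinear_iterations: list = field(default_factory=list)
    converged: bool = True

    def cycle_indices(self, cycle: int) -> np.ndarray:
        """Snapshot indices whose times fall in cardiac cycle ``cycle``."""
        T = self.config.cycle_period
        eps = 1e-9
        return np.nonzero((self.times >= (cycle - 1) * T - eps) & (self.times <= cycle * T + eps))[0]


class _Discretization:
    """Constant index machinery of the masked MAC grid for one domain."""

    def __init__(self, dom: SimDomain2D):
        self.dom = dom
        nx, ny = dom.nx, dom.ny
        F = dom.fluid
        solid = ~F

        # u faces: (nx+1, ny).  Solid-embedded mask (both adjacent cells solid).
        su = np.ones((nx + 1, ny), dtype=bool)
        su[1:nx] = solid[:-1] & solid[1:]
        su[0] = solid[0]
        su[nx] = solid[-1]
        self.solid_u = su
        au = np.zeros((nx + 1, ny), dtype=bool)
        au[1:nx] = F[:-1] & F[1:]
        self.active_u = au
        self.inlet_j = np.nonzero(F[0])[0]
        self.outlet_j = np.nonzero(F[-1])[0]

        # v faces: (nx, ny+1)
        sv = np.ones((nx, ny + 1), dtype=bool)
        sv[:, 1:ny] = solid[:, :-1] & solid[:, 1:]
        sv[:, 0] = solid[:, 0]
        sv[:, ny] = solid[:, -1]
        self.solid_v = sv
        av = np.zeros((nx, ny + 1), dtype=bool)
        av[:, 1:ny] = F[:, :-1] & F[:, 1:]
        self.active_v = av

        self.u_index = -np.ones((nx + 1, ny), dtype=np.int64)
        ui, uj = np.nonzero(au)
        self.u_index[ui, uj] = np.arange(ui.size)
        self.ui, self.uj = ui, uj

        self.v_index = -np.ones((nx, ny + 1), dtype=np.int64)
        vi, vj = np.nonzero(av)
        self.v_index[vi, vj] = np.arange(vi.size)
        self.vi, self.vj = vi, vj

        self._classify_u()
        self._classify_v()
        self._build_poisson()

    # -- neighbor classification ----------------------------------------
    def _classify_u(self):
        dom, nx, ny = self.dom, self.dom.nx, self.dom.ny
        F = dom.fluid
        ui, uj = self.ui, self.uj
        n = ui.size
        self.u_nb = {}
        for name, di, dj in (("E", 1, 0), ("W", -1, 0), ("N", 0, 1), ("S", 0, -1)):
            idx = -np.ones(n, dtype=np.int64)
            typ = np.full(n, _TYPE_KNOWN, dtype=np.int8)
            ni, nj = ui + di, uj + dj
            if dj == 0:
                # E/W neighbours share the row; boundary columns are known values
                inside = (ni >= 1) & (ni <= nx - 1)
                act = np.zeros(n, dtype=bool)
                act[inside] = self.active_u[ni[inside], nj[inside]]
                typ[act] = _TYPE_UNKNOWN
                idx[act] = self.u_index[ni[act], nj[act]]
                # i == 0 (inlet) and i == nx (outlet lagged) stay KNOWN;
                # inactive interior faces are no-penetration values (0), KNOWN.
            else:
                off = (nj < 0) | (nj >= ny)
                typ[off] = _TYPE_GHOST
                ok = ~off
                act = np.zeros(n, dtype=bool)
                act[ok] = self.active_u[ni[ok], nj[ok]]
                typ[ok & act] = _TYPE_UNKNOWN
                idx[ok & act] = self.u_index[ni[ok & act], nj[ok & act]]
                rest = ok & ~act
                # wall ghost iff the whole neighbouring face is inside solid
                ghost = np.zeros(n, dtype=bool)
                ghost[rest] = self.solid_u[ni[rest], nj[rest]]
                typ[rest & ghost] = _TYPE_GHOST
                # staircase corner (one fluid cell): face value 0, KNOWN
            self.u_nb[name] = (idx, typ, ni, nj)

    def _classify_v(self):
        dom, nx, ny = self.dom, self.dom.nx, self.dom.ny
        vi, vj = self.vi, self.vj
        n = vi.size
        self.v_nb = {}
        for name, di, dj in (("E", 1, 0), ("W", -1, 0), ("N", 0, 1), ("S", 0, -1)):
            idx = -np.ones(n, dtype=np.int64)
            typ = np.full(n, _TYPE_KNOWN, dtype=np.int8)
            ni, nj = vi + di, vj + dj
            if dj == 0:
                west_ghost = ni < 0  # inlet line: v = 0 at x = 0, half-cell away
                east_zg = ni >= nx  # outlet: zero streamwise gradient
                typ[west_ghost] = _TYPE_GHOST
                typ[east_zg] = _TYPE_ZEROGRAD
                ok = ~(west_ghost | east_zg)
                act = np.zeros(n, dtype=bool)
                act[ok] = self.active_v[ni[ok], nj[ok]]
                typ[ok & act] = _TYPE_UNKNOWN
                idx[ok & act] = self.v_index[ni[ok & act], nj[ok & act]]
                rest = ok & ~act
                ghost = np.zeros(n, dtype=bool)
                ghost[rest] = self.solid_v[ni[rest], nj[rest]]
                typ[rest & ghost] = _TYPE_GHOST
            else:
                off = (nj < 0) | (nj > ny)
                typ[off] = _TYPE_KNOWN  # never happens for active faces
                ok = ~off
                act = np.zeros(n, dtype=bool)
                act[ok] = self.active_v[ni[ok], np.clip(nj[ok], 0, ny)]
                typ[ok & act] = _TYPE_UNKNOWN
                idx[ok & act] = self.v_index[ni[ok & act], nj[ok & act]]
                # inactive N/S neighbours are wall faces with v = 0: KNOWN
            self.v_nb[name] = (idx, typ, ni, nj)

    # -- pressure Poisson -------------------------------------------------
    def _build_poisson(self):
        dom = self.dom
        nx, ny, h = dom.nx, dom.ny, dom.h
        F = dom.fluid
        self.p_index = -np.ones((nx, ny), dtype=np.int64)
        pi, pj = np.nonzero(F)
        self.p_index[pi, pj] = np.arange(pi.size)
        self.pi, self.pj = pi, pj
        n = pi.size

        rows, cols, vals = [], [], []
        diag = np.zeros(n)
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ni, nj = pi + di, pj + dj
            # link exists iff the shared face is a correctable (active) one
            if dj == 0:
                fi = np.maximum(pi, ni)  # u-face index between the two cells
                inside = (ni >= 0) & (ni < nx)
                link = np.zeros(n, dtype=bool)
                link[inside] = self.active_u[fi[inside], pj[inside]]
            else:
                fj = np.maximum(pj, nj)
                inside = (nj >= 0) & (nj < ny)
                link = np.zeros(n, dtype=bool)
                link[inside] = self.active_v[pi[inside], fj[inside]]
            lk = np.nonzero(link)[0]
            rows.append(self.p_index[pi[lk], pj[lk]])
            cols.append(self.p_index[ni[lk], nj[lk]])
            vals.append(np.full(lk.size, 1.0 / h**2))
            diag[self.p_index[pi[lk], pj[lk]]] -= 1.0 / h**2

        rows.append(np.arange(n))
        cols.append(np.arange(n))
        vals.append(diag)
        A = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
        ).tocsr()
        # pin one cell: the operator is otherwise all-Neumann (singular)
        pin = 0
        A = A.tolil()
        A.rows[pin], A.data[pin] = [pin], [1.0]
        self._poisson_lu = splu(A.tocsc())
        self._poisson_pin = pin


def _get_disc(dom: SimDomain2D) -> _Discretization:
    disc = getattr(dom, "_disc", None)
    if disc is None:
        disc = _Discretization(dom)
        dom._disc = disc
    return disc


# ---------------------------------------------------------------------------
# field operators


def shear_rate_nodes(dom: SimDomain2D, u: np.ndarray, v: np.ndarray):
    """du/dy and dv/dx at grid nodes, no-slip ghost values at walls."""
    disc = _get_disc(dom)
    nx, ny, h = dom.nx, dom.ny, dom.h
    fu = ~disc.solid_u  # face carries a meaningful velocity value
    dyu = np.zeros((nx + 1, ny + 1))
    # interior node rows
    a = fu[:, 1:]  # face above node row j (j = 1..ny-1) -> u[:, j]
    b = fu[:, :-1]
    both = a & b
    dyu[:, 1:ny][both] = (u[:, 1:][both] - u[:, :-1][both]) / h
    onlya = a & ~b
    dyu[:, 1:ny][onlya] = 2.0 * u[:, 1:][onlya] / h
    onlyb = ~a & b
    dyu[:, 1:ny][onlyb] = -2.0 * u[:, :-1][onlyb] / h
    dyu[:, 0][fu[:, 0]] = 2.0 * u[:, 0][fu[:, 0]] / h
    dyu[:, ny][fu[:, -1]] = -2.0 * u[:, -1][fu[:, -1]] / h

    fv = ~disc.solid_v
    dxv = np.zeros((nx + 1, ny + 1))
    a = fv[1:, :]
    b = fv[:-1, :]
    both = a & b
    dxv[1:nx, :][both] = (v[1:, :][both] - v[:-1, :][both]) / h
    onlya = a & ~b
    dxv[1:nx, :][onlya] = 2.0 * v[1:, :][onlya] / h
    onlyb = ~a & b
    dxv[1:nx, :][onlyb] = -2.0 * v[:-1, :][onlyb] / h
    dxv[0, :][fv[0, :]] = 2.0 * v[0, :][fv[0, :]] / h  # inlet line: v = 0 there
    # outlet column: zero streamwise gradient -> leave 0
    return dyu, dxv


def shear_rate_centers(dom: SimDomain2D, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Scalar shear rate gamma_dot = sqrt(2 D:D) at cell centres [1/s]."""
    h = dom.h
    ux = (u[1:, :] - u[:-1, :]) / h
    vy = (v[:, 1:] - v[:, :-1]) / h
    dyu, dxv = shear_rate_nodes(dom, u, v)
    s_nodes = dyu + dxv
    s_c = 0.25 * (s_nodes[:-1, :-1] + s_nodes[1:, :-1] + s_nodes[:-1, 1:] + s_nodes[1:, 1:])
    g = np.sqrt(2.0 * ux**2 + 2.0 * vy**2 + s_c**2)
    g[~dom.fluid] = 0.0
    return g


def _viscosity_fields(dom: SimDomain2D, u, v, params: CassonParams):
    """mu at cell centres (solid cells excluded) and at nodes (fluid average)."""
    g = shear_rate_centers(dom, u, v)
    mu_c = np.zeros_like(g)
    mu_c[dom.fluid] = effective_viscosity(g[dom.fluid], params)
    F = dom.fluid.astype(float)
    nx, ny = dom.nx, dom.ny
    mu_n = np.zeros((nx + 1, ny + 1))
    wsum = np.zeros((nx + 1, ny + 1))
    for di in (0, 1):
        for dj in (0, 1):
            mu_n[di : nx + di, dj : ny + dj] += mu_c
            wsum[di : nx + di, dj : ny + dj] += F
    mu_n = np.divide(mu_n, wsum, out=np.zeros_like(mu_n), where=wsum > 0)
    return mu_c, mu_n, g


# ---------------------------------------------------------------------------
# momentum assembly


def _assemble_momentum(disc, comp, u, v, mu_c, mu_n, p, rho, inv_dt, u_old_vals, rhs_extra):
    """Build the sparse system for one velocity component.

    ``comp`` is 'u' or 'v'; advection coefficients and known neighbour
    values come from the current Picard iterate arrays ``u, v``.
    """
    dom = disc.dom
    nx, ny, h = dom.nx, dom.ny, dom.h

    if comp == "u":
        fi, fj = disc.ui, disc.uj
        nbs = disc.u_nb
        arr = u
        # advecting velocities on the u control volume
        ue = 0.5 * (u[fi, fj] + u[np.minimum(fi + 1, nx), fj])
        uw = 0.5 * (u[np.maximum(fi - 1, 0), fj] + u[fi, fj])
        vn = 0.5 * (v[fi - 1, fj + 1] + v[fi, fj + 1])
        vs = 0.5 * (v[fi - 1, fj] + v[fi, fj])
        mu_e = mu_c[fi, fj]
        mu_w = mu_c[fi - 1, fj]
        mu_n_ = mu_n[fi, fj + 1]
        mu_s = mu_n[fi, fj]
        dp = -(p[fi, fj] - p[fi - 1, fj]) / h
    else:
        fi, fj = disc.vi, disc.vj
        nbs = disc.v_nb
        arr = v
        ue = 0.5 * (u[fi + 1, fj - 1] + u[fi + 1, fj])
        uw = 0.5 * (u[fi, fj - 1] + u[fi, fj])
        vn = 0.5 * (v[fi, fj] + v[fi, np.minimum(fj + 1, ny)])
        vs = 0.5 * (v[fi, np.maximum(fj - 1, 0)] + v[fi, fj])
        mu_e = mu_n[fi + 1, fj]
        mu_w = mu_n[fi, fj]
        mu_n_ = mu_c[fi, fj]
        mu_s = mu_c[fi, fj - 1]
        dp = -(p[fi, fj] - p[fi, fj - 1]) / h

    n = fi.size
    adv = {
        "E": rho * np.maximum(-ue, 0.0) / h,
        "W": rho * np.maximum(uw, 0.0) / h,
        "N": rho * np.maximum(-vn, 0.0) / h,
        "S": rho * np.maximum(vs, 0.0) / h,
    }
    adv_diag = rho * (np.maximum(ue, 0.0) + np.maximum(-uw, 0.0) + np.maximum(vn, 0.0) + np.maximum(-vs, 0.0)) / h
    dif = {"E": mu_e / h**2, "W": mu_w / h**2, "N": mu_n_ / h**2, "S": mu_s / h**2}

    diag = rho * inv_dt + adv_diag
    rhs = rho * inv_dt * u_old_vals + dp + rhs_extra
    rows, cols, vals = [np.arange(n)], [np.arange(n)], [None]

    opposite = {"E": "W", "W": "E", "N": "S", "S": "N"}
    for name in ("E", "W", "N", "S"):
        idx, typ, ni, nj = nbs[name]
        coeff = dif[name] + adv[name]
        unk = typ == _TYPE_UNKNOWN
        rows.append(np.nonzero(unk)[0])
        cols.append(idx[unk])
        vals.append(-coeff[unk])
        diag = diag + dif[name]  # default: neighbour at distance h
        ghost = typ == _TYPE_GHOST
        zg = typ == _TYPE_ZEROGRAD
        diag[zg] -= dif[name][zg] + adv[name][zg]  # drop the link entirely
        known = typ == _TYPE_KNOWN
        if np.any(known):
            ki = np.nonzero(known)[0]
            vals_known = arr[np.clip(ni[ki], 0, arr.shape[0] - 1), np.clip(nj[ki], 0, arr.shape[1] - 1)]
            rhs[ki] += coeff[ki] * vals_known
        if np.any(ghost):
            # no-slip wall half a cell beyond the face.  Second-order ghost:
            # the quadratic through (wall 0, centre, opposite neighbour)
            # gives u_ghost = -2 u_C + u_opp / 3; falls back to the linear
            # reflection u_ghost = -u_C where the opposite leg is unusable.
            oidx, otyp, oni, onj = nbs[opposite[name]]
            g2 = ghost & (otyp == _TYPE_UNKNOWN)
            gi = np.nonzero(g2)[0]
            diag[gi] += 2.0 * dif[name][gi]
            rows.append(gi)
            cols.append(oidx[gi])
            vals.append(-dif[name][gi] / 3.0)
            gk = ghost & (otyp == _TYPE_KNOWN)
            ki = np.nonzero(gk)[0]
            diag[ki] += 2.0 * dif[name][ki]
            ovals = arr[np.clip(oni[ki], 0, arr.shape[0] - 1), np.clip(onj[ki], 0, arr.shape[1] - 1)]
            rhs[ki] += dif[name][ki] / 3.0 * ovals
            g1 = ghost & ~g2 & ~gk
            diag[g1] += dif[name][g1]  # linear reflection fallback

    vals[0] = diag
    A = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    ).tocsc()
    return A, rhs


def _transpose_stress(disc, u, v, mu_c, mu_n):
    """Explicit part of the stress divergence: div(mu grad(u)^T) per component."""
    dom = disc.dom
    nx, ny, h = dom.nx, dom.ny, dom.h
    dyu, dxv = shear_rate_nodes(dom, u, v)

    # x-component at u faces: d/dx(mu du/dx) + d/dy(mu dv/dx)
    ux = (u[1:, :] - u[:-1, :]) / h  # at cell centres
    flux_x = mu_c * ux
    tx = np.zeros_like(u)
    tx[1:nx, :] = (flux_x[1:, :] - flux_x[:-1, :]) / h
    fy = mu_n * dxv
    tx += (fy[:, 1:] - fy[:, :-1]) / h

    # y-component at v faces: d/dy(mu dv/dy) + d/dx(mu du/dy)
    vy = (v[:, 1:] - v[:, :-1]) / h
    flux_y = mu_c * vy
    ty = np.zeros_like(v)
    ty[:, 1:ny] = (flux_y[:, 1:] - flux_y[:, :-1]) / h
    fx = mu_n * dyu
    ty += (fx[1:, :] - fx[:-1, :]) / h
    return tx, ty


# ---------------------------------------------------------------------------
# stepping


def _apply_outlet(disc, u):
    dom = disc.dom
    rows_in, rows_out = disc.inlet_j, disc.outlet_j
    q_in = u[0, rows_in].sum()
    u[-1, :] = 0.0
    u[-1, rows_out] = u[-2, rows_out]
    q_out = u[-1, rows_out].sum()
    if abs(q_out) > 1e-300:
        u[-1, rows_out] *= q_in / q_out
    else:
        u[-1, rows_out] = q_in / max(rows_out.size, 1)


def _project(disc, u, v, p, rho, dt):
    dom = disc.dom
    h = dom.h
    div = (u[1:, :] - u[:-1, :] + v[:, 1:] - v[:, :-1]) / h
    rhs = (rho / dt) * div[disc.pi, disc.pj]
    rhs[disc._poisson_pin] = 0.0
    phi_flat = disc._poisson_lu.solve(rhs)
    phi = np.zeros((dom.nx, dom.ny))
    phi[disc.pi, disc.pj] = phi_flat
    fac = dt / (rho * h)
    gx = phi[1:, :] - phi[:-1, :]
    u[1:-1, :][disc.active_u[1:-1, :]] -= fac * gx[disc.active_u[1:-1, :]]
    gy = phi[:, 1:] - phi[:, :-1]
    v[:, 1:-1][disc.active_v[:, 1:-1]] -= fac * gy[disc.active_v[:, 1:-1]]
    p += phi
    return u, v, p


def _advance(disc, params, config, u0, v0, p0, dt, inlet_u, steady=False):
    """One time step (or pseudo-step): Picard loop + projection.

    Returns (u, v, p, n_iterations, final relative increment).
    """
    dom = disc.dom
    rho = config.density
    # steady solves use the same update with dt as a pseudo-time relaxation
    inv_dt = 1.0 / dt

    u_it, v_it, p_it = u0.copy(), v0.copy(), p0.copy()
    u_it[0, :] = 0.0
    u_it[0, disc.inlet_j] = inlet_u
    n_iter = 0
    rel = np.inf
    for m in range(config.max_nonlinear_iterations):
        n_iter = m + 1
        mu_c, mu_n, _ = _viscosity_fields(dom, u_it, v_it, params)
        tx, ty = _transpose_stress(disc, u_it, v_it, mu_c, mu_n)

        Au, bu = _assemble_momentum(
            disc, "u", u_it, v_it, mu_c, mu_n, p_it, rho, inv_dt,
            u0[disc.ui, disc.uj], tx[disc.ui, disc.uj],
        )
        Av, bv = _assemble_momentum(
            disc, "v", u_it, v_it, mu_c, mu_n, p_it, rho, inv_dt,
            v0[disc.vi, disc.vj], ty[disc.vi, disc.vj],
        )
        u_new = u_it.copy()
        v_new = v_it.copy()
        u_new[disc.ui, disc.uj] = splu(Au).solve(bu)
        v_new[disc.vi, disc.vj] = splu(Av).solve(bv)
        _apply_outlet(disc, u_new)
        u_new, v_new, p_new = _project(disc, u_new, v_new, p_it.copy(), rho, dt)

        num = np.sqrt(
            np.sum((u_new[disc.ui, disc.uj] - u_it[disc.ui, disc.uj]) ** 2)
            + np.sum((v_new[disc.vi, disc.vj] - v_it[disc.vi, disc.vj]) ** 2)
        )
        den = max(
            np.sqrt(np.sum(u_new[disc.ui, disc.uj] ** 2) + np.sum(v_new[disc.vi, disc.vj] ** 2)),
            1e-14,
        )
        rel = num / den
        u_it, v_it, p_it = u_new, v_new, p_new
        if not np.isfinite(rel) or den > 1e6:
            raise SolverFailure("velocity norm diverged during nonlinear iteration")
        if rel < config.relative_tolerance:
            break
    return u_it, v_it, p_it, n_iter, rel


def solve_unsteady(
    dom: SimDomain2D,
    params: CassonParams,
    config: SolverConfig | None = None,
    inlet_area_mm2: float | None = None,
    store_cycles: tuple[int, ...] | None = None,
) -> FlowSolution:
    """Advance the pulsatile problem over ``config.n_cycles`` cardiac cycles.

    Only the cycles in ``store_cycles`` (default: the report cycle) are
    stored; each stored cycle spans exactly one period including both
    endpoints.  Peak-systole / end-diastole indices refer to the report
    cycle and are located at the waveform extrema (T/4 and 3T/4).
    """
    config = config or SolverConfig()
    disc = _get_disc(dom)
    T = config.cycle_period
    dt = config.time_step if config.time_step is not None else T / 200.0
    spc = max(2, int(round(T / dt)))
    dt = T / spc
    if store_cycles is None:
        store_cycles = (config.report_cycle,)
    store_steps = set()
    for c in store_cycles:
        for s in range((c - 1) * spc, c * spc + 1, config.store_every):
            store_steps.add(s)
        store_steps.add(c * spc)

    y_faces = dom.face_y()
    base = inlet_profile(config.mean_flow_rate, y_faces[disc.inlet_j], dom.channel_height, inlet_area_mm2)

    nx, ny = dom.nx, dom.ny
    u = np.zeros((nx + 1, ny))
    v = np.zeros((nx, ny + 1))
    p = np.zeros((nx, ny))
    # start from the steady solution at the initial flow rate: shortens the
    # start-up transient so the report cycle is close to periodic
    q0 = inlet_waveform(0.0, config)
    u, v, p = _steady_march(disc, params, config, base * (q0 / config.mean_flow_rate))

    times, us, vs, ps, iters = [], [], [], [], []
    if 0 in store_steps:
        times.append(0.0)
        us.append(u.copy())
        vs.append(v.copy())
        ps.append(p.copy())
    converged = True
    n_steps = config.n_cycles * spc
    for nstep in range(1, n_steps + 1):
        t = nstep * dt
        q = inlet_waveform(t, config)
        inlet_u = base * (q / config.mean_flow_rate)
        u, v, p, nit, rel = _advance(disc, params, config, u, v, p, dt, inlet_u)
        iters.append((nit, rel))
        if nit >= config.max_nonlinear_iterations and rel >= config.relative_tolerance:
            converged = False
            warnings.warn(
                f"nonlinear iteration hit the cap at t={t:.4f}s (relative increment {rel:.3g})",
                RuntimeWarning,
                stacklevel=2,
            )
        if nstep in store_steps:
            times.append(t)
            us.append(u.copy())
            vs.append(v.copy())
            ps.append(p.copy())

    times = np.array(times)
    rc = config.report_cycle
    tmod = np.mod(times - 1e-12, T)
    in_rc = (times >= (rc - 1) * T - 1e-9) & (times <= rc * T + 1e-9)
    ps_candidates = np.where(in_rc, np.abs(tmod - T / 4.0), np.inf)
    ed_candidates = np.where(in_rc, np.abs(tmod - 3.0 * T / 4.0), np.inf)
    return FlowSolution(
        domain=dom,
        config=config,
        times=times,
        u=np.array(us),
        v=np.array(vs),
        p=np.array(ps),
        ps_index=int(np.argmin(ps_candidates)),
        ed_index=int(np.argmin(ed_candidates)),
        nonlinear_iterations=iters,
        converged=converged,
    )


def _steady_march(disc, params, config, inlet_u, dt_pseudo=0.05, tol=1e-5, max_steps=400):
    dom = disc.dom
    nx, ny = dom.nx, dom.ny
    u = np.zeros((nx + 1, ny))
    v = np.zeros((nx, ny + 1))
    p = np.zeros((nx, ny))
    u[0, disc.inlet_j] = inlet_u
    cfg = replace(config, relative_tolerance=min(config.relative_tolerance, 0.01))
    for _ in range(max_steps):
        u_new, v_new, p, nit, rel = _advance(disc, params, cfg, u, v, p, dt_pseudo, inlet_u)
        change = np.max(np.abs(u_new - u)) / max(np.max(np.abs(u_new)), 1e-14)
        u, v = u_new, v_new
        if change < tol:
            break
    return u, v, p


def steady_solve(
    dom: SimDomain2D,
    params: CassonParams,
    q_ml_s: float,
    config: SolverConfig | None = None,
    inlet_area_mm2: float | None = None,
    tol: float = 1e-5,
    max_steps: int = 400,
) -> FlowSolution:
    """Steady solution at constant inflow ``q_ml_s`` (single snapshot).

    Obtained by pseudo-time marching of the implicit scheme to a fixed
    point; used as the quasi-steady oracle and for validation against
    closed-form channel profiles.
    """
    config = config or SolverConfig()
    disc = _get_disc(dom)
    y_faces = dom.face_y()
    inlet_u = inlet_profile(q_ml_s, y_faces[disc.inlet_j], dom.channel_height, inlet_area_mm2)
    u, v, p = _steady_march(disc, params, config, inlet_u, tol=tol, max_steps=max_steps)
    return FlowSolution(
        domain=dom,
        config=config,
        times=np.array([0.0]),
        u=u[None, :, :],
        v=v[None, :, :],
        p=p[None, :, :],
        ps_index=0,
        ed_index=0,
    )


def boundary_flux_imbalance(sol: FlowSolution, time_index: int = 0) -> float:
    """|net boundary flux| / inlet flux at a stored time (mass check)."""
    disc = _get_disc(sol.domain)
    u = sol.u[time_index]
    q_in = u[0, disc.inlet_j].sum()
    q_out = u[-1, disc.outlet_j].sum()
    return abs(q_out - q_in) / max(abs(q_in), 1e-300)
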