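"""Dome-resolved hemodynamic metrics.

From a stored flow solution this module derives the per-patient factors
used to compare small and large aneurysms:

* scalar shear rate gamma_dot = sqrt(2 D:D) and the apparent Casson
  viscosity mu(gamma_dot), averaged over the dome region at peak systole
  and end diastole (the 2D dome area standing in for the dome volume);
* instantaneous wall shear stress WSS_i = mu(gamma_w) * gamma_w at each
  dome-wall sample, the tangential viscous traction on the rigid wall;
* the time average TAWSS = (1/T) int_0^T |WSS_i| dt over one cardiac
  cycle (trapezoidal rule on the stored snapshots), area-averaged over the
  dome wall to a single per-patient scalar;
* minimal and maximal WSS, by default the global extremum over dome-wall
  samples x cycle times (one number per patient per the lowest/highest
  value seen anywhere on the dome during the cycle).

Viscosities are reported in centipoise, stresses in Pa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .domain import SimDomain2D
from .rheology import CassonParams, effective_viscosity, pa_s_to_cp
from .solver import FlowSolution, shear_rate_centers


def scalar_shear_rate(velocity_gradient) -> float:
    """Scalar shear rate of a 2x2 (or 3x3) velocity gradient tensor.

    gamma_dot = sqrt(2 D:D) with D the symmetric part; zero for rigid
    rotation, equal to the shear coefficient for simple shear.
    """
    G = np.asarray(velocity_gradient, dtype=float)
    if not np.all(np.isfinite(G)):
        raise ValueError("velocity gradient must be finite")
    D = 0.5 * (G + G.T)
    return float(np.sqrt(2.0 * np.sum(D * D)))


def dome_average(scalar_field: np.ndarray, dom: SimDomain2D, time_index: int | None = None) -> float:
    """Measure-weighted mean of a cell-centred field over the dome region.

    ``scalar_field`` is (nx, ny) or (n_times, nx, ny) with ``time_index``.
    On the uniform grid all cells have equal measure, so this is the
    arithmetic mean over dome-tagged cells.
    """
    if not dom.dome.any():
        raise ValueError("domain has an empty dome region")
    f = np.asarray(scalar_field, dtype=float)
    if f.ndim == 3:
        if time_index is None:
            raise ValueError("time_index required for a time-resolved field")
        f = f[time_index]
    return float(f[dom.dome].mean())


@dataclass
class WallField:
    """Instantaneous WSS magnitude at wall samples over stored times.

    ``wss`` has shape (n_samples, n_times); ``on_dome`` flags the dome-wall
    subset; ``positions`` are the wall-face midpoints in metres.
    """

    positions: np.ndarray = field(repr=False)  # (n_samples, 2)
    on_dome: np.ndarray = field(repr=False)  # (n_samples,) bool
    times: np.ndarray = field(repr=False)
    wss: np.ndarray = field(repr=False)
    period: float = 1.0

    def __post_init__(self):
        if np.any(self.wss < 0):
            raise ValueError("WSS magnitudes must be non-negative")


def wall_shear_stress(
    sol: FlowSolution, params: CassonParams, time_indices: np.ndarray | None = None
) -> WallField:
    """Instantaneous WSS at every wall face of the domain.

    The wall shear rate is the one-sided quadratic estimate of the
    tangential velocity gradient at the wall (exact for a parabolic
    profile): with the no-slip value 0 at the wall and tangential samples
    ``t1`` at h/2 and ``t2`` at 3h/2 into the fluid,
    gamma_w = |9 t1 - t2| / (3 h), falling back to the linear two-point
    estimate where only one interior sample exists.  Then
    WSS_i = mu(gamma_w) * gamma_w per the Casson law.
    """
    dom = sol.domain
    if not dom.wall_faces:
        raise ValueError("domain has no wall faces")
    h = dom.h
    if time_indices is None:
        time_indices = np.arange(len(sol.times))
    u = sol.u[time_indices]
    v = sol.v[time_indices]
    F = dom.fluid
    nx, ny = dom.nx, dom.ny

    gammas = []
    pos = []
    on_dome = []
    for wf in dom.wall_faces:
        i, j = wf.i, wf.j
        if wf.direction in ("N", "S"):
            t1 = 0.5 * (u[:, i, j] + u[:, i + 1, j])
            j2 = j - 1 if wf.direction == "N" else j + 1
            has2 = (0 <= j2 < ny) and F[i, j2]
            t2 = 0.5 * (u[:, i, j2] + u[:, i + 1, j2]) if has2 else None
        else:
            t1 = 0.5 * (v[:, i, j] + v[:, i, j + 1])
            i2 = i - 1 if wf.direction == "E" else i + 1
            has2 = (0 <= i2 < nx) and F[i2, j]
            t2 = 0.5 * (v[:, i2, j] + v[:, i2, j + 1]) if has2 else None
        if t2 is not None:
            g = np.abs(9.0 * t1 - t2) / (3.0 * h)
        else:
            g = 2.0 * np.abs(t1) / h
        gammas.append(g)
        pos.append((wf.x, wf.y))
        on_dome.append(wf.on_dome)

    gam = np.array(gammas)  # (n_samples, n_times)
    wss = effective_viscosity(gam, params) * gam
    return WallField(
        positions=np.array(pos),
        on_dome=np.array(on_dome),
        times=sol.times[time_indices],
        wss=wss,
        period=sol.config.cycle_period,
    )


def time_averaged_wss(wall_field: WallField) -> np.ndarray:
    """Per-sample TAWSS [Pa]: (1/T) int |WSS_i| dt by the trapezoidal rule.

    The stored times must span one full cardiac cycle.
    """
    t = wall_field.times
    if t.size < 2:
        raise ValueError("need at least 2 time samples")
    span = t[-1] - t[0]
    if span < wall_field.period * (1.0 - 1e-6):
        raise ValueError(
            f"stored times span {span:.4g}s, less than one cycle ({wall_field.period:.4g}s)"
        )
    integral = np.trapezoid(np.abs(wall_field.wss), t, axis=1)
    return integral / wall_field.period


def wss_extrema(wall_field: WallField, dome_only: bool = True) -> tuple[float, float]:
    """(min, max) of instantaneous WSS over (dome) samples x cycle times."""
    w = wall_field.wss[wall_field.on_dome] if dome_only else wall_field.wss
    if w.size == 0:
        raise ValueError("no dome wall samples")
    return float(w.min()), float(w.max())


@dataclass(frozen=True)
class HemodynamicSummary:
    """Per-patient scalars: dome-averaged shear rate and viscosity at
    peak systole / end diastole, and dome-wall WSS statistics."""

    avg_shear_rate_ps: float  # 1/s
    avg_shear_rate_ed: float  # 1/s
    avg_viscosity_ps: float  # cP
    avg_viscosity_ed: float  # cP
    wss_min: float  # Pa
    wss_tavg: float  # Pa
    wss_max: float  # Pa

    def __post_init__(self):
        vals = (
            self.avg_shear_rate_ps,
            self.avg_shear_rate_ed,
            self.avg_viscosity_ps,
            self.avg_viscosity_ed,
            self.wss_min,
            self.wss_tavg,
            self.wss_max,
        )
        if any(x < 0 for x in vals):
            raise ValueError("hemodynamic summary scalars must be non-negative")

    def to_dict(self):
        return {
            "avg_shear_rate_ps_per_s": self.avg_shear_rate_ps,
            "avg_shear_rate_ed_per_s": self.avg_shear_rate_ed,
            "avg_viscosity_ps_cp": self.avg_viscosity_ps,
            "avg_viscosity_ed_cp": self.avg_viscosity_ed,
            "wss_min_pa": self.wss_min,
            "wss_tavg_pa": self.wss_tavg,
            "wss_max_pa": self.wss_max,
        }


def summarize(
    sol: FlowSolution,
    params: CassonParams,
    extrema_mode: str = "global",
) -> HemodynamicSummary:
    """Reduce a flow solution to the per-patient hemodynamic scalars.

    Shear rate and viscosity are dome-area averages at the peak-systole and
    end-diastole snapshots; TAWSS is the dome-wall average of the per-sample
    time average over the report cycle.  ``extrema_mode='global'`` takes the
    min/max WSS over dome samples x times; ``'spatial_mean'`` instead
    area-averages the per-sample temporal extrema (the alternative reading
    of a per-patient "minimal/maximal WSS").
    """
    dom = sol.domain
    out = {}
    for label, idx in (("ps", sol.ps_index), ("ed", sol.ed_index)):
        g = shear_rate_centers(dom, sol.u[idx], sol.v[idx])
        out[f"g_{label}"] = dome_average(g, dom)
        mu_cp = pa_s_to_cp(effective_viscosity(g[dom.dome], params))
        out[f"mu_{label}"] = float(np.mean(mu_cp))

    cyc = sol.cycle_indices(sol.config.report_cycle)
    wall = wall_shear_stress(sol, params, time_indices=cyc)
    tawss = time_averaged_wss(wall)
    wss_tavg = float(tawss[wall.on_dome].mean())
    if extrema_mode == "global":
        wss_min, wss_max = wss_extrema(wall, dome_only=True)
    elif extrema_mode == "spatial_mean":
        dome_wss = wall.wss[wall.on_dome]
        wss_min = float(dome_wss.min(axis=1).mean())
        wss_max = float(dome_wss.max(axis=1).mean())
    else:
        raise ValueError(f"unknown extrema_mode {extrema_mode!r}")

    return HemodynamicSummary(
        avg_shear_rate_ps=out["g_ps"],
        avg_shear_rate_ed=out["g_ed"],
        avg_viscosity_ps=out["mu_ps"],
        avg_viscosity_ed=out["mu_ed"],
        wss_min=wss_min,
        wss_tavg=wss_tavg,
        wss_max=wss_max,
    )
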