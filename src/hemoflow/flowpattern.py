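"""Qualitative flow-pattern classification of the aneurysm dome.

Two clinical axes, both evaluated on the peak-systole snapshot:

* **flow complexity** — "simple" flow has at most one recirculation zone
  in the dome, "complex" flow two or more.  A recirculation zone is a
  nest of closed streamlines around an interior extremum of the stream
  function; zones are counted as interior extrema of psi whose prominence
  exceeds a circulation threshold (default 1% of the dome's psi range),
  which suppresses numerical micro-eddies while reproducing the visual
  count;
* **inflow jet** — "concentrated" if the high-speed portion of the
  ostium inflow streams to the dome tip, "diffused" if it hugs the dome
  wall.  Operationalized by seeding streamlines at the top-decile-speed
  ostium faces, tracing them to their first dome-wall approach and
  testing whether the median impingement angle lies within a window
  (default +/-30 degrees) of the tip direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .domain import SimDomain2D
from .solver import FlowSolution


class NoInflowError(ValueError):
    """No flux through the ostium; the jet cannot be classified."""


@dataclass(frozen=True)
class FlowPatternLabel:
    """Recirculation count plus the two qualitative labels."""

    n_recirculation: int
    complexity: str  # "simple" | "complex"
    jet: str  # "diffused" | "concentrated"

    def __post_init__(self):
        expect = classify_complexity(self.n_recirculation)
        if self.complexity != expect:
            raise ValueError(f"complexity {self.complexity!r} inconsistent with n={self.n_recirculation}")

    def to_dict(self):
        return {"n_recirculation": self.n_recirculation, "complexity": self.complexity, "jet": self.jet}


def classify_complexity(n_recirculation: int) -> str:
    """Complex iff two or more recirculation zones (0 or 1 -> simple)."""
    if n_recirculation < 0:
        raise ValueError("recirculation count must be >= 0")
    return "complex" if n_recirculation >= 2 else "simple"


def stream_function(dom: SimDomain2D, u: np.ndarray, v: np.ndarray, div_tol: float = 1e-3) -> np.ndarray:
    """Stream function psi at grid nodes, with u = dpsi/dy, v = -dpsi/dx.

    Built by line integration of the face fluxes from the bottom-left
    corner; path independence requires the discrete field to be
    divergence-free, which is checked against ``div_tol`` (relative to the
    maximum speed).  psi is constant along each connected wall.
    """
    h = dom.h
    div = (u[1:, :] - u[:-1, :] + v[:, 1:] - v[:, :-1]) / h
    speed = max(np.max(np.abs(u)), np.max(np.abs(v)), 1e-300)
    rel = np.max(np.abs(div[dom.fluid])) * h / speed if dom.fluid.any() else 0.0
    if rel > div_tol:
        raise ValueError(f"velocity field is not divergence-free (relative residual {rel:.3g})")
    psi = np.zeros((dom.nx + 1, dom.ny + 1))
    psi[:, 0] = -np.concatenate([[0.0], np.cumsum(v[:, 0]) * h])  # bottom row (v=0 on the wall)
    psi[:, 1:] = psi[:, [0]] + np.cumsum(u * h, axis=1)
    return psi


def _dome_node_mask(dom: SimDomain2D) -> np.ndarray:
    mask = np.zeros((dom.nx + 1, dom.ny + 1), dtype=bool)
    for di in (0, 1):
        for dj in (0, 1):
            mask[di : dom.nx + di, dj : dom.ny + dj] |= dom.dome
    return mask


def count_recirculation_zones(
    psi: np.ndarray, dom: SimDomain2D, circulation_threshold: float = 0.01
) -> int:
    """Count thresholded interior stream-function extrema in the dome.

    A recirculation zone is a nest of closed psi level sets around an
    interior extremum.  Each extremum is scored by its *closed-level-set
    depth*: the drop from the extremum to the level at which its
    surrounding level set first reaches the dome-region boundary (wall or
    ostium line) or merges into a stronger zone — beyond that level the
    streamlines are no longer closed inside the dome.  Extrema with depth
    at least ``circulation_threshold`` times the dome's psi range are
    counted (maxima and minima; the two rotation senses).  Deterministic;
    raising the threshold never increases the count.
    """
    if circulation_threshold < 0:
        raise ValueError("circulation_threshold must be >= 0")
    mask = _dome_node_mask(dom)
    if not mask.any():
        raise ValueError("domain has an empty dome region")
    vals = psi[mask]
    rng = float(vals.max() - vals.min())
    if rng == 0.0:
        return 0
    hthr = max(circulation_threshold * rng, 1e-12 * rng)

    edge = mask & ~(
        np.roll(mask, 1, 0) & np.roll(mask, -1, 0) & np.roll(mask, 1, 1) & np.roll(mask, -1, 1)
    )
    count = 0
    for sign in (1.0, -1.0):
        count += _count_persistent_extrema(sign * psi, mask, edge, hthr)
    return count


def _count_persistent_extrema(field, mask, edge, depth_threshold):
    """Maxima of ``field`` on ``mask`` whose superlevel component stays
    edge-free over a depth of at least ``depth_threshold`` (union-find
    flood in decreasing order; the elder rule resolves merges)."""
    idx = np.flatnonzero(mask.ravel())
    vals = field.ravel()[idx]
    ny1 = mask.shape[1]
    node_of = -np.ones(mask.size, dtype=np.int64)
    node_of[idx] = np.arange(idx.size)
    order = np.argsort(-vals, kind="stable")
    on_edge = edge.ravel()[idx]

    parent = np.arange(idx.size)
    birth = np.full(idx.size, -np.inf)
    comp_edge = np.zeros(idx.size, dtype=bool)
    alive = np.zeros(idx.size, dtype=bool)
    active = np.zeros(idx.size, dtype=bool)
    count = 0

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for n in order:
        v = vals[n]
        active[n] = True
        birth[n] = v
        alive[n] = True
        if on_edge[n]:
            comp_edge[n] = True
            alive[n] = False  # born on the boundary: never a closed zone
        flat = idx[n]
        col = flat % ny1
        for off in (-1, 1, -ny1, ny1):
            if off == -1 and col == 0:
                continue
            if off == 1 and col == ny1 - 1:
                continue
            nb = flat + off
            m = node_of[nb] if 0 <= nb < mask.size else -1
            if m < 0 or not active[m]:
                continue
            ra, rb = find(n), find(m)
            if ra == rb:
                continue
            # elder rule: the higher-born root survives
            if birth[ra] < birth[rb]:
                ra, rb = rb, ra
            # rb (younger) merges into ra at level v
            if alive[rb]:
                # the younger zone's closed level sets end here
                if birth[rb] - v >= depth_threshold:
                    count += 1
                alive[rb] = False
            if comp_edge[rb] and alive[ra]:
                # the elder zone reaches the boundary through this merge
                if birth[ra] - v >= depth_threshold:
                    count += 1
                alive[ra] = False
            parent[rb] = ra
            comp_edge[ra] = comp_edge[ra] or comp_edge[rb]
        # a live component can also touch the edge by absorbing an edge node
        r = find(n)
        if on_edge[n] and alive[r]:
            if birth[r] - v >= depth_threshold:
                count += 1
            alive[r] = False
        if on_edge[n]:
            comp_edge[r] = True

    # components that never reached the boundary die at the global minimum
    seen = set()
    vmin = vals.min()
    for n in range(idx.size):
        r = find(n)
        if r not in seen:
            seen.add(r)
            if alive[r] and birth[r] - vmin >= depth_threshold:
                count += 1
    return count


def _velocity_interpolators(dom: SimDomain2D, u: np.ndarray, v: np.ndarray):
    h = dom.h
    xu = np.arange(dom.nx + 1) * h
    yu = (np.arange(dom.ny) + 0.5) * h
    xv = (np.arange(dom.nx) + 0.5) * h
    yv = np.arange(dom.ny + 1) * h
    fu = RegularGridInterpolator((xu, yu), u, bounds_error=False, fill_value=0.0)
    fv = RegularGridInterpolator((xv, yv), v, bounds_error=False, fill_value=0.0)
    return fu, fv


def classify_inflow_jet(
    sol_or_uv,
    dom: SimDomain2D | None = None,
    time_index: int | None = None,
    angle_window_deg: float = 30.0,
    speed_decile: float = 0.9,
    max_steps: int = 4000,
) -> str:
    """Classify the ostium inflow jet as 'concentrated' or 'diffused'.

    Accepts a :class:`FlowSolution` (peak-systole snapshot by default) or a
    ``(u, v)`` pair with an explicit domain.  Streamlines are seeded at the
    ostium faces whose entering speed is in the top decile, traced by RK4,
    and scored by the angular position of their first close approach to the
    dome wall relative to the tip direction (the neck normal through the
    dome apex).
    """
    if isinstance(sol_or_uv, FlowSolution):
        sol = sol_or_uv
        dom = sol.domain
        idx = sol.ps_index if time_index is None else time_index
        u, v = sol.u[idx], sol.v[idx]
    else:
        u, v = sol_or_uv
        if dom is None:
            raise ValueError("domain required when passing raw fields")
    if dom.ostium_faces is None or dom.ostium_faces.size == 0:
        raise NoInflowError("domain has no ostium")
    h = dom.h
    jw = dom.channel_cells
    v_ostium = v[dom.ostium_faces, jw]
    inflow = v_ostium > 0
    if not np.any(inflow) or v_ostium[inflow].sum() * h <= 1e-300:
        raise NoInflowError("no flux entering the dome through the ostium")

    speeds = v_ostium[inflow]
    cols = dom.ostium_faces[inflow]
    thr = np.quantile(speeds, speed_decile)
    seeds = cols[speeds >= thr]

    fu, fv = _velocity_interpolators(dom, u, v)
    cx, cy = dom.dome_center
    R = dom.dome_radius_m
    wall_y = dom.channel_height
    step = 0.5 * h
    angles = []
    for i in seeds:
        pt = np.array([(i + 0.5) * h, jw * h + 0.25 * h])
        for _ in range(max_steps):
            r = np.hypot(pt[0] - cx, pt[1] - cy)
            if pt[1] > wall_y and r >= R - 1.5 * h:
                ang = np.degrees(np.arctan2(pt[0] - cx, pt[1] - cy))
                angles.append(ang)
                break
            if pt[1] < wall_y - 2 * h:  # returned to the parent vessel
                break
            vel = _rk4_velocity(fu, fv, pt, step)
            sp = np.linalg.norm(vel)
            if sp < 1e-12:
                break
            pt = pt + step * vel / sp
    if not angles:
        return "diffused"
    return "concentrated" if abs(float(np.median(angles))) <= angle_window_deg else "diffused"


def _rk4_velocity(fu, fv, pt, step):
    def f(q):
        vel = np.array([fu(q).item(), fv(q).item()])
        n = np.linalg.norm(vel)
        return vel / n if n > 1e-14 else vel

    k1 = f(pt)
    k2 = f(pt + 0.5 * step * k1)
    k3 = f(pt + 0.5 * step * k2)
    k4 = f(pt + step * k3)
    return (k1 + 2 * k2 + 2 * k3 + k4) / 6.0


def classify_flow_pattern(
    sol: FlowSolution, circulation_threshold: float = 0.01, angle_window_deg: float = 30.0
) -> FlowPatternLabel:
    """Full pattern label from the peak-systole snapshot of a solution."""
    dom = sol.domain
    u, v = sol.u[sol.ps_index], sol.v[sol.ps_index]
    psi = stream_function(dom, u, v)
    n = count_recirculation_zones(psi, dom, circulation_threshold)
    jet = classify_inflow_jet(sol, angle_window_deg=angle_window_deg)
    return FlowPatternLabel(n_recirculation=n, complexity=classify_complexity(n), jet=jet)
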