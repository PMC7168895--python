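"""Legacy ASCII VTK export of stored flow fields for visual inspection.

Writes STRUCTURED_POINTS files with cell data (fluid/dome masks, pressure,
cell-centred velocity, shear rate, apparent viscosity), one file per
stored snapshot.  The legacy text format is deliberately simple and opens
in ParaView/VisIt.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .hemodynamics import shear_rate_centers
from .rheology import CassonParams, effective_viscosity
from .solver import FlowSolution


def _write_scalars(fh, name, data):
    fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
    np.savetxt(fh, data.T.reshape(-1)[None].T, fmt="%.6e")


def export_vtk(sol: FlowSolution, params: CassonParams, out_dir, time_indices=None, prefix="flow") -> list:
    """Export snapshots as ``<prefix>_<k>.vtk``; returns the written paths."""
    dom = sol.domain
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if time_indices is None:
        time_indices = range(len(sol.times))
    h = dom.h
    written = []
    for k in time_indices:
        u, v, p = sol.u[k], sol.v[k], sol.p[k]
        uc = 0.5 * (u[1:, :] + u[:-1, :])
        vc = 0.5 * (v[:, 1:] + v[:, :-1])
        g = shear_rate_centers(dom, u, v)
        mu = np.zeros_like(g)
        mu[dom.fluid] = effective_viscosity(g[dom.fluid], params)
        path = out / f"{prefix}_{k:04d}.vtk"
        with open(path, "w") as fh:
            fh.write("# vtk DataFile Version 3.0\n")
            fh.write(f"hemoflow snapshot t={sol.times[k]:.6f}s\nASCII\n")
            fh.write("DATASET STRUCTURED_POINTS\n")
            fh.write(f"DIMENSIONS {dom.nx + 1} {dom.ny + 1} 1\n")
            fh.write("ORIGIN 0 0 0\n")
            fh.write(f"SPACING {h:.9e} {h:.9e} {h:.9e}\n")
            fh.write(f"CELL_DATA {dom.nx * dom.ny}\n")
            _write_scalars(fh, "fluid", dom.fluid.astype(float))
            _write_scalars(fh, "dome", dom.dome.astype(float))
            _write_scalars(fh, "pressure", p)
            _write_scalars(fh, "velocity_x", uc)
            _write_scalars(fh, "velocity_y", vc)
            _write_scalars(fh, "shear_rate", g)
            _write_scalars(fh, "viscosity", mu)
        written.append(path)
    return written
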