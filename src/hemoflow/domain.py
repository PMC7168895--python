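"""2D simulation domain: parent-vessel channel with a dome opening.

The desk-scale analog of the patient-specific 3D lumen is the mid-plane of
the aneurysm: a straight channel (width = parent-artery diameter, length 10
diameters) with a circular-segment dome communicating with the channel
through a neck gap in the upper wall.  The domain is discretized on a
uniform Cartesian marker-and-cell (MAC) grid with cells flagged fluid or
solid; curved dome walls are staircase-approximated.  All solver-facing
quantities are in SI metres.

Cell-centred fields live on an ``(nx, ny)`` array; horizontal velocity u on
x-faces ``(nx+1, ny)``; vertical velocity v on y-faces ``(nx, ny+1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import ShapeParams, analytic_segment_area

MM = 1e-3


class GeometryError(ValueError):
    """Domain construction impossible for the requested shape."""


@dataclass(frozen=True)
class WallFace:
    """One solid wall face of a fluid cell: (i, j) cell index, outward
    normal direction ('N','S','E','W'), dome flag, and midpoint (m)."""

    i: int
    j: int
    direction: str
    on_dome: bool
    x: float
    y: float


@dataclass
class SimDomain2D:
    """Masked MAC grid for the channel-plus-dome domain (SI units)."""

    h: float  # grid spacing, m
    nx: int
    ny: int
    channel_height: float  # m
    channel_cells: int  # rows of channel
    length: float  # m
    fluid: np.ndarray = field(repr=False)  # (nx, ny) bool
    dome: np.ndarray = field(repr=False)  # (nx, ny) bool, subset of fluid
    shape: ShapeParams | None = None
    dome_center: tuple[float, float] | None = None  # circle centre, m
    dome_radius_m: float = 0.0
    tip_point: tuple[float, float] | None = None  # dome apex, m
    ostium_faces: np.ndarray = field(default=None, repr=False)  # i-indices of open v-faces at the wall row
    wall_faces: list = field(default_factory=list, repr=False)

    # -- derived helpers -------------------------------------------------
    @property
    def inlet_rows(self) -> np.ndarray:
        """j-indices of fluid cells on the inlet column."""
        return np.nonzero(self.fluid[0])[0]

    @property
    def outlet_rows(self) -> np.ndarray:
        return np.nonzero(self.fluid[-1])[0]

    @property
    def dome_area(self) -> float:
        """Tagged dome area (2D 'dome volume'), m^2."""
        return float(self.dome.sum()) * self.h**2

    def cell_centers(self):
        x = (np.arange(self.nx) + 0.5) * self.h
        y = (np.arange(self.ny) + 0.5) * self.h
        return x, y

    def face_y(self):
        """y of u-face centres (cell-row centres)."""
        return (np.arange(self.ny) + 0.5) * self.h


def build_2d_domain(shape: ShapeParams | None, mesh_size: float = 0.2) -> SimDomain2D:
    """Build the masked-grid domain for ``shape`` at target spacing
    ``mesh_size`` (mm).

    The grid spacing is snapped so the channel width is an integer number of
    cells (the inlet boundary length then equals the parent diameter
    exactly).  ``shape=None`` or ``dome_radius=0`` gives a plain channel.
    """
    if mesh_size <= 0:
        raise ValueError("mesh_size must be > 0")
    if shape is None:
        shape = ShapeParams(dome_radius=0.0)
    d = shape.parent_diameter * MM
    n_chan = max(4, round(d / (mesh_size * MM)))
    h = d / n_chan
    length = 10.0 * d
    nx = int(round(length / h))
    length = nx * h

    has_dome = shape.dome_radius > 0
    if has_dome:
        R = shape.dome_radius * MM
        dome_h = shape.height * MM
        O = shape.ostium_diameter * MM
        x_neck = (shape.neck_position * MM) if shape.neck_position is not None else length / 2.0
        margin = 2.0 * d
        if x_neck - O / 2 < margin or x_neck + O / 2 > length - margin:
            raise GeometryError("neck gap does not fit the channel with a 2-diameter margin")
        delta = dome_h - R  # circle-centre height above the channel top wall
        cy = d + delta
        n_dome_rows = int(np.ceil(dome_h / h)) + 1
    else:
        n_dome_rows = 0
        cy = x_neck = R = 0.0

    ny = n_chan + n_dome_rows
    xc = (np.arange(nx) + 0.5) * h
    yc = (np.arange(ny) + 0.5) * h
    X, Y = np.meshgrid(xc, yc, indexing="ij")

    fluid = Y < d
    dome = np.zeros_like(fluid)
    if has_dome:
        inside = (X - x_neck) ** 2 + (Y - cy) ** 2 < R**2
        dome = inside & (Y > d)
        fluid = fluid | dome
        if dome.sum() == 0:
            raise GeometryError("mesh_size too coarse to resolve the dome")

    dom = SimDomain2D(
        h=h,
        nx=nx,
        ny=ny,
        channel_height=d,
        channel_cells=n_chan,
        length=length,
        fluid=fluid,
        dome=dome,
        shape=shape,
        dome_center=(x_neck, cy) if has_dome else None,
        dome_radius_m=R if has_dome else 0.0,
        tip_point=(x_neck, d + (dome_h if has_dome else 0.0)) if has_dome else None,
    )
    _tag_boundaries(dom)
    return dom


def _tag_boundaries(dom: SimDomain2D) -> None:
    """Find ostium faces and wall faces of the masked grid."""
    F = dom.fluid
    nx, ny, h = dom.nx, dom.ny, dom.h
    jw = dom.channel_cells  # index of the first row above the channel

    if dom.dome.any() and jw < ny:
        dom.ostium_faces = np.nonzero(F[:, jw - 1] & dom.dome[:, jw])[0]
    else:
        dom.ostium_faces = np.array([], dtype=int)

    walls = []
    solid = ~F
    for (di, dj, name) in ((1, 0, "E"), (-1, 0, "W"), (0, 1, "N"), (0, -1, "S")):
        for i in range(nx):
            ii = i + di
            skip_x = (ii < 0) or (ii >= nx)
            for j in np.nonzero(F[i])[0]:
                jj = j + dj
                if dj != 0:
                    if 0 <= jj < ny:
                        is_solid = solid[i, jj]
                    else:
                        is_solid = True  # top/bottom of grid are walls
                    if not is_solid:
                        continue
                else:
                    if skip_x:
                        continue  # inlet/outlet, not walls
                    if not solid[ii, j]:
                        continue
                x = (i + 0.5) * h + (di * 0.5 * h)
                y = (j + 0.5) * h + (dj * 0.5 * h)
                walls.append(WallFace(i=i, j=j, direction=name, on_dome=bool(dom.dome[i, j]), x=x, y=y))
    dom.wall_faces = walls


def analytic_dome_area(shape: ShapeParams) -> float:
    """Closed-form circular-segment dome area in m^2 for a cap shape."""
    R = shape.dome_radius * MM
    delta = (shape.height - shape.dome_radius) * MM  # centre height above the wall
    return analytic_segment_area(R, delta)
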