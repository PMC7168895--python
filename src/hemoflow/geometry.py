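"""Saccular aneurysm surface geometry and morphometrics.

A saccular (berry) aneurysm is modelled as a spherical cap: a sphere of
radius ``dome_radius`` cut by the neck (ostium) plane at signed offset
``neck_offset`` from the sphere centre.  ``neck_offset < 0`` gives a
supra-hemispherical dome (equator wider than the neck), ``neck_offset = 0``
a hemisphere, ``neck_offset > 0`` a shallow blister.

The five morphological variables measured on triangulated domes are the
clinical standards:

* height ``H`` — maximum distance from the neck plane to the dome tip,
  measured along the neck-plane normal;
* width ``W`` — longest dome diameter orthogonal to the height axis;
* ostium diameter ``O`` — maximum diameter of the neck cross-section;
* ostium cross-sectional area;
* dome surface area.

Aneurysms are classed small/large at a height cutoff (default 5 mm,
``height <= cutoff`` is small).  All lengths are millimetres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist

SIZE_CUTOFF_MM = 5.0


class ResolutionError(ValueError):
    """Mesh resolution too coarse to resolve the requested feature."""


class TopologyError(ValueError):
    """Surface mesh has invalid (non-manifold) topology."""


@dataclass(frozen=True)
class SurfaceMesh:
    """Triangulated surface, vertices in mm."""

    vertices: np.ndarray = field(repr=False)  # (n, 3) float
    triangles: np.ndarray = field(repr=False)  # (m, 3) int

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        t = np.asarray(self.triangles, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if t.ndim != 2 or t.shape[1] != 3:
            raise ValueError("triangles must be (m, 3)")
        if t.size and (t.min() < 0 or t.max() >= len(v)):
            raise ValueError("triangle indices out of range")
        areas = _triangle_areas(v, t)
        if t.size and areas.min() <= 1e-12:
            raise ValueError("mesh contains degenerate (zero-area) triangles")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "triangles", t)

    @property
    def area(self) -> float:
        """Total surface area, mm^2."""
        return float(_triangle_areas(self.vertices, self.triangles).sum())

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "SurfaceMesh":
        return SurfaceMesh(self.vertices @ np.asarray(rotation).T + np.asarray(translation), self.triangles)


@dataclass(frozen=True)
class NeckPlane:
    """Ostium plane: a point on the plane and the unit normal into the dome."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.point, dtype=float).reshape(3)
        n = np.asarray(self.normal, dtype=float).reshape(3)
        norm = np.linalg.norm(n)
        if not np.isfinite(norm) or norm == 0:
            raise ValueError("neck normal must be non-zero")
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "normal", n / norm)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Signed distance of points to the plane; positive on the dome side."""
        return (np.atleast_2d(points) - self.point) @ self.normal

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "NeckPlane":
        R = np.asarray(rotation)
        return NeckPlane(R @ self.point + np.asarray(translation), R @ self.normal)

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump({"point": self.point.tolist(), "normal": self.normal.tolist()}, fh)

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            d = json.load(fh)
        return cls(point=d["point"], normal=d["normal"])


@dataclass(frozen=True)
class ShapeParams:
    """Spherical-cap dome parameterization (mm).

    ``dome_radius`` is the sphere radius; ``neck_offset`` the signed distance
    of the neck plane from the sphere centre (negative = dome taller than a
    hemisphere).  ``parent_diameter`` is the parent-artery calibre and
    ``neck_position`` the dome location along the parent vessel (``None`` =
    mid-vessel).  ``dome_radius = 0`` denotes the degenerate no-dome case
    (plain parent vessel).
    """

    dome_radius: float
    neck_offset: float = 0.0
    parent_diameter: float = 4.0
    neck_position: float | None = None

    def __post_init__(self):
        if self.dome_radius < 0:
            raise ValueError("dome_radius must be >= 0")
        if self.dome_radius > 0 and abs(self.neck_offset) >= self.dome_radius:
            raise ValueError("|neck_offset| must be < dome_radius")
        if self.parent_diameter <= 0:
            raise ValueError("parent_diameter must be > 0")

    @property
    def height(self) -> float:
        """Analytic cap height H = R - c, mm."""
        return self.dome_radius - self.neck_offset

    @property
    def ostium_diameter(self) -> float:
        """Analytic ostium diameter O = 2 sqrt(R^2 - c^2), mm."""
        if self.dome_radius == 0:
            return 0.0
        return 2.0 * np.sqrt(self.dome_radius**2 - self.neck_offset**2)

    @property
    def width(self) -> float:
        """Analytic cap width: the equator if included, else the ostium."""
        if self.neck_offset < 0:
            return 2.0 * self.dome_radius
        return self.ostium_diameter

    @classmethod
    def from_height_and_ostium(cls, height: float, ostium_diameter: float, **kw) -> "ShapeParams":
        """Invert the cap family from (H, O): R = (H + O^2/(4H)) / 2."""
        if height <= 0 or ostium_diameter <= 0:
            raise ValueError("height and ostium diameter must be positive")
        r = 0.5 * (height + ostium_diameter**2 / (4.0 * height))
        return cls(dome_radius=r, neck_offset=r - height, **kw)

    def to_dict(self):
        return {
            "dome_radius_mm": self.dome_radius,
            "neck_offset_mm": self.neck_offset,
            "parent_diameter_mm": self.parent_diameter,
            "neck_position_mm": self.neck_position,
        }

    @classmethod
    def from_dict(cls, d):
        return cls(
            dome_radius=d["dome_radius_mm"],
            neck_offset=d.get("neck_offset_mm", 0.0),
            parent_diameter=d.get("parent_diameter_mm", 4.0),
            neck_position=d.get("neck_position_mm"),
        )


@dataclass(frozen=True)
class Morphometrics:
    """The five morphological variables plus the size class."""

    height: float  # mm
    width: float  # mm
    ostium_diameter: float  # mm
    ostium_area: float  # mm^2
    surface_area: float  # mm^2
    size_class: str  # "small" | "large"

    def to_dict(self):
        return {
            "height_mm": self.height,
            "width_mm": self.width,
            "ostium_diameter_mm": self.ostium_diameter,
            "ostium_area_mm2": self.ostium_area,
            "surface_area_mm2": self.surface_area,
            "size_class": self.size_class,
        }


def classify_size(height: float, cutoff: float = SIZE_CUTOFF_MM) -> str:
    """Small/large size class at the height cutoff; ``height <= cutoff`` is small."""
    if height <= 0:
        raise ValueError("height must be positive")
    return "small" if height <= cutoff else "large"


def _triangle_areas(vertices, triangles):
    v = vertices[triangles]
    return 0.5 * np.linalg.norm(np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1)


def make_dome_mesh(shape: ShapeParams, resolution: float = 0.3) -> tuple[SurfaceMesh, NeckPlane]:
    """Triangulate the spherical-cap dome of ``shape``.

    The cap is built in a canonical frame: sphere centred at the origin,
    neck plane ``z = neck_offset``, tip at ``(0, 0, R)``, inward neck normal
    ``+z``.  ``resolution`` is the target edge length in mm.  The boundary
    ring lies exactly on the neck plane.
    """
    R, c = shape.dome_radius, shape.neck_offset
    if R <= 0:
        raise ValueError("cannot mesh a zero-radius dome")
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    theta_max = float(np.arccos(np.clip(c / R, -1.0, 1.0)))
    r_max = R * (1.0 if theta_max >= np.pi / 2 else np.sin(theta_max))
    n_phi = int(np.ceil(2.0 * np.pi * r_max / resolution))
    if n_phi < 8:
        raise ResolutionError(
            f"resolution {resolution} mm gives only {n_phi} boundary vertices (need >= 8)"
        )
    n_theta = max(2, int(np.ceil(R * theta_max / resolution)))

    verts = [np.array([0.0, 0.0, R])]  # apex
    rings = []
    for i in range(1, n_theta + 1):
        th = theta_max * i / n_theta
        ring = np.arange(len(verts), len(verts) + n_phi)
        phi = 2.0 * np.pi * np.arange(n_phi) / n_phi
        verts.extend(
            np.column_stack(
                [R * np.sin(th) * np.cos(phi), R * np.sin(th) * np.sin(phi), np.full(n_phi, R * np.cos(th))]
            )
        )
        rings.append(ring)
    verts = np.vstack(verts)

    tris = []
    first = rings[0]
    for a in range(n_phi):  # apex fan
        tris.append([0, first[a], first[(a + 1) % n_phi]])
    for upper, lower in zip(rings[:-1], rings[1:]):
        for a in range(n_phi):
            b = (a + 1) % n_phi
            tris.append([upper[a], lower[a], lower[b]])
            tris.append([upper[a], lower[b], upper[b]])
    mesh = SurfaceMesh(verts, np.array(tris))
    neck = NeckPlane(point=[0.0, 0.0, c], normal=[0.0, 0.0, 1.0])
    return mesh, neck


def _boundary_loop(mesh: SurfaceMesh) -> np.ndarray:
    """Vertex indices on the open boundary; error on non-manifold edges."""
    edges = np.vstack(
        [mesh.triangles[:, [0, 1]], mesh.triangles[:, [1, 2]], mesh.triangles[:, [2, 0]]]
    )
    edges = np.sort(edges, axis=1)
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    if np.any(counts > 2):
        raise TopologyError("non-manifold edge (shared by more than two triangles)")
    boundary_edges = uniq[counts == 1]
    if len(boundary_edges) == 0:
        raise TopologyError("mesh has no boundary loop (closed surface?)")
    return np.unique(boundary_edges)


def measure_morphometrics(mesh: SurfaceMesh, neck: NeckPlane, cutoff: float = SIZE_CUTOFF_MM) -> Morphometrics:
    """Measure H, W, O, ostium area and surface area on a dome mesh.

    Height is the maximum signed vertex distance to the neck plane along its
    normal; width the maximum pairwise distance among dome vertices after
    projection onto the neck plane; the ostium diameter the maximum pairwise
    distance among boundary-loop vertices; the ostium area the shoelace area
    of the boundary polygon ordered angularly about its in-plane centroid.
    """
    d = neck.signed_distance(mesh.vertices)
    tol = 1e-9
    if not np.any(d > tol):
        raise ValueError("no vertices on the dome side of the neck plane")
    height = float(d.max())

    # in-plane orthonormal basis
    n = neck.normal
    a = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(n, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)

    dome = mesh.vertices[d > tol]
    proj = np.column_stack([(dome - neck.point) @ e1, (dome - neck.point) @ e2])
    width = _max_pairwise(proj)

    loop = _boundary_loop(mesh)
    lv = mesh.vertices[loop]
    lp = np.column_stack([(lv - neck.point) @ e1, (lv - neck.point) @ e2])
    ostium_diameter = _max_pairwise(lp)

    centroid = lp.mean(axis=0)
    order = np.argsort(np.arctan2(lp[:, 1] - centroid[1], lp[:, 0] - centroid[0]))
    poly = lp[order]
    x, y = poly[:, 0], poly[:, 1]
    ostium_area = float(0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))

    return Morphometrics(
        height=height,
        width=width,
        ostium_diameter=ostium_diameter,
        ostium_area=ostium_area,
        surface_area=mesh.area,
        size_class=classify_size(height, cutoff),
    )


def _max_pairwise(points2d: np.ndarray) -> float:
    """Largest pairwise distance; via the convex hull when it helps."""
    pts = points2d
    if len(pts) > 16:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:  # collinear points etc.
            pass
    if len(pts) < 2:
        return 0.0
    return float(pdist(pts).max())


def save_stl(mesh: SurfaceMesh, path) -> None:
    """Write the mesh as ASCII STL (mm units)."""
    import trimesh

    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.triangles, process=False)
    tm.export(path, file_type="stl_ascii")


def load_stl(path) -> SurfaceMesh:
    """Read an STL (binary or ASCII) as a SurfaceMesh in mm."""
    import trimesh

    tm = trimesh.load_mesh(path, process=False)
    return SurfaceMesh(np.asarray(tm.vertices, dtype=float), np.asarray(tm.faces, dtype=np.int64))


def analytic_cap_area(radius: float, height: float) -> float:
    """Lateral surface area of a spherical cap: 2 pi R H."""
    return 2.0 * np.pi * radius * height


def analytic_segment_area(radius: float, center_offset: float) -> float:
    """Area of the part of a disc of ``radius`` lying above a line at signed
    distance ``-center_offset`` below the centre (2D circular segment).

    ``center_offset`` is the height of the circle centre above the cutting
    line; +R gives the full disc, -R gives zero.
    """
    d = np.clip(center_offset / radius, -1.0, 1.0)
    return float(radius**2 * np.arccos(-d) + center_offset * np.sqrt(max(radius**2 - center_offset**2, 0.0)))
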