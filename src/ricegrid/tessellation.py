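"""Per-cluster occupied area via the Delaunay-circumcenter Voronoi construction.

Each cluster's "occupied region" is its Voronoi cell, built explicitly from
the Delaunay triangulation: the cell of a site is the polygon whose vertices
are the circumcenters of the Delaunay triangles incident to that site,
ordered angularly around it.  For sites strictly interior to the convex hull
this ring is closed, convex, and contains the site; hull sites have open
(unbounded) cells and are excluded from all area statistics.

Area statistics additionally require the cell to lie within the convex hull
of the sites (``interior`` flag): a bounded cell of a site just inside the
hull legitimately extends far outside the planted region (there are no
neighbours beyond it to close it off), and such edge cells would swamp the
CV index with window artefacts.  This is the minus-sampling edge correction
of spatial statistics; under it a completely random layout recovers the
classical Poisson-Voronoi cell-area CV of ~0.53 while a perfect lattice
keeps all its interior cells.

The construction satisfies the four classical Voronoi criteria: uniqueness
(one cell per site), mutual exclusion (disjoint interiors), full coverage,
and space sharing (the shared edge of two neighbouring cells passes through
the midpoint of the segment joining their sites).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull as _ConvexHull
from scipy.spatial import Delaunay as _SciPyDelaunay

from .errors import DegenerateGeometryError, InvalidInputError

__all__ = [
    "PointSet",
    "Triangulation",
    "VoronoiCell",
    "Tessellation",
    "delaunay",
    "circumcenter",
    "build_cell",
    "polygon_area",
    "tessellate",
]

#: Coincident circumcenters (co-circular point quadruples, e.g. exact
#: lattices) are merged when closer than this times the point-cloud scale.
MERGE_TOL = 1e-9


@dataclass(frozen=True)
class PointSet:
    """Planar site coordinates with their unit of measure ("px" or "cm")."""

    points: np.ndarray
    units: str = "cm"

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class Triangulation:
    """Delaunay triangulation: vertex-index triples plus neighbour relation."""

    points: np.ndarray
    triangles: np.ndarray  # (m, 3) vertex indices
    neighbors: np.ndarray  # (m, 3) triangle adjacency, -1 on the hull
    hull_vertices: np.ndarray  # indices of sites on the convex hull


def _as_points(points) -> np.ndarray:
    if isinstance(points, PointSet):
        points = points.points
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InvalidInputError("expected an (n, 2) array of planar points")
    return pts


def delaunay(points) -> Triangulation:
    """Delaunay triangulation of the sites (empty-circumcircle property)."""
    pts = _as_points(points)
    if len(pts) < 3:
        raise DegenerateGeometryError("triangulation needs at least 3 points")
    if len(np.unique(pts, axis=0)) != len(pts):
        raise InvalidInputError("duplicate points are not allowed")
    # collinearity check: rank of the centred coordinates
    centred = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centred, tol=1e-12 * max(1.0, np.abs(centred).max())) < 2:
        raise DegenerateGeometryError("all points are collinear")
    tri = _SciPyDelaunay(pts)
    return Triangulation(
        points=pts,
        triangles=tri.simplices,
        neighbors=tri.neighbors,
        hull_vertices=np.unique(tri.convex_hull),
    )


def circumcenter(p1, p2, p3) -> np.ndarray:
    """Center of the circle through three non-collinear points."""
    ax, ay = map(float, p1)
    bx, by = map(float, p2)
    cx, cy = map(float, p3)
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if d == 0.0:
        raise DegenerateGeometryError("collinear triple has no circumcenter")
    a2, b2, c2 = ax * ax + ay * ay, bx * bx + by * by, cx * cx + cy * cy
    ux = (a2 * (by - cy) + b2 * (cy - ay) + c2 * (ay - by)) / d
    uy = (a2 * (cx - bx) + b2 * (ax - cx) + c2 * (bx - ax)) / d
    return np.array([ux, uy])


def _circumcenters(pts: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Vectorised circumcenters of every triangle."""
    a, b, c = pts[triangles[:, 0]], pts[triangles[:, 1]], pts[triangles[:, 2]]
    d = 2.0 * (
        a[:, 0] * (b[:, 1] - c[:, 1])
        + b[:, 0] * (c[:, 1] - a[:, 1])
        + c[:, 0] * (a[:, 1] - b[:, 1])
    )
    if np.any(d == 0.0):
        raise DegenerateGeometryError("degenerate (collinear) Delaunay triangle")
    a2 = (a * a).sum(axis=1)
    b2 = (b * b).sum(axis=1)
    c2 = (c * c).sum(axis=1)
    ux = (a2 * (b[:, 1] - c[:, 1]) + b2 * (c[:, 1] - a[:, 1]) + c2 * (a[:, 1] - b[:, 1])) / d
    uy = (a2 * (c[:, 0] - b[:, 0]) + b2 * (a[:, 0] - c[:, 0]) + c2 * (b[:, 0] - a[:, 0])) / d
    return np.column_stack([ux, uy])


@dataclass(frozen=True)
class VoronoiCell:
    """One site's occupied polygon.

    ``vertices`` is the angularly ordered ring of circumcenters (clockwise in
    image coordinates).  ``area`` is defined only for bounded cells; hull
    sites are flagged ``bounded=False``.  ``interior`` marks bounded cells
    wholly contained in the sites' convex hull — only those enter area
    statistics (minus-sampling edge correction).
    """

    site_index: int
    vertices: np.ndarray
    bounded: bool
    area: float | None
    interior: bool = False


@dataclass(frozen=True)
class Tessellation:
    """All cells of one point set, one per site."""

    points: np.ndarray
    cells: tuple[VoronoiCell, ...]
    units: str = "cm"

    @property
    def n_bounded(self) -> int:
        return sum(c.bounded for c in self.cells)

    @property
    def n_interior(self) -> int:
        return sum(c.interior for c in self.cells)

    def bounded_areas(self) -> np.ndarray:
        """Areas of every closed cell, including edge cells."""
        return np.array([c.area for c in self.cells if c.bounded], dtype=float)

    def interior_areas(self) -> np.ndarray:
        """Areas entering the heterogeneity index (edge-corrected)."""
        return np.array([c.area for c in self.cells if c.interior], dtype=float)


def polygon_area(ring) -> float:
    """Shoelace area of a simple ring; orientation-invariant (absolute value)."""
    ring = np.asarray(ring, dtype=float)
    if ring.ndim != 2 or len(ring) < 3:
        raise InvalidInputError("a polygon needs at least 3 vertices")
    x, y = ring[:, 0], ring[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def _ordered_ring(site: np.ndarray, centers: np.ndarray, scale: float) -> np.ndarray:
    """Sort circumcenters clockwise about the site and merge near-duplicates."""
    ang = np.arctan2(centers[:, 1] - site[1], centers[:, 0] - site[0])
    order = np.argsort(-ang, kind="stable")  # clockwise in image coords
    ring = centers[order]
    tol = MERGE_TOL * max(1.0, scale)
    keep = [0]
    for i in range(1, len(ring)):
        if np.hypot(*(ring[i] - ring[keep[-1]])) > tol:
            keep.append(i)
    if len(keep) > 1 and np.hypot(*(ring[keep[-1]] - ring[keep[0]])) <= tol:
        keep.pop()
    return ring[keep]


def _hull_contains(pts: np.ndarray, query: np.ndarray, scale: float) -> bool:
    """True iff every query point lies inside the convex hull of pts."""
    eqs = _ConvexHull(pts).equations  # rows (a, b, c): ax + by + c <= 0 inside
    tol = MERGE_TOL * max(1.0, scale)
    return bool(np.all(query @ eqs[:, :2].T + eqs[:, 2] <= tol))


def build_cell(site_index: int, points, tri: Triangulation) -> VoronoiCell:
    """Voronoi cell of one site from the circumcenters of its incident triangles."""
    pts = _as_points(points)
    incident = np.nonzero((tri.triangles == site_index).any(axis=1))[0]
    if len(incident) == 0:
        raise DegenerateGeometryError(f"site {site_index} belongs to no triangle")
    centers = _circumcenters(pts, tri.triangles[incident])
    scale = float(np.ptp(pts, axis=0).max())
    ring = _ordered_ring(pts[site_index], centers, scale)
    bounded = site_index not in tri.hull_vertices and len(ring) >= 3
    area = polygon_area(ring) if bounded else None
    interior = bounded and _hull_contains(pts, ring, scale)
    return VoronoiCell(
        site_index=site_index, vertices=ring, bounded=bounded, area=area, interior=interior
    )


def tessellate(points, units: str = "cm") -> Tessellation:
    """Build every site's cell; areas of bounded cells feed the CV index.

    The index is scale-invariant, so pixel and centimetre inputs give
    identical heterogeneity values; ``units`` is metadata only.
    """
    if isinstance(points, PointSet):
        units = points.units
    pts = _as_points(points)
    tri = delaunay(pts)
    interior = np.ones(len(pts), dtype=bool)
    interior[tri.hull_vertices] = False

    centers = _circumcenters(pts, tri.triangles)
    scale = float(np.ptp(pts, axis=0).max())
    incident: list[list[int]] = [[] for _ in range(len(pts))]
    for t, (i, j, k) in enumerate(tri.triangles):
        incident[i].append(t)
        incident[j].append(t)
        incident[k].append(t)

    hull_eqs = _ConvexHull(pts).equations
    tol = MERGE_TOL * max(1.0, scale)
    cells = []
    for s in range(len(pts)):
        cc = centers[incident[s]]
        ring = _ordered_ring(pts[s], cc, scale) if len(cc) else np.empty((0, 2))
        bounded = bool(interior[s]) and len(ring) >= 3
        area = polygon_area(ring) if bounded else None
        inside = bounded and bool(
            np.all(ring @ hull_eqs[:, :2].T + hull_eqs[:, 2] <= tol)
        )
        cells.append(
            VoronoiCell(site_index=s, vertices=ring, bounded=bounded, area=area, interior=inside)
        )
    return Tessellation(points=pts, cells=tuple(cells), units=units)
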