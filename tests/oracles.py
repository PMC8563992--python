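"""Independent brute-force oracles used only by the tests.

These deliberately avoid the code paths they check: the Voronoi oracle
builds each cell by Sutherland-Hodgman half-plane clipping against every
other site's bisector (never via Delaunay circumcenters), the component
oracle is a plain flood fill, and the major-axis oracle evaluates the
second-moment ellipse formula directly on the pixel set.
"""

from __future__ import annotations

import numpy as np


def clip_halfplane(poly: list[tuple[float, float]], m, n) -> list[tuple[float, float]]:
    """Keep the part of convex polygon ``poly`` with n . (x - m) <= 0."""
    m = np.asarray(m, float)
    n = np.asarray(n, float)
    out: list[tuple[float, float]] = []
    k = len(poly)
    for idx in range(k):
        a = np.asarray(poly[idx], float)
        b = np.asarray(poly[(idx + 1) % k], float)
        da = float(n @ (a - m))
        db = float(n @ (b - m))
        if da <= 0:
            out.append(tuple(a))
        if da * db < 0:
            t = da / (da - db)
            out.append(tuple(a + t * (b - a)))
    return out


def halfplane_voronoi_cell(points: np.ndarray, i: int, box_pad: float = 1e4):
    """Voronoi cell of site i as repeated bisector half-plane clipping.

    Starts from the bounding box of the sites inflated by ``box_pad`` times
    its diagonal; a cell that still touches that box is (effectively)
    unbounded.  Returns (polygon_vertices, touches_box).
    """
    points = np.asarray(points, float)
    lo = points.min(axis=0)
    hi = points.max(axis=0)
    diag = float(np.hypot(*(hi - lo))) or 1.0
    lo = lo - box_pad * diag
    hi = hi + box_pad * diag
    poly = [(lo[0], lo[1]), (hi[0], lo[1]), (hi[0], hi[1]), (lo[0], hi[1])]
    p = points[i]
    for j, q in enumerate(points):
        if j == i or not poly:
            continue
        poly = clip_halfplane(poly, (p + q) / 2.0, q - p)
    arr = np.asarray(poly, float)
    eps = 1e-6 * diag
    touches = bool(
        len(arr)
        and (
            np.any(arr[:, 0] < lo[0] + eps)
            or np.any(arr[:, 0] > hi[0] - eps)
            or np.any(arr[:, 1] < lo[1] + eps)
            or np.any(arr[:, 1] > hi[1] - eps)
        )
    )
    return arr, touches


def shoelace(poly: np.ndarray) -> float:
    poly = np.asarray(poly, float)
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def flood_fill_components(mask: np.ndarray, connectivity: int) -> list[set]:
    """Connected components by explicit flood fill."""
    mask = np.asarray(mask, bool)
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    seen = np.zeros_like(mask, bool)
    comps = []
    h, w = mask.shape
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r, c]:
                stack = [(r, c)]
                seen[r, c] = True
                comp = set()
                while stack:
                    rr, cc = stack.pop()
                    comp.add((rr, cc))
                    for dr, dc in nbrs:
                        nr, nc = rr + dr, cc + dc
                        if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] and not seen[nr, nc]:
                            seen[nr, nc] = True
                            stack.append((nr, nc))
                comps.append(comp)
    return comps


def major_axis_from_pixels(pixels: set) -> float:
    """Length of the major axis of the matching second-central-moment ellipse."""
    pts = np.array(sorted(pixels), float)
    if len(pts) == 0:
        return 0.0
    centred = pts - pts.mean(axis=0)
    cov = centred.T @ centred / len(pts)
    eig = np.linalg.eigvalsh(cov)
    return 4.0 * np.sqrt(max(eig.max(), 0.0))


def disk_pixels(radius: int) -> set:
    """All integer offsets within Euclidean distance radius of the origin."""
    out = set()
    for dr in range(-radius, radius + 1):
        for dc in range(-radius, radius + 1):
            if dr * dr + dc * dc <= radius * radius:
                out.add((dr, dc))
    return out
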