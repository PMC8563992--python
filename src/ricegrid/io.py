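"""CSV / GeoJSON readers and writers shared by the CLI and scripts.

Two point-table dialects are understood:

* detection tables: ``id,row_px,col_px,x_cm,y_cm,stage`` (pixel coordinates
  plus their ground conversion when a gsd is known);
* simulation tables: ``id,x,y`` (planar coordinates, cm).

``read_points_xy`` resolves either into planar (x, y) sites for the
tessellation, preferring ground units when present.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .detection import ClusterSet
from .errors import ParseError
from .tessellation import PointSet, Tessellation

__all__ = [
    "write_points_csv",
    "write_xy_csv",
    "read_points_xy",
    "write_areas_csv",
    "write_geojson",
]


def write_points_csv(clusters: ClusterSet, path) -> None:
    """Detection-style point table; ground columns filled when gsd is known."""
    n = len(clusters)
    pos = clusters.positions
    gsd = clusters.gsd
    df = pd.DataFrame(
        {
            "id": np.arange(n),
            "row_px": pos[:, 0],
            "col_px": pos[:, 1],
            "x_cm": pos[:, 1] * gsd if gsd else np.full(n, np.nan),
            "y_cm": pos[:, 0] * gsd if gsd else np.full(n, np.nan),
            "stage": list(clusters.stages) if clusters.stages is not None else [""] * n,
        }
    )
    df.to_csv(path, index=False)


def write_xy_csv(points: PointSet, path) -> None:
    """Simulation-style point table: id,x,y."""
    pts = points.points
    pd.DataFrame({"id": np.arange(len(pts)), "x": pts[:, 0], "y": pts[:, 1]}).to_csv(
        path, index=False
    )


def read_points_xy(path) -> PointSet:
    """Load planar sites from either point-table dialect."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pandas raises many parser types
        raise ParseError(f"cannot parse point table {path}: {exc}") from exc
    cols = {c.strip().lower(): c for c in df.columns}
    if "x_cm" in cols and "y_cm" in cols and not df[cols["x_cm"]].isna().any():
        return PointSet(df[[cols["x_cm"], cols["y_cm"]]].to_numpy(float), units="cm")
    if "x" in cols and "y" in cols:
        return PointSet(df[[cols["x"], cols["y"]]].to_numpy(float), units="cm")
    if "row_px" in cols and "col_px" in cols:
        xy = df[[cols["col_px"], cols["row_px"]]].to_numpy(float)
        return PointSet(xy, units="px")
    raise ParseError(f"no usable coordinate columns in {path} (have {list(df.columns)})")


def write_areas_csv(tess: Tessellation, path) -> None:
    rows = [
        {
            "site_id": c.site_index,
            "area": c.area if c.bounded else "",
            "bounded": c.bounded,
            "interior": c.interior,
        }
        for c in tess.cells
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_geojson(tess: Tessellation, path) -> None:
    """Cell polygons as a GeoJSON FeatureCollection (closed rings)."""
    features = []
    for c in tess.cells:
        ring = [[float(x), float(y)] for x, y in c.vertices]
        if ring:
            ring.append(ring[0])
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]} if len(ring) >= 4 else None,
                "properties": {
                    "site_id": int(c.site_index),
                    "area": float(c.area) if c.area is not None else None,
                    "bounded": bool(c.bounded),
                },
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
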