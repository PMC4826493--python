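"""Raster/vector glue: polygons in micrometre coordinates vs pixel grids.

Convention: origin at the top-left corner, x rightward, y downward, physical
units are micrometres.  Pixel (i, j) covers the half-open square
[j*s, (j+1)*s) x [i*s, (i+1)*s) with s = um_per_px; its centre is at
((j + 0.5)*s, (i + 0.5)*s).  A pixel belongs to a polygon iff its centre
does.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon, shape as geo_shape, mapping


def pixel_center_axes(shape: tuple[int, int], um_per_px: float) -> tuple[np.ndarray, np.ndarray]:
    """Return (xs, ys) of pixel-centre coordinates in um for an (H, W) grid."""
    h, w = shape
    xs = (np.arange(w) + 0.5) * um_per_px
    ys = (np.arange(h) + 0.5) * um_per_px
    return xs, ys


def rasterize(geom, shape: tuple[int, int], um_per_px: float) -> np.ndarray:
    """Rasterize a shapely geometry to a boolean (H, W) mask by pixel-centre test.

    Only the bounding-box window of the geometry is tested, the rest is False.
    """
    h, w = shape
    mask = np.zeros((h, w), dtype=bool)
    if geom is None or geom.is_empty:
        return mask
    minx, miny, maxx, maxy = geom.bounds
    s = um_per_px
    j0 = max(int(np.floor(minx / s - 0.5)), 0)
    j1 = min(int(np.ceil(maxx / s + 0.5)) + 1, w)
    i0 = max(int(np.floor(miny / s - 0.5)), 0)
    i1 = min(int(np.ceil(maxy / s + 0.5)) + 1, h)
    if j0 >= j1 or i0 >= i1:
        return mask
    xs = (np.arange(j0, j1) + 0.5) * s
    ys = (np.arange(i0, i1) + 0.5) * s
    xx, yy = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(geom, xx.ravel(), yy.ravel()).reshape(yy.shape)
    mask[i0:i1, j0:j1] = inside
    return mask


def contains_points(geom, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized point-in-geometry test; empty/None geometry contains nothing."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if geom is None or geom.is_empty:
        return np.zeros(x.shape, dtype=bool)
    return shapely.contains_xy(geom, x, y)


def union_all(geoms: Iterable) -> "shapely.Geometry | None":
    geoms = [g for g in geoms if g is not None and not g.is_empty]
    if not geoms:
        return None
    return shapely.union_all(geoms)


def validate_simple_polygon(coords: Sequence[Sequence[float]]) -> Polygon:
    """Build a Polygon from an (x, y) ring and require it to be simple and non-empty."""
    poly = Polygon(coords)
    if not poly.is_valid or poly.area <= 0:
        raise ValueError("polygon must be simple (non-self-intersecting) with positive area")
    return poly


def read_geojson(path: str | Path) -> list[Polygon]:
    """Read all (Multi)Polygon geometries from a GeoJSON file, in um coordinates."""
    with open(path) as fh:
        doc = json.load(fh)
    geoms: list[Polygon] = []

    def collect(g):
        obj = geo_shape(g)
        if obj.geom_type == "Polygon":
            geoms.append(obj)
        elif obj.geom_type == "MultiPolygon":
            geoms.extend(obj.geoms)
        else:
            raise ValueError(f"unsupported geometry type {obj.geom_type!r}")

    if doc.get("type") == "FeatureCollection":
        for feat in doc["features"]:
            collect(feat["geometry"])
    elif doc.get("type") == "Feature":
        collect(doc["geometry"])
    else:
        collect(doc)
    return geoms


def write_geojson(path: str | Path, geoms: Sequence[Polygon]) -> None:
    doc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "properties": {}, "geometry": mapping(g)} for g in geoms
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)
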