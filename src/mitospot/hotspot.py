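"""Circle-overlap heat map, hot-spot selection, and hot-spot overlap categories.

A circle of fixed radius (default 200 um) is centred on every positive cell;
each grid point's intensity is the number of circles covering it, i.e. the
number of positive cells within the radius.  The hot-spot centre is the
position of maximal intensity, encompassed by a 1-mm^2 square.  An
alternative selector places the square to maximise the contained cell count
directly (used as the exhaustive oracle mode).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from . import geometry
from .detect import CellSet

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class HeatMap:
    """Integer circle-overlap intensity on a regular grid (um coordinates)."""

    values: np.ndarray  # (ny, nx) int32
    xs: np.ndarray  # (nx,) grid x coordinates [um]
    ys: np.ndarray  # (ny,) grid y coordinates [um]
    radius_um: float
    grid_step_um: float


@dataclass(frozen=True)
class HotSpot:
    """Selected hot spot: centre plus axis-aligned 1-mm^2 square."""

    center_um: tuple[float, float]
    square_side_um: float
    peak_intensity: int

    @property
    def square_origin_um(self) -> tuple[float, float]:
        half = self.square_side_um / 2.0
        return (self.center_um[0] - half, self.center_um[1] - half)


class OverlapCategory(str, Enum):
    PERFECT = "perfect"
    MAYOR = "mayor"
    MINOR = "minor"
    NONE = "none"


@dataclass(frozen=True)
class OverlapResult:
    dx_mm: float
    dy_mm: float
    category: OverlapCategory


def _cell_points(cells) -> np.ndarray:
    if isinstance(cells, CellSet):
        return cells.positive_centroids()
    pts = np.asarray(cells, dtype=float)
    return pts.reshape(-1, 2)


def _domain_bounds(domain) -> tuple[float, float, float, float]:
    if domain is None:
        raise ValueError("heat-map domain must not be empty")
    if hasattr(domain, "bounds"):
        if domain.is_empty or domain.area <= 0:
            raise ValueError("heat-map domain must not be empty")
        return domain.bounds
    minx, miny, maxx, maxy = domain
    if maxx <= minx or maxy <= miny:
        raise ValueError("heat-map domain must not be empty")
    return minx, miny, maxx, maxy


def build_heatmap(
    cells, domain, radius_um: float = 200.0, grid_step_um: float = 10.0
) -> HeatMap:
    """Object Heat Map: intensity = positive cells within radius of each grid point.

    The grid spans the domain bounding box at the given step; the distance
    test is boundary-inclusive (<= radius).
    """
    if radius_um <= 0 or grid_step_um <= 0:
        raise ValueError("radius_um and grid_step_um must be > 0")
    minx, miny, maxx, maxy = _domain_bounds(domain)
    xs = minx + grid_step_um * np.arange(int(np.floor((maxx - minx) / grid_step_um)) + 1)
    ys = miny + grid_step_um * np.arange(int(np.floor((maxy - miny) / grid_step_um)) + 1)
    pts = _cell_points(cells)
    if len(pts) == 0:
        values = np.zeros((len(ys), len(xs)), dtype=np.int32)
        return HeatMap(values, xs, ys, radius_um, grid_step_um)
    xx, yy = np.meshgrid(xs, ys)
    grid = np.column_stack([xx.ravel(), yy.ravel()])
    tree = cKDTree(pts)
    counts = tree.query_ball_point(grid, r=radius_um, return_length=True)
    values = np.asarray(counts, dtype=np.int32).reshape(len(ys), len(xs))
    return HeatMap(values, xs, ys, radius_um, grid_step_um)


def _eligible(heatmap: HeatMap, domain, exclusions) -> np.ndarray:
    xx, yy = np.meshgrid(heatmap.xs, heatmap.ys)
    elig = np.ones(xx.shape, dtype=bool)
    if domain is not None and hasattr(domain, "bounds"):
        elig &= geometry.contains_points(domain, xx, yy)
    if exclusions:
        excl = geometry.union_all(
            exclusions if isinstance(exclusions, (list, tuple)) else [exclusions]
        )
        if excl is not None:
            elig &= ~geometry.contains_points(excl, xx, yy)
    return elig


def select_hotspot(
    heatmap: HeatMap,
    exclusions=None,
    domain=None,
    square_side_um: float = 1000.0,
) -> HotSpot | None:
    """Pick the hottest position; None is the distinguished "no hot spot" outcome.

    The centre is the centroid of the largest connected component of maximal
    eligible grid points; among equally large components the one whose first
    grid point comes earliest in (y, x) scan order wins.  Excluded grid
    points are ineligible as centres.
    """
    elig = _eligible(heatmap, domain, exclusions)
    if not elig.any():
        return None
    vals = np.where(elig, heatmap.values, -1)
    peak = int(vals.max())
    if peak <= 0:
        return None  # no positive cell covers any eligible grid point
    at_max = vals == peak
    labels, n = ndimage.label(at_max, structure=_EIGHT)
    sizes = ndimage.sum_labels(at_max, labels, index=np.arange(1, n + 1))
    best_size = sizes.max()
    candidates = np.flatnonzero(sizes == best_size) + 1
    if len(candidates) > 1:
        # earliest component in scan order
        first_idx = {
            lab: np.flatnonzero(labels.ravel() == lab)[0] for lab in candidates
        }
        best = min(candidates, key=lambda lab: first_idx[lab])
    else:
        best = candidates[0]
    iy, ix = np.nonzero(labels == best)
    center = (float(np.mean(heatmap.xs[ix])), float(np.mean(heatmap.ys[iy])))
    return HotSpot(center, square_side_um, peak)


def select_hotspot_square(
    cells,
    domain,
    grid_step_um: float = 10.0,
    square_side_um: float = 1000.0,
    exclusions=None,
) -> HotSpot | None:
    """Alternative selector: place the square to maximise the contained cell count.

    Exhaustive over candidate centres on the grid (the square-placement
    oracle); ties resolve to the earliest centre in (y, x) scan order.
    """
    pts = _cell_points(cells)
    if exclusions:
        excl = geometry.union_all(
            exclusions if isinstance(exclusions, (list, tuple)) else [exclusions]
        )
        if excl is not None and len(pts):
            pts = pts[~geometry.contains_points(excl, pts[:, 0], pts[:, 1])]
    if len(pts) == 0:
        return None
    minx, miny, maxx, maxy = _domain_bounds(domain)
    xs = minx + grid_step_um * np.arange(int(np.floor((maxx - minx) / grid_step_um)) + 1)
    ys = miny + grid_step_um * np.arange(int(np.floor((maxy - miny) / grid_step_um)) + 1)
    half = square_side_um / 2.0
    in_x = (pts[:, 0][None, :] >= xs[:, None] - half) & (pts[:, 0][None, :] < xs[:, None] + half)
    in_y = (pts[:, 1][None, :] >= ys[:, None] - half) & (pts[:, 1][None, :] < ys[:, None] + half)
    counts = in_y.astype(np.int32) @ in_x.T.astype(np.int32)  # (ny, nx)
    if domain is not None and hasattr(domain, "bounds"):
        xx, yy = np.meshgrid(xs, ys)
        counts = np.where(geometry.contains_points(domain, xx, yy), counts, -1)
    best = int(counts.max())
    if best <= 0:
        return None
    iy, ix = np.unravel_index(int(np.argmax(counts)), counts.shape)  # first in scan order
    return HotSpot((float(xs[ix]), float(ys[iy])), square_side_um, best)


def count_in_square(cells, square, exclusions=None) -> int:
    """Positive cells with centroid in the half-open square, outside exclusions."""
    pts = _cell_points(cells)
    if len(pts) == 0:
        return 0
    if isinstance(square, HotSpot):
        x0, y0 = square.square_origin_um
        side = square.square_side_um
    else:
        x0, y0, side = square
    inside = (
        (pts[:, 0] >= x0)
        & (pts[:, 0] < x0 + side)
        & (pts[:, 1] >= y0)
        & (pts[:, 1] < y0 + side)
    )
    if exclusions:
        excl = geometry.union_all(
            exclusions if isinstance(exclusions, (list, tuple)) else [exclusions]
        )
        if excl is not None:
            inside &= ~geometry.contains_points(excl, pts[:, 0], pts[:, 1])
    return int(np.count_nonzero(inside))


def categorize_overlap(center_a, center_b, units: str = "um") -> OverlapResult:
    """Categorize two hot-spot squares by |dx| and |dy| between their centres.

    Combined with the Chebyshev rule d = max(|dx|, |dy|) in mm:
    perfect d < 0.10; mayor 0.10 <= d < 0.75; minor 0.75 <= d <= 1.0;
    none d > 1.0 (exactly when two 1-mm^2 squares are disjoint).
    """
    scale = 1e-3 if units == "um" else 1.0
    dx = abs(center_a[0] - center_b[0]) * scale
    dy = abs(center_a[1] - center_b[1]) * scale
    d = max(dx, dy)
    if d < 0.10:
        cat = OverlapCategory.PERFECT
    elif d < 0.75:
        cat = OverlapCategory.MAYOR
    elif d <= 1.0:
        cat = OverlapCategory.MINOR
    else:
        cat = OverlapCategory.NONE
    return OverlapResult(dx, dy, cat)
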