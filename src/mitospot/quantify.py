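"""Proliferation indices: global and hot-spot counts per MART1-verified area.

The MART1-adjusted index is the number of positive cells divided by the
MART1-verified tumor area (mm^2), globally or within the 1-mm^2 hot-spot
square.  Because very small reference areas make the quotient unstable,
zero-area handling is a tri-state: a value, a distinguished "undefined"
(None, for 0 cells / 0 area), or an inconsistency error (cells present in
zero area signals a detection bug).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geometry
from .detect import CellSet, TumorMask
from .hotspot import HotSpot, count_in_square


class InconsistencyError(ValueError):
    """Positive cells reported inside a zero reference area."""


#: Named dichotomization presets: name -> (cutoff, rule).
CUTOFF_PRESETS: dict[str, tuple[float, str]] = {
    "manual_hotspot_count": (1.0, "ge"),  # 0 vs >= 1 cells per square
    "manual_hotspot_adjusted": (7.7, "gt"),  # <= 7.7/mm^2 vs > 7.7/mm^2
    "manual_global_adjusted": (3.3, "gt"),
    "auto_hotspot_count": (2.0, "gt"),  # <= 2.0 vs > 2.0 cells per square
    "auto_hotspot_adjusted": (14.0, "gt"),
    "auto_global_adjusted": (4.0, "gt"),
}


@dataclass
class ProliferationResult:
    """Global and hot-spot counts and MART1-adjusted indices for one slide."""

    global_count: int
    global_area_mm2: float
    global_index: float | None  # cells/mm^2; None = undefined (0 cells, 0 area)
    hotspot_count: int | None = None
    hotspot_area_mm2: float | None = None
    hotspot_adjusted_index: float | None = None
    hotspot_center_um: tuple[float, float] | None = None
    no_hotspot: bool = False
    dichotomies: dict[str, str] = field(default_factory=dict)
    config_hash: str | None = None

    def to_dict(self) -> dict:
        return {
            "global_count": self.global_count,
            "global_area_mm2": self.global_area_mm2,
            "global_index": self.global_index,
            "hotspot_count": self.hotspot_count,
            "hotspot_area_mm2": self.hotspot_area_mm2,
            "hotspot_adjusted_index": self.hotspot_adjusted_index,
            "hotspot_center_um": list(self.hotspot_center_um) if self.hotspot_center_um else None,
            "no_hotspot": self.no_hotspot,
            "dichotomies": self.dichotomies,
            "config_hash": self.config_hash,
        }


def global_index(cells: CellSet, tumor: TumorMask) -> float | None:
    """Positive cells per mm^2 of MART1-verified tumor area.

    Returns None (undefined) for 0 cells in 0 area; raises
    :class:`InconsistencyError` for cells in 0 area.
    """
    count = len(cells.positives())
    area = tumor.area_mm2
    if area == 0:
        if count == 0:
            return None
        raise InconsistencyError(
            f"{count} positive cells but zero MART1-verified tumor area"
        )
    return count / area


def _square_area_mm2(tumor: TumorMask, hotspot: HotSpot, exclusions=None) -> float:
    """MART1-verified area (mm^2) of tumor pixels whose centres fall in the square."""
    s = tumor.um_per_px
    x0, y0 = hotspot.square_origin_um
    side = hotspot.square_side_um
    h, w = tumor.mask.shape
    # pixel centre (j + 0.5) * s in [x0, x0 + side)
    j0 = max(int(np.ceil(x0 / s - 0.5)), 0)
    j1 = min(int(np.ceil((x0 + side) / s - 0.5)), w)
    i0 = max(int(np.ceil(y0 / s - 0.5)), 0)
    i1 = min(int(np.ceil((y0 + side) / s - 0.5)), h)
    if i0 >= i1 or j0 >= j1:
        return 0.0
    window = tumor.mask[i0:i1, j0:j1]
    if exclusions:
        excl = geometry.union_all(
            exclusions if isinstance(exclusions, (list, tuple)) else [exclusions]
        )
        if excl is not None:
            xs = (np.arange(j0, j1) + 0.5) * s
            ys = (np.arange(i0, i1) + 0.5) * s
            xx, yy = np.meshgrid(xs, ys)
            window = window & ~geometry.contains_points(excl, xx, yy)
    return float(window.sum()) * s * s / 1e6


def hotspot_indices(
    cells: CellSet, tumor: TumorMask, hotspot: HotSpot, exclusions=None
) -> tuple[int, float | None, float]:
    """(count in square, MART1-adjusted index, MART1 area in square [mm^2]).

    The adjusted index divides by the MART1-verified area inside the square
    (regions outside tumor are subtracted from the 1-mm^2 reference area).
    """
    count = count_in_square(cells, hotspot, exclusions)
    area = _square_area_mm2(tumor, hotspot, exclusions)
    if area == 0:
        if count == 0:
            return 0, None, 0.0
        raise InconsistencyError(
            f"{count} positive cells in the hot-spot square but zero MART1 area"
        )
    return count, count / area, area


def dichotomize(value: float, cutoff: float, rule: str = "gt") -> str:
    """Threshold a count or index into 'low'/'high' ('gt': high iff > cutoff)."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    if rule == "gt":
        return "high" if value > cutoff else "low"
    if rule == "ge":
        return "high" if value >= cutoff else "low"
    raise ValueError("rule must be 'gt' or 'ge'")


def dichotomize_preset(value: float, preset: str) -> str:
    cutoff, rule = CUTOFF_PRESETS[preset]
    return dichotomize(value, cutoff, rule)


def summarize(
    cells: CellSet,
    tumor: TumorMask,
    hotspot: HotSpot | None,
    exclusions=None,
    config_hash: str | None = None,
) -> ProliferationResult:
    """Assemble the full per-slide result (global + hot spot + dichotomies)."""
    count = len(cells.positives())
    gi = global_index(cells, tumor)
    result = ProliferationResult(
        global_count=count,
        global_area_mm2=tumor.area_mm2,
        global_index=gi,
        config_hash=config_hash,
    )
    if hotspot is None:
        result.no_hotspot = True
        result.hotspot_count = 0
    else:
        hs_count, hs_index, hs_area = hotspot_indices(cells, tumor, hotspot, exclusions)
        result.hotspot_count = hs_count
        result.hotspot_adjusted_index = hs_index
        result.hotspot_area_mm2 = hs_area
        result.hotspot_center_um = hotspot.center_um
    result.dichotomies = {
        "auto_hotspot_count": dichotomize_preset(result.hotspot_count or 0, "auto_hotspot_count"),
        "auto_global_adjusted": dichotomize_preset(gi or 0.0, "auto_global_adjusted"),
    }
    if result.hotspot_adjusted_index is not None:
        result.dichotomies["auto_hotspot_adjusted"] = dichotomize_preset(
            result.hotspot_adjusted_index, "auto_hotspot_adjusted"
        )
    return result
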