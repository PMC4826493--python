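"""File-format plumbing: TIFF/PNG images with calibration sidecars, CSV cell
tables, GeoJSON polygons, JSON reports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .detect import CellObject, CellSet, TumorMask
from .hotspot import HeatMap, HotSpot
from .stains import CalibratedImage

CELL_COLUMNS = [
    "x_um",
    "y_um",
    "area_um2",
    "mean_brown_od",
    "irregularity",
    "mart1_surround_fraction",
    "positive",
]


def _sidecar_path(image_path: Path) -> Path:
    return image_path.with_suffix(image_path.suffix + ".calibration.json")


def write_image(path: str | Path, image: CalibratedImage) -> None:
    """Write an 8-bit RGB TIFF plus a calibration sidecar JSON."""
    path = Path(path)
    tifffile.imwrite(path, image.pixels.astype(np.uint8))
    _sidecar_path(path).write_text(json.dumps({"um_per_px": image.um_per_px}))


def read_image(path: str | Path, um_per_px: float | None = None) -> CalibratedImage:
    """Read TIFF/PNG; calibration precedence: explicit override > sidecar > error."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        pixels = tifffile.imread(path)
    else:
        pixels = np.asarray(Image.open(path).convert("RGB"))
    if um_per_px is None:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise ValueError(
                f"no calibration for {path.name}: pass um_per_px or provide {sidecar.name}"
            )
        um_per_px = float(json.loads(sidecar.read_text())["um_per_px"])
    return CalibratedImage(pixels, um_per_px)


def write_cells_csv(path: str | Path, cells: CellSet) -> None:
    rows = [
        {
            "x_um": c.centroid_um[0],
            "y_um": c.centroid_um[1],
            "area_um2": c.area_um2,
            "mean_brown_od": c.mean_brown_od,
            "irregularity": c.irregularity,
            "mart1_surround_fraction": c.mart1_surround_fraction,
            "positive": c.positive,
        }
        for c in cells.cells
    ]
    pd.DataFrame(rows, columns=CELL_COLUMNS).to_csv(path, index=False)


def read_cells_csv(path: str | Path) -> CellSet:
    df = pd.read_csv(path)
    cells = [
        CellObject(
            label=i + 1,
            centroid_um=(float(r.x_um), float(r.y_um)),
            area_um2=float(getattr(r, "area_um2", 0.0) or 0.0),
            mean_brown_od=float(getattr(r, "mean_brown_od", 0.0) or 0.0),
            irregularity=float(getattr(r, "irregularity", 0.0) or 0.0),
            mart1_surround_fraction=float(getattr(r, "mart1_surround_fraction", 0.0) or 0.0),
            positive=bool(r.positive),
        )
        for i, r in enumerate(df.itertuples())
    ]
    return CellSet(cells=cells)


def write_mask_png(path: str | Path, mask: np.ndarray) -> None:
    Image.fromarray((np.asarray(mask, bool) * 255).astype(np.uint8)).save(path)


def write_heatmap_tiff(path: str | Path, heatmap: HeatMap) -> None:
    tifffile.imwrite(path, heatmap.values.astype(np.uint16))


def write_hotspot_json(path: str | Path, hotspot: HotSpot | None, count: int | None = None,
                       config_hash: str | None = None) -> None:
    if hotspot is None:
        doc = {"no_hotspot": True, "config_hash": config_hash}
    else:
        x0, y0 = hotspot.square_origin_um
        doc = {
            "no_hotspot": False,
            "center_um": list(hotspot.center_um),
            "square_origin_um": [x0, y0],
            "square_side_um": hotspot.square_side_um,
            "peak_intensity": hotspot.peak_intensity,
            "count_in_square": count,
            "config_hash": config_hash,
        }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))


def write_tumor_report(path: str | Path, tumor: TumorMask, config_hash: str | None = None) -> None:
    Path(path).write_text(
        json.dumps({"area_mm2": tumor.area_mm2, "config_hash": config_hash}, indent=2)
    )


def write_truth_csv(path: str | Path, truth) -> None:
    rows = [
        {"x_um": float(x), "y_um": float(y), "kind": "positive"}
        for x, y in truth.positive_centroids
    ] + [
        {"x_um": x, "y_um": y, "kind": kind} for x, y, kind in truth.confounder_centroids
    ]
    pd.DataFrame(rows, columns=["x_um", "y_um", "kind"]).to_csv(path, index=False)
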