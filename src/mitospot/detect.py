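"""Positive-cell detection and MART1-verified tumor area.

Turns the pixel class map into candidate PHH3 objects (dilation fuses split
anaphase/telophase chromatin into one object), measures each object on its
original pixels, applies the positivity gates — size, MART1 surrounding,
color intensity, nuclear irregularity — and builds the MART1-verified tumor
area in which PHH3-negative blue tumor nuclei are reclassified as MART1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from . import geometry
from .config import DetectConfig, RunConfig
from .stains import (
    CalibratedImage,
    ClassMap,
    PixelClass,
    classify_pixels,
    deconvolve,
    hsi_intensity,
    sd_filter,
)

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class CellObject:
    """One candidate PHH3 object with its audit features."""

    label: int
    centroid_um: tuple[float, float]  # (x, y)
    area_um2: float
    mean_brown_od: float
    irregularity: float  # 1 - solidity
    mart1_surround_fraction: float
    positive: bool = False


@dataclass
class CellSet:
    """All measured objects plus run provenance; positives carry the flag."""

    cells: list[CellObject] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def positives(self) -> list[CellObject]:
        return [c for c in self.cells if c.positive]

    def positive_centroids(self) -> np.ndarray:
        pos = self.positives()
        if not pos:
            return np.zeros((0, 2))
        return np.array([c.centroid_um for c in pos])

    def __len__(self) -> int:
        return len(self.cells)


@dataclass(frozen=True)
class TumorMask:
    """Binary mask of the MART1-verified tumor area (including nuclei)."""

    mask: np.ndarray  # bool (H, W)
    um_per_px: float

    @property
    def area_mm2(self) -> float:
        return float(self.mask.sum()) * self.um_per_px**2 / 1e6


def _disc_dilate(mask: np.ndarray, radius_um: float, um_per_px: float) -> np.ndarray:
    """Euclidean dilation by a physical radius (sub-pixel accurate via EDT)."""
    if radius_um <= 0 or not mask.any():
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask) * um_per_px
    return dist <= radius_um


def fuse_chromatin(class_map: ClassMap, dilation_radius_um: float) -> np.ndarray:
    """Label PHH3 objects after disc dilation; labels sit on the ORIGINAL pixels.

    Dilation by the physical radius merges chromatin fragments whose edge gap
    is at most twice the radius (so a split anaphase becomes one object), but
    all measurements downstream use the undilated member pixels.
    """
    if dilation_radius_um < 0:
        raise ValueError("dilation_radius_um must be >= 0")
    phh3 = class_map.mask(PixelClass.PHH3)
    dilated = _disc_dilate(phh3, dilation_radius_um, class_map.um_per_px)
    labels, _ = ndimage.label(dilated, structure=_EIGHT)
    return np.where(phh3, labels, 0)


def mart1_surround(obj_mask: np.ndarray, class_map: ClassMap, ring_width_um: float) -> float:
    """Fraction of the perinuclear ring classified MART1.

    Ring = dilation of the object by ``ring_width_um`` minus the object;
    clipped at the image border, the fraction is over the available ring.
    """
    if ring_width_um <= 0:
        raise ValueError("ring_width_um must be > 0")
    ring = _disc_dilate(obj_mask, ring_width_um, class_map.um_per_px) & ~obj_mask
    n = int(ring.sum())
    if n == 0:
        return 0.0
    return float(np.count_nonzero(class_map.labels[ring] == int(PixelClass.MART1))) / n


def _windowed_surround(
    obj_slice: tuple[slice, slice],
    obj_mask_bbox: np.ndarray,
    class_map: ClassMap,
    ring_width_um: float,
) -> float:
    """mart1_surround computed on a padded bounding-box window (fast path)."""
    s = class_map.um_per_px
    pad = int(np.ceil(ring_width_um / s)) + 1
    h, w = class_map.labels.shape
    r0 = max(obj_slice[0].start - pad, 0)
    r1 = min(obj_slice[0].stop + pad, h)
    c0 = max(obj_slice[1].start - pad, 0)
    c1 = min(obj_slice[1].stop + pad, w)
    window = np.zeros((r1 - r0, c1 - c0), dtype=bool)
    window[
        obj_slice[0].start - r0 : obj_slice[0].stop - r0,
        obj_slice[1].start - c0 : obj_slice[1].stop - c0,
    ] = obj_mask_bbox
    ring = _disc_dilate(window, ring_width_um, s) & ~window
    n = int(ring.sum())
    if n == 0:
        return 0.0
    labels = class_map.labels[r0:r1, c0:c1]
    return float(np.count_nonzero(labels[ring] == int(PixelClass.MART1))) / n


def measure_objects(
    labeled: np.ndarray,
    class_map: ClassMap,
    brown_od: np.ndarray,
    ring_width_um: float,
) -> list[CellObject]:
    """Measure area, centroid, mean DAB OD, irregularity and MART1 surround per object."""
    s = class_map.um_per_px
    out: list[CellObject] = []
    for region in measure.regionprops(labeled, intensity_image=brown_od):
        cy, cx = region.centroid  # (row, col) means of pixel indices
        surround = _windowed_surround(region.slice, region.image, class_map, ring_width_um)
        out.append(
            CellObject(
                label=int(region.label),
                centroid_um=((cx + 0.5) * s, (cy + 0.5) * s),
                area_um2=float(region.area) * s * s,
                mean_brown_od=float(region.intensity_mean),
                irregularity=float(1.0 - region.solidity),
                mart1_surround_fraction=surround,
            )
        )
    return out


def score_objects(
    objects: list[CellObject], config: DetectConfig, provenance: dict | None = None
) -> CellSet:
    """Apply the positivity gates; every object is retained with its flag."""
    for obj in objects:
        obj.positive = (
            config.min_area_um2 <= obj.area_um2 <= config.max_area_um2
            and obj.mean_brown_od >= config.object_od_min
            and obj.mart1_surround_fraction >= config.surround_min
            and obj.irregularity <= config.irregularity_max
        )
    return CellSet(cells=list(objects), provenance=dict(provenance or {}))


def tumor_area(
    class_map: ClassMap,
    outline,
    config: DetectConfig | None = None,
    positive_mask: np.ndarray | None = None,
) -> TumorMask:
    """MART1-verified tumor area (including nuclei) within the outline.

    Mask = MART1 pixels, plus hematoxylin components whose MART1 surround
    reaches ``surround_min`` (PHH3-negative tumor nuclei reclassified into
    MART1), plus the pixels of positive PHH3 cells; holes up to
    ``hole_max_um2`` are filled.
    """
    cfg = config or DetectConfig()
    s = class_map.um_per_px
    shape = class_map.labels.shape
    region = geometry.rasterize(outline, shape, s)
    if not region.any():
        return TumorMask(np.zeros(shape, dtype=bool), s)

    mask = class_map.mask(PixelClass.MART1).copy()

    blue = class_map.mask(PixelClass.HEMATOXYLIN)
    labels, _ = ndimage.label(blue, structure=_EIGHT)
    for region_props in measure.regionprops(labels):
        frac = _windowed_surround(
            region_props.slice, region_props.image, class_map, cfg.ring_width_um
        )
        if frac >= cfg.surround_min:
            mask[labels == region_props.label] = True

    if positive_mask is not None:
        mask |= positive_mask

    mask &= region
    hole_px = int(cfg.hole_max_um2 / (s * s))
    if hole_px > 0:
        mask = morphology.remove_small_holes(mask, max_size=hole_px)
        mask &= region
    return TumorMask(mask, s)


def detect_cells(
    image: CalibratedImage,
    outline,
    exclusions=None,
    config: RunConfig | None = None,
) -> tuple[CellSet, TumorMask]:
    """Full detection chain: stains -> fuse -> features -> score -> tumor area.

    The analysis region is the outline minus any exclusion polygons
    (epidermis/adnexa); pixels outside it are treated as background.
    Deterministic for a fixed config.
    """
    cfg = config or RunConfig()
    s = image.um_per_px
    basis = cfg.stain_basis()

    densities = deconvolve(image, basis, epsilon=cfg.classify.od_epsilon)
    sd_map = sd_filter(densities.dab, cfg.classify.sd_radius_px)
    intensity = hsi_intensity(image)
    class_map = classify_pixels(densities, sd_map, intensity, cfg.classify, s)

    analysis_geom = outline
    if exclusions:
        excl = geometry.union_all(exclusions if isinstance(exclusions, (list, tuple)) else [exclusions])
        if excl is not None:
            analysis_geom = outline.difference(excl)
    region = geometry.rasterize(analysis_geom, class_map.labels.shape, s)
    restricted = ClassMap(
        np.where(region, class_map.labels, np.int8(PixelClass.BACKGROUND)), s
    )

    labeled = fuse_chromatin(restricted, cfg.detect.dilation_radius_um)
    objects = measure_objects(labeled, restricted, densities.dab, cfg.detect.ring_width_um)
    provenance = {"config_hash": cfg.hash(), "um_per_px": s}
    cells = score_objects(objects, cfg.detect, provenance)

    pos_labels = {c.label for c in cells.positives()}
    positive_mask = np.isin(labeled, sorted(pos_labels)) if pos_labels else None
    tumor = tumor_area(restricted, analysis_geom, cfg.detect, positive_mask)
    return cells, tumor
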