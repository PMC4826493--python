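"""Synthetic dual-stain slide phantoms with exhaustive ground truth.

Renders calibrated RGB images that emulate PHH3/MART1 dual staining — blue
hematoxylin nuclei, red MART1 cytoplasm, brown DAB-positive chromatin
(including split anaphase/telophase figures), plus the classic confounders:
PHH3-positive lymphocytes without MART1 surrounding, brown pigment granules,
pale-MART1 regions and over-dark MART1 artifacts.  Colors come from the same
forward Beer-Lambert model that :mod:`mitospot.stains` inverts, so stain
deconvolution of a phantom is an approximate round trip.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from shapely.geometry import Polygon

from . import geometry
from .stains import CalibratedImage, StainBasis, forward_transmittance

# stain channel indices in the amounts array (matches stains.STAIN_ORDER)
_HEMA, _DAB, _RED = 0, 1, 2

PHASES = ("prophase", "metaphase", "anaphase", "telophase")


class PhantomSpec(BaseModel):
    """Full description of one synthetic slide."""

    model_config = ConfigDict(extra="forbid", arbitrary_types_allowed=True)

    width_um: float = 1500.0
    height_um: float = 1500.0
    um_per_px: float = 0.46  # typical 20X scan
    lesion_polygon: Optional[list[tuple[float, float]]] = None  # default: inset rectangle
    n_tumor_nuclei: int = 150
    n_positive: int = 40
    cluster_center: Optional[tuple[float, float]] = None  # default: lesion centroid
    cluster_sd_um: float = 150.0
    cluster_fraction: float = 0.7
    n_lymphocytes: int = 0
    n_pigment: int = 0
    n_dark_mart1: int = 0
    pale_mart1_fraction: float = 0.0
    phase_mix: tuple[float, float, float, float] = (0.3, 0.3, 0.2, 0.2)
    noise_sd: float = 0.0
    seed: int = 0

    # morphology / rendering knobs
    min_distance_um: float = 8.0  # center-to-center between nuclei
    chromatin_gap_um: tuple[float, float] = (2.0, 6.0)  # anaphase/telophase edge gap
    inner_margin_um: float = 12.0  # figures are sampled this far inside the lesion
    clearing_radius_um: float = 10.0  # MART1-free halo around lymphocytes
    hematoxylin_od: float = 0.85
    dab_od: float = 0.9
    mart1_od: float = 0.5
    pale_mart1_od: float = 0.25
    pigment_od: float = 1.2
    dark_mart1_red_od: float = 1.8
    dark_mart1_dab_od: float = 0.45

    @model_validator(mode="after")
    def _validate(self) -> "PhantomSpec":
        if self.width_um <= 0 or self.height_um <= 0:
            raise ValueError("phantom dimensions must be positive")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be > 0")
        for name in ("n_tumor_nuclei", "n_positive", "n_lymphocytes", "n_pigment", "n_dark_mart1"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("cluster_fraction", "pale_mart1_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if any(p < 0 for p in self.phase_mix) or abs(sum(self.phase_mix) - 1.0) > 1e-6:
            raise ValueError("phase_mix must be non-negative and sum to 1")
        if self.lesion_polygon is not None:
            geometry.validate_simple_polygon(self.lesion_polygon)
        return self

    def lesion(self) -> Polygon:
        if self.lesion_polygon is None:
            m = 60.0
            return Polygon(
                [
                    (m, m),
                    (self.width_um - m, m),
                    (self.width_um - m, self.height_um - m),
                    (m, self.height_um - m),
                ]
            )
        return geometry.validate_simple_polygon(self.lesion_polygon)

    def cluster_xy(self) -> tuple[float, float]:
        if self.cluster_center is not None:
            return self.cluster_center
        c = self.lesion().centroid
        return (c.x, c.y)


@dataclass
class GroundTruth:
    """Exact generator output: what was planted, where, and the true tumor area."""

    positive_centroids: np.ndarray  # (n, 2) of (x_um, y_um)
    confounder_centroids: list[tuple[float, float, str]]  # kind in {lymphocyte, pigment, dark}
    tumor_mask: np.ndarray  # bool (H, W)
    planted_cluster_center: tuple[float, float]


def _sample_in_polygon(
    poly: Polygon,
    n: int,
    rng: np.random.Generator,
    min_dist: float,
    existing: np.ndarray,
    gaussian: tuple[tuple[float, float], float] | None = None,
    max_attempts_per_point: int = 2000,
) -> np.ndarray:
    """Rejection-sample n points into poly, min center distance vs existing+accepted.

    gaussian = ((cx, cy), sd) switches from uniform-over-bbox to an isotropic
    Gaussian proposal (still rejected into the polygon).
    """
    if n == 0:
        return np.zeros((0, 2))
    if poly.is_empty or poly.area <= 0:
        raise ValueError("sampling polygon has zero area")
    minx, miny, maxx, maxy = poly.bounds
    pts: list[np.ndarray] = []
    occupied = existing.reshape(-1, 2)
    budget = max_attempts_per_point * n
    while len(pts) < n:
        if budget <= 0:
            raise RuntimeError(
                f"could not place {n} points at min distance {min_dist} um; density infeasible"
            )
        budget -= 1
        if gaussian is not None:
            (cx, cy), sd = gaussian
            p = rng.normal((cx, cy), max(sd, 1e-9))
        else:
            p = rng.uniform((minx, miny), (maxx, maxy))
        if not geometry.contains_points(poly, p[0], p[1]):
            continue
        if min_dist > 0:
            cand = np.vstack([occupied] + [q[None, :] for q in pts]) if (len(pts) or len(occupied)) else None
            if cand is not None and len(cand):
                if np.min(np.hypot(cand[:, 0] - p[0], cand[:, 1] - p[1])) < min_dist:
                    continue
        pts.append(p)
    return np.array(pts)


def sample_positions(spec: PhantomSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """Sample the PHH3/MART1-positive centroids for a phantom.

    A ``cluster_fraction`` share is drawn from an isotropic Gaussian around
    the planted cluster center (rejection-sampled into the lesion); the rest
    is uniform over the lesion.  Minimum center-to-center distance is
    enforced between all positives.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    lesion = spec.lesion()
    inner = lesion.buffer(-spec.inner_margin_um)
    if inner.is_empty:
        inner = lesion
    n_cluster = int(round(spec.cluster_fraction * spec.n_positive))
    none = np.zeros((0, 2))
    clustered = _sample_in_polygon(
        inner, n_cluster, rng, spec.min_distance_um, none,
        gaussian=(spec.cluster_xy(), spec.cluster_sd_um),
    )
    background = _sample_in_polygon(
        inner, spec.n_positive - n_cluster, rng, spec.min_distance_um, clustered
    )
    return np.vstack([clustered, background])


def _paint_ellipse(channel: np.ndarray, cx: float, cy: float, a: float, b: float,
                   theta: float, value: float, s: float,
                   extra_mask: np.ndarray | None = None) -> None:
    """Max-blend an ellipse (half-axes a, b um, rotation theta) into a stain channel."""
    h, w = channel.shape
    r = max(a, b)
    j0 = max(int((cx - r) / s) - 1, 0)
    j1 = min(int((cx + r) / s) + 2, w)
    i0 = max(int((cy - r) / s) - 1, 0)
    i1 = min(int((cy + r) / s) + 2, h)
    if j0 >= j1 or i0 >= i1:
        return
    xs = (np.arange(j0, j1) + 0.5) * s - cx
    ys = (np.arange(i0, i1) + 0.5) * s - cy
    xx, yy = np.meshgrid(xs, ys)
    u = (xx * np.cos(theta) + yy * np.sin(theta)) / a
    v = (-xx * np.sin(theta) + yy * np.cos(theta)) / b
    inside = u * u + v * v <= 1.0
    region = channel[i0:i1, j0:j1]
    np.copyto(region, np.maximum(region, value), where=inside)
    if extra_mask is not None:
        extra_mask[i0:i1, j0:j1] |= inside


def _pale_column_split(lesion_raster: np.ndarray, fraction: float) -> np.ndarray:
    """Leftmost columns of the lesion holding ~fraction of its area."""
    mask = np.zeros_like(lesion_raster)
    if fraction <= 0:
        return mask
    col_counts = lesion_raster.sum(axis=0)
    total = col_counts.sum()
    if total == 0:
        return mask
    cum = np.cumsum(col_counts) / total
    j_split = int(np.searchsorted(cum, fraction))
    mask[:, : j_split + 1] = lesion_raster[:, : j_split + 1]
    return mask


def render_phantom(
    spec: PhantomSpec, basis: StainBasis | None = None
) -> tuple[CalibratedImage, GroundTruth]:
    """Render a phantom slide and its exhaustive ground truth.

    Deterministic for a fixed spec (all randomness flows from ``spec.seed``).
    """
    if basis is None:
        basis = StainBasis.default()
    rng = np.random.default_rng(spec.seed)
    s = spec.um_per_px
    h = int(round(spec.height_um / s))
    w = int(round(spec.width_um / s))
    if h < 1 or w < 1:
        raise ValueError("phantom smaller than one pixel")

    lesion = spec.lesion()
    inner = lesion.buffer(-spec.inner_margin_um)
    if inner.is_empty:
        inner = lesion
    lesion_raster = geometry.rasterize(lesion, (h, w), s)

    # --- placement (fixed order => deterministic) -------------------------
    positives = sample_positions(spec, rng)
    occupied = positives
    tumor_nuclei = _sample_in_polygon(lesion, spec.n_tumor_nuclei, rng,
                                      spec.min_distance_um, occupied)
    occupied = np.vstack([occupied, tumor_nuclei])
    lymphocytes = _sample_in_polygon(inner, spec.n_lymphocytes, rng,
                                     max(spec.min_distance_um, 2 * spec.clearing_radius_um),
                                     occupied)
    occupied = np.vstack([occupied, lymphocytes])
    pigment = _sample_in_polygon(lesion, spec.n_pigment, rng,
                                 spec.min_distance_um, occupied)
    occupied = np.vstack([occupied, pigment])
    dark = _sample_in_polygon(inner, spec.n_dark_mart1, rng,
                              spec.min_distance_um, occupied)

    phases = rng.choice(len(PHASES), size=len(positives), p=list(spec.phase_mix))

    # --- stain amount maps ------------------------------------------------
    amounts = np.zeros((h, w, 3), dtype=float)
    has_tumor_cells = (spec.n_tumor_nuclei + spec.n_positive) > 0
    if has_tumor_cells:
        red = np.where(lesion_raster, spec.mart1_od, 0.0)
        pale = _pale_column_split(lesion_raster, spec.pale_mart1_fraction)
        red[pale] = spec.pale_mart1_od
        amounts[..., _RED] = red

    nucleus_mask = np.zeros((h, w), dtype=bool)  # chromatin occludes cytoplasm
    clearing_mask = np.zeros((h, w), dtype=bool)

    for (x, y) in tumor_nuclei:
        a = rng.uniform(3.5, 5.0)  # major axis 7-10 um
        b = rng.uniform(2.0, 3.0)
        _paint_ellipse(amounts[..., _HEMA], x, y, a, b, rng.uniform(0, np.pi),
                       spec.hematoxylin_od * rng.uniform(0.9, 1.1), s, nucleus_mask)

    for (x, y), ph in zip(positives, phases):
        od = spec.dab_od * rng.uniform(0.95, 1.05)
        theta = rng.uniform(0, np.pi)
        name = PHASES[ph]
        if name == "prophase":
            r = rng.uniform(2.6, 3.2)
            _paint_ellipse(amounts[..., _DAB], x, y, r, r, 0.0, od, s, nucleus_mask)
        elif name == "metaphase":
            _paint_ellipse(amounts[..., _DAB], x, y, 4.0, 1.5, theta, od, s, nucleus_mask)
        else:  # anaphase / telophase: two chromatin blobs with an edge gap
            r = rng.uniform(1.8, 2.2)
            gap = rng.uniform(*spec.chromatin_gap_um)
            off = (gap + 2 * r) / 2.0
            dx, dy = off * np.cos(theta), off * np.sin(theta)
            _paint_ellipse(amounts[..., _DAB], x - dx, y - dy, r, r, 0.0, od, s, nucleus_mask)
            _paint_ellipse(amounts[..., _DAB], x + dx, y + dy, r, r, 0.0, od, s, nucleus_mask)

    for (x, y) in lymphocytes:
        r = rng.uniform(2.3, 2.8)
        _paint_ellipse(amounts[..., _DAB], x, y, r, r, 0.0,
                       spec.dab_od * rng.uniform(0.95, 1.05), s, nucleus_mask)
        _paint_ellipse(np.zeros((h, w)), x, y, spec.clearing_radius_um,
                       spec.clearing_radius_um, 0.0, 1.0, s, clearing_mask)

    for (x, y) in pigment:
        _paint_ellipse(amounts[..., _DAB], x, y, 1.0, 1.0, 0.0, spec.pigment_od, s)

    for (x, y) in dark:
        theta = rng.uniform(0, np.pi)
        _paint_ellipse(amounts[..., _RED], x, y, 3.5, 3.0, theta, spec.dark_mart1_red_od, s)
        _paint_ellipse(amounts[..., _DAB], x, y, 3.5, 3.0, theta, spec.dark_mart1_dab_od, s)

    # chromatin and clearings carry no cytoplasmic MART1
    amounts[..., _RED][nucleus_mask] = 0.0
    amounts[..., _RED][clearing_mask] = 0.0

    # --- forward model ----------------------------------------------------
    rgb = forward_transmittance(amounts, basis)
    if spec.noise_sd > 0:
        rgb = rgb + rng.normal(0.0, spec.noise_sd, rgb.shape)
    image = CalibratedImage(np.clip(np.round(rgb), 0, 255).astype(np.uint8), s)

    tumor_mask = lesion_raster & ~clearing_mask if has_tumor_cells else np.zeros((h, w), bool)
    confounders = (
        [(float(x), float(y), "lymphocyte") for x, y in lymphocytes]
        + [(float(x), float(y), "pigment") for x, y in pigment]
        + [(float(x), float(y), "dark") for x, y in dark]
    )
    truth = GroundTruth(
        positive_centroids=positives,
        confounder_centroids=confounders,
        tumor_mask=tumor_mask,
        planted_cluster_center=spec.cluster_xy(),
    )
    return image, truth
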