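"""Stain separation and pixel classification for dual-stained slides.

The three chromogens — hematoxylin (blue nuclei), DAB (brown PHH3-positive
chromatin) and alkaline-phosphatase red (MART1 cytoplasm) — are separated by
color deconvolution in optical-density space, and every pixel is assigned to
exactly one of four classes: BACKGROUND, PHH3, MART1, HEMATOXYLIN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
from scipy import ndimage

# Published optical-density RGB vectors (Ruifrok & Johnston style constants;
# AP-red taken from the FastRed entry of the standard vector tables).
DEFAULT_STAIN_VECTORS: dict[str, tuple[float, float, float]] = {
    "hematoxylin": (0.650, 0.704, 0.286),
    "dab": (0.268, 0.570, 0.776),
    "ap_red": (0.21393921, 0.85112669, 0.47794022),
}

STAIN_ORDER = ("hematoxylin", "dab", "ap_red")


class PixelClass(IntEnum):
    BACKGROUND = 0
    PHH3 = 1
    MART1 = 2
    HEMATOXYLIN = 3


@dataclass(frozen=True)
class CalibratedImage:
    """RGB pixel array plus physical calibration (um per pixel)."""

    pixels: np.ndarray  # (H, W, 3), values in [0, 255]
    um_per_px: float

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.ndim != 3 or p.shape[2] != 3 or p.shape[0] < 1 or p.shape[1] < 1:
            raise ValueError("pixels must be a non-empty (H, W, 3) array")
        if not (self.um_per_px > 0):
            raise ValueError("um_per_px must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class StainBasis:
    """Three unit-norm optical-density vectors spanning RGB-OD space.

    Rows of ``matrix`` are the stain vectors in ``STAIN_ORDER``
    (hematoxylin, DAB, AP-red); vectors are normalized on construction.
    """

    matrix: np.ndarray
    max_condition: float = 1e3

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("stain basis must be a 3x3 matrix (rows = stains)")
        if np.any(m < 0):
            raise ValueError("stain OD vectors must be non-negative")
        norms = np.linalg.norm(m, axis=1)
        if np.any(norms == 0):
            raise ValueError("stain OD vectors must be non-zero")
        m = m / norms[:, None]
        cond = np.linalg.cond(m)
        if not np.isfinite(cond) or cond > self.max_condition:
            raise ValueError(
                f"stain basis is ill-conditioned (condition number {cond:.3g} "
                f"exceeds {self.max_condition:.3g})"
            )
        object.__setattr__(self, "matrix", m)

    @classmethod
    def default(cls) -> "StainBasis":
        return cls(np.array([DEFAULT_STAIN_VECTORS[k] for k in STAIN_ORDER]))

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)


@dataclass(frozen=True)
class StainDensities:
    """Per-pixel stain amounts, one (H, W) map per stain in STAIN_ORDER."""

    values: np.ndarray  # (H, W, 3)

    @property
    def hematoxylin(self) -> np.ndarray:
        return self.values[..., 0]

    @property
    def dab(self) -> np.ndarray:
        return self.values[..., 1]

    @property
    def ap_red(self) -> np.ndarray:
        return self.values[..., 2]


@dataclass(frozen=True)
class ClassMap:
    """Per-pixel label map over the four stain classes, same frame as the image."""

    labels: np.ndarray  # (H, W) of PixelClass values
    um_per_px: float

    def __post_init__(self) -> None:
        if np.asarray(self.labels).ndim != 2:
            raise ValueError("labels must be 2-D")
        if not (self.um_per_px > 0):
            raise ValueError("um_per_px must be > 0")

    def mask(self, cls: PixelClass) -> np.ndarray:
        return self.labels == int(cls)


def forward_transmittance(amounts: np.ndarray, basis: StainBasis) -> np.ndarray:
    """Beer-Lambert forward model: stain amounts (..., 3) -> float RGB in [0, 255].

    The phantom renderer uses this, which makes :func:`deconvolve` its
    approximate inverse (exact up to quantization and the log epsilon).
    """
    od = np.asarray(amounts, dtype=float) @ basis.matrix
    return 255.0 * np.power(10.0, -od)


def deconvolve(
    image: CalibratedImage, basis: StainBasis | None = None, epsilon: float = 1e-4
) -> StainDensities:
    """Project per-pixel optical density onto the stain basis.

    OD = -log10((I + epsilon) / 255) per channel, unmixed by the inverse of
    the basis matrix; negative unmixed densities are clipped at zero.
    """
    if basis is None:
        basis = StainBasis.default()
    rgb = np.asarray(image.pixels, dtype=float)
    od = -np.log10((rgb + epsilon) / 255.0)
    dens = od @ basis.inverse
    np.clip(dens, 0.0, None, out=dens)
    return StainDensities(dens)


def sd_filter(density_map: np.ndarray, radius_px: int) -> np.ndarray:
    """Local population standard deviation in a (2r+1)^2 window, reflect edges."""
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    x = np.asarray(density_map, dtype=float)
    if x.ndim != 2:
        raise ValueError("density map must be 2-D")
    size = 2 * radius_px + 1
    mean = ndimage.uniform_filter(x, size=size, mode="reflect")
    mean_sq = ndimage.uniform_filter(x * x, size=size, mode="reflect")
    var = mean_sq - mean * mean
    np.clip(var, 0.0, None, out=var)
    return np.sqrt(var)


def hsi_intensity(image: CalibratedImage) -> np.ndarray:
    """Intensity band of the HSI color model: per-pixel mean of R, G, B."""
    return np.asarray(image.pixels, dtype=float).mean(axis=2)


def classify_pixels(
    densities: StainDensities,
    sd_map: np.ndarray,
    intensity_map: np.ndarray,
    thresholds,
    um_per_px: float,
) -> ClassMap:
    """Deterministic threshold cascade into the four pixel classes.

    Order: BACKGROUND (bright and stain-free) -> PHH3 (brown, browner than
    blue, and either locally textured or dark) -> MART1 (red) ->
    HEMATOXYLIN (blue) -> BACKGROUND.
    """
    t = thresholds
    hema = densities.hematoxylin
    brown = densities.dab
    red = densities.ap_red
    if not (brown.shape == sd_map.shape == intensity_map.shape):
        raise ValueError("density, sd and intensity maps must share one shape")

    is_bg = (
        (intensity_map > t.background_intensity_min)
        & (hema < t.background_density_max)
        & (brown < t.background_density_max)
        & (red < t.background_density_max)
    )
    is_phh3 = (
        (brown >= t.brown_od_min)
        & (brown > hema)
        & ((sd_map >= t.sd_min) | (intensity_map <= t.dark_intensity_max))
    )
    is_red = red >= t.red_od_min
    is_blue = hema >= t.blue_od_min

    labels = np.select(
        [is_bg, is_phh3, is_red, is_blue],
        [
            int(PixelClass.BACKGROUND),
            int(PixelClass.PHH3),
            int(PixelClass.MART1),
            int(PixelClass.HEMATOXYLIN),
        ],
        default=int(PixelClass.BACKGROUND),
    ).astype(np.int8)
    return ClassMap(labels, um_per_px)
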