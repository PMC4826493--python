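"""Run configuration: every threshold and radius of the pipeline, unit-annotated.

All values live in a versioned YAML config with declared defaults; a SHA-256
hash of the canonical serialization is embedded in every output artifact so a
result can always be traced to the exact protocol that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .stains import DEFAULT_STAIN_VECTORS, STAIN_ORDER, StainBasis


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class ClassifyConfig(_StrictModel):
    """Pixel-classification thresholds (densities are optical densities)."""

    background_intensity_min: float = Field(200.0, description="I above this is background-eligible (0-255)")
    background_density_max: float = Field(0.15, ge=0, description="all stain ODs below this => background")
    brown_od_min: float = Field(0.25, ge=0, description="minimum DAB OD for PHH3 (t_brown)")
    sd_min: float = Field(0.08, ge=0, description="minimum local-SD response for PHH3 (t_sd)")
    dark_intensity_max: float = Field(120.0, ge=0, description="intensity at or below rescues dark PHH3 (t_dark)")
    red_od_min: float = Field(0.18, ge=0, description="minimum AP-red OD for MART1 (t_red)")
    blue_od_min: float = Field(0.18, ge=0, description="minimum hematoxylin OD for HEMATOXYLIN (t_blue)")
    sd_radius_px: int = Field(2, ge=1, description="SD-filter window radius in pixels")
    od_epsilon: float = Field(1e-4, gt=0, description="epsilon added before log in OD conversion")


class DetectConfig(_StrictModel):
    """Object post-processing gates (size, MART1 surrounding, intensity, irregularity)."""

    dilation_radius_um: float = Field(2.5, ge=0, description="PHH3 dilation radius fusing split chromatin [um]")
    ring_width_um: float = Field(2.0, gt=0, description="perinuclear ring width for MART1 surround [um]")
    min_area_um2: float = Field(8.0, gt=0, description="minimum object area [um^2]")
    max_area_um2: float = Field(120.0, gt=0, description="maximum object area [um^2]")
    object_od_min: float = Field(0.3, ge=0, description="minimum mean DAB OD over the object")
    surround_min: float = Field(0.3, ge=0, le=1, description="minimum MART1 fraction of the perinuclear ring")
    irregularity_max: float = Field(0.6, ge=0, le=1, description="maximum 1 - solidity")
    hole_max_um2: float = Field(100.0, ge=0, description="holes up to this area are filled in the tumor mask [um^2]")


class HotspotConfig(_StrictModel):
    """Circle-overlap heat-map hot-spot selection."""

    radius_um: float = Field(200.0, gt=0, description="circle radius [um]")
    grid_step_um: float = Field(10.0, gt=0, description="heat-map grid step [um]")
    square_side_um: float = Field(1000.0, gt=0, description="hot-spot square side [um]")
    selector: str = Field("center", description="'center' (peak of circle overlaps) or 'square' (max cells per square)")

    @field_validator("selector")
    @classmethod
    def _check_selector(cls, v: str) -> str:
        if v not in ("center", "square"):
            raise ValueError("selector must be 'center' or 'square'")
        return v


class RunConfig(_StrictModel):
    """Complete fixed protocol for one pipeline run."""

    stain_vectors: dict[str, tuple[float, float, float]] = Field(
        default_factory=lambda: dict(DEFAULT_STAIN_VECTORS)
    )
    classify: ClassifyConfig = Field(default_factory=ClassifyConfig)
    detect: DetectConfig = Field(default_factory=DetectConfig)
    hotspot: HotspotConfig = Field(default_factory=HotspotConfig)
    um_per_px: float | None = Field(None, description="calibration override [um/px]; None = use image sidecar")
    seed: int = Field(0, description="seed for any stochastic step")

    @field_validator("stain_vectors")
    @classmethod
    def _check_vectors(cls, v):
        missing = set(STAIN_ORDER) - set(v)
        if missing:
            raise ValueError(f"stain_vectors missing entries: {sorted(missing)}")
        return v

    @field_validator("um_per_px")
    @classmethod
    def _check_cal(cls, v):
        if v is not None and v <= 0:
            raise ValueError("um_per_px must be > 0")
        return v

    def stain_basis(self) -> StainBasis:
        import numpy as np

        return StainBasis(np.array([self.stain_vectors[k] for k in STAIN_ORDER]))

    def hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def validate_config(path: str | Path | None = None) -> RunConfig:
    """Load and schema-check a YAML config; an empty/absent file yields defaults.

    Unknown keys are rejected with a message naming the offending key.
    """
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        return RunConfig()
    if not isinstance(data, dict):
        raise ValueError("config file must contain a YAML mapping")
    return RunConfig.model_validate(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=True)
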