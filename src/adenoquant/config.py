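"""Validated configuration models for simulation and the analysis pipeline.

All tunable parameters of the pipeline live here so that a resolved
configuration can be serialized next to the outputs and a run can be
reproduced exactly from (config, seed).
"""
from __future__ import annotations

import enum
from typing import Dict, Optional, Tuple

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

#: Myometrial invasion depth (mm) beyond which ectopic endometrium counts as
#: adenomyosis. Strict inequality: depth must exceed this value.
INVASION_THRESHOLD_MM = 2.5


class Group(str, enum.Enum):
    adenomyosis = "adenomyosis"
    control = "control"


class TissueType(str, enum.Enum):
    eutopic_endometrium = "eutopic_endometrium"
    ectopic_endometrium = "ectopic_endometrium"
    myometrium = "myometrium"
    control_endometrium = "control_endometrium"


class CyclePhase(str, enum.Enum):
    proliferative = "proliferative"
    secretory = "secretory"


class Medication(str, enum.Enum):
    none_other = "none_other"
    antiangiogenic = "antiangiogenic"


ENDOMETRIAL_TISSUES = (
    TissueType.control_endometrium,
    TissueType.eutopic_endometrium,
    TissueType.ectopic_endometrium,
)


class NoiseConfig(BaseModel):
    """Additive acquisition-noise model on the 8-bit intensity scale."""

    model_config = ConfigDict(frozen=True)

    background: float = Field(10.0, ge=0.0, description="constant offset added to every pixel")
    sigma: float = Field(5.0, ge=0.0, description="std. dev. of Gaussian read noise")
    bleedthrough: float = Field(
        0.0, ge=0.0, le=1.0,
        description="fraction of each channel added to its spectral neighbour",
    )

    @classmethod
    def none(cls) -> "NoiseConfig":
        return cls(background=0.0, sigma=0.0, bleedthrough=0.0)


class VEGFPlan(BaseModel):
    """Planted VEGF expression for one compartment."""

    model_config = ConfigDict(frozen=True)

    fraction: float = Field(..., ge=0.0, le=1.0, description="fraction of immunoreactive cells")
    intensity_level: int = Field(..., ge=0, le=4, description="staining intensity level 0-4")


def _default_vegf() -> Dict[str, VEGFPlan]:
    return {
        "stroma": VEGFPlan(fraction=0.05, intensity_level=1),
        "glands": VEGFPlan(fraction=0.60, intensity_level=1),
        "myometrium": VEGFPlan(fraction=0.30, intensity_level=2),
    }


class SpecimenConfig(BaseModel):
    """Everything needed to render one tissue sample (specimen) and its fields.

    A specimen is one tissue sample of one patient (e.g. the eutopic
    endometrium of an adenomyosis case), imaged as ``n_fields`` multispectral
    fields of ``field_mm`` at ``pixel_um`` per pixel.
    """

    model_config = ConfigDict(validate_assignment=True)

    specimen_id: str = Field(..., min_length=1)
    group: Group
    tissue_type: TissueType
    cycle_phase: CyclePhase
    medication: Medication = Medication.none_other
    n_fields: int = Field(5, ge=1)
    field_mm: Tuple[float, float] = (0.9, 0.7)  # (width, height)
    pixel_um: float = Field(0.5, gt=0.0)
    planted_bvd: float = Field(25.0, ge=0.0, description="blood vessels per mm^2, primary compartment")
    planted_lvd: float = Field(8.0, ge=0.0, description="lymph vessels per mm^2, primary compartment")
    planted_mature_fraction: float = Field(0.6, ge=0.0, le=1.0)
    planted_vegf: Dict[str, VEGFPlan] = Field(default_factory=_default_vegf)
    myo_bvd: float = Field(12.0, ge=0.0, description="myometrial background BVD in ectopic fields")
    myo_lvd: float = Field(3.0, ge=0.0, description="myometrial background LVD in ectopic fields")
    lesion_depth_mm: float = Field(0.0, ge=0.0)
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    seed: int = Field(0, ge=0)

    @field_validator("field_mm")
    @classmethod
    def _positive_field(cls, v: Tuple[float, float]) -> Tuple[float, float]:
        if v[0] <= 0 or v[1] <= 0:
            raise ValueError("field_mm must be positive")
        return v

    @field_validator("planted_vegf")
    @classmethod
    def _known_compartments(cls, v: Dict[str, VEGFPlan]) -> Dict[str, VEGFPlan]:
        allowed = {"stroma", "glands", "myometrium"}
        unknown = set(v) - allowed
        if unknown:
            raise ValueError(f"unknown VEGF compartments: {sorted(unknown)}")
        return v

    @property
    def field_px(self) -> Tuple[int, int]:
        """Field shape in pixels, (rows, cols) = (height, width)."""
        w_mm, h_mm = self.field_mm
        px_mm = self.pixel_um / 1000.0
        return (int(round(h_mm / px_mm)), int(round(w_mm / px_mm)))

    @property
    def primary_compartment(self) -> str:
        """Compartment to which planted_bvd / planted_lvd refer."""
        return "myometrium" if self.tissue_type is TissueType.myometrium else "stroma"


class SegmentationParams(BaseModel):
    method: str = Field("otsu", pattern="^(otsu|fixed)$")
    fixed_thresholds: Dict[str, float] = Field(default_factory=dict)
    min_object_um2: float = Field(5.0, ge=0.0)
    closing_radius_um: float = Field(1.0, ge=0.0)
    connectivity: int = Field(8)
    min_class_separation: float = Field(32.0, ge=0.0)
    gland_min_dapi_fraction: float = Field(0.01, ge=0.0, le=1.0)
    small_hole_max_um2: float = Field(800.0, ge=0.0)

    @field_validator("connectivity")
    @classmethod
    def _conn(cls, v: int) -> int:
        if v not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        return v

    def min_object_px(self, pixel_um: float) -> int:
        return max(1, int(round(self.min_object_um2 / pixel_um**2)))

    def closing_radius_px(self, pixel_um: float) -> int:
        return max(1, int(round(self.closing_radius_um / pixel_um))) if self.closing_radius_um > 0 else 0

    def small_hole_max_px(self, pixel_um: float) -> int:
        return int(round(self.small_hole_max_um2 / pixel_um**2))


class QuantParams(BaseModel):
    min_area_um2: float = Field(5.0, ge=0.0)
    lymph_overlap_cut: float = Field(0.5, ge=0.0, le=1.0)
    maturity_dilation_um: float = Field(3.5, gt=0.0)
    maturity_overlap_cut: float = Field(0.1, ge=0.0, le=1.0)

    def maturity_dilation_px(self, pixel_um: float) -> int:
        return max(1, int(round(self.maturity_dilation_um / pixel_um)))


class IHSParams(BaseModel):
    vegf_threshold: float = Field(25.0, ge=0.0)
    dapi_threshold: float = Field(60.0, ge=0.0)
    cell_radius_um: float = Field(3.0, gt=0.0)
    calibration: Tuple[float, float, float, float] = (25.0, 75.0, 125.0, 175.0)

    @field_validator("calibration")
    @classmethod
    def _ascending(cls, v: Tuple[float, ...]) -> Tuple[float, ...]:
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("calibration cutpoints must be strictly ascending")
        return v

    def cell_radius_px(self, pixel_um: float) -> int:
        return max(1, int(round(self.cell_radius_um / pixel_um)))


class StatsParams(BaseModel):
    alpha: float = Field(0.05, gt=0.0, lt=1.0)
    stratify_by: str = Field("cycle_phase", pattern="^(cycle_phase|medication|pooled)$")
    include_pooled: bool = False
    holm: bool = False
    mwu_method: str = Field("auto", pattern="^(auto|exact|normal_approx)$")


class PresetOverrides(BaseModel):
    """Knobs for scaling the paper-like cohort to a problem size."""

    n_adenomyosis: int = Field(19, ge=1)
    n_control: int = Field(19, ge=1)
    n_fields: int = Field(5, ge=1)
    pixel_um: float = Field(0.5, gt=0.0)
    field_mm: Tuple[float, float] = (0.9, 0.7)
    noise: NoiseConfig = Field(default_factory=NoiseConfig)


class PipelineConfig(BaseModel):
    """Resolved configuration of a full pipeline run."""

    input_dir: Optional[str] = None
    preset: Optional[str] = None
    preset_overrides: PresetOverrides = Field(default_factory=PresetOverrides)
    channel_aliases: Dict[str, str] = Field(default_factory=dict)
    pixel_um_override: Optional[float] = None
    segmentation: SegmentationParams = Field(default_factory=SegmentationParams)
    quantification: QuantParams = Field(default_factory=QuantParams)
    ihs: IHSParams = Field(default_factory=IHSParams)
    stats: StatsParams = Field(default_factory=StatsParams)
    out_dir: str = "adenoquant_out"
    seed: int = Field(0, ge=0)
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _source(self) -> "PipelineConfig":
        if self.preset is not None and self.preset != "paper-like":
            raise ValueError(f"unknown preset {self.preset!r}; available: 'paper-like'")
        return self
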