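"""Structured, validated configuration for the whole pipeline.

Every stage parameter has the study default (bone Poisson 0.3, disc
Poisson 0.1, 2 mm mesh edge, 60 N force target with 0.1% tolerance,
Cook multiplier 4, averaging radius = registration RMSE); a YAML file
overrides any subset.  Invalid values fail loudly with the offending
field names (pydantic validation).
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, model_validator

from .calibration import DiscModel
from .materials import MaterialLaw
from .phantom import PhantomSpec
from .validation import ValidationConfig

__all__ = ["PipelineConfig", "load_config"]


class MaterialSection(BaseModel):
    cal_intercept: float = -0.016404
    cal_slope: float = Field(0.00085164, gt=0)
    ash_intercept: float = 0.079
    ash_slope: float = Field(0.877, gt=0)
    app_ratio: float = Field(0.6, gt=0, le=1)
    mod_coeff: float = Field(4730.0, gt=0)
    mod_exp: float = Field(1.56, gt=0)
    nu_bone: float = Field(0.3, ge=0, lt=0.5)
    e_floor: float = Field(0.01, gt=0)
    samples_per_element: int = Field(8, ge=1)

    def law(self) -> MaterialLaw:
        return MaterialLaw(**self.model_dump(exclude={"samples_per_element"}))


class PhantomSection(BaseModel):
    radius: float = Field(6.0, gt=0)
    shell_wall: float = Field(0.9, gt=0)
    full_height: float = Field(14.0, gt=0)
    half_height: float = Field(7.0, gt=0)
    disc_height: float = Field(4.0, gt=0)
    background_vbmd: float = 0.520
    osteoporotic_vbmd: float = 0.076
    lesion_vbmd: float = 0.105
    mesh_edge: float = Field(2.0, gt=0)
    order: int = 10
    anterior_offset_fraction: float = Field(0.10, ge=0, le=0.5)
    target_load: float = Field(60.0, gt=0)
    compression: float = 3.39
    flexion_deg: float = 8.0
    lateral_bending_deg: float = 4.0
    axial_rotation_deg: float = 7.0
    lateral_shift: tuple[float, float] = (1.9, 3.8)
    dic_noise_random: float = Field(0.025, ge=0)
    dic_noise_systematic: float = Field(0.010, ge=0)

    def spec(self, seed: int = 0) -> PhantomSpec:
        return PhantomSpec(seed=seed, **self.model_dump())


class CalibrationSection(BaseModel):
    nu_disc: float = Field(0.1, ge=0, lt=0.5)
    bracket: tuple[float, float] = (0.1, 100.0)
    rel_tol: float = Field(0.001, gt=0)   # the 0.1% force criterion
    max_iter: int = Field(50, ge=1)

    @model_validator(mode="after")
    def _ordered_bracket(self):
        lo, hi = self.bracket
        if not (0 < lo < hi):
            raise ValueError("bracket must be positive and ordered")
        return self

    def disc(self) -> DiscModel:
        return DiscModel(nu_disc=self.nu_disc, bracket=tuple(self.bracket))


class RegistrationSection(BaseModel):
    max_iter: int = Field(100, ge=1)
    tol: float = Field(1e-6, gt=0)
    misregistration_deg: float = 1.0    # known perturbation exercised in-pipeline
    misregistration_mm: float = 0.5


class ValidationSection(BaseModel):
    radius: float | None = None          # None -> registration RMSE (floored)
    radius_floor: float = Field(0.1, gt=0)
    cook_multiplier: float = Field(4.0, gt=0)
    min_points_per_sphere: int = Field(1, ge=1)
    components: tuple[str, ...] = ("RL", "AP", "SI")

    def cfg(self, registration_rmse: float | None = None) -> ValidationConfig:
        r = self.radius
        if r is None:
            r = max(registration_rmse or 0.0, self.radius_floor)
        return ValidationConfig(
            radius=r, cook_multiplier=self.cook_multiplier,
            components=tuple(self.components),
            min_points_per_sphere=self.min_points_per_sphere,
        )


class PipelineConfig(BaseModel):
    seed: int = 0
    material: MaterialSection = MaterialSection()
    phantom: PhantomSection = PhantomSection()
    calibration: CalibrationSection = CalibrationSection()
    registration: RegistrationSection = RegistrationSection()
    validation: ValidationSection = ValidationSection()
    # component label -> signed axis of the model frame
    axes: dict[str, str] = {"RL": "+x", "AP": "+y", "SI": "+z"}


def load_config(path=None, **overrides) -> PipelineConfig:
    data = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    data.update(overrides)
    return PipelineConfig(**data)
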