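"""Pipeline configuration schema.

Unit-bearing fields carry the unit in their name (``fluence_photons_per_um2``)
so that the dosimetry and electron-count conversions cannot silently receive
the wrong scale.  Validation errors report the offending field path.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

from .geometry_phantom import ExperimentGeometry, PhantomSpec, default_phantom_spec


class GeometryConfig(BaseModel):
    energy_kev: float = 8.0
    camera_length_m: float = 5.29
    pixel_pitch_um: float = 55.0
    detector_side: int = 516
    beamstop_radius_px: float = 6.0
    gap_width_px: int = 4
    fluence_photons_per_um2: float = 4.99e9
    exposure_s: float = 100.0

    def build(self) -> ExperimentGeometry:
        return ExperimentGeometry(
            photon_energy_kev=self.energy_kev,
            camera_length_m=self.camera_length_m,
            pixel_pitch_um=self.pixel_pitch_um,
            detector_side=self.detector_side,
            beamstop_radius_px=self.beamstop_radius_px,
            gap_width_px=self.gap_width_px,
            fluence_per_um2=self.fluence_photons_per_um2,
            exposure_s=self.exposure_s,
        )


class PhantomConfig(BaseModel):
    """Tachyzoite-like phantom, optionally scaled down for desk-size grids."""

    scale: float = Field(1.0, gt=0)
    voxel_size_nm: float = Field(30.0, gt=0)
    grid_side: int = Field(128, gt=0)
    base_density: float = Field(1.0, ge=0)
    texture_amplitude: float = Field(0.05, ge=0)
    edge_sigma_nm: float = Field(30.0, ge=0)
    total_electrons: float | None = Field(None, gt=0)
    rng_seed: int = 0

    def build(self) -> PhantomSpec:
        spec = default_phantom_spec(scale=self.scale)
        spec.base_density = self.base_density
        spec.texture_amplitude = self.texture_amplitude
        spec.edge_sigma_um = self.edge_sigma_nm * 1e-3
        spec.rng_seed = self.rng_seed
        return spec


class AcquisitionConfig(BaseModel):
    n_positive: int = 37
    n_negative: int = 34
    max_angle_deg: float = 50.9
    max_angle_negative_deg: float | None = 60.6
    scheme: str = "est"
    poisson_noise: bool = True
    background_level: float = Field(0.0, ge=0)
    noise_seed: int = 0

    @field_validator("scheme")
    @classmethod
    def _scheme_known(cls, v: str) -> str:
        if v not in ("est", "uniform"):
            raise ValueError("scheme must be 'est' or 'uniform'")
        return v


class AssemblyConfig(BaseModel):
    grid_side: int | None = None
    idw_power: float = Field(2.0, gt=0)
    idw_radius: float = Field(0.71, gt=0)


class ReconstructionConfig(BaseModel):
    n_iterations: int = Field(1000, gt=0)
    n_seeds: int = Field(100, gt=0)
    keep_best: int = Field(10, gt=0)
    beta: float = Field(0.9, gt=0, lt=2)
    n_filter_stages: int = Field(10, gt=0)
    positivity: bool = True
    support_threshold: float = Field(0.1, gt=0, lt=1)
    support_dilation: int = Field(2, ge=0)
    rng_seed: int = 0


class QuantifyConfig(BaseModel):
    mass_attenuation_cm2_g: float = Field(9.9, gt=0)
    segment_threshold_frac: float = Field(0.10, gt=0, lt=1)
    prtf_threshold: float = Field(0.5, gt=0, le=1)


class PipelineConfig(BaseModel):
    geometry: GeometryConfig = GeometryConfig()
    phantom: PhantomConfig = PhantomConfig()
    acquisition: AcquisitionConfig = AcquisitionConfig()
    assembly: AssemblyConfig = AssemblyConfig()
    reconstruction: ReconstructionConfig = ReconstructionConfig()
    quantify: QuantifyConfig = QuantifyConfig()


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(raw)
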