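"""Layered, strictly validated run configuration.

All physical quantities are SI internally; boundary-friendly units
(mL/min flow rates, mm geometry keys suffixed ``_mm``) are converted once
at parse time.  Unknown keys are rejected so unit mistakes fail loudly.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryConfig(_Strict):
    lumen_diameter_mm: float = 2.0
    wall_outer_diameter_mm: float = 4.0
    construct_width_mm: float = 14.0
    construct_height_mm: float = 25.0
    trunk_length_mm: float = 10.0
    branch_length_mm: float = 8.0
    branch_half_angle_deg: float = 30.0
    spacing_mm: float = 0.125
    target_roi_radius_mm: float = 2.0

    def spec(self):
        from .geometry import BifurcationSpec

        return BifurcationSpec(
            lumen_diameter=self.lumen_diameter_mm * 1e-3,
            wall_outer_diameter=self.wall_outer_diameter_mm * 1e-3,
            construct_width=self.construct_width_mm * 1e-3,
            construct_height=self.construct_height_mm * 1e-3,
            trunk_length=self.trunk_length_mm * 1e-3,
            branch_length=self.branch_length_mm * 1e-3,
            branch_half_angle_deg=self.branch_half_angle_deg,
        )


class MagnetConfig(_Strict):
    Br_T: float = 1.3
    radius_mm: float = 2.0
    thickness_mm: float = 2.4
    gap_mm: float = 0.4          # near face to top lumen surface

    def magnet(self, face_center=(0.0, 0.0), axis=(0.0, -1.0)):
        from .magnet import DiscMagnet

        return DiscMagnet(Br=self.Br_T, R=self.radius_mm * 1e-3,
                          D=self.thickness_mm * 1e-3,
                          face_center=tuple(face_center), axis=tuple(axis))


class FlowSectionConfig(_Strict):
    density_kg_m3: float = 1000.0
    viscosity_pa_s: float = 1.0e-3
    mean_ml_min: float = 2.0
    period_s: float = 0.48
    q_forward_ml_min: float = 6.5
    q_reverse_ml_min: float = -2.0
    t_peak_forward_s: float = 0.07
    t_peak_reverse_s: float = 0.24
    n_cycles: int = 3

    def flow_config(self):
        from .hemodynamics import FlowConfig

        return FlowConfig(density=self.density_kg_m3,
                          viscosity=self.viscosity_pa_s,
                          n_cycles=self.n_cycles)

    def waveform(self):
        from .hemodynamics import make_waveform

        return make_waveform(mean=self.mean_ml_min, period=self.period_s,
                             q_forward=self.q_forward_ml_min,
                             q_reverse=self.q_reverse_ml_min,
                             t_peak_forward=self.t_peak_forward_s,
                             t_peak_reverse=self.t_peak_reverse_s)


class ParticlesConfig(_Strict):
    n: int = 2000
    mean_d_nm: float = 78.9
    sd_d_nm: float = 21.2
    cores_per_particle: float = 1500.0
    core_diameter_nm: float = 10.0
    chi: float = 20.0
    Msat_A_m: float = 4.8e5
    temperature_K: float = 310.0
    duration_s: float = 120.0
    dt_s: float = 0.02
    capture_flow_ml_min: float = 0.02
    # capture ROI covers the lumen walls under the raised in-plane magnet
    # footprint (the ROI's purpose per the geometry module)
    target_roi_radius_mm: float = 3.0


class QuantConfig(_Strict):
    pixel_size_um: float = 1.0
    min_area_px: int = 5
    threshold: str = "otsu"


class CellcycleConfig(_Strict):
    fix_ratio: float | None = None


class SynthConfig(_Strict):
    master_seed: int = 0


class RunConfig(_Strict):
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    magnet: MagnetConfig = Field(default_factory=MagnetConfig)
    flow: FlowSectionConfig = Field(default_factory=FlowSectionConfig)
    particles: ParticlesConfig = Field(default_factory=ParticlesConfig)
    quant: QuantConfig = Field(default_factory=QuantConfig)
    cellcycle: CellcycleConfig = Field(default_factory=CellcycleConfig)
    synth: SynthConfig = Field(default_factory=SynthConfig)
    master_seed: int = 0
    output_dir: str = "results"
    log_level: str = "INFO"


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML config file (strict schema); missing file -> defaults."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update(overrides)
    return RunConfig(**data)
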