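"""Schema-validated pipeline configuration (YAML).

Unknown keys are rejected so a typo in a config file fails loudly instead
of silently falling back to a default.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import simulator
from .behavior import SmoothParams
from .fusion import FusionParams
from .geometry import CageModel
from .lidar import ClusterParams


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CageConfig(_Strict):
    width: float = 820.0
    depth: float = 610.0
    height: float = 1578.0

    def build(self) -> CageModel:
        return CageModel(self.width, self.depth, self.height)


class RigConfig(_Strict):
    standoff: float = 1000.0
    heights: tuple[float, float] = (900.0, 1900.0)
    spread: float = 600.0
    focal: tuple[float, float] = (620.0, 620.0)
    image_size: tuple[int, int] = (1920, 1080)


class ClusterConfig(_Strict):
    tolerance: float = 50.0
    s1: float = 100.0
    s2: float = 500.0
    voxel_size: float = 30.0
    gate: float = 300.0
    dropout_window: float = 1.0

    def build(self) -> ClusterParams:
        return ClusterParams(self.tolerance, self.s1, self.s2)


class FusionConfig(_Strict):
    gate: float = 300.0
    switch_gate: float = 200.0
    max_gap: float = 1.0

    def build(self) -> FusionParams:
        return FusionParams(self.gate, self.switch_gate, self.max_gap)


class SmoothConfig(_Strict):
    window: float = 50.0
    slide: float = 5.0
    sigma: float | None = None
    threshold: float = 0.5

    def build(self) -> SmoothParams:
        return SmoothParams(self.window, self.slide, self.sigma, self.threshold)


class ZoneConfig(_Strict):
    name: str
    lo: tuple[float, float, float]
    hi: tuple[float, float, float]


class IdentityConfig(_Strict):
    match_gate: float = 200.0
    min_confidence: float = 0.0
    vote: str = "windowed"


class SimulatorConfig(_Strict):
    preset: str = "family3"
    horizon: float = 120.0
    pixel_noise: float = 1.0
    face_accuracy: float = 0.98
    face_rate: float = 0.2

    def sensor_spec(self) -> simulator.SensorSpec:
        return simulator.SensorSpec(
            camera=simulator.CameraSensorSpec(pixel_noise=self.pixel_noise),
            face=simulator.FaceSensorSpec(rate=self.face_rate, accuracy=self.face_accuracy),
        )


class PipelineConfig(_Strict):
    seed: int = 0
    tick_rate: float = 7.4
    max_residual: float = 15.0
    cage: CageConfig = Field(default_factory=CageConfig)
    rig: RigConfig = Field(default_factory=RigConfig)
    cluster: ClusterConfig = Field(default_factory=ClusterConfig)
    fusion: FusionConfig = Field(default_factory=FusionConfig)
    smooth: SmoothConfig = Field(default_factory=SmoothConfig)
    identity: IdentityConfig = Field(default_factory=IdentityConfig)
    zones: list[ZoneConfig] | None = None
    simulator: SimulatorConfig = Field(default_factory=SimulatorConfig)


def load_config(path: str | Path | None = None) -> PipelineConfig:
    if path is None:
        return PipelineConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig.model_validate(data)
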