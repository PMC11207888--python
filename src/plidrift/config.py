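"""Validated pipeline configuration (YAML-backed, unknown keys rejected)."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .bands import DEFAULT_BANDS, BandDefinition
from .montage import MontageSpec, make_default_montage
from .simulate import PlantedEdge, SimulationConfig
from .trend import ThresholdConfig


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PlantedEdgeSettings(_Strict):
    channel_a: str
    channel_b: str
    band: str
    phase_lag: float
    base_coupling: float
    coupling_slope: float
    subjects: list[int] | None = None

    def build(self) -> PlantedEdge:
        return PlantedEdge(
            channel_a=self.channel_a,
            channel_b=self.channel_b,
            band=self.band,
            phase_lag=self.phase_lag,
            base_coupling=self.base_coupling,
            coupling_slope=self.coupling_slope,
            subjects=tuple(self.subjects) if self.subjects is not None else None,
        )


class SimulationSettings(_Strict):
    n_subjects: int = 21
    n_epochs: int = 20
    epoch_duration_s: float = 300.0
    sampling_rate: float = 256.0
    noise_sd: float = 1.0
    component_sd: float = 1.0
    common_source_gain: float = 0.5
    planted_edges: list[PlantedEdgeSettings] = Field(default_factory=list)

    def build(self, montage: MontageSpec, bands: tuple[BandDefinition, ...],
              master_seed: int) -> SimulationConfig:
        return SimulationConfig(
            n_subjects=self.n_subjects,
            montage=montage,
            sampling_rate=self.sampling_rate,
            n_epochs=self.n_epochs,
            epoch_duration=self.epoch_duration_s,
            planted_edges=tuple(e.build() for e in self.planted_edges),
            noise_sd=self.noise_sd,
            component_sd=self.component_sd,
            common_source_gain=self.common_source_gain,
            bands=bands,
            master_seed=master_seed,
        )


class PreprocessingSettings(_Strict):
    target_rate: float = 256.0
    band_low: float = 1.0
    band_high: float = 45.0
    notch_hz: float | None = 50.0
    epoch_window_s: float = 300.0
    epoch_step_s: float = 150.0
    epoch_trim_s: float = 300.0
    qc_threshold_db: float = 6.0
    reference_labels: list[str] = Field(default_factory=lambda: ["M1", "M2"])


class BandSettings(_Strict):
    low: float
    high: float
    nominal_low: float | None = None


class ThresholdSettings(_Strict):
    r2_min: float = 0.25
    alpha: float = 0.05

    def build(self) -> ThresholdConfig:
        return ThresholdConfig(r2_min=self.r2_min, alpha=self.alpha)


class GroupSettings(_Strict):
    shared_threshold_fraction: float = 0.40


class InputSettings(_Strict):
    kind: str = "synthetic"  # "synthetic" | "files"
    paths: list[str] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check(self):
        if self.kind not in ("synthetic", "files"):
            raise ValueError(f"input.kind must be 'synthetic' or 'files', got {self.kind!r}")
        if self.kind == "files" and not self.paths:
            raise ValueError("input.kind='files' requires at least one path")
        return self


class PipelineConfig(_Strict):
    """Top-level run configuration; see ``docs/methods.md`` for semantics."""

    input: InputSettings = Field(default_factory=InputSettings)
    simulation: SimulationSettings = Field(default_factory=SimulationSettings)
    preprocessing: PreprocessingSettings = Field(default_factory=PreprocessingSettings)
    bands: dict[str, BandSettings] | None = None
    thresholds: ThresholdSettings = Field(default_factory=ThresholdSettings)
    group: GroupSettings = Field(default_factory=GroupSettings)
    master_seed: int = 0
    log_level: str = "INFO"

    def band_definitions(self) -> tuple[BandDefinition, ...]:
        if self.bands is None:
            return DEFAULT_BANDS
        return tuple(
            BandDefinition(name, spec.low, spec.high, nominal_low=spec.nominal_low)
            for name, spec in self.bands.items()
        )

    def simulation_config(self) -> SimulationConfig:
        return self.simulation.build(
            make_default_montage(), self.band_definitions(), self.master_seed
        )

    def threshold_config(self) -> ThresholdConfig:
        return self.thresholds.build()

    def snapshot(self) -> dict:
        return self.model_dump(mode="json")


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(raw)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.snapshot(), fh, sort_keys=False)
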