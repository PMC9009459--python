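"""Schema-validated run configuration (YAML) for the CLI workflows.

Unknown keys are rejected so typos in config files fail loudly with field
paths rather than silently falling back to defaults.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .beamline import BeamConfig, FragmentModelConfig, PhantomConfig, SpeciesConfig
from .geometry import StackGeometry, make_stack

__all__ = ["RunConfig", "load_config", "config_hash"]


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class BeamBlock(_Block):
    n_primaries: int = 200_000
    spot_sigma_x: float = 1.3
    spot_sigma_y: float = 1.6
    nominal_range: float = 105.2
    range_straggling_sigma: float = 1.0
    spot_shift_x: float = 0.0
    spot_shift_y: float = 0.0

    def to_obj(self, seed: int) -> BeamConfig:
        return BeamConfig(seed=seed, **self.model_dump())


class PhantomBlock(_Block):
    extent_x: float = 153.5
    extent_y: float = 106.5
    extent_z: float = 180.5
    shell_thickness: float = 6.75
    voxel_size: float = 1.0

    def to_obj(self) -> PhantomConfig:
        return PhantomConfig(**self.model_dump())


class SpeciesBlock(_Block):
    name: str
    relative_yield: float = Field(ge=0)
    angular_sigma: float = Field(gt=0)
    exit_scatter_sigma: float = Field(ge=0)
    primary_vertex_fraction: float = Field(ge=0, le=1)
    out_of_field_fraction: float = Field(default=0.0, ge=0, le=1)
    secondary_smear_sigma: float = Field(default=5.0, ge=0)


class FragmentsBlock(_Block):
    species: list[SpeciesBlock] | None = None
    mean_free_path: float = 250.0

    def to_obj(self) -> FragmentModelConfig:
        if self.species is None:
            return FragmentModelConfig(mean_free_path=self.mean_free_path)
        return FragmentModelConfig(
            species=tuple(SpeciesConfig(**s.model_dump()) for s in self.species),
            mean_free_path=self.mean_free_path,
        )


class GeometryBlock(_Block):
    angle_to_beam: float = 30.0
    distance_from_isocenter: float = 140.0
    plane_spacing: float = 50.0
    half_width: float = 25.0
    half_height: float = 25.0
    pixel_pitch: float = 0.055
    dual_stack: bool = False

    def to_obj(self) -> tuple[StackGeometry, StackGeometry | None]:
        kw = self.model_dump()
        kw.pop("dual_stack")
        first = make_stack(side=+1, **kw)
        second = make_stack(side=-1, **kw) if self.dual_stack else None
        return first, second


class AcquisitionBlock(_Block):
    gate_ns: float = 10.0
    event_period_ns: int = 1000
    time_jitter_ns: float = 0.0
    spm_half_aperture: float = 25.0


class AnalysisBlock(_Block):
    bin_width: float = 1.0
    margin: float = 40.0
    fit_window: tuple[float, float] | None = None
    parallel_tol: float = 1e-6
    miss_cut: float | None = None
    boundary_threshold: float = 0.5


class RunConfig(_Block):
    beam: BeamBlock = Field(default_factory=BeamBlock)
    phantom: PhantomBlock = Field(default_factory=PhantomBlock)
    fragments: FragmentsBlock = Field(default_factory=FragmentsBlock)
    geometry: GeometryBlock = Field(default_factory=GeometryBlock)
    acquisition: AcquisitionBlock = Field(default_factory=AcquisitionBlock)
    analysis: AnalysisBlock = Field(default_factory=AnalysisBlock)
    seed: int = 0

    @field_validator("seed")
    @classmethod
    def _seed_range(cls, v):
        if not 0 <= v < 2**31:
            raise ValueError("seed must be in [0, 2^31)")
        return v


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(raw)


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of a run configuration, embedded in outputs."""
    blob = json.dumps(cfg.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
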