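"""Study configuration: schema-validated, fully serialisable, hashable.

A :class:`StudyConfig` captures everything a run needs — phantom
parameters, error model, radiobiology constants, beam geometry, objective
sets, optimiser settings and seeds — so that a study is reproducible from
the YAML file alone.  Unknown keys are rejected.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .dose import BeamGeometry, EngineParams
from .phantom import PhantomConfig
from .planning import (
    DEFAULT_OAR_OBJECTIVES,
    DEFAULT_UNIFORM_OBJECTIVES,
    ObjectiveSpec,
    OptimizerSettings,
)
from .radiobiology import AlphaDistribution, RadiobioParams, discretize_alpha
from .uncertainty import ErrorModel

__all__ = ["StudyConfig", "load_config", "save_config", "default_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PhantomSection(_Strict):
    shape: tuple[int, int, int] = (48, 48, 24)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.5)
    n_lesions: int = 2
    lesion_radius_range: tuple[float, float] = (5.0, 9.0)
    density_background: float = 150.0
    density_lesion: float = 250.0
    noise_corr_mm: float = 6.0

    def build(self) -> PhantomConfig:
        return PhantomConfig(**self.model_dump())


class ErrorSection(_Strict):
    """Per-axis (AP, LR, SI) geometric error model in mm."""

    mean: tuple[float, float, float] = (-0.4, 0.2, 0.1)
    sigma_sys: tuple[float, float, float] = (2.56, 2.47, 2.58)
    sigma_rand: tuple[float, float, float] = (1.26, 0.67, 1.18)

    def build(self) -> ErrorModel:
        return ErrorModel(self.mean, self.sigma_sys, self.sigma_rand)


class RadiobioSection(_Strict):
    alpha_mean: float = 0.15
    alpha_sd: float = 0.04
    alpha_samples: int = 11
    alpha_moments_of_log: bool = False
    alpha_beta: float = 3.1
    n_fractions: int = 39
    prescription_gy: float = 78.0
    t_pot_days: float = 42.0

    def build_params(self) -> RadiobioParams:
        return RadiobioParams(
            alpha_beta=self.alpha_beta,
            n_fractions=self.n_fractions,
            prescription_gy=self.prescription_gy,
            t_pot_days=self.t_pot_days,
        )

    def build_alpha(self) -> AlphaDistribution:
        return discretize_alpha(
            self.alpha_mean, self.alpha_sd, self.alpha_samples,
            self.alpha_moments_of_log,
        )


class BeamSection(_Strict):
    gantry_angles_deg: tuple[float, ...] = (0.0, 40.0, 80.0, 110.0, 250.0, 280.0, 310.0)
    beamlet_width_mm: float = 2.5
    sad_mm: float = 1000.0
    mu_per_mm: float = 0.005
    buildup_mm: float = 15.0
    penumbra_sd_mm: float = 3.0
    cutoff_rel: float = 1e-4

    def build_geometry(self) -> BeamGeometry:
        return BeamGeometry(self.gantry_angles_deg, self.beamlet_width_mm, self.sad_mm)

    def build_engine(self) -> EngineParams:
        return EngineParams(
            mu_per_mm=self.mu_per_mm, buildup_mm=self.buildup_mm,
            penumbra_sd_mm=self.penumbra_sd_mm, cutoff_rel=self.cutoff_rel,
        )


class ObjectiveItem(_Strict):
    structure: str
    kind: Literal["square_deviation", "square_overdose", "square_underdose", "dose_volume"]
    d_ref: float
    weight: float = 1.0
    v_ref: float | None = None

    def build(self) -> ObjectiveSpec:
        return ObjectiveSpec(**self.model_dump())


class OptimizerSection(_Strict):
    max_iter: int = 500
    ftol: float = 1e-9
    n_shift_nodes: int = 5

    def build(self) -> OptimizerSettings:
        return OptimizerSettings(
            max_iter=self.max_iter, ftol=self.ftol, n_shift_nodes=self.n_shift_nodes
        )


def _specs_to_items(specs) -> list[dict]:
    return [
        {"structure": s.structure, "kind": s.kind, "d_ref": s.d_ref,
         "weight": s.weight, "v_ref": s.v_ref}
        for s in specs
    ]


class StudyConfig(_Strict):
    """Complete study specification (see module docstring)."""

    n_patients: int = Field(5, ge=1)
    master_seed: int = 42
    target_tcp: float = Field(0.95, gt=0, lt=1)
    phantom: PhantomSection = PhantomSection()
    errors: ErrorSection = ErrorSection()
    radiobiology: RadiobioSection = RadiobioSection()
    beams: BeamSection = BeamSection()
    uniform_objectives: list[ObjectiveItem] = Field(
        default_factory=lambda: [ObjectiveItem(**d) for d in _specs_to_items(DEFAULT_UNIFORM_OBJECTIVES)]
    )
    oar_objectives: list[ObjectiveItem] = Field(
        default_factory=lambda: [ObjectiveItem(**d) for d in _specs_to_items(DEFAULT_OAR_OBJECTIVES)]
    )
    optimizer: OptimizerSection = OptimizerSection()
    output_dir: str = "study_output"

    def config_hash(self) -> str:
        """Stable SHA-256 of the canonical JSON serialisation (short form)."""
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def default_config() -> StudyConfig:
    """The shipped preset: 78 Gy / 39 fx, 7-field IMRT, combined prostate
    error model, five synthetic patients."""
    return StudyConfig()


def load_config(path: str | Path) -> StudyConfig:
    """Read and validate a YAML study configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    return StudyConfig.model_validate(raw)


def save_config(config: StudyConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(mode="json"), sort_keys=False))
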