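"""JSON run configuration: schema-validated, round-trippable.

A :class:`RunConfig` names (or inlines) the antibody and disease
parameterization, the dose regimen, and optional geometry / transfer /
solver overrides.  Unknown keys are rejected so that typos fail loudly.
"""

from __future__ import annotations

import json
from pathlib import Path
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .geometry import BrainGeometry, ValidationError
from .pbpk import BrainTransferParams, DoseRegimen
from .presets import ANTIBODIES, DISEASES, get_antibody, get_disease
from .species import Antibody
from .trials import TrialSpec


class AntibodyConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str = "custom"
    kd_mono_nM: float = Field(gt=0)
    kd_oligo_nM: float = Field(gt=0)
    half_life_h: float = Field(gt=0)

    def build(self) -> Antibody:
        return Antibody(self.name, self.kd_mono_nM, self.kd_oligo_nM, self.half_life_h)


class RegimenConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    dose_mg: float | None = None
    dose_mg_per_kg: float | None = None
    body_weight_kg: float = 70.0
    n_doses: int = Field(default=13, ge=1)
    interval_h: float = Field(default=672.0, gt=0)
    infusion_duration_h: float = Field(default=0.0, ge=0)
    trial_duration_weeks: float = Field(default=52.0, gt=0)

    @field_validator("dose_mg", "dose_mg_per_kg")
    @classmethod
    def _non_negative(cls, v, info):
        if v is not None and v < 0:
            raise ValueError(f"{info.field_name} must be non-negative")
        return v

    def build(self) -> DoseRegimen:
        return DoseRegimen(
            dose_mg=self.dose_mg, dose_mg_per_kg=self.dose_mg_per_kg,
            body_weight_kg=self.body_weight_kg, n_doses=self.n_doses,
            interval_h=self.interval_h, infusion_duration_h=self.infusion_duration_h,
            trial_duration_weeks=self.trial_duration_weeks,
        )


class RunConfig(BaseModel):
    """Top-level configuration for a trial run."""

    model_config = ConfigDict(extra="forbid")

    antibody: str | AntibodyConfig
    disease: str
    regimen: RegimenConfig = RegimenConfig(dose_mg=0.0)
    geometry: dict[str, float] = Field(default_factory=dict)
    transfer: dict[str, float] = Field(default_factory=dict)
    disease_overrides: dict[str, float] = Field(default_factory=dict)
    solver_rtol: float = 1e-8
    solver_atol: float = 1e-12
    out_dir: str | None = None
    seed: int = 0   # fixture generation only; core simulations are deterministic

    @field_validator("antibody")
    @classmethod
    def _known_antibody(cls, v):
        if isinstance(v, str) and v not in ANTIBODIES:
            raise ValueError(f"antibody: unknown preset {v!r} (available: {sorted(ANTIBODIES)})")
        return v

    @field_validator("disease")
    @classmethod
    def _known_disease(cls, v):
        if v not in DISEASES:
            raise ValueError(f"disease: unknown preset {v!r} (available: {sorted(DISEASES)})")
        return v

    def build_trial_spec(self) -> TrialSpec:
        from .cleft import SolverOptions

        ab = self.antibody.build() if isinstance(self.antibody, AntibodyConfig) else get_antibody(self.antibody)
        disease = get_disease(self.disease)
        if self.disease_overrides:
            disease = disease.with_(**self.disease_overrides)
        geometry = BrainGeometry(**self.geometry) if self.geometry else BrainGeometry()
        transfer = BrainTransferParams(**self.transfer) if self.transfer else BrainTransferParams()
        return TrialSpec(
            antibody=ab, disease=disease, regimen=self.regimen.build(),
            transfer=transfer, geometry=geometry,
            solver=SolverOptions(rtol=self.solver_rtol, atol=self.solver_atol),
        )


def load_config(path) -> RunConfig:
    """Load and validate a JSON run configuration."""
    p = Path(path)
    if not p.exists():
        raise ValidationError(f"config file not found: {p}")
    try:
        payload = json.loads(p.read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"config is not valid JSON: {exc}") from exc
    try:
        return RunConfig.model_validate(payload)
    except Exception as exc:
        raise ValidationError(f"invalid config {p.name}: {exc}") from exc


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(config.model_dump_json(indent=2, exclude_none=True))
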