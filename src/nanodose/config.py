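"""Run configuration: schema, validation, and unit conversion.

Config files are YAML (JSON is a YAML subset) with conventional lab units —
nm, g cm^-3, mg ml^-1, mPa s, degrees C, mm, um, hours — converted to strict
SI when the domain objects are built. Unknown keys are rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import io as nio
from .grid import DissolutionScenario, LangmuirParams, SimulationSettings
from .metrics import SizeDistribution, number_to_volume_distribution
from .physics import AgglomerateSpecies, CoefficientOptions, ENMaterial, FrictionCorrection, Medium
from .presets import get_preset

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunPlan", "load_config"]

_CELSIUS_OFFSET = 273.15


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class MaterialBlock(_Block):
    preset: str | None = None
    name: str | None = None
    density_g_cm3: float | None = Field(default=None, gt=0)
    ssa_m2_g: float | None = Field(default=None, gt=0)
    molar_mass_g_mol: float | None = Field(default=None, gt=0)

    @model_validator(mode="after")
    def _check(self) -> "MaterialBlock":
        if self.preset is None and self.density_g_cm3 is None:
            raise ValueError("material requires either 'preset' or 'density_g_cm3'")
        return self


class SuspensionBlock(_Block):
    concentration_mg_ml: float = Field(gt=0)
    diameter_nm: float | None = Field(default=None, gt=0)
    distribution_file: str | None = None
    weighting: Literal["number", "volume"] = "volume"
    effective_density_g_cm3: float | None = Field(default=None, gt=0)

    @model_validator(mode="after")
    def _check(self) -> "SuspensionBlock":
        if (self.diameter_nm is None) == (self.distribution_file is None):
            raise ValueError(
                "suspension requires exactly one of 'diameter_nm' or 'distribution_file'"
            )
        return self


class MediumBlock(_Block):
    density_g_cm3: float = Field(default=1.005, gt=0)
    viscosity_mpa_s: float = Field(default=0.955, gt=0)
    temperature_c: float = 22.0
    mean_free_path_nm: float = Field(default=0.25, gt=0)

    @model_validator(mode="after")
    def _check(self) -> "MediumBlock":
        if self.temperature_c <= -_CELSIUS_OFFSET:
            raise ValueError("temperature_c must be above absolute zero")
        if not 0.0 <= self.temperature_c <= 60.0:
            logger.warning("temperature %.1f degC is outside the usual incubation range", self.temperature_c)
        return self


class DissolutionBlock(_Block):
    mode: Literal["none", "initial_only", "constant_rate", "linear_ramp"] = "none"
    initial_fraction: float = Field(default=0.0, ge=0.0, le=1.0)
    rate_per_hour: float = Field(default=0.0, ge=0.0)
    ramp_hours: float | None = Field(default=None, gt=0)
    max_fraction: float | None = Field(default=None, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _check(self) -> "DissolutionBlock":
        if self.mode == "linear_ramp" and (self.ramp_hours is None or self.max_fraction is None):
            raise ValueError("linear_ramp requires 'ramp_hours' and 'max_fraction'")
        return self


class SimulationBlock(_Block):
    column_height_mm: float = Field(gt=0)
    duration_h: float = Field(ge=0)
    compartment_um: float = Field(default=5.0, gt=0)
    n_compartments: int | None = Field(default=None, ge=2)
    time_step_s: float = Field(default=1.0, gt=0)
    output_interval_h: float = Field(default=1.0, gt=0)
    boundary: Literal["reflective", "langmuir"] = "reflective"
    kd_molar: float | None = Field(default=None, gt=0)
    bottom_slice_um: float = Field(default=10.0, gt=0)
    area_cm2: float | None = Field(default=None, gt=0)
    dissolution: DissolutionBlock = DissolutionBlock()
    seed: int | None = None

    @model_validator(mode="after")
    def _check(self) -> "SimulationBlock":
        if self.boundary == "langmuir" and self.kd_molar is None:
            raise ValueError("boundary='langmuir' requires 'kd_molar'")
        if not 0.1 <= self.time_step_s <= 1.0:
            logger.warning("time_step_s %.3g is outside the validated 0.1-1.0 s range", self.time_step_s)
        return self


class CorrectionsBlock(_Block):
    slip: bool = True
    shape: Literal["sphere", "cube", "prolate", "oblate", "cylinder", "explicit"] = "sphere"
    aspect_ratio: float | None = None
    shape_factor: float | None = None
    solvation: float = Field(default=1.0, gt=0)
    roughness: float = Field(default=1.0, gt=0)
    concentration_factor_ml_mg: float = Field(default=0.0, ge=0.0)


@dataclass
class RunPlan:
    """Fully resolved, SI-unit inputs for :func:`nanodose.grid.run_simulation`."""

    settings: SimulationSettings
    species: list[AgglomerateSpecies]
    medium: Medium
    material: ENMaterial
    initial_concentration: float
    scenario: DissolutionScenario | None
    correction: FrictionCorrection
    options: CoefficientOptions


class RunConfig(_Block):
    """Top-level run configuration (conventional units, see module docstring)."""

    material: MaterialBlock
    suspension: SuspensionBlock
    simulation: SimulationBlock
    medium: MediumBlock = MediumBlock()
    corrections: CorrectionsBlock = CorrectionsBlock()

    def build(self, base_dir: str | Path = ".") -> RunPlan:
        """Resolve presets and files, convert units, and build domain objects."""
        mat = self.material
        if mat.preset is not None:
            preset = get_preset(mat.preset)
            name = mat.name or preset.name
            density = mat.density_g_cm3 or preset.density_g_cm3
            ssa = mat.ssa_m2_g or preset.ssa_m2_g
            molar_mass = mat.molar_mass_g_mol or preset.molar_mass_g_mol
            effective_density = (
                self.suspension.effective_density_g_cm3 or preset.effective_density_g_cm3
            )
            default_diameter_nm = preset.d_hv_nm
        else:
            name = mat.name or "custom"
            density = mat.density_g_cm3
            ssa = mat.ssa_m2_g
            molar_mass = mat.molar_mass_g_mol
            effective_density = self.suspension.effective_density_g_cm3
            default_diameter_nm = None
        if effective_density is None:
            raise ValueError("suspension.effective_density_g_cm3 is required without a preset")

        material = ENMaterial(
            name=name,
            density=density * 1000.0,
            ssa=ssa * 1000.0 if ssa is not None else None,  # m2/g -> m2/kg
            molar_mass=molar_mass * 1e-3 if molar_mass is not None else None,  # g/mol -> kg/mol
        )
        medium = Medium(
            density=self.medium.density_g_cm3 * 1000.0,
            viscosity=self.medium.viscosity_mpa_s * 1e-3,
            temperature=self.medium.temperature_c + _CELSIUS_OFFSET,
            mean_free_path=self.medium.mean_free_path_nm * 1e-9,
        )

        rho_ev = effective_density * 1000.0
        if self.suspension.diameter_nm is not None:
            species = [AgglomerateSpecies(self.suspension.diameter_nm * 1e-9, rho_ev, 1.0)]
        else:
            path = Path(base_dir) / self.suspension.distribution_file
            dist = nio.read_size_distribution(path, weighting=self.suspension.weighting)
            if dist.weighting == "number":
                dist = number_to_volume_distribution(dist)
            species = _distribution_to_species(dist, rho_ev)
        if self.suspension.diameter_nm is None and default_diameter_nm is not None:
            pass  # distribution overrides the preset mean size

        sim = self.simulation
        scenario = None
        if sim.dissolution.mode != "none":
            d = sim.dissolution
            scenario = DissolutionScenario(
                mode=d.mode,
                initial_fraction=d.initial_fraction,
                rate_per_hour=d.rate_per_hour,
                ramp_hours=d.ramp_hours or 0.0,
                max_fraction=d.max_fraction if d.max_fraction is not None else d.initial_fraction,
            )
        settings = SimulationSettings(
            height=sim.column_height_mm * 1e-3,
            duration=sim.duration_h * 3600.0,
            compartment_height=sim.compartment_um * 1e-6,
            n_compartments=sim.n_compartments,
            time_step=sim.time_step_s,
            output_interval=sim.output_interval_h * 3600.0,
            langmuir=LangmuirParams(sim.kd_molar) if sim.boundary == "langmuir" else None,
            bottom_slice=sim.bottom_slice_um * 1e-6,
            area=sim.area_cm2 * 1e-4 if sim.area_cm2 is not None else None,
            seed=sim.seed,
        )
        correction = FrictionCorrection(
            slip=self.corrections.slip,
            shape=self.corrections.shape,
            aspect_ratio=self.corrections.aspect_ratio,
            shape_factor=self.corrections.shape_factor,
            solvation=self.corrections.solvation,
            roughness=self.corrections.roughness,
        )
        options = CoefficientOptions(
            # ml/mg == m3/kg: the conventional and SI inverse-concentration units coincide
            concentration_factor=self.corrections.concentration_factor_ml_mg
        )
        return RunPlan(
            settings=settings,
            species=species,
            medium=medium,
            material=material,
            initial_concentration=self.suspension.concentration_mg_ml,  # mg/ml == kg/m3
            scenario=scenario,
            correction=correction,
            options=options,
        )

    def resolved_dict(self) -> dict:
        """Round-trippable plain-dict form with defaults filled in."""
        return self.model_dump(mode="json")


def _distribution_to_species(dist: SizeDistribution, rho_ev: float) -> list[AgglomerateSpecies]:
    species = [
        AgglomerateSpecies(diameter=float(d), effective_density=rho_ev, mass_fraction=float(f))
        for d, f in zip(dist.diameters, dist.fractions)
        if f > 0.0
    ]
    # renormalize after dropping empty bins so fractions sum to exactly 1
    total = sum(s.mass_fraction for s in species)
    return [
        AgglomerateSpecies(s.diameter, s.effective_density, s.mass_fraction / total)
        for s in species
    ]


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration file."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} does not contain a mapping")
    return RunConfig.model_validate(raw)
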