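"""Dose metrics and size-distribution arithmetic.

Converts solid nanomaterial mass concentrations into particle-number and
surface-area metrics, handles number<->volume weighting of size
distributions, and assembles the per-output-time dose rows produced by the
grid engine.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SizeDistribution",
    "ConcentrationProfile",
    "DoseTimeSeries",
    "nm_volume_fraction",
    "number_concentration",
    "surface_concentrations",
    "number_to_volume_distribution",
    "volume_to_number_distribution",
    "volume_weighted_mean",
    "bet_equivalent_diameter",
    "dose_row",
]

_FRACTION_SUM_TOL = 1e-9


@dataclass(frozen=True)
class SizeDistribution:
    """Paired diameter/fraction arrays, number- or volume-weighted.

    Diameters in metres; fractions must sum to 1 (within 1e-9).
    """

    diameters: np.ndarray
    fractions: np.ndarray
    weighting: str = "volume"

    def __post_init__(self) -> None:
        diameters = np.atleast_1d(np.asarray(self.diameters, dtype=float))
        fractions = np.atleast_1d(np.asarray(self.fractions, dtype=float))
        object.__setattr__(self, "diameters", diameters)
        object.__setattr__(self, "fractions", fractions)
        if diameters.shape != fractions.shape or diameters.ndim != 1:
            raise ValueError("diameters and fractions must be 1-D arrays of equal length")
        if self.weighting not in ("number", "volume"):
            raise ValueError(f"weighting must be 'number' or 'volume', got {self.weighting!r}")
        if np.any(diameters <= 0):
            raise ValueError("all diameters must be > 0")
        if np.any(fractions < 0):
            raise ValueError("all fractions must be >= 0")
        total = fractions.sum()
        if abs(total - 1.0) > _FRACTION_SUM_TOL:
            raise ValueError(f"fractions must sum to 1 within {_FRACTION_SUM_TOL}, got {total}")

    def __len__(self) -> int:
        return self.diameters.size


@dataclass(frozen=True)
class ConcentrationProfile:
    """Solid-mass concentration vs depth at one output time.

    ``depths`` are compartment midpoints measured up from the well bottom,
    ascending; ``concentrations`` has shape (n_compartments, n_species) in
    the same (bottom-up) order, kg m^-3.
    """

    time: float
    depths: np.ndarray
    concentrations: np.ndarray

    def __post_init__(self) -> None:
        depths = np.asarray(self.depths, dtype=float)
        conc = np.atleast_2d(np.asarray(self.concentrations, dtype=float))
        object.__setattr__(self, "depths", depths)
        object.__setattr__(self, "concentrations", conc)
        if conc.shape[0] != depths.size:
            raise ValueError("concentration rows must match depth array length")
        if np.any(conc < -1e-30):
            raise ValueError("concentrations must be non-negative")

    @property
    def total(self) -> np.ndarray:
        """Total (all-species) concentration per compartment."""
        return self.concentrations.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format frame: time_h, z_um, species_id, mass_conc_mg_ml."""
        rows = []
        time_h = self.time / 3600.0
        z_um = self.depths * 1e6
        for j in range(self.concentrations.shape[1]):
            rows.append(
                pd.DataFrame(
                    {
                        "time_h": time_h,
                        "z_um": z_um,
                        "species_id": str(j),
                        "mass_conc_mg_ml": self.concentrations[:, j],
                    }
                )
            )
        rows.append(
            pd.DataFrame(
                {
                    "time_h": time_h,
                    "z_um": z_um,
                    "species_id": "total",
                    "mass_conc_mg_ml": self.total,
                }
            )
        )
        return pd.concat(rows, ignore_index=True)


@dataclass
class DoseTimeSeries:
    """Dose metrics over output times (SI units internally).

    Per-area quantities are per well-bottom area; the cross-sectional area
    cancels in the solver so none of these require it.
    """

    times: np.ndarray = field(default_factory=lambda: np.empty(0))
    bottom_concentration: np.ndarray = field(default_factory=lambda: np.empty(0))
    deposited_per_area: np.ndarray = field(default_factory=lambda: np.empty(0))
    deposited_fraction: np.ndarray = field(default_factory=lambda: np.empty(0))
    number_concentration: np.ndarray = field(default_factory=lambda: np.empty(0))
    number_per_area: np.ndarray = field(default_factory=lambda: np.empty(0))
    surface_concentration: np.ndarray = field(default_factory=lambda: np.empty(0))
    surface_per_area: np.ndarray = field(default_factory=lambda: np.empty(0))
    bound_per_area: np.ndarray = field(default_factory=lambda: np.empty(0))
    dissolved_concentration: np.ndarray = field(default_factory=lambda: np.empty(0))

    @classmethod
    def from_rows(cls, rows: list[dict[str, float]]) -> "DoseTimeSeries":
        out = cls()
        for name in cls.__dataclass_fields__:
            setattr(out, name, np.array([row[name] for row in rows], dtype=float))
        return out

    def to_dataframe(self) -> pd.DataFrame:
        """CSV-facing frame in conventional units (h, mg, cm, ml)."""
        return pd.DataFrame(
            {
                "time_h": self.times / 3600.0,
                "bottom_conc_mg_ml": self.bottom_concentration,  # kg/m3 == mg/ml
                "deposited_mg_cm2": self.deposited_per_area * 100.0,
                "fraction_deposited": self.deposited_fraction,
                "number_conc_per_ml": self.number_concentration * 1e-6,
                "number_per_cm2": self.number_per_area * 1e-4,
                "surface_cm2_per_ml": self.surface_concentration * 1e-2,
                "surface_cm2_per_cm2": self.surface_per_area,
                "bound_mg_cm2": self.bound_per_area * 100.0,
                "dissolved_mg_ml": self.dissolved_concentration,
            }
        )


def nm_volume_fraction(
    effective_density: float, material_density: float, medium_density: float
) -> float:
    """Solid volume fraction of an agglomerate.

    f_V,NM = (rho_EV - rho_m) / (rho_NM - rho_m). For physical inputs
    rho_m <= rho_EV <= rho_NM the value lies in (0, 1]; out-of-range
    effective densities are clamped with a warning (inconsistent measured
    densities).
    """
    if material_density == medium_density:
        raise ValueError("material and medium densities must differ")
    value = (effective_density - medium_density) / (material_density - medium_density)
    if not 0.0 <= value <= 1.0:
        clamped = min(max(value, 0.0), 1.0)
        logger.warning(
            "effective density %.4g outside [medium, material] range; "
            "volume fraction %.4g clamped to %.4g",
            effective_density,
            value,
            clamped,
        )
        value = clamped
    return value


def number_concentration(
    mass_concentration: float,
    diameter: float,
    material_density: float,
    volume_fraction: float,
) -> float:
    """Agglomerate number concentration 6 C / (pi d^3 rho_NM f_V,NM), m^-3."""
    if volume_fraction <= 0:
        raise ValueError("volume_fraction must be > 0 (no solid content)")
    if diameter <= 0 or material_density <= 0:
        raise ValueError("diameter and material_density must be > 0")
    return 6.0 * mass_concentration / (math.pi * diameter**3 * material_density * volume_fraction)


def surface_concentrations(
    mass_concentration: float,
    diameter: float,
    material_density: float,
    volume_fraction: float,
) -> tuple[float, float]:
    """(agglomerate, nanomaterial) surface-area concentrations, m^2 m^-3.

    The nanomaterial value 6 C / (d rho_NM) is independent of the solid
    volume fraction; the agglomerate envelope value carries the 1/f_V,NM.
    """
    if volume_fraction <= 0:
        raise ValueError("volume_fraction must be > 0 (no solid content)")
    if diameter <= 0 or material_density <= 0:
        raise ValueError("diameter and material_density must be > 0")
    nm_surface = 6.0 * mass_concentration / (diameter * material_density)
    return nm_surface / volume_fraction, nm_surface


def number_to_volume_distribution(dist: SizeDistribution) -> SizeDistribution:
    """Convert number-weighted fractions to volume-weighted (d^3 weighting)."""
    if dist.weighting != "number":
        raise ValueError("input distribution must be number-weighted")
    weights = dist.fractions * dist.diameters**3
    return SizeDistribution(dist.diameters, weights / weights.sum(), weighting="volume")


def volume_to_number_distribution(dist: SizeDistribution) -> SizeDistribution:
    """Inverse of :func:`number_to_volume_distribution` (1/d^3 weighting)."""
    if dist.weighting != "volume":
        raise ValueError("input distribution must be volume-weighted")
    weights = dist.fractions / dist.diameters**3
    return SizeDistribution(dist.diameters, weights / weights.sum(), weighting="number")


def volume_weighted_mean(dist: SizeDistribution) -> float:
    """Volume-weighted mean diameter sum(f_V,i d_i); converts if needed."""
    if dist.weighting == "number":
        dist = number_to_volume_distribution(dist)
    return float(np.dot(dist.fractions, dist.diameters))


def bet_equivalent_diameter(ssa: float, material_density: float) -> float:
    """Equivalent smooth-sphere diameter 6 / (SSA rho), m.

    ``ssa`` in m^2 kg^-1 and density in kg m^-3 (SI).
    """
    if ssa <= 0 or material_density <= 0:
        raise ValueError("ssa and material_density must be > 0")
    return 6.0 / (ssa * material_density)


def dose_row(
    time: float,
    slice_concentrations: np.ndarray,
    bound_per_area: np.ndarray,
    dissolved_concentration: float,
    diameters: np.ndarray,
    effective_densities: np.ndarray,
    material_density: float,
    medium_density: float,
    slice_thickness: float,
    suspended_per_area: float,
) -> dict[str, float]:
    """One dose-metric row for the bottom slice at one output time.

    ``slice_concentrations`` is the per-species mean suspended concentration
    over the bottom-slice compartments (kg m^-3). Deposited mass per area is
    slice concentration x thickness plus bound areal mass, and the deposited
    fraction is taken relative to the *current* suspended + bound mass per
    area (equal to C0 x H whenever no dissolution occurs). Number and surface
    metrics use each species' current diameter and solid volume fraction and
    are summed over species (suspended mass only).
    """
    slice_concentrations = np.asarray(slice_concentrations, dtype=float)
    bound_per_area = np.asarray(bound_per_area, dtype=float)
    diameters = np.asarray(diameters, dtype=float)
    effective_densities = np.asarray(effective_densities, dtype=float)

    bottom_conc = float(slice_concentrations.sum())
    bound_total = float(bound_per_area.sum())
    deposited = bottom_conc * slice_thickness + bound_total
    denominator = suspended_per_area + bound_total
    fraction = deposited / denominator if denominator > 0 else 0.0

    number_conc = 0.0
    surface_conc = 0.0
    for c_j, d_j, rho_ev in zip(slice_concentrations, diameters, effective_densities):
        if c_j <= 0.0 or d_j <= 0.0:
            continue
        f_v = nm_volume_fraction(rho_ev, material_density, medium_density)
        if f_v <= 0.0:
            continue
        number_conc += number_concentration(c_j, d_j, material_density, f_v)
        surface_conc += surface_concentrations(c_j, d_j, material_density, f_v)[1]

    return {
        "times": time,
        "bottom_concentration": bottom_conc,
        "deposited_per_area": deposited,
        "deposited_fraction": min(fraction, 1.0),
        "number_concentration": number_conc,
        "number_per_area": number_conc * slice_thickness,
        "surface_concentration": surface_conc,
        "surface_per_area": surface_conc * slice_thickness,
        "bound_per_area": bound_total,
        "dissolved_concentration": dissolved_concentration,
    }
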