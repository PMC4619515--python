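"""Transport coefficients for suspended agglomerates.

Stokes settling velocity, Stokes-Einstein diffusion, and the corrections to
the ideal Stokes friction factor (slip, dynamic shape, solvation, surface
roughness) that rescale both. All quantities are strict SI; unit conversion
from conventional lab units happens at the I/O boundary (see
:mod:`nanodose.config`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

__all__ = [
    "GRAVITY",
    "BOLTZMANN",
    "AVOGADRO",
    "Medium",
    "ENMaterial",
    "AgglomerateSpecies",
    "Shape",
    "FrictionCorrection",
    "CoefficientOptions",
    "sedimentation_velocity",
    "diffusion_coefficient",
    "sedimentation_coefficient",
    "cunningham_factor",
    "dynamic_shape_factor",
    "friction_ratio",
    "concentration_corrected_coefficient",
    "transport_coefficients",
]

#: Standard gravitational acceleration (m s^-2).
GRAVITY = 9.80665
#: Boltzmann constant (J K^-1).
BOLTZMANN = 1.380649e-23
#: Avogadro constant (mol^-1).
AVOGADRO = 6.02214076e23


def _require_positive(**values: float) -> None:
    for name, value in values.items():
        if not value > 0:
            raise ValueError(f"{name} must be > 0, got {value!r}")


@dataclass(frozen=True)
class Medium:
    """Suspending-fluid properties.

    Parameters
    ----------
    density : float
        Fluid density rho_m (kg m^-3).
    viscosity : float
        Dynamic viscosity eta (Pa s).
    temperature : float
        Absolute temperature (K).
    mean_free_path : float
        Solvent mean free path lambda (m); ~2.5e-10 m for water.
    """

    density: float = 1005.0
    viscosity: float = 9.55e-4
    temperature: float = 295.15
    mean_free_path: float = 2.5e-10

    def __post_init__(self) -> None:
        _require_positive(
            density=self.density,
            viscosity=self.viscosity,
            temperature=self.temperature,
            mean_free_path=self.mean_free_path,
        )


@dataclass(frozen=True)
class ENMaterial:
    """Bulk nanomaterial properties.

    ``ssa`` (specific surface area, m^2 kg^-1) is optional and only needed for
    BET-equivalent diameters; ``molar_mass`` (kg mol^-1) only for dissolution
    unit conversions.
    """

    name: str
    density: float
    ssa: float | None = None
    molar_mass: float | None = None

    def __post_init__(self) -> None:
        _require_positive(density=self.density)
        if self.ssa is not None:
            _require_positive(ssa=self.ssa)
        if self.molar_mass is not None:
            _require_positive(molar_mass=self.molar_mass)


@dataclass(frozen=True)
class AgglomerateSpecies:
    """One size class of suspended agglomerates.

    Parameters
    ----------
    diameter : float
        Hydrodynamic diameter d_H (m).
    effective_density : float
        Agglomerate effective density rho_EV (kg m^-3), media + trapped solid.
    mass_fraction : float
        Fraction of the total suspended solid mass carried by this class.
    """

    diameter: float
    effective_density: float
    mass_fraction: float = 1.0

    def __post_init__(self) -> None:
        _require_positive(diameter=self.diameter, effective_density=self.effective_density)
        if not 0.0 <= self.mass_fraction <= 1.0:
            raise ValueError(f"mass_fraction must be in [0, 1], got {self.mass_fraction!r}")


class Shape(str, Enum):
    """Shapes with known dynamic shape factors."""

    SPHERE = "sphere"
    CUBE = "cube"
    PROLATE = "prolate"
    OBLATE = "oblate"
    CYLINDER = "cylinder"
    EXPLICIT = "explicit"


#: Shape factor for a cube (constant, no axis ratio).
_CUBE_SHAPE_FACTOR = 1.08

_ASPECT_SHAPES = (Shape.PROLATE, Shape.OBLATE, Shape.CYLINDER)


@dataclass(frozen=True)
class FrictionCorrection:
    """Corrections to the ideal Stokes friction factor, as a ratio f/f0.

    Corrected coefficients are obtained by *dividing* the uncorrected
    diffusion coefficient and sedimentation velocity by :func:`friction_ratio`.
    """

    slip: bool = True
    shape: Shape = Shape.SPHERE
    aspect_ratio: float | None = None
    shape_factor: float | None = None
    solvation: float = 1.0
    roughness: float = 1.0

    def __post_init__(self) -> None:
        shape = Shape(self.shape)
        object.__setattr__(self, "shape", shape)
        _require_positive(solvation=self.solvation, roughness=self.roughness)
        if shape in _ASPECT_SHAPES:
            if self.aspect_ratio is None:
                raise ValueError(f"aspect_ratio is required for shape={shape.value!r}")
            if not self.aspect_ratio > 1:
                raise ValueError(
                    f"aspect_ratio must be > 1 for shape={shape.value!r}, got {self.aspect_ratio!r}"
                )
        if shape is Shape.EXPLICIT:
            if self.shape_factor is None:
                raise ValueError("shape_factor is required for shape='explicit'")
            _require_positive(shape_factor=self.shape_factor)


@dataclass(frozen=True)
class CoefficientOptions:
    """Options for concentration-dependent transport coefficients.

    ``concentration_factor`` k (m^3 kg^-1) rescales both D and S as
    X/(1 + k C); the default 0 leaves coefficients concentration-independent.
    """

    concentration_factor: float = 0.0

    def __post_init__(self) -> None:
        if self.concentration_factor < 0:
            raise ValueError("concentration_factor must be >= 0")


def sedimentation_velocity(species: AgglomerateSpecies, medium: Medium) -> float:
    """Stokes settling velocity v_s = g (rho_EV - rho_m) d_H^2 / (18 eta), m s^-1.

    Negative for buoyant species (rho_EV < rho_m).
    """
    return (
        GRAVITY
        * (species.effective_density - medium.density)
        * species.diameter**2
        / (18.0 * medium.viscosity)
    )


def diffusion_coefficient(species: AgglomerateSpecies, medium: Medium) -> float:
    """Stokes-Einstein diffusivity D = k_B T / (3 pi eta d_H), m^2 s^-1."""
    return BOLTZMANN * medium.temperature / (3.0 * math.pi * medium.viscosity * species.diameter)


def sedimentation_coefficient(species: AgglomerateSpecies, medium: Medium) -> float:
    """Sedimentation coefficient S = v_s / g (s); sign follows v_s."""
    return sedimentation_velocity(species, medium) / GRAVITY


def cunningham_factor(diameter: float, mean_free_path: float = 2.5e-10) -> float:
    """Cunningham slip correction C_c = 1 + (l/d)(2.34 + 1.05 e^(-0.39 d / 2l)).

    Always > 1; approaches 1 as d grows past the mean free path.
    """
    _require_positive(diameter=diameter, mean_free_path=mean_free_path)
    ratio = mean_free_path / diameter
    return 1.0 + ratio * (2.34 + 1.05 * math.exp(-0.39 * diameter / (2.0 * mean_free_path)))


def dynamic_shape_factor(
    shape: Shape | str,
    aspect_ratio: float | None = None,
    shape_factor: float | None = None,
) -> float:
    """Dynamic shape factor chi for the supported shapes.

    Sphere -> 1; cube -> 1.08; prolate/oblate ellipsoids and circular
    cylinders use the closed forms in terms of the axis ratio P = a/b > 1;
    ``explicit`` passes through the user-supplied value.
    """
    shape = Shape(shape)
    if shape is Shape.SPHERE:
        return 1.0
    if shape is Shape.CUBE:
        return _CUBE_SHAPE_FACTOR
    if shape is Shape.EXPLICIT:
        if shape_factor is None:
            raise ValueError("shape_factor is required for shape='explicit'")
        _require_positive(shape_factor=shape_factor)
        return float(shape_factor)
    if aspect_ratio is None or not aspect_ratio > 1:
        raise ValueError(f"aspect_ratio must be > 1 for shape={shape.value!r}, got {aspect_ratio!r}")
    p = float(aspect_ratio)
    q = math.sqrt(p * p - 1.0)
    if shape is Shape.PROLATE:
        return p ** (-1.0 / 3.0) * q / math.log(p + q)
    if shape is Shape.OBLATE:
        return q / (p ** (2.0 / 3.0) * math.atan(q))
    # circular cylinder
    return (2.0 / 3.0) ** (1.0 / 3.0) * p ** (2.0 / 3.0) / (math.log(2.0 * p) - 0.3)


def friction_ratio(
    correction: FrictionCorrection, diameter: float, mean_free_path: float = 2.5e-10
) -> float:
    """Combined friction ratio f/f0 for a given particle diameter.

    Multiplicative composition of shape, solvation and roughness factors,
    with the slip correction entering reciprocally (slip *reduces* friction).
    Corrected D and v_s are the uncorrected values divided by this ratio.
    """
    ratio = (
        dynamic_shape_factor(correction.shape, correction.aspect_ratio, correction.shape_factor)
        * correction.solvation
        * correction.roughness
    )
    if correction.slip:
        ratio /= cunningham_factor(diameter, mean_free_path)
    return ratio


def concentration_corrected_coefficient(coefficient: float, concentration: float, k: float) -> float:
    """Concentration-dependent rescaling X / (1 + k C); identity at k = 0."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0.0:
        return coefficient
    return coefficient / (1.0 + k * concentration)


def transport_coefficients(
    species: AgglomerateSpecies,
    medium: Medium,
    correction: FrictionCorrection | None = None,
) -> tuple[float, float]:
    """Friction-corrected (D, v_s) for one species.

    With ``correction=None`` no correction is applied (bit-identical to the
    raw Stokes/Stokes-Einstein values); pass ``FrictionCorrection()`` for the
    default slip-corrected behaviour.
    """
    d_coeff = diffusion_coefficient(species, medium)
    v_s = sedimentation_velocity(species, medium)
    if correction is not None:
        ratio = friction_ratio(correction, species.diameter, medium.mean_free_path)
        d_coeff /= ratio
        v_s /= ratio
    return d_coeff, v_s
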