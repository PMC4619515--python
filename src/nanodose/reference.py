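"""Independent oracles for the grid engine.

Two cross-checks that share the physics but not the numerics of the solver:
the closed-form exponential sedimentation-diffusion equilibrium profile, and
a Brownian-dynamics random-walk particle tracker with drift and reflecting
walls. Both use the same friction-corrected coefficients as the solver so
that any disagreement isolates the grid scheme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .physics import AgglomerateSpecies, FrictionCorrection, Medium, transport_coefficients

__all__ = ["EquilibriumProfile", "TrackerSettings", "equilibrium_profile", "random_walk_tracker"]


@dataclass(frozen=True)
class EquilibriumProfile:
    """Steady-state exponential concentration profile.

    ``scale_height`` is z0 = D / v_s; depth z is measured up from the well
    bottom. For non-settling species (``scale_height`` = inf) the profile is
    uniform. The profile integrates to c0 * height exactly.
    """

    scale_height: float
    height: float
    c0: float

    def concentration(self, z) -> np.ndarray:
        """Concentration at depth(s) ``z`` above the bottom (kg m^-3)."""
        z = np.asarray(z, dtype=float)
        if not np.isfinite(self.scale_height):
            return np.full_like(z, self.c0)
        z0 = self.scale_height
        norm = self.c0 * self.height / (z0 * (1.0 - math.exp(-self.height / z0)))
        return norm * np.exp(-z / z0)

    def mass_fraction_below(self, z: float) -> float:
        """Fraction of total mass lying below depth ``z``."""
        if not np.isfinite(self.scale_height):
            return min(max(z / self.height, 0.0), 1.0)
        z0 = self.scale_height
        return (1.0 - math.exp(-z / z0)) / (1.0 - math.exp(-self.height / z0))

    def compartment_means(self, n: int) -> np.ndarray:
        """Mean concentration in n equal compartments, bottom-up (exact integrals)."""
        edges = np.linspace(0.0, self.height, n + 1)
        if not np.isfinite(self.scale_height):
            return np.full(n, self.c0)
        below = np.array([self.mass_fraction_below(z) for z in edges])
        mass_per_area = np.diff(below) * self.c0 * self.height
        return mass_per_area / np.diff(edges)


@dataclass(frozen=True)
class TrackerSettings:
    """Random-walk tracker configuration."""

    n_particles: int
    duration: float
    height: float
    time_step: float = 1.0
    seed: int = 0
    bin_width: float | None = None

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if self.duration < 0 or self.time_step <= 0 or self.height <= 0:
            raise ValueError("duration >= 0, time_step > 0 and height > 0 required")


def equilibrium_profile(
    species: AgglomerateSpecies,
    medium: Medium,
    height: float,
    c0: float = 1.0,
    correction: FrictionCorrection | None = None,
) -> EquilibriumProfile:
    """Closed-form steady state of the sedimentation-diffusion balance.

    For settling species the profile is exponential with scale height
    z0 = D / v_s; for neutrally buoyant or rising species the steady state
    within a closed column is approximated by the uniform (pure-diffusion)
    limit, returned as an infinite scale height.
    """
    d_coeff, v_s = transport_coefficients(species, medium, correction)
    if v_s <= 0:
        return EquilibriumProfile(scale_height=math.inf, height=height, c0=c0)
    return EquilibriumProfile(scale_height=d_coeff / v_s, height=height, c0=c0)


def random_walk_tracker(
    species: AgglomerateSpecies,
    medium: Medium,
    settings: TrackerSettings,
    correction: FrictionCorrection | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Brownian dynamics with drift, reflecting at both walls.

    Evolves ``n_particles`` initially uniform positions by
    z <- z - v_s dt + sqrt(2 D dt) xi and reflects off z = 0 and z = height.
    Returns ``(bin_edges, number_fractions)`` with bins ordered bottom-up.
    Deterministic for a given seed.
    """
    d_coeff, v_s = transport_coefficients(species, medium, correction)
    h = settings.height
    rng = np.random.default_rng(settings.seed)
    z = rng.uniform(0.0, h, size=settings.n_particles)

    n_steps = int(round(settings.duration / settings.time_step))
    sigma = math.sqrt(2.0 * d_coeff * settings.time_step)
    drift = v_s * settings.time_step
    for _ in range(n_steps):
        z += -drift + sigma * rng.standard_normal(settings.n_particles)
        # reflect: fold into [0, 2h] then mirror the upper half
        z = np.abs(z)
        np.mod(z, 2.0 * h, out=z)
        np.minimum(z, 2.0 * h - z, out=z)

    bin_width = settings.bin_width if settings.bin_width is not None else h / 50.0
    n_bins = max(1, int(round(h / bin_width)))
    edges = np.linspace(0.0, h, n_bins + 1)
    counts, _ = np.histogram(z, bins=edges)
    return edges, counts / settings.n_particles
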