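"""Shared fixtures: default medium, preset-derived cases, tiny run helper."""

import math

import numpy as np
import pytest

from nanodose.physics import AgglomerateSpecies, ENMaterial, Medium
from nanodose.presets import get_preset


@pytest.fixture(scope="session")
def medium() -> Medium:
    """Water-like culture medium at 22 degC (package defaults)."""
    return Medium()


def preset_case(name: str) -> tuple[ENMaterial, list[AgglomerateSpecies]]:
    """Material + monodisperse (volume-mean) species for a built-in preset."""
    p = get_preset(name)
    material = ENMaterial(
        name=p.name,
        density=p.density_g_cm3 * 1000.0,
        ssa=p.ssa_m2_g * 1000.0,
        molar_mass=p.molar_mass_g_mol * 1e-3 if p.molar_mass_g_mol else None,
    )
    species = [
        AgglomerateSpecies(
            diameter=p.d_hv_nm * 1e-9,
            effective_density=p.effective_density_g_cm3 * 1000.0,
        )
    ]
    return material, species


@pytest.fixture(scope="session")
def sio2_case():
    return preset_case("SiO2")


def lognormal_species(
    mean_diameter_m: float, pdi: float, effective_density: float, bins: int = 21
) -> list[AgglomerateSpecies]:
    """Volume-weighted lognormal species list with the given volume mean.

    The geometric SD follows from the polydispersity index via the lognormal
    relation PdI = exp(ln^2 GSD) - 1; diameters are rescaled so the achieved
    volume-weighted mean matches ``mean_diameter_m`` exactly.
    """
    from nanodose.io import synth_distribution
    from nanodose.metrics import number_to_volume_distribution, volume_weighted_mean

    gsd = math.exp(math.sqrt(math.log(1.0 + pdi)))
    gm_number_nm = mean_diameter_m * 1e9 * math.exp(-3.5 * math.log(gsd) ** 2)
    vol = number_to_volume_distribution(synth_distribution(gm_number_nm, gsd, bins=bins))
    scale = mean_diameter_m / volume_weighted_mean(vol)
    return [
        AgglomerateSpecies(float(d * scale), effective_density, float(f))
        for d, f in zip(vol.diameters, vol.fractions)
    ]


def column_mass_per_area(profile, series_row_index, series, height: float) -> float:
    """Suspended + bound + dissolved mass per area at one output time."""
    h = profile.depths[1] - profile.depths[0] if profile.depths.size > 1 else 2 * profile.depths[0]
    suspended = profile.concentrations.sum() * h
    bound = series.bound_per_area[series_row_index]
    dissolved = series.dissolved_concentration[series_row_index] * height
    return float(suspended + bound + dissolved)


def assert_mass_conserved(profiles, series, c0: float, height: float, rtol: float = 1e-9):
    total0 = c0 * height
    for i, profile in enumerate(profiles):
        total = column_mass_per_area(profile, i, series, height)
        assert total == pytest.approx(total0, rel=rtol), f"mass balance broken at t={profile.time}"
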