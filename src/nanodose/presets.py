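"""Built-in material presets for five well-characterized metal-oxide powders.

Each preset bundles the powder properties (specific surface area, bulk
density) with the measured suspension properties (volume-weighted mean
hydrodynamic diameter, polydispersity index, agglomerate effective density)
and the dispersion medium label. The medium label and PdI are metadata only;
media density/viscosity are configured separately since they were not part
of the characterization data.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["MaterialPreset", "PRESETS", "get_preset", "preset_names"]


@dataclass(frozen=True)
class MaterialPreset:
    """Characterization record for one powder + suspension (conventional units)."""

    name: str
    ssa_m2_g: float
    d_bet_nm: float
    media: str
    d_hv_nm: float
    pdi: float
    density_g_cm3: float
    effective_density_g_cm3: float
    molar_mass_g_mol: float | None = None


PRESETS: dict[str, MaterialPreset] = {
    "SiO2": MaterialPreset(
        name="SiO2",
        ssa_m2_g=147.0,
        d_bet_nm=18.6,
        media="PBS + 0.1 % BSA",
        d_hv_nm=149.9,
        pdi=0.175,
        density_g_cm3=2.648,
        effective_density_g_cm3=1.564,
    ),
    "Fe2O3": MaterialPreset(
        name="Fe2O3",
        ssa_m2_g=41.5,
        d_bet_nm=27.6,
        media="RPMI + 10 % HS",
        d_hv_nm=234.5,
        pdi=0.755,
        density_g_cm3=5.242,
        effective_density_g_cm3=1.335,
    ),
    "CeO2": MaterialPreset(
        name="CeO2",
        ssa_m2_g=14.0,
        d_bet_nm=45.4,
        media="RPMI + 0.5 % BSA",
        d_hv_nm=982.1,
        pdi=0.310,
        density_g_cm3=7.215,
        effective_density_g_cm3=1.420,
    ),
    "TiO2": MaterialPreset(
        name="TiO2",
        ssa_m2_g=50.0,
        d_bet_nm=21.0,
        media="RPMI + 10 % HS",
        d_hv_nm=397.8,
        pdi=0.233,
        density_g_cm3=4.230,
        effective_density_g_cm3=1.251,
    ),
    "ZnO": MaterialPreset(
        name="ZnO",
        ssa_m2_g=17.0,
        d_bet_nm=63.0,
        media="RPMI + 10 % FBS",
        d_hv_nm=307.0,
        pdi=0.303,
        density_g_cm3=5.606,
        effective_density_g_cm3=1.650,
        molar_mass_g_mol=81.38,
    ),
}

_LOOKUP = {key.lower(): key for key in PRESETS}


def preset_names() -> list[str]:
    """Names of the built-in presets, in catalogue order."""
    return list(PRESETS)


def get_preset(name: str) -> MaterialPreset:
    """Case-insensitive preset lookup; raises ``KeyError`` with choices listed."""
    key = _LOOKUP.get(name.lower())
    if key is None:
        raise KeyError(f"unknown preset {name!r}; available: {', '.join(PRESETS)}")
    return PRESETS[key]
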