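"""Compartmental 1-D sedimentation-diffusion solver.

The suspension column is split into n equal compartments between n + 1
horizontal boundaries (boundary 1 is the top of the column, boundary n + 1
the well bottom; both are impermeable). Each iteration applies an explicit
diffusion exchange, then a fractional-displacement sedimentation transfer,
then (optionally) a Langmuir adsorption partition in the bottom compartment
and a dissolution update. Species are transported independently; the column
cross-sectional area cancels throughout, so all bookkeeping is per unit
well-bottom area.

Concentration arrays are indexed top-to-bottom: row 0 is the topmost
compartment, row n - 1 sits on the well bottom.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from . import metrics
from .physics import (
    AVOGADRO,
    GRAVITY,
    AgglomerateSpecies,
    CoefficientOptions,
    ENMaterial,
    FrictionCorrection,
    Medium,
    transport_coefficients,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationSettings",
    "DissolutionScenario",
    "LangmuirParams",
    "GridState",
    "StabilityError",
    "initialize_grid",
    "diffusion_step",
    "sedimentation_step",
    "cap_time_step",
    "langmuir_partition",
    "apply_dissolution",
    "run_simulation",
    "agglomerate_molar_concentration",
    "mass_specific_cross_section",
]

#: Diffusion-number bound for the explicit scheme, D dt / h^2 <= 1/2.
_STABILITY_LIMIT = 0.5
#: Max per-step sedimentation displacement, as a fraction of h.
_DISPLACEMENT_LIMIT = 0.5

_MASS_FRACTION_TOL = 1e-12


class StabilityError(RuntimeError):
    """Explicit diffusion step driven outside its stability bound."""


@dataclass(frozen=True)
class LangmuirParams:
    """Langmuir adsorption boundary: equilibrium dissociation constant (mol L^-1)."""

    k_d: float

    def __post_init__(self) -> None:
        if not self.k_d > 0:
            raise ValueError(f"k_d must be > 0, got {self.k_d!r}")


@dataclass(frozen=True)
class DissolutionScenario:
    """Dissolution of suspended solid into a well-mixed dissolved pool.

    ``mode`` is one of ``none``, ``initial_only``, ``constant_rate``
    (``rate_per_hour`` as a fraction of the initial total mass per hour) or
    ``linear_ramp`` (ramping from ``initial_fraction`` to ``max_fraction``
    over ``ramp_hours``, constant after). The cumulative dissolved fraction
    is clamped to 1.
    """

    mode: str = "none"
    initial_fraction: float = 0.0
    rate_per_hour: float = 0.0
    ramp_hours: float = 0.0
    max_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("none", "initial_only", "constant_rate", "linear_ramp"):
            raise ValueError(f"unknown dissolution mode {self.mode!r}")
        if not 0.0 <= self.initial_fraction <= 1.0:
            raise ValueError("initial_fraction must be in [0, 1]")
        if self.rate_per_hour < 0:
            raise ValueError("rate_per_hour must be >= 0")
        if self.mode == "linear_ramp":
            if not self.ramp_hours > 0:
                raise ValueError("ramp_hours must be > 0 for linear_ramp")
            if self.max_fraction < self.initial_fraction:
                raise ValueError("max_fraction must be >= initial_fraction")

    @property
    def active(self) -> bool:
        return self.mode != "none"

    def dissolved_fraction(self, time: float) -> float:
        """Target cumulative dissolved fraction of the initial mass at ``time`` (s)."""
        if self.mode == "none":
            return 0.0
        hours = time / 3600.0
        if self.mode == "initial_only":
            target = self.initial_fraction
        elif self.mode == "constant_rate":
            target = self.initial_fraction + self.rate_per_hour * hours
        else:  # linear_ramp
            progress = min(hours / self.ramp_hours, 1.0)
            target = self.initial_fraction + (self.max_fraction - self.initial_fraction) * progress
        return min(target, 1.0)


@dataclass(frozen=True)
class SimulationSettings:
    """Column geometry, time stepping, boundary and reporting options.

    The compartment count is ``n_compartments`` when given, otherwise
    ``round(height / compartment_height)``; the realized compartment height
    ``h`` is ``height / n`` exactly. The bottom reporting slice must span at
    least one compartment. A ``langmuir`` block switches the well bottom
    from reflective to adsorptive.
    """

    height: float
    duration: float
    compartment_height: float = 5e-6
    n_compartments: int | None = None
    time_step: float = 1.0
    output_interval: float = 3600.0
    langmuir: LangmuirParams | None = None
    bottom_slice: float = 10e-6
    area: float | None = None
    seed: int | None = None  # reserved for fixture generation, unused by the solver

    def __post_init__(self) -> None:
        if not self.height > 0:
            raise ValueError("height must be > 0")
        if self.duration < 0:
            raise ValueError("duration must be >= 0")
        if not self.time_step > 0:
            raise ValueError("time_step must be > 0")
        if not self.output_interval > 0:
            raise ValueError("output_interval must be > 0")
        if self.n_compartments is None:
            if not self.compartment_height > 0:
                raise ValueError("compartment_height must be > 0")
            object.__setattr__(
                self, "n_compartments", max(2, round(self.height / self.compartment_height))
            )
        if self.n_compartments < 2:
            raise ValueError("n_compartments must be >= 2")
        if not 0 < self.bottom_slice <= self.height:
            raise ValueError("bottom_slice must be in (0, height]")
        if self.bottom_slice < self.h * (1 - 1e-9):
            raise ValueError(
                f"bottom slice ({self.bottom_slice} m) is thinner than one compartment "
                f"({self.h} m); increase n_compartments or the slice thickness"
            )

    @property
    def h(self) -> float:
        """Realized compartment height (m)."""
        return self.height / self.n_compartments

    @property
    def slice_compartments(self) -> int:
        """Number of bottom compartments inside the reporting slice."""
        k = max(1, round(self.bottom_slice / self.h))
        if abs(k * self.h - self.bottom_slice) > 1e-6 * self.bottom_slice:
            logger.warning(
                "bottom slice %.3g m is not an integer multiple of the compartment "
                "height %.3g m; reporting over %d compartments (%.3g m)",
                self.bottom_slice,
                self.h,
                k,
                k * self.h,
            )
        return k


@dataclass
class GridState:
    """Mutable solver state at one instant.

    ``concentrations`` is (n, m) suspended solid mass concentration
    (kg m^-3), top-to-bottom; ``bound`` is per-species adsorbed mass per
    well-bottom area (kg m^-2); ``dissolved`` is the column-average
    dissolved concentration (kg m^-3, single well-mixed pool);
    ``diameters`` are the species' current hydrodynamic diameters (they
    shrink only under dissolution).
    """

    time: float
    h: float
    height: float
    concentrations: np.ndarray
    bound: np.ndarray
    dissolved: float
    diameters: np.ndarray
    effective_densities: np.ndarray
    initial_diameters: np.ndarray | None = None
    initial_dissolved_fraction: float = 0.0

    def __post_init__(self) -> None:
        self.concentrations = np.atleast_2d(np.asarray(self.concentrations, dtype=float))
        self.bound = np.atleast_1d(np.asarray(self.bound, dtype=float))
        self.diameters = np.atleast_1d(np.asarray(self.diameters, dtype=float))
        self.effective_densities = np.atleast_1d(np.asarray(self.effective_densities, dtype=float))
        if self.initial_diameters is None:
            self.initial_diameters = self.diameters.copy()

    @property
    def n_compartments(self) -> int:
        return self.concentrations.shape[0]

    @property
    def n_species(self) -> int:
        return self.concentrations.shape[1]

    def suspended_per_area(self) -> float:
        """Suspended solid mass per well-bottom area (kg m^-2)."""
        return float(self.concentrations.sum() * self.h)

    def total_mass_per_area(self) -> float:
        """Suspended + bound + dissolved mass per area (kg m^-2)."""
        return self.suspended_per_area() + float(self.bound.sum()) + self.dissolved * self.height


def _check_fractions(species: list[AgglomerateSpecies]) -> None:
    total = sum(s.mass_fraction for s in species)
    if abs(total - 1.0) > _MASS_FRACTION_TOL:
        raise ValueError(
            f"species mass fractions must sum to 1 within {_MASS_FRACTION_TOL}, got {total}"
        )


def initialize_grid(
    settings: SimulationSettings,
    species: list[AgglomerateSpecies],
    initial_concentration: float,
    scenario: DissolutionScenario | None = None,
) -> GridState:
    """Homogeneous initial state: C[i, j] = C0 f_j in every compartment.

    With a dissolution scenario, ``initial_fraction`` of the total mass
    starts in the dissolved pool and the suspended solid is reduced
    accordingly; diameters are *not* pre-shrunk because the input sizes are
    taken to describe the suspension after any initial dissolution.
    """
    if initial_concentration < 0:
        raise ValueError("initial_concentration must be >= 0")
    _check_fractions(species)
    settings.slice_compartments  # validates slice resolution, may warn
    n = settings.n_compartments
    fractions = np.array([s.mass_fraction for s in species], dtype=float)
    diameters = np.array([s.diameter for s in species], dtype=float)

    f0 = scenario.initial_fraction if scenario is not None and scenario.active else 0.0
    conc = np.tile(initial_concentration * (1.0 - f0) * fractions, (n, 1))
    return GridState(
        time=0.0,
        h=settings.h,
        height=settings.height,
        concentrations=conc,
        bound=np.zeros(len(species)),
        dissolved=f0 * initial_concentration,
        diameters=diameters,
        effective_densities=np.array([s.effective_density for s in species], dtype=float),
        initial_diameters=diameters.copy(),
        initial_dissolved_fraction=f0,
    )


def diffusion_step(state: GridState, diffusivity: np.ndarray, dt: float) -> GridState:
    """One explicit diffusion exchange of duration ``dt`` (in place).

    ``diffusivity`` is either (m,) per species or (n - 1, m) per interior
    boundary per species. Boundaries 1 and n + 1 (column top and well
    bottom) carry no flux; total suspended mass is conserved to round-off.
    """
    c = state.concentrations
    h = state.h
    d_arr = np.asarray(diffusivity, dtype=float)
    number = np.max(d_arr) * dt / h**2
    if number > _STABILITY_LIMIT * (1 + 1e-9):
        raise StabilityError(
            f"diffusion number D*dt/h^2 = {number:.3g} exceeds {_STABILITY_LIMIT}; reduce dt"
        )
    exchange = (dt / h**2) * d_arr * (c[1:] - c[:-1])
    c[:-1] += exchange
    c[1:] -= exchange
    return state


def sedimentation_step(state: GridState, sed_coefficients: np.ndarray, dt: float) -> GridState:
    """One fractional-displacement sedimentation transfer (in place).

    Each compartment passes the fraction ``S g dt / h`` of its content to
    the next compartment downward (upward for buoyant species). The top
    compartment receives no inflow and the bottom compartment has no
    outflow, so mass accumulates against the impermeable well bottom.
    ``sed_coefficients`` is (m,) per species or (n, m) per compartment.
    """
    c = state.concentrations
    frac = np.asarray(sed_coefficients, dtype=float) * GRAVITY * dt / state.h
    if np.any(np.abs(frac) > 1.0 + 1e-12):
        raise RuntimeError(
            "per-step sedimentation displacement exceeds one compartment; time-step cap failed"
        )

    per_compartment = frac.ndim == 2
    # a species' settling direction never flips within one step
    col_sign = frac.max(axis=0) if per_compartment else frac
    down = col_sign > 0
    if np.any(down):
        f = frac[:-1][:, down] if per_compartment else frac[down]
        moved = c[:-1][:, down] * f
        c[:-1][:, down] -= moved
        c[1:][:, down] += moved
    up = col_sign < 0
    if np.any(up):
        f = -frac[1:][:, up] if per_compartment else -frac[up]
        moved = c[1:][:, up] * f
        c[1:][:, up] -= moved
        c[:-1][:, up] += moved
    return state


def cap_time_step(
    time_step: float,
    h: float,
    sed_coefficients: np.ndarray,
    diffusivities: np.ndarray,
    log: bool = True,
) -> float:
    """Largest admissible step: min of the user step, the h/2 displacement rule
    for the fastest-settling species, and the explicit-diffusion stability bound."""
    dt = time_step
    v_max = float(np.max(np.abs(np.asarray(sed_coefficients, dtype=float)))) * GRAVITY
    if v_max > 0:
        dt = min(dt, _DISPLACEMENT_LIMIT * h / v_max)
    d_max = float(np.max(np.asarray(diffusivities, dtype=float)))
    if d_max > 0:
        dt = min(dt, _STABILITY_LIMIT * h**2 / d_max)
    if dt < time_step and log:
        logger.warning(
            "time step reduced from %.3g s to %.3g s (h/2 displacement / stability caps)",
            time_step,
            dt,
        )
    return dt


def agglomerate_molar_concentration(
    mass_concentration: float, diameter: float, effective_density: float
) -> float:
    """Agglomerate molar concentration (mol L^-1) from mass concentration.

    [P] = 1e-3 C / (N_A rho_EV (4/3) pi r^3); the 1e-3 converts mol m^-3 to
    mol L^-1.
    """
    radius = diameter / 2.0
    agglomerate_mass = effective_density * (4.0 / 3.0) * math.pi * radius**3
    return 1e-3 * mass_concentration / (AVOGADRO * agglomerate_mass)


def mass_specific_cross_section(diameter: float, effective_density: float) -> float:
    """Projected cross-section per agglomerate mass, A_m = 3/(4 r rho_EV), m^2 kg^-1."""
    return 3.0 / (4.0 * (diameter / 2.0) * effective_density)


def langmuir_partition(state: GridState, params: LangmuirParams) -> GridState:
    """Partition bottom-compartment mass into bound and free (in place).

    Per species: surface coverage theta = [P]/(K_D + [P]) from the
    agglomerate molar concentration in the bottom compartment; the coverage
    achievable from the mass actually present there is
    theta_avail = h C A_m; the bound fraction F_b = min(theta/theta_avail, 1)
    of the bottom-compartment mass is moved to the per-species bound pool
    (areal mass) and never re-enters suspension.
    """
    bottom = state.concentrations[-1]
    for j in range(state.n_species):
        c_j = bottom[j]
        d_j = state.diameters[j]
        if c_j <= 0.0 or d_j <= 0.0:
            continue
        rho_ev = state.effective_densities[j]
        molar = agglomerate_molar_concentration(c_j, d_j, rho_ev)
        theta = molar / (params.k_d + molar)
        theta_avail = state.h * c_j * mass_specific_cross_section(d_j, rho_ev)
        bound_fraction = min(theta / theta_avail, 1.0) if theta_avail > 0 else 1.0
        bound_mass = bound_fraction * c_j
        state.bound[j] += bound_mass * state.h
        bottom[j] = c_j - bound_mass
    return state


def apply_dissolution(
    state: GridState, scenario: DissolutionScenario, initial_concentration: float
) -> GridState:
    """Advance the dissolved pool to the scenario target at ``state.time`` (in place).

    Newly dissolved mass is removed proportionally from every compartment's
    suspended solid (bound mass does not dissolve) and added to the
    well-mixed dissolved pool; species diameters shrink so agglomerate
    volume tracks the remaining solid fraction,
    d = d0 ((1 - f_d)/(1 - f0))^(1/3).
    """
    if not scenario.active or initial_concentration <= 0:
        return state
    target = scenario.dissolved_fraction(state.time)
    delta_conc = target * initial_concentration - state.dissolved
    if delta_conc > 0:
        needed = delta_conc * state.height  # mass per area to dissolve
        available = state.suspended_per_area()
        if needed > available:
            logger.warning(
                "dissolution target exceeds suspended solid at t=%.0f s; clamping "
                "(all suspended solid dissolved)",
                state.time,
            )
            needed = available
        if available > 0:
            state.concentrations *= 1.0 - needed / available
        state.dissolved += needed / state.height

    f_d = state.dissolved / initial_concentration
    f0 = state.initial_dissolved_fraction
    remaining = max(1.0 - f_d, 0.0) / max(1.0 - f0, 1e-300)
    state.diameters = state.initial_diameters * np.cbrt(max(remaining, 1e-12))
    return state


def _shrunk_diameters(state: GridState, fraction: float) -> np.ndarray:
    remaining = max(1.0 - fraction, 0.0) / max(1.0 - state.initial_dissolved_fraction, 1e-300)
    return state.initial_diameters * np.cbrt(max(remaining, 1e-12))


def _species_coefficients(
    diameters: np.ndarray,
    effective_densities: np.ndarray,
    medium: Medium,
    correction: FrictionCorrection | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Friction-corrected (D, S) arrays for the given current diameters."""
    m = len(diameters)
    d_coeffs = np.empty(m)
    s_coeffs = np.empty(m)
    for j in range(m):
        sp = AgglomerateSpecies(
            diameter=float(diameters[j]),
            effective_density=float(effective_densities[j]),
            mass_fraction=1.0,
        )
        d_j, v_j = transport_coefficients(sp, medium, correction)
        d_coeffs[j] = d_j
        s_coeffs[j] = v_j / GRAVITY
    return d_coeffs, s_coeffs


def _concentration_corrected(
    state: GridState, d_coeffs: np.ndarray, s_coeffs: np.ndarray, k: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-boundary D and per-compartment S with the 1/(1 + kC) rescaling."""
    c = state.concentrations
    d_boundary = d_coeffs / (1.0 + k * 0.5 * (c[:-1] + c[1:]))
    s_local = s_coeffs / (1.0 + k * c)
    return d_boundary, s_local


def run_simulation(
    settings: SimulationSettings,
    species: list[AgglomerateSpecies],
    medium: Medium,
    material: ENMaterial,
    initial_concentration: float,
    scenario: DissolutionScenario | None = None,
    correction: FrictionCorrection | None = None,
    options: CoefficientOptions | None = None,
) -> tuple[list[metrics.ConcentrationProfile], metrics.DoseTimeSeries]:
    """Run the full solver and collect profiles and dose metrics.

    Iterates diffusion -> sedimentation (-> Langmuir partition -> dissolution)
    with the capped effective time step until ``settings.duration``,
    recording a :class:`~nanodose.metrics.ConcentrationProfile` and one dose
    row at t = 0 and at every output interval. Deterministic; no randomness
    anywhere in the solver. With ``correction=None`` the default
    (slip-corrected sphere) friction correction is applied.
    """
    if correction is None:
        correction = FrictionCorrection()
    k_factor = options.concentration_factor if options is not None else 0.0
    dissolving = scenario is not None and scenario.active

    state = initialize_grid(settings, species, initial_concentration, scenario)
    slice_k = settings.slice_compartments
    # bottom-up: depths[0] is the midpoint of the compartment on the well bottom
    depths = (np.arange(settings.n_compartments) + 0.5) * settings.h

    profiles: list[metrics.ConcentrationProfile] = []
    rows: list[dict[str, float]] = []

    def record() -> None:
        profiles.append(
            metrics.ConcentrationProfile(
                time=state.time,
                depths=depths.copy(),
                concentrations=state.concentrations[::-1].copy(),
            )
        )
        slice_conc = state.concentrations[-slice_k:].mean(axis=0)
        rows.append(
            metrics.dose_row(
                time=state.time,
                slice_concentrations=slice_conc,
                bound_per_area=state.bound,
                dissolved_concentration=state.dissolved,
                diameters=state.diameters,
                effective_densities=state.effective_densities,
                material_density=material.density,
                medium_density=medium.density,
                slice_thickness=slice_k * state.h,
                suspended_per_area=state.suspended_per_area(),
            )
        )

    record()

    n_blocks = math.ceil(settings.duration / settings.output_interval) if settings.duration > 0 else 0
    logged_dt: float | None = None
    for block in range(n_blocks):
        block_end = min((block + 1) * settings.output_interval, settings.duration)
        block_seconds = block_end - state.time
        if block_seconds <= 0:
            record()
            continue

        # Cap with end-of-block diameters: dissolution only shrinks diameters,
        # which raises D monotonically, so the end-of-block diffusivity bounds
        # the whole block.
        if dissolving:
            end_diameters = _shrunk_diameters(state, scenario.dissolved_fraction(block_end))
            d_cap, s_cap = _species_coefficients(
                end_diameters, state.effective_densities, medium, correction
            )
            d_now, s_now = _species_coefficients(
                state.diameters, state.effective_densities, medium, correction
            )
            s_cap = np.where(np.abs(s_now) > np.abs(s_cap), s_now, s_cap)
        else:
            d_cap, s_cap = _species_coefficients(
                state.diameters, state.effective_densities, medium, correction
            )
        dt_cap = cap_time_step(settings.time_step, state.h, s_cap, d_cap, log=block == 0)
        steps = max(1, math.ceil(block_seconds / dt_cap))
        dt = block_seconds / steps
        if logged_dt is None or abs(dt - logged_dt) > 1e-12:
            logger.info(
                "effective time step %.6g s (%d steps per %.6g s output block)",
                dt,
                steps,
                block_seconds,
            )
            logged_dt = dt

        d_coeffs, s_coeffs = _species_coefficients(
            state.diameters, state.effective_densities, medium, correction
        )
        for _ in range(steps):
            if k_factor > 0.0:
                d_use, s_use = _concentration_corrected(state, d_coeffs, s_coeffs, k_factor)
            else:
                d_use, s_use = d_coeffs, s_coeffs
            diffusion_step(state, d_use, dt)
            sedimentation_step(state, s_use, dt)
            state.time += dt
            if settings.langmuir is not None:
                langmuir_partition(state, settings.langmuir)
            if dissolving:
                apply_dissolution(state, scenario, initial_concentration)
                d_coeffs, s_coeffs = _species_coefficients(
                    state.diameters, state.effective_densities, medium, correction
                )
        state.time = block_end  # absorb float accumulation drift
        record()

    return profiles, metrics.DoseTimeSeries.from_rows(rows)
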