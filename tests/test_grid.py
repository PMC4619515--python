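"""Unit tests for the compartmental solver."""

import numpy as np
import pytest

from conftest import assert_mass_conserved, preset_case
from nanodose.grid import (
    GRAVITY,
    DissolutionScenario,
    GridState,
    LangmuirParams,
    SimulationSettings,
    StabilityError,
    agglomerate_molar_concentration,
    apply_dissolution,
    cap_time_step,
    diffusion_step,
    initialize_grid,
    langmuir_partition,
    mass_specific_cross_section,
    run_simulation,
    sedimentation_step,
)
from nanodose.physics import AgglomerateSpecies, ENMaterial


def make_state(concentrations, h=1.0, diameters=None, eff_density=1500.0):
    conc = np.atleast_2d(np.asarray(concentrations, dtype=float))
    if conc.shape[1] > conc.shape[0]:
        conc = conc.T
    m = conc.shape[1]
    return GridState(
        time=0.0,
        h=h,
        height=h * conc.shape[0],
        concentrations=conc,
        bound=np.zeros(m),
        dissolved=0.0,
        diameters=np.full(m, 150e-9) if diameters is None else np.asarray(diameters),
        effective_densities=np.full(m, eff_density),
    )


class TestSettings:
    def test_compartment_count_from_target_height(self):
        s = SimulationSettings(height=3e-3, duration=1.0, compartment_height=5e-6)
        assert s.n_compartments == 600
        assert s.h == pytest.approx(5e-6)

    def test_slice_spans_two_default_compartments(self):
        s = SimulationSettings(height=3e-3, duration=1.0)
        assert s.slice_compartments == 2

    def test_slice_thinner_than_compartment_rejected(self):
        with pytest.raises(ValueError, match="bottom slice"):
            SimulationSettings(height=3e-3, duration=1.0, n_compartments=10)

    def test_minimum_compartments(self):
        with pytest.raises(ValueError):
            SimulationSettings(height=1e-3, duration=1.0, n_compartments=1, bottom_slice=1e-3)


class TestInitializeGrid:
    def test_homogeneous_monodisperse(self):
        settings = SimulationSettings(height=3e-3, duration=0.0)
        species = [AgglomerateSpecies(150e-9, 1500.0)]
        state = initialize_grid(settings, species, 0.1)
        assert state.concentrations.shape == (600, 1)
        assert np.all(state.concentrations == 0.1)
        assert state.bound.sum() == 0.0 and state.dissolved == 0.0

    def test_two_species_mass_partition(self):
        settings = SimulationSettings(height=3e-3, duration=0.0)
        species = [
            AgglomerateSpecies(100e-9, 1500.0, 0.25),
            AgglomerateSpecies(300e-9, 1500.0, 0.75),
        ]
        state = initialize_grid(settings, species, 0.1)
        np.testing.assert_allclose(state.concentrations[0], [0.025, 0.075])

    def test_fractions_must_sum_to_one(self):
        settings = SimulationSettings(height=3e-3, duration=0.0)
        species = [AgglomerateSpecies(100e-9, 1500.0, 0.5)]
        with pytest.raises(ValueError, match="sum to 1"):
            initialize_grid(settings, species, 0.1)

    def test_initial_dissolution_moves_mass_to_pool(self):
        settings = SimulationSettings(height=3e-3, duration=0.0)
        species = [AgglomerateSpecies(150e-9, 1500.0)]
        scen = DissolutionScenario(mode="initial_only", initial_fraction=0.2)
        state = initialize_grid(settings, species, 0.1, scen)
        assert np.all(state.concentrations == pytest.approx(0.08))
        assert state.dissolved == pytest.approx(0.02)
        # input diameters describe the post-initial-dissolution suspension
        assert state.diameters[0] == 150e-9


class TestDiffusionStep:
    def test_uniform_profile_unchanged(self):
        state = make_state([1.0, 1.0, 1.0])
        diffusion_step(state, np.array([0.1]), 1.0)
        np.testing.assert_allclose(state.concentrations[:, 0], [1.0, 1.0, 1.0])

    def test_three_compartment_hand_case(self):
        # dC_i = (dt/dz^2) [D (C_{i-1} - C_i) + D (C_{i+1} - C_i)], no-flux walls
        state = make_state([1.0, 0.0, 0.0])
        diffusion_step(state, np.array([0.1]), 1.0)
        np.testing.assert_allclose(state.concentrations[:, 0], [0.9, 0.1, 0.0], atol=1e-15)

    def test_mass_conserved(self):
        rng = np.random.default_rng(42)
        state = make_state(rng.uniform(0.0, 2.0, size=50))
        before = state.concentrations.sum()
        for _ in range(100):
            diffusion_step(state, np.array([0.2]), 1.0)
        assert state.concentrations.sum() == pytest.approx(before, rel=1e-13)
        assert np.all(state.concentrations >= 0)

    def test_stability_violation_raises(self):
        state = make_state([1.0, 0.0, 0.0])
        with pytest.raises(StabilityError):
            diffusion_step(state, np.array([1.0]), 1.0)

    def test_per_boundary_diffusivity_array(self):
        state = make_state([1.0, 0.0, 0.0])
        d_b = np.array([[0.1], [0.0]])  # lower boundary closed
        diffusion_step(state, d_b, 1.0)
        np.testing.assert_allclose(state.concentrations[:, 0], [0.9, 0.1, 0.0], atol=1e-15)


class TestSedimentationStep:
    def test_zero_coefficient_unchanged(self):
        state = make_state([1.0, 2.0, 3.0])
        sedimentation_step(state, np.array([0.0]), 1.0)
        np.testing.assert_allclose(state.concentrations[:, 0], [1.0, 2.0, 3.0])

    def test_hand_case_bottom_accumulates(self):
        # S g dt / h = 0.2: uniform column -> (0.8, 1.0, 1.2), mass preserved
        state = make_state([1.0, 1.0, 1.0])
        s = np.array([0.2 / GRAVITY])
        sedimentation_step(state, s, 1.0)
        np.testing.assert_allclose(state.concentrations[:, 0], [0.8, 1.0, 1.2], atol=1e-15)
        assert state.concentrations.sum() == pytest.approx(3.0, rel=1e-15)

    def test_buoyant_mirror_symmetry(self):
        rng = np.random.default_rng(7)
        profile = rng.uniform(0.0, 1.0, size=20)
        down = make_state(profile.copy())
        up = make_state(profile[::-1].copy())
        sedimentation_step(down, np.array([0.3 / GRAVITY]), 1.0)
        sedimentation_step(up, np.array([-0.3 / GRAVITY]), 1.0)
        np.testing.assert_allclose(up.concentrations[::-1, 0], down.concentrations[:, 0], rtol=1e-14)

    def test_overshoot_raises(self):
        state = make_state([1.0, 1.0, 1.0])
        with pytest.raises(RuntimeError, match="displacement"):
            sedimentation_step(state, np.array([1.5 / GRAVITY]), 1.0)


class TestCapTimeStep:
    def test_user_step_kept_when_safe(self):
        assert cap_time_step(1.0, 5e-6, np.array([1e-10]), np.array([1e-12])) == 1.0

    def test_half_height_rule(self):
        # S g dt_user = h -> dt halves
        h = 5e-6
        s = h / GRAVITY  # displacement h per 1 s
        assert cap_time_step(1.0, h, np.array([s]), np.array([0.0])) == pytest.approx(0.5)

    def test_fastest_species_dominates(self):
        h = 5e-6
        slow, fast = 1e-11, 1e-6
        capped = cap_time_step(1.0, h, np.array([slow, fast]), np.array([1e-13]))
        assert capped == pytest.approx(0.5 * h / (fast * GRAVITY))

    def test_diffusion_stability_cap(self):
        h = 1e-6
        d = 1e-11  # 0.5 h^2 / D = 0.05 s
        assert cap_time_step(1.0, h, np.array([0.0]), np.array([d])) == pytest.approx(0.05)


class TestLangmuir:
    def test_mass_specific_cross_section_hand_value(self):
        # A_m = 3 / (4 r rho_EV) with r = 100 nm, rho = 1500 -> 5000 m2/kg
        assert mass_specific_cross_section(200e-9, 1500.0) == pytest.approx(5000.0)

    def test_half_coverage_at_kd(self):
        # choose C so [P] exactly equals K_D (theta = 1/2) and geometry so
        # theta_avail = 1, putting the partition on its fractional branch
        d, rho = 200e-9, 1500.0
        c_bottom = 2e-4
        h = 1.0 / (c_bottom * mass_specific_cross_section(d, rho))  # theta_avail = 1
        kd = agglomerate_molar_concentration(c_bottom, d, rho)
        state = make_state([0.0, c_bottom], h=h, diameters=[d], eff_density=rho)
        langmuir_partition(state, LangmuirParams(kd))
        assert state.bound[0] == pytest.approx(0.5 * c_bottom * h, rel=1e-12)
        assert state.concentrations[-1, 0] == pytest.approx(0.5 * c_bottom, rel=1e-12)

    def test_huge_kd_matches_reflective(self, medium):
        material, species = preset_case("SiO2")
        common = dict(height=1e-3, duration=3600.0, output_interval=3600.0, n_compartments=200)
        ref_profiles, _ = run_simulation(
            SimulationSettings(**common), species, medium, material, 0.1
        )
        lang_profiles, lang_series = run_simulation(
            SimulationSettings(**common, langmuir=LangmuirParams(1e6)),
            species,
            medium,
            material,
            0.1,
        )
        np.testing.assert_allclose(
            lang_profiles[-1].total, ref_profiles[-1].total, rtol=1e-6
        )
        assert lang_series.bound_per_area[-1] < 1e-6 * 0.1 * 1e-3

    def test_invalid_kd(self):
        with pytest.raises(ValueError):
            LangmuirParams(0.0)

    def test_sticky_limit_binds_arriving_mass(self):
        state = make_state([0.0, 1.0], h=5e-6, diameters=[500e-9], eff_density=1500.0)
        langmuir_partition(state, LangmuirParams(1e-15))
        # theta ~ 1 and theta_avail < 1 here, so everything in the bottom binds
        assert state.concentrations[-1, 0] == pytest.approx(0.0, abs=1e-12)
        assert state.bound[0] == pytest.approx(5e-6, rel=1e-9)


class TestDissolution:
    def test_mode_none_is_inert(self):
        state = make_state([1.0, 1.0])
        scen = DissolutionScenario()
        apply_dissolution(state, scen, 1.0)
        assert state.dissolved == 0.0
        np.testing.assert_array_equal(state.concentrations[:, 0], [1.0, 1.0])

    def test_constant_rate_fraction(self):
        scen = DissolutionScenario(mode="constant_rate", initial_fraction=0.163, rate_per_hour=0.016)
        assert scen.dissolved_fraction(0.0) == pytest.approx(0.163)
        assert scen.dissolved_fraction(3600.0) == pytest.approx(0.179)
        assert scen.dissolved_fraction(1e9) == 1.0  # clamped

    def test_linear_ramp_fraction(self):
        scen = DissolutionScenario(
            mode="linear_ramp", initial_fraction=0.163, ramp_hours=12.0, max_fraction=0.7327
        )
        assert scen.dissolved_fraction(0.0) == pytest.approx(0.163)
        assert scen.dissolved_fraction(6 * 3600.0) == pytest.approx((0.163 + 0.7327) / 2.0)
        assert scen.dissolved_fraction(24 * 3600.0) == pytest.approx(0.7327)

    def test_dissolved_mass_removed_proportionally(self):
        state = make_state([2.0, 1.0, 1.0])
        scen = DissolutionScenario(mode="constant_rate", rate_per_hour=0.1)
        state.time = 3600.0
        apply_dissolution(state, scen, 4.0 / 3.0)  # c0 = column mean of (2,1,1)
        assert state.dissolved == pytest.approx(4.0 / 30.0)
        np.testing.assert_allclose(state.concentrations[:, 0], [1.8, 0.9, 0.9])

    def test_diameter_shrinks_with_cube_root(self):
        state = make_state([1.0, 1.0], diameters=[200e-9])
        scen = DissolutionScenario(mode="constant_rate", rate_per_hour=0.5)
        state.time = 3600.0
        apply_dissolution(state, scen, 1.0)
        assert state.diameters[0] == pytest.approx(200e-9 * 0.5 ** (1 / 3), rel=1e-12)

    def test_clamped_when_everything_dissolves(self, caplog):
        # part of the column mass is bound, so the target (all of c0) exceeds
        # what is suspended and the update clamps with a warning
        state = make_state([0.75, 0.75], diameters=[200e-9])
        state.bound[0] = 0.5
        scen = DissolutionScenario(mode="constant_rate", rate_per_hour=2.0)
        state.time = 3600.0
        with caplog.at_level("WARNING", logger="nanodose.grid"):
            apply_dissolution(state, scen, 1.0)
        assert state.dissolved == pytest.approx(0.75)
        assert state.concentrations.sum() == pytest.approx(0.0, abs=1e-15)
        assert any("clamping" in r.message for r in caplog.records)

    def test_invalid_scenarios(self):
        with pytest.raises(ValueError):
            DissolutionScenario(mode="linear_ramp", ramp_hours=0.0, max_fraction=0.5)
        with pytest.raises(ValueError):
            DissolutionScenario(mode="bogus")


class TestRunSimulation:
    def test_zero_duration_returns_initial_state(self, medium):
        material, species = preset_case("SiO2")
        settings = SimulationSettings(height=3e-3, duration=0.0)
        profiles, series = run_simulation(settings, species, medium, material, 0.1)
        assert len(profiles) == 1 and series.times.size == 1
        assert np.all(profiles[0].concentrations == 0.1)
        assert series.deposited_fraction[0] == pytest.approx(10e-6 / 3e-3, rel=1e-12)

    def test_mass_conserved_reflective(self, medium):
        material, species = preset_case("SiO2")
        settings = SimulationSettings(
            height=1e-3, duration=2 * 3600.0, output_interval=1800.0, n_compartments=200
        )
        profiles, series = run_simulation(settings, species, medium, material, 0.1)
        assert_mass_conserved(profiles, series, 0.1, 1e-3)

    def test_mass_conserved_langmuir_with_dissolution(self, medium):
        material, species = preset_case("ZnO")
        scen = DissolutionScenario(mode="constant_rate", initial_fraction=0.163, rate_per_hour=0.016)
        settings = SimulationSettings(
            height=1e-3,
            duration=2 * 3600.0,
            output_interval=1800.0,
            n_compartments=200,
            langmuir=LangmuirParams(1e-9),
        )
        profiles, series = run_simulation(
            settings, species, medium, material, 0.01, scenario=scen
        )
        assert_mass_conserved(profiles, series, 0.01, 1e-3)
        assert series.dissolved_concentration[-1] > series.dissolved_concentration[0]
        assert series.bound_per_area[-1] > 0

    def test_superposition_of_species(self, medium):
        material, _ = preset_case("SiO2")
        rho = 1500.0
        mix = [
            AgglomerateSpecies(120e-9, rho, 0.25),
            AgglomerateSpecies(350e-9, rho, 0.75),
        ]
        settings = SimulationSettings(
            height=1e-3, duration=3600.0, output_interval=3600.0, n_compartments=200
        )
        poly_profiles, _ = run_simulation(settings, mix, medium, material, 0.1)
        total = np.zeros(200)
        for sp in mix:
            mono = [AgglomerateSpecies(sp.diameter, rho, 1.0)]
            mono_profiles, _ = run_simulation(
                settings, mono, medium, material, 0.1 * sp.mass_fraction
            )
            total += mono_profiles[-1].total
        np.testing.assert_allclose(poly_profiles[-1].total, total, rtol=1e-12)

    def test_deterministic_rerun(self, medium):
        material, species = preset_case("Fe2O3")
        settings = SimulationSettings(
            height=1e-3, duration=3600.0, output_interval=1800.0, n_compartments=100
        )
        p1, s1 = run_simulation(settings, species, medium, material, 0.1)
        p2, s2 = run_simulation(settings, species, medium, material, 0.1)
        np.testing.assert_array_equal(p1[-1].concentrations, p2[-1].concentrations)
        np.testing.assert_array_equal(s1.bottom_concentration, s2.bottom_concentration)

    def test_bound_mass_monotone_under_sticky_boundary(self, medium):
        material, species = preset_case("SiO2")
        settings = SimulationSettings(
            height=1e-3,
            duration=2 * 3600.0,
            output_interval=1800.0,
            n_compartments=200,
            langmuir=LangmuirParams(1e-12),
        )
        _, series = run_simulation(settings, species, medium, material, 0.1)
        assert np.all(np.diff(series.bound_per_area) > 0)
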