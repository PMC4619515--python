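# nanodose

Compartmental 1-D sedimentation–diffusion dosimetry for engineered-nanomaterial
suspensions in cell-culture wells.

The suspension column is discretized into equal compartments between
impermeable top and bottom boundaries. Each iteration alternates an explicit
diffusion exchange (Stokes–Einstein diffusivity) with a fractional-displacement
sedimentation transfer (Stokes settling velocity), per size species. The well
bottom is either reflective or adsorptive via a Langmuir-isotherm partition
governed by a dissociation constant K_D; soluble materials can dissolve into a
well-mixed pool (initial-only, constant-rate, or linear-ramp scenarios) with
volume-proportional agglomerate shrinkage. Outputs are concentration profiles
over depth and time plus bottom-slice dose metrics: mass concentration,
deposited mass / particle number / surface area per well-bottom area, deposited
fraction, bound mass, and dissolved concentration.

## Layout

- `nanodose.physics` — transport coefficients and friction corrections
  (Cunningham slip, dynamic shape factors, solvation/roughness).
- `nanodose.grid` — the compartmental solver: initialization, diffusion and
  sedimentation steps, time-step capping (h/2 displacement rule plus explicit
  stability bound), Langmuir partition, dissolution, and the run loop.
- `nanodose.metrics` — number/volume size-distribution weighting,
  BET-equivalent diameters, number/surface concentrations, dose rows.
- `nanodose.reference` — independent oracles: closed-form exponential
  sedimentation–diffusion equilibrium and a Brownian random-walk tracker.
- `nanodose.presets` / `nanodose.config` / `nanodose.io` / `nanodose.cli` —
  five built-in material presets, YAML config with unit conversion
  (nm, g cm⁻³, mg ml⁻¹, mPa s, °C at the boundary; strict SI inside),
  CSV/JSON export, lognormal DLS-like fixture generation, CLI.

## CLI

```sh
nanodose presets list
nanodose presets show SiO2
nanodose synth-dls --gm-nm 150 --gsd 1.5 --bins 25 --out dist.csv
nanodose run --config run.yaml --out results/
nanodose diagnose tracker --diameter-nm 300 --effective-density-g-cm3 1.4 --out hist.csv
```

Example `run.yaml`:

```yaml
material:
  preset: SiO2
suspension:
  concentration_mg_ml: 0.1
  diameter_nm: 149.9        # or distribution_file: dist.csv + weighting: number
simulation:
  column_height_mm: 3.0
  duration_h: 24.0
  output_interval_h: 1.0
  boundary: reflective       # or langmuir + kd_molar: 1.0e-9
medium:
  density_g_cm3: 1.005       # defaults: water-like culture medium at 22 degC
  viscosity_mpa_s: 0.955
  temperature_c: 22.0
```

`run` writes `profile.csv` (time_h, z_um, species_id, mass_conc_mg_ml; depths
measured up from the well bottom), `timeseries.csv` (bottom-slice dose metrics
per output time) and `manifest.json` (resolved config, version, mass echo).
The deposited fraction is reported relative to the current suspended + bound
mass, so it equals the fraction of initial mass whenever nothing dissolves.

## Notes

- Default media properties (ρ = 1.005 g cm⁻³, η = 0.955 mPa s, 22 °C) are
  assumptions for protein-supplemented aqueous culture media and can be
  overridden in the `medium` block.
- The solver is deterministic; only the random-walk reference tracker consumes
  a seed.
- Bound (adsorbed) mass is accumulated permanently per species and excluded
  from the diffusion gradient; desorption is not simulated.
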