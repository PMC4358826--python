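# objdensity

Analysis pipeline for an environmental statistic of everyday liftable
objects — density falling as a power function of volume — and its
quantitative comparison against human ratio reports of expected weight
and perceived volume.

The package covers:

- **objects_io** — reading/writing object tables (volume, weight, derived
  density, dataset/class labels), with box-volume derivation from
  length × width × height and per-file unit conversion.
- **mesh_volume** — enclosed volume of watertight triangle meshes
  (OFF / ASCII PLY / triangulated OBJ) by signed-tetrahedron summation;
  refuses non-watertight meshes, ignores nested inner shells.
- **density_stats** — log-log Pearson correlations with exact t-transform
  p-values, power-law fits `d = c·V^γ`, per-dataset contrasts.
- **pair_ratios** — the full-factorial small/large pair set with
  natural-log volume/weight/density ratios (`DR = WR − VR` identically),
  OLS ratio lines, stimulus pair-ratio tables, and per-pair predictions
  via the weight-to-density ratio identity.
- **perception_stats** — ratio-report normalization, per-subject collapsed
  log-ratio means, Lilliefors normality test with seeded Monte-Carlo null,
  one-sample t-tests, the 2 (condition) × 3 (object set) × 6 (pair)
  split-plot ANOVA, per-pair post-hoc ANOVAs with Benjamini–Hochberg FDR,
  Cohen's d, and perceptual ratio-line fits.
- **synthetic_data** — seeded generators for power-law object populations
  and simulated observer cohorts (volume compression + density prior),
  plus a parameter-recovery harness.
- **cli** — config-driven orchestration.

## CLI

```sh
# environment analysis: correlations, power laws, pair lines, predictions
objdensity env --config env.yaml --out results/env

# perception analysis: ANOVAs, post-hoc table, effect sizes, line fits
objdensity perception --trials trials.csv --out results/perc

# synthetic data generation
objdensity simulate --config sim.yaml --seed 1 --out results/sim

# mesh volume
objdensity meshvol model.off
```

`env.yaml` lists object tables (either normalized CSVs or raw CSVs with a
column map); `sim.yaml` holds `environment:` and/or `observers:` sections
mirroring `EnvGenConfig` / `ObserverGenConfig`. Example:

```yaml
# sim.yaml
environment: {n_objects: 195, density_exponent: -0.387, log_noise_sd: 0.5}
observers:
  n_per_group: 10
  compression_beta: 0.85
  prior_line: {slope: -0.387, intercept: 0.114}
  report_log_noise_sd: 0.25
  trials_per_cell: 10
```

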