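# rowerchain

Simulation and analysis of hydrodynamically coupled "rower" chains near a
no-slip wall — a minimal model of motile-cilia coordination.

A rower is a bead driven along a fixed 1-D track by an attractive power-law
trap whose direction flips when the bead crosses a geometric switch point,
producing phase-free oscillations. Sixty rowers on tilted parallel tracks
above a wall, coupled through the wall-corrected (image-system) Green's
function of Stokes flow and subject to correlated Brownian noise, settle
into metachronal-wave states. Three control mechanisms can split the chain
into phase-locked subsets:

- **spacing** — every N_g-th gap widened by `d_x` (reduced coupling between
  groups),
- **amplitude** — every N_g-th rower's beat amplitude changed by `a_x`
  (trap recalibrated so its period is unchanged),
- **frequency** — every N_g-th rower's trap strength scaled by `f_x`
  (detuning).

Subset boundaries appear as "chevrons": sign reversals of the neighbour
phase difference. The analysis chain detects them via thresholded spatial
Fourier modes of the phase-difference profile and quantifies their
occurrence across seeded ensembles with an exact two-tailed binomial test
against chance (p = 0.5).

## Package layout

| module | contents |
| --- | --- |
| `rowerchain.geometry` | `ChainSpec`/`ChainConfig`, `build_chain`, control mechanisms, minimum-image convention |
| `rowerchain.hydrodynamics` | Oseen tensor, wall (image-system) Green's function, track-projected N×N mobility |
| `rowerchain.dynamics` | trap force, geometric switch, trap calibration, correlated-noise Brownian integrator, `simulate` |
| `rowerchain.phase_analysis` | geometric phase, phase-difference profiles, Fourier coefficients, chevron detection |
| `rowerchain.chevron_stats` | chevron surveys, p_ch estimation, exact binomial preference test, histograms |
| `rowerchain.experiments` | sweep runner, full/reduced presets, synthetic fixture profiles |
| `rowerchain.io`, `rowerchain.cli` | YAML configs, HDF5/CSV trajectories, command line |

## Command line

```sh
# one seeded run (YAML config optional; defaults are the published parameters)
rowerchain simulate --seed 1 --cycles 2000 --out run.h5 --csv run.csv

# chevron detection on stored trajectories
rowerchain analyze run.h5 --out chevrons.csv

# seeded sweep over one mechanism (presets: full | reduced)
rowerchain sweep --mechanism spacing --values 0,8,16 --preset reduced \
    --seed 0 --out sweep_out/

# synthetic phase profiles with known ground truth
rowerchain fixtures --kind square --k 3 --amplitude 0.3 --out profiles.csv
```

Config files mirror `ChainSpec`, with mechanism-specific keys nested under
`control:`; see `rowerchain.io.dump_spec` for the schema.

## Units

Internally the bead radius sets the length unit and seconds the time unit;
defaults correspond to amplitude 30a, spacing 7a, height 3a, switch offset
2.5a, a 2 s beat period, and dimensionless noise 3.7e-5. The overall
viscosity scale cancels from the phase dynamics.
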