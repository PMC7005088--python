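# axoporate

Desk-scale, multiscale analysis of axonal stretch injury. The package
couples two scales:

1. **Axon scale** — randomized representative volumes (RVs) of an
   unmyelinated axon (8 µm long, 1.15 µm diameter): a hexagonally
   packed bundle of 19 microtubule rows, each with two randomly placed
   discontinuities, cross-linked by viscoelastic tau proteins that stop
   carrying load at twice their rest length, embedded in a
   neurofilament network and wrapped in a 50 nm viscoelastic cortical
   shell. The RV is stretched uniaxially (displacement controlled, at
   1–40 /s) with an implicit Newmark solver, and the localized in-plane
   Green–Lagrange principal strains of the cortex are extracted.
2. **Membrane scale** — synthetic coarse-grained two-leaflet bilayer
   configurations at the axolemmal composition (6,700 lipids,
   42×42×12 nm box, ~100,000 water beads, optional embedded channel
   footprint) with planted ground truth, analysed by membrane metrics:
   area compressibility fit, pore detection (surface-tension jump and
   geometric water-column search), interdigitation index, water
   partition coefficient and the derived permeability change.

A configurable state map (interdigitation / poration onsets in local
strain, permeability cap, with and without an embedded channel) maps
the ensemble cortex-strain curves to axonal-strain injury thresholds
per strain rate.

## Layout

| module | role |
|---|---|
| `axoporate.axon_geometry` | randomized RV generation, ensembles, quarter symmetry |
| `axoporate.axon_mechanics` | material table, link/shell constitutive laws, implicit stretch solver with tau failure |
| `axoporate.cortex_strain` | Green–Lagrange strain extraction, max-strain curves, ensemble statistics, iso-strain tables, sensitivity scan |
| `axoporate.membrane_synth` | synthetic membrane generator: composition, protein footprint, planted pores / interdigitation / core water, affine strain, tension series |
| `axoporate.membrane_metrics` | compressibility fit, pore detectors, interdigitation index, partition/permeability |
| `axoporate.injury_map` | state map, threshold crossings, injury report |
| `axoporate.cli_io` | CLI, YAML run configuration, GRO/XYZ/CSV/JSON/HDF5 round-trips |

## CLI

```sh
axoporate generate-axon --seed 1 --out rv.json
axoporate simulate --rv rv.json --rate 10 --target 0.30 --out traj.h5
axoporate strains --traj traj.h5 --out curves.csv
axoporate gen-membrane --out mem.gro
axoporate gen-tension --ka 303 --noise-sd 1 --out tension.csv
axoporate metrics --config mem.gro --tension tension.csv --out metrics.json
axoporate injury-map --curves curves.csv --out report.json
axoporate run --out-dir run_out        # full pipeline, default settings
```

`axoporate run` with no overrides executes the reference experiment at
desk scale: a 10-member ensemble at strain rates 1, 10, 20, 40 /s up to
30 % axonal strain, followed by the state-map classification.

## Notes on scale

The membrane-scale reference values (compressibility 303/352 mN/m,
poration onsets ε_x = 0.34/0.47, log K = −1.73, permeability caps
40 %/51 %) are MD-derived quantities that enter this package as
configuration defaults and planted truths for estimator round-trips —
they are not re-derivable here. The axon-scale results (strain
localization, rate effects, the 10–15 % axonal-strain poration window)
are emergent properties of the mechanical model at desk scale.
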