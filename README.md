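# dpslattice

Tools for the structural analysis of intracellular DNA–Dps protein
crystals.  Dps, the major DNA-binding protein of starved bacteria, protects
the genome by co-crystallizing with DNA; in the crystal the protein appears
not as its familiar ~90 Å dodecamer but as a ~70 × 44 Å torus-like trimer.
`dpslattice` implements, as a tested pipeline on synthetic data with known
ground truth, the computational chain behind that assignment:

- **Triclinic cell mathematics** — metric tensors, volumes, d-spacings,
  Friedel-canonical reflection enumeration, and conversions among d,
  q = 4π sin θ/λ and 2θ (`dpslattice.cell`).
- **Lattice inference** — recovery of the P1 cell
  a = b = 83.3 ± 3.2 Å, c = 54.2 ± 2.7 Å, α ≈ β ≈ γ ≈ 60.5 ± 4° from
  trimer-center coordinates via pair distance/angle distribution functions
  and neighbor-vector clustering (`dpslattice.inference`).
- **Powder simulation** — structure factors of a trimer/DNA-rod bead
  crystal, Scherrer size broadening for 200 nm crystallites, and matching
  of the simulated peaks against the measured interplanar distances
  d = 69.6, 54.5, 45.0, 34.4 Å (`dpslattice.powder`).
- **SAXS reduction** — azimuthal averaging of 2D powder images, SNIP-style
  background estimation, Bragg-peak picking and indexing
  (`dpslattice.reduction`).
- **Energetics & packing** — thermodynamic-integration bookkeeping
  ΔΔG = ΔG_bound − ΔG_solvation for the two candidate trimer types, the
  (shifted) Lennard-Jones 12-6 potential of the coarse-grained water model,
  and the rigid-volume monomer capacity of the toroidal particle
  (`dpslattice.energetics`).
- **Synthetic data** — jittered finite lattices, bead crystals, powder
  curves and detector images, all seeded and bit-reproducible
  (`dpslattice.synthetic`).

See `docs/methods.md` for the models, conventions and design choices.

## Worked example

The `demo` subcommand runs the whole chain — generate 150 jittered trimer
centers from the fitted cell, infer the lattice back, simulate the powder
pattern of the trimer/DNA-rod crystal, render and reduce a detector image,
and match against the measured d-spacings:

```sh
$ dpslattice demo --out demo_out --seed 0
recovered cell:
  a = 83.22 +/- 2.14
  b = 83.14 +/- 1.99
  c = 54.09 +/- 2.32
  alpha = 60.53 +/- 1.88
  beta = 60.27 +/- 1.90
  gamma = 60.58 +/- 1.32
experimental peaks matched: 4/4
outputs in demo_out/ (see report.json)
```

The recovered constants sit well inside the quoted uncertainties of the
fitted cell (±3.2 Å, ±2.7 Å, ±4°), and every one of the four measured
powder rings is accounted for by a model reflection within 5%.

The free-energy bookkeeping compares the two ways of cutting a trimer out
of the dodecamer:

```sh
$ dpslattice energetics
{
 "dps_pore":      { "ddG_kJ_per_mol": -115.46, "err_kJ_per_mol": 42.36, ... },
 "ferritin_pore": { "ddG_kJ_per_mol": -185.98, "err_kJ_per_mol": 38.74, ... }
}
```

The ferritin-like pore trimer binds its subunit ~70 kJ/mol more favorably —
the energetic argument for which trimer builds the crystal.  The packing
argument is one line each:

```sh
$ dpslattice capacity --mode box        # 70x70x44 A bounding box
4
$ dpslattice capacity --mode cylinder   # cylindrical particle volume
3
```

Four monomers fit the bounding box, three fit the actual cylindrical
volume: the particle is a trimer.

The same operations are available as library calls
(`infer_lattice`, `simulate_powder_pattern`, `reduce_image`,
`binding_delta_g`, …) and as further subcommands
(`simulate-crystal`, `infer-lattice`, `powder`, `reduce-saxs`,
`match-peaks`, `run`).

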