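# Methods

`dpslattice` implements the computational chain by which the crystal formed
by the DNA-binding protein Dps with DNA is assigned a trimeric building
block: inference of a triclinic (P1) lattice from oligomer-center
coordinates, simulation of the powder X-ray pattern of the resulting model
crystal, reduction of 2D powder detector images to indexed Bragg peaks, and
the scalar free-energy and volume-packing arithmetic that supports the
trimer assignment.  This note records the models, the parameters that
matter, and the design choices made where the procedure was genuinely open.

## Units and conventions

All lengths are Angstrom, everywhere.  Several source dimensions for this
system are printed with nm units where Angstrom is clearly meant (a 70 nm
protein torus would be larger than the cell structures it sits in); the
package interprets all such values as Angstrom.  Angles cross the API in
degrees.  Momentum transfer follows the small-angle convention
q = 4π sin θ / λ with d = 2π/q; the X-ray wavelength is Cu Kα, λ = 1.542 Å.
Lattice bases are row matrices with a along x, b in the xy-plane, and c
completing a right-handed set.  Reflections are stored Friedel-canonically
(first nonzero Miller index positive) with multiplicity 2; P1 has no other
symmetry.

## Lattice inference from center coordinates

The observable is a cloud of ~150 trimer centers placed in an
electron-density map.  Two densities summarize it: the pair distance
distribution (kernel density over all pairwise distances, default bandwidth
1.5 Å) and the pair angle distribution.  The angle function is not uniquely
defined in the literature this mirrors; here it is the density of angles
between pairs of neighbor displacement vectors sharing a center (default
neighbor cutoff 90 Å, bandwidth 3°), which reproduces the characteristic
~60.5°/~121° two-mode pattern of this lattice.  Both are implemented as
fine histograms (bandwidth/4 bins) smoothed with a Gaussian, with modes
refined by three-point parabolic interpolation, so results are independent
of point ordering.

`infer_lattice` recovers the full cell rather than reading constants off
the mode positions: nearest-neighbor displacement vectors within the cutoff
are merged antipodally (v ≡ −v), clustered by single linkage with an 8 Å
tolerance, and the three shortest mutually non-coplanar cluster means seed
a basis.  Every displacement vector is then indexed to its nearest integer
combination and the basis re-fit by linear least squares.  Per-constant
uncertainties are the standard deviations of cluster-member lengths and
directions — the scatter style in which ± values are quoted for averaged
placements — not covariances of the least-squares fit, which would
overclaim.

**Presentation convention.**  A lattice has infinitely many primitive
bases.  The shortest all-acute basis of the Dps crystal lattice is
(73.7, 73.7, 54.2 Å; 79.7°, 79.7°, 69.4°), yet the cell is conventionally
reported in its near-rhombohedral setting a = b = 83.3, c = 54.2 Å, all
angles 60.5°, whose basis vectors follow the dominant neighbor-distance
families.  The package therefore reduces to a deterministic presentation
basis: starting from a pair-reduced (short) basis it searches small
unimodular re-combinations (coefficients in [−2, 2], vector length capped
at 1.3× the longest reduced vector) and picks the triple with the fewest
obtuse inter-axial angles, then the most isometric angle set (minimal
spread), then minimal total length, ordered longest-first and right-handed.
For orthogonal lattices this returns the ordinary setting (right angles,
spread zero); for the Dps lattice it returns the equal-angle setting
exactly.  `canonical_cell` exposes the convention, and recovery tests
compare against the canonical form of the generating cell.

## Synthetic data

The generator module produces every input with known ground truth:

- **Centers** — nodes i·a + j·b + k·c over an extent box, each kept with
  probability 1 − vacancy rate and displaced by isotropic Gaussian jitter.
  The demo conditions are a (6, 6, 5) box from the fitted cell, jitter
  σ = 1.5 Å, 5% vacancies, subsampled to 150 centers to emulate partial
  tomographic coverage.  The jitter default keeps recovery comfortably
  inside the quoted ±3.2 Å / ±2.7 Å / ±4° bands.
- **Scatterers** — a three-bead trimer motif (beads at 120° on a 20 Å
  circle, a torus analogue of the ~70 × 44 Å particle) on every node, plus
  an optional DNA rod threaded along the c channel at the cell's in-plane
  midpoint, one bead per 3.4 Å base-pair rise.  Scattering weights are in
  kDa-equivalent units — 18.7 kDa per protein bead, 0.66 kDa per base
  pair — because scattering power scales with molecular mass; with equal
  unit weights the rod would dominate and artificially extinguish the
  l ≠ 0 reflections a real protein crystal shows.
- **1D curves** — power-law-plus-constant background (the smooth
  "amorphous" cell-material component) plus Gaussian Bragg peaks, with
  optional Poisson counting noise that preserves expectations.
- **Detector images** — azimuthally symmetric rendering of a 1D curve onto
  a flat detector at 2.0 m, 512² pixels of 0.3 mm, via the exact
  2θ = arctan(r/L) mapping, plus Poisson noise.  The pixel size is chosen
  so all four observed rings (d = 69.6 … 34.4 Å, 2θ up to 2.6°) land on
  the detector.
- **Projections** — centers splatted as Gaussians on a pixel grid, a
  stand-in for TEM projections with no contrast-transfer function.

What the generators do *not* emulate: real electron-density maps and their
fitting ambiguity, TEM contrast/CTF, detector flat-field or dark current,
absorption, preferred orientation, or all-atom structure.  Passing tests
therefore demonstrate the correctness and self-consistency of the
computational chain under the stated noise model, not the microscopy-side
results (in vivo crystal fractions, TEM repeat distances), which depend on
real images.

## Powder simulation

Structure factors are computed directly from the scatterers:
F(hkl) = Σⱼ wⱼ exp(−q²sⱼ²/2) exp(2πi (hkl)·xⱼ) with fractional coordinates
xⱼ and per-site Gaussian widths sⱼ as a simple isotropic form factor — no
map FFT and no Cromer–Mann coefficients, which point scatterers at this
resolution (d ≥ 30 Å) do not need.  Each canonical reflection becomes a
Gaussian at its Bragg angle whose FWHM follows the Scherrer relation
K·λ/(L·cos θ) for a crystallite of linear size L (default 2000 Å = 200 nm;
shape constant K = 0.9, configurable — the conventional value for unknown
habit).  Gaussian profiles are used deliberately (finite-size blurring by a
normal distribution), not Voigt.  The Lorentz/polarization correction is
off by default: peak *positions* are the comparison surface, and the
correction moves only intensities.  Peak areas are 2|F|² (Friedel pair);
total integrated intensity is conserved to the grid's quadrature accuracy.

Model-to-experiment agreement is scored by `match_peaks`: greedy best-pair
matching of experimental to model d-spacings by relative difference, each
value used at most once, at 5% tolerance.

## SAXS reduction

Azimuthal (polar-angle) averaging bins pixels by exact 2θ and takes the
per-bin mean of unmasked pixels (median available); empty bins are marked
invalid, never zero.  The background under the Bragg peaks is estimated by
a SNIP-style iterative clipping filter — each interior sample is replaced
by min(itself, average of its ±w neighbors) with w swept from the window
(default 15 bins) down to 1 — iterated until a fixed point (≤200 sweeps),
so the baseline never exceeds the curve and is idempotent.  Clipping skips
the first/last w samples: averaging across the array edge would drag a
monotone curve down at its ends.  Features wider than about twice the
window survive into the baseline; peaks that close to the edge of the
angular range are not recovered.

Peaks are local maxima of the background-subtracted residual above two
floors: a fraction of the residual maximum (default 5%) and `min_snr` = 8
times the noise level, estimated globally from the residual MAD and locally
from the counting statistics of the bin mean (√(I/n_pixels)).  Extreme
peak-to-valley prominences of pure noise across ~10³ bins reach about 5
noise units, so the floor of 8 sits above the noise extreme-value range
while genuine Bragg peaks in this regime exceed it by an order of
magnitude.  Positions are refined by three-point parabolic interpolation
(ties toward larger d) and converted to q and d.  Overlapping peaks closer
than about the profile width merge into a single maximum and are reported
as one peak with a correspondingly large width; no deblending is attempted.

## Energetics and packing

The trimer-assignment arithmetic is exact bookkeeping.  Subunit binding
free energies are ΔΔG = ΔG_bound − ΔG_solvation of the slow-growth
thermodynamic-integration legs, with errors propagated in quadrature under
an independence assumption (the source reports ± on the legs but none on
the differences; the propagation is this package's extension).  Computed at
full precision, ΔΔG is −115.46 kJ/mol for the Dps-type pore trimer and
−185.98 kJ/mol for the ferritin-like pore trimer; the commonly quoted
−185 kJ/mol differs from the latter by just under 1 kJ/mol, a rounding gap
the reports flag explicitly.  The 12-6 Lennard-Jones potential
U = 4ε[(σ/r)¹² − (σ/r)⁶] is provided in plain and cutoff-shifted form
(U(r_cut) = 0, cutoff 1.2 nm, the coarse-grained van der Waals cutoff);
the ordinary/antifreeze water distinction lives entirely in σ (0.47 vs
0.57 nm).

Monomer capacity is a rigid-volume bound, not a packing algorithm: the
particle volume (d × d × h box, π(d/2)²h cylinder, or cylinder minus a
central cavity cylinder) divided by the monomer bounding-box volume,
floored.  For the 70 × 70 × 44 Å torus and a 58 × 25 × 35 Å monomer the box
gives 4 and the cylinder gives 3 — the trimer — without needing an explicit
cavity size, which is never quantified for this particle; the cavity mode
exists for sensitivity analysis.

## Numerical choices and degenerate inputs

Cells must satisfy the triclinic realizability discriminant
1 − cos²α − cos²β − cos²γ + 2cosα cosβ cosγ > 0; violations raise
immediately with the violated invariant named.  Reflection enumeration
bounds each index by ⌈|vᵢ|/d_min⌉ + 1 (a Cauchy–Schwarz bound, proven
sufficient, with one index of margin).  Bragg conversions reject λ ≥ 2d
(unreachable reflection) and round-trip to 1e-10 relative.  Lattice
inference requires ≥ 8 centers and three non-coplanar displacement
clusters; coplanar clouds raise with the deficiency named.  The Scherrer
width diverges as θ → 90° and raises there.  All generators accept integer
seeds (or a shared `numpy` Generator) and are bit-reproducible; the
pipeline derives per-stage child seeds as `SeedSequence([seed, stage])` so
stages can be rerun in isolation.

## Problem sizes

The shipped demo and the reproduction script run at the scale of the
original analysis: 150 centers, ~20 reflections to d = 30 Å, 512² detector
images, 800 azimuthal bins, 100 replicates for the recovery-rate check.
Everything completes in seconds on one core.

## Known limitations

- The presentation convention for the fitted cell is a package choice;
  other reduction conventions (strict Niggli) would report the same
  lattice with different constants.
- The trimer motif is a bead cartoon; simulated intensities are not
  comparable to experiment beyond peak positions.
- The angle-distribution modes at ~60.5° and ~121° are not forced to be
  supplementary, and the package does not attempt to explain their exact
  relation to the cell angles.
- No deblending of overlapping Bragg peaks; no detector calibration
  corrections; no space-group machinery beyond P1.
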