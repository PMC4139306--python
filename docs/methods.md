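# Methods

This note records the physical model, the parameter choices with units
and defaults, the numerical methods, and the known limitations of the
`memesp` toolkit.  All lengths are Å, energies kcal/mol, potentials
kcal/mol/e, charges in units of the proton charge e, temperatures in K.

## Physical model

The toolkit analyzes the continuum electrostatic potential around a
charged lipid headgroup — a phosphoinositide such as PtdIns(3)P, net
−3 e — embedded in a neutral zwitterionic (POPC-like) bilayer in
physiological salt.

The potential obeys the Poisson–Boltzmann (PB) equation

```
∇·(ε(r) ∇φ(r)) − κ̄²(r) φ(r) = −4π C ρ(r)
```

with `C = 332.0637 kcal·Å/(mol·e²)` the Coulomb constant in these
units, `ε` the position-dependent relative dielectric, `κ̄² = ε κ²` the
screening coefficient (zero inside the solute and inside the
ion-exclusion layer), and `ρ` the fixed charge density.  The default is
the **linearized** form; the full `sinh` form is available behind
`PBConfig(nonlinear=True)` via a damped fixed-point iteration on the
excess source term.  The linearized default keeps the solver a linear
operator (superposition and sign-flip hold exactly, which the tests
exploit); for a −3 e headgroup in 100 mM salt, linear and nonlinear
solutions differ by a few percent where |φ| ≲ kT/e, the region all
downstream metrics read.

At T = 296 K, kT = 0.5882 kcal/mol, so the conventional contour level
−0.6 kcal/mol/e is ≈ 1 kT/e.  In 100 mM 1:1 salt at ε = 80 the inverse
Debye length is κ = 0.10335 Å⁻¹ (computed from scipy's physical
constants, not hard-coded).

### Default PB protocol

| parameter | default | notes |
|---|---|---|
| solute dielectric | 2 | inside atom spheres |
| solvent dielectric | 80 | |
| ionic strength | 0.1 mol/L | 1:1 electrolyte |
| temperature | 296 K | |
| ion exclusion radius | 2.0 Å | inflates atoms for the κ̄² map |
| outer grid | 271 × 271 × 222 @ 2.0 Å | Dirichlet boundary from the screened-Coulomb superposition |
| inner (focus) grid | 201³ @ 0.5 Å | centered on the P1 phosphate, boundary interpolated from the outer solve |
| tolerance | 1e-6 relative residual | |

Dielectric maps use atom spheres with harmonic-mean face dielectrics;
charges are spread to the 8 surrounding grid points (trilinear
antialiasing), which conserves total charge exactly.

## Synthetic bilayer generator

There is no bundled molecular-dynamics data; the generator produces the
*kind* of system the analyses were designed for, with known ground
truth:

- two leaflets of pseudo-lipids on a hexagonal lattice
  (`lattice_constant = 8.4 Å` → area per lipid ≈ 61 Å², leaflet
  separation 38 Å, typical of fluid POPC);
- each pseudo-lipid is a ±1 e dipole: phosphate charge at the leaflet
  plane, choline charge 4.5 Å toward solvent — the zwitterionic
  headgroup reduced to its leading multipole;
- one probe lipid at the central upper-leaflet site: a −3 e `P1`
  phosphate plus uncharged `C3/C4/C5/P3` ring markers planted at known
  tilt angles (defaults Θ = 44.3°, Φ = −26.9°) and protrusion
  (`probe_z_offset`);
- snapshots are Gaussian positional jitter (`fluctuation_sigma`,
  default 0.5 Å) of every atom; optionally a snapshot grid is "spiked"
  with probability `outlier_rate` — an additive `outlier_amplitude`
  (default 50 kcal/mol/e) at a random 0.1% of voxels — to exercise
  robust averaging.

Snapshot potentials come from the closed-form screened-Coulomb
(Debye–Hückel) superposition, which doubles as an exact oracle for the
finite-difference solver.  The generator does **not** emulate acyl
chains, lateral diffusion, undulations, membrane dielectric contrast in
the analytic potential, or correlated lipid motion; it is a test
harness, not a simulation.

## Analyses

**Robust ensemble average (remedian).**  A streaming median-of-medians:
`depth` cascading buffers of `base` grids (defaults 9 and 3, capacity
9³ = 729 grids) with memory `base × depth` grids regardless of ensemble
length.  When a buffer fills, its voxel-wise median is pushed one level
up.  At full capacity the result equals the nested median exactly.  For
partial fills, finalization takes the voxel-wise *weighted* median of
all buffered entries, a level-`i` entry carrying weight `base^i`
(smallest index with twice the cumulative weight ≥ total; midpoint at
an exact tie) — equivalent to the plain median of the weight-expanded
sample.  Exceeding capacity raises rather than silently degrading.

**Similarity.**  Hodgkin index `SI = 2Σab / (Σa² + Σb²)` over a skin
region; electrostatic distance `D = √(2 − 2·SI) ∈ [0, 2]`.  The skin is
the set of voxels between the probe-inflated and probe+skin-inflated
van der Waals surfaces (defaults: probe 2 Å, skin 3 Å), intersected
with a sphere around P1 (10 or 14 Å typical).  Default policy is one
*shared* mask for all grids of an ensemble (distances then satisfy the
triangle inequality on the common vector space); per-grid masks with
pairwise intersection are available explicitly.  The similarity
autocorrelation of an evenly sampled ensemble is
`ACF(τ) = 1 − ⟨D(t, t+τ)⟩_t / ⟨D⟩_all pairs`: 1 at lag 0, ≈0 for an
uncorrelated ensemble.

**Isopotential bulge height.**  Along the vertical column above P1, the
topmost crossing of the −0.6 kcal/mol/e level (bilinear interpolation
of the column profile in x,y; linear interpolation in z between
bracketing voxels).  An optional lateral search takes the maximum over
columns within a radius of P1.  The height is referenced either to P1
itself or to the mean z of same-leaflet POPC phosphates beyond a 15 Å
lateral exclusion around the probe (the unperturbed-membrane plane).
If the potential never reaches the level, the result is `None` — the
contour does not protrude.

**Headgroup geometry.**  Θ is the angle of the P1→C4 vector to the
membrane normal (+z for the upper leaflet); Φ the angle of C3→C5,
signed by rotating the frame about z so that P1→C4 lies in the xz
half-plane with positive x and taking the sign of the x-component.
Both are invariant under rotation about z and translation.  The
`from-plane` convention (angles from the membrane plane rather than the
normal) subtracts 90°.

## Numerical choices

- Finite differences: 7-point stencil, red–black successive
  over-relaxation with ω = 2/(1 + sin(π/n)); convergence is the
  relative residual against max(‖source‖, ‖diag·φ‖).
- Focusing: inner-boundary values trilinearly interpolated from the
  outer solution; the inner box must be contained in the outer box.
- On a 65³ grid at 0.5 Å the solver reproduces the single-ion
  closed form to < 3% relative error for r ≥ 2 Å (measured by the test
  suite), and the error decreases when the spacing is halved.
- Desk-scale problem sizes used in tests and examples (33³–81³ grids,
  16–64 lipids per leaflet, ensembles of 20–200 snapshots) are this
  package's own choice so the whole suite runs in minutes on one CPU;
  the full protocol sizes above are defaults of `PBConfig` only.

## Reference-grid reproduction

One acceptance test replays the measurement pipeline on deposited
ensemble-average potential grids of an all-atom bilayer study (two
force fields; regular-membrane averages, single snapshots, remedian and
mean averages).  Those grids are multi-megabyte binaries that cannot be
bundled and must be downloaded separately; place them as

```
data/reference_grids/
    regular_gaff.grd     regular_charmm.grd
    snapshot_gaff.grd    snapshot_charmm.grd
    remedian_gaff.grd    remedian_charmm.grd
    mean_gaff.grd        mean_charmm.grd
    headgroup.pqr        # probe structure; P1 centers the skin masks
```

(UHBD format, converted if necessary with `memesp grid convert`).  With
the files present the test checks bulge heights (±0.25 Å) and
cross-force-field electrostatic distances at 10/14 Å spheres (±0.02)
using the shared-skin mode.  Without them the test *fails* — it does
not skip — so an offline run makes the unverified pathway visible
instead of hiding it.

## Limitations

- Cubic voxels and axis-aligned grids only.
- The linear solver is plain SOR (no multigrid); the default 201³/271³
  protocol sizes take far longer than the desk-scale grids used in the
  tests.
- The nonlinear PB path is a damped fixed-point iteration; it is
  validated only in the small-potential regime against the linear
  solution.
- The synthetic generator's simplifications listed above; in particular
  the analytic snapshot potentials use a uniform solvent dielectric, so
  generator-based checks probe the analysis chain, not membrane
  dielectric physics.
- Remedian results depend (mildly) on input order below full buffer
  boundaries, as for any streaming median-of-medians.
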