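# Methods

This note documents the models, conventions and numerical choices behind
`etsnocv`, and what the shipped tests do and do not establish.

## Decomposition model

The interaction energy of two frozen-geometry fragments is resolved through
three reference states evaluated with the *same* supermolecule integrals
and one shared quadrature grid:

1. **Summed frozen densities** ρ_A + ρ_B. Its energy relative to the
   fragments splits exactly into the classical electrostatic term (assembled
   directly from its definition: fragment densities in the other fragment's
   nuclear potential, cross nuclear repulsion, cross Coulomb) and the
   XC-nonadditivity ΔE_XC⁰, which for hybrids includes the a-scaled exact-
   exchange cross term. Both routes are computed and must agree; the
   residual is recorded with every run.
2. **Promolecule** ρ⁰: the occupied fragment orbitals embedded into the
   supermolecule AO basis and sequentially Schmidt-orthonormalized in the
   overlap metric, per spin channel, all of A first, then B. The occupied
   projector (hence every downstream energy) is order-invariant; A-first is
   fixed for reproducible per-orbital provenance. Linear dependence is
   detected at a residual S-norm² of 1e-8. ΔẼ_Pauli = E[ρ⁰] − E[ρ_A+ρ_B];
   the reported Pauli repulsion adds ΔE_XC⁰.
3. **Relaxed adduct** ρ. The reported ΔE_orb is the exact difference
   E[ρ] − E[ρ⁰], which guarantees that ΔE_elstat + ΔE_Pauli + ΔE_orb
   (+ ΔE_disp + ΔE_C^MP2 + corrections) telescopes to the supramolecular
   ΔE_int identically; the residual is asserted below 1e-9 Ha on every
   test system. The first- and second-order transition-state estimates
   Tr{F[ρ^TS] ΔP} and Tr{F̃ ΔP} are reported alongside; the latter anchors
   the NOCV channel energies. For Hartree-Fock the energy is quadratic in
   the density matrix, so both estimates coincide with the exact
   difference; the distinction is only visible with DFT functionals.

Fragment reference energies enter in two forms: the fragment's own SCF
energy (monomer basis and grid), and the embedded fragment density
evaluated with supermolecule integrals, the shared grid and the fragment's
own nuclei. The decomposition uses the latter so all identities hold to
machine precision; the difference between the two is pure quadrature error
(zero for HF) and is reported as a per-fragment grid-consistency
diagnostic. Fragment SCF runs in the fragment-only (monomer) AO basis;
a ghost-augmented fragment basis is a possible extension, not implemented.

ΔE_prep is computed from relaxed fragment geometries when supplied and
reported as 0 with a warning otherwise.

## NOCV conventions

* The valence operator is represented by (ΔP, S); the eigenproblem is
  solved symmetrically via the Löwdin transform S^{1/2} ΔP S^{1/2}, which
  guarantees a real spectrum and S-orthonormal back-transformed vectors.
* Restricted (closed-shell) runs diagonalize the occupancy-2 spatial ΔP,
  so eigenvalues are per spatial orbital pair and channel energies sum
  directly to the restricted Tr{F̃ ΔP}. Conventions differ between codes;
  halve v_k to compare with per-spin-orbital conventions.
* Any open-shell participant switches the whole decomposition to the
  spin-resolved path: per-spin ΔP^σ are diagonalized and paired
  independently, ΔE_orb = Σ_σ Σ_k ΔE_orb,k^σ, and the total deformation
  density is the spin sum. Open-shell fragment pairs couple with fragment
  A carrying excess α and B excess β by default; a per-fragment
  orientation flag overrides this.
* Eigenvectors are phase-fixed (largest-magnitude coefficient positive)
  and channels ordered by descending eigenvalue, so output is reproducible
  across linear-algebra backends. Degenerate channels (e.g. a π pair) are
  reported individually.
* Pairing tolerance 1e-7; unmatched eigenvalues above it raise on
  idempotent inputs and are reported as diagnostics otherwise. The printed
  channel cutoff is v ≥ 0.001 (configurable); energy completeness is
  always verified against the full spectrum.
* Double hybrids: the NOCV analysis runs on the SCF (DFT-part) density
  difference only, preserving pairing. The MP2 contribution is the
  unrelaxed (amplitude-level) difference density; the a_C-scaled energy
  delta is its own decomposition line, and ΔΔρ_C^MP2 — the adduct MP2
  density correction minus the embedded fragment corrections — is exported
  as a scalar field. Orbital-relaxed MP2 densities are not implemented,
  and the double-hybrid path requires closed-shell fragments and adduct.

## Electronic-structure engine

The package ships its own compact Gaussian-basis engine behind the backend
interface (an external SCF engine can be adapted to the same surface):

* **Integrals**: McMurchie-Davidson over contracted Cartesian Gaussians
  (s, p; d-ready), numba-compiled, with a series/downward-recursion Boys
  function. Validated against closed forms and independent 3-D quadrature
  in the test suite.
* **Basis**: an STO-3G-type minimal basis for H–Ar. H–Ne use the standard
  published contractions; Na–Ar use the same universal three-Gaussian fits
  (the 3s3p fit regenerated by overlap maximization, matching the
  published contraction to seven digits) scaled by Slater-rule exponents.
  Minimal-basis consequences worth knowing: rare-gas atoms have no virtual
  orbitals, so for He₂ and Ar₂ the orbital term vanishes identically and
  no channels exist — the physically expected minimal-basis limit, useful
  as an exact null case.
* **SCF**: one spin-resolved loop serves RHF/UHF/RKS/UKS (restricted path
  ties the channels), DIIS on the orthonormal-basis commutator with light
  early damping, core-Hamiltonian guess. Defaults: energy 1e-8 Ha and
  density RMS 1e-7 convergence — decomposition terms printed to
  0.01 kcal/mol (≈1.6e-5 Ha) need tighter SCF than the print precision.
  Non-convergence raises with the iteration history attached.
* **Functionals**: Slater exchange, VWN parameterization V, Becke-88
  exchange correction, Lee-Yang-Parr correlation (Miehlich form).
  Available methods: `hf`; `lda`; `blyp`; `b3lyp` (0.20 exact exchange,
  0.08/0.72 Slater/B88 exchange, 0.19/0.81 VWN5/LYP correlation — the
  VWN5 variant, so cross-code comparisons against VWN3-based B3LYP
  implementations will differ slightly); `b2plyp` (a_X = 0.53,
  a_C = 0.27); `mp2`. XC potentials are pointwise central finite
  differences of the energy density in (ρ_α, ρ_β, σ_αα, σ_αβ, σ_ββ) with
  domain-respecting stencils — one uniform, well-tested code path instead
  of per-functional analytic derivatives; correctness is enforced by a
  directional-derivative property test (E[P ± εD] vs Tr(F D)).
* **Grid**: Becke fuzzy-cell partitioning (three switching iterations,
  Bragg-Slater radii, no size adjustment) with Gauss-Chebyshev radial
  points (Becke mapping) and a Gauss-Legendre × uniform-φ angular product
  rule; default 40 radial × (12×24) angular points per atom. One grid —
  the supermolecule's — is used for every XC evaluation in a run, so grid
  error cancels between the terms of an energy difference. Grid accuracy
  is tested against the analytic local-exchange integral of an exponential
  density (6 significant digits at default settings).
* **Dispersion**: providers behind a registry. `none` (default) and
  `pairwise-bj`, a lightweight atom-pairwise −C₆/R⁶ model with
  Becke-Johnson-style rational damping (free-atom C₆, combination rule
  2C₆ᵢC₆ⱼ/(C₆ᵢ+C₆ⱼ), damping radius 0.40·(r_vdW,i + r_vdW,j) + 1.8 bohr).
  This is a generic damped London term for qualitative decompositions —
  not Grimme's D3 parameterization (no coordination-number dependence,
  no C₈, no three-body term). Composite-method corrections (geometric
  counterpoise, short-range basis) enter through the same provider
  interface as grouped deltas; no specific parameterization is bundled.

## Fixtures: what they emulate and what they do not

The generated toy systems cover the qualitatively distinct bonding
regimes: closed-shell repulsion (he2 at 2.0 Å), donor-acceptor cations
(heh+ 0.93 Å, arli+ 2.40 Å), covalent bonding from open-shell atoms
(h2_from_atoms at 1.4 bohr), dispersion-bound rare gases (ar2 3.76 Å),
borderline metallic-covalent Be₂ (2.45 Å), and hydrogen bonds (hf2,
water2 at standard hydrogen-bonded motifs). Separations are realistic
near-equilibrium values chosen once for property testing.

Passing tests establish the internal identities of the scheme (closure,
pairing, completeness, charge conservation, spin symmetry, order
invariance) and agreement with independent closed-form/brute-force
oracles at minimal-basis scale. They do not establish quantitative
agreement with published large-basis decompositions: that requires the
original geometries, a quadruple-zeta basis and the D3(BJ) dispersion
model, none of which are distributed here. The corresponding comparison
test activates when reference geometries are placed under
`tests/data/reference_geometries/` and is skipped otherwise.

## Numerical choices and degenerate inputs

* Internal units Hartree/Bohr; XYZ input in Å; reports in kcal/mol
  (1 Ha = 627.5094740631 kcal/mol).
* Zero-electron species (e.g. H⁺) bypass the SCF loop and return the bare
  nuclear repulsion; fragments without electrons contribute no occupied
  orbitals and a promolecule identical to the partner's density, making
  ΔẼ_Pauli exactly zero.
* Grid points with total density below 1e-11 are screened out of XC
  evaluations; quadrature weights below 1e-14 are dropped.
* Cube export uses Bohr units and z-fastest ordering; density cubes use
  the positive-atom-count header, orbital cubes the negative-count
  MO-block dialect. Default volumetric grid: bounding box + 4 bohr
  padding at 0.2 bohr spacing (resolves isosurfaces down to ~2e-5
  e/bohr³; channel fields integrate to < 1e-4 e at this setting).
* The pipeline has no stochastic stages: identical configurations produce
  byte-identical machine-readable reports.

## Known limitations

* Minimal basis only (H–Ar); no f-block, no effective core potentials.
* Dispersion model is qualitative (see above).
* MP2 is canonical RMP2 with unrelaxed densities; no UMP2, no
  orbital-relaxed densities, no resolution-of-identity acceleration, so
  double hybrids are practical only for small systems.
* Exactly two fragments; multi-fragment promolecules are out of scope.
* No kinetic/potential resolution of ΔE_orb and no NOCV-like analysis of
  the Pauli term.
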