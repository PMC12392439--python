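# etsnocv

Energy decomposition analysis with natural orbitals for chemical valence
(ETS-NOCV) for two-fragment molecular systems.

## The problem

When two molecular fragments A and B form an adduct AB, the supramolecular
binding energy ΔE = E_AB − E_A − E_B is a single number that hides the
physics. The extended-transition-state (ETS) scheme resolves it into
chemically interpretable steps:

    ΔE = ΔE_prep + ΔE_int
    ΔE_int = ΔE_elstat + ΔE_Pauli + ΔE_orb + ΔE_disp (+ ΔE_C^MP2)

* **ΔE_prep** — cost of distorting each fragment from its relaxed geometry
  to the one it adopts in the adduct.
* **ΔE_elstat** — classical electrostatic interaction of the frozen
  fragment charge distributions (densities against the other fragment's
  nuclei, cross nuclear repulsion, cross Coulomb).
* **ΔE_Pauli** — destabilization from antisymmetrizing the product of the
  fragment determinants (Schmidt orthogonalization of the occupied
  fragment orbitals yields the *promolecule* state Ψ⁰ with density ρ⁰),
  plus the exchange-correlation nonadditivity ΔE_XC⁰ of the frozen
  densities.
* **ΔE_orb** — stabilization when ρ⁰ relaxes to the adduct density ρ
  (charge transfer and polarization): ΔE_orb = E[ρ] − E[ρ⁰].
* **ΔE_disp** — additive pairwise dispersion correction.
* **ΔE_C^MP2** — for double-hybrid functionals, the a_C-scaled MP2
  correlation contribution, reported as its own line.

The NOCV part diagonalizes the deformation-density matrix ΔP = P − P⁰ in
the Löwdin-orthogonalized AO basis. For single-determinant states the
eigenvalues come in ±v_k pairs; each pair is one *charge-flow channel*
Δρ_k(r) = v_k [ψ_k²(r) − ψ_-k²(r)] with energy

    ΔE_orb,k = (F̃_kk − F̃_-k-k) v_k,
    F̃ = ⅔ F[ρ^TS] + ⅙ F[ρ] + ⅙ F[ρ⁰],   ρ^TS = ½(ρ + ρ⁰),

so the channel energies sum to the transition-state estimate Tr{F̃ ΔP} of
ΔE_orb. Open-shell systems are treated per spin channel; double hybrids
run the NOCV analysis on the SCF (DFT-part) density, which preserves
pairing, with the MP2 difference density exported separately.

The package is aimed at method developers and teaching/analysis use: it is
a complete, self-contained implementation of the decomposition — including
its own Gaussian-basis HF/DFT engine (McMurchie–Davidson integrals,
restricted/unrestricted SCF, Becke-grid XC for Slater/VWN5/B88/LYP-based
functionals, RMP2) — with a minimal STO-3G-type basis for elements H–Ar.
Every identity the scheme promises (telescoping closure, eigenvalue
pairing, channel completeness) is enforced to near machine precision.

## Worked example

Decompose the hydrogen bond of a water dimer (the geometry below is the
built-in fixture; any XYZ file works):

```
python -c "from etsnocv import make_fixture; from etsnocv.system import write_xyz; \
           write_xyz(make_fixture('water2').adduct, 'water2.xyz')"
etsnocv --xyz water2.xyz --fragments "1-3;4-6" --charges 0,0 --mults 1,1 \
        --method blyp --dispersion pairwise-bj --out run/
```

prints (kcal/mol, minimal basis):

```
ETS energy decomposition (kcal/mol)
-------------------------------------
dE_int                 -9.44
dE_orb                 -8.26
dE_Pauli                4.80
dE_elstat              -3.87
dE_disp                -2.10
dE_C(MP2)               0.00
dE_corrections          0.00
-------------------------------------
dE_steric               0.93
dE_orb (TS est.)       -8.26
dE_prep                 0.00
dE_binding             -9.44
closure residual  -4.923e-14 Ha

NOCV channels
  k       spin        v_k  dE_orb,k (kcal/mol)
  1 restricted    0.19808                -7.97
  2 restricted    0.03925                -0.23
  3 restricted    0.01472                -0.03
  4 restricted    0.01342                -0.03
```

Reading the output: the dimer is bound by 9.4 kcal/mol; Pauli repulsion
(+4.8) opposes binding while electrostatics (−3.9), orbital relaxation
(−8.3) and dispersion (−2.1) stabilize it, and the terms add up to ΔE_int
exactly (the closure residual is numerical noise). One NOCV channel
dominates ΔE_orb (v₁ = 0.198, −7.97 kcal/mol): the charge transfer from
the acceptor oxygen lone pair into the donor O–H σ* — the hydrogen bond.
Its deformation density can be exported as a Gaussian cube file with
`--cube total,1`. Note that minimal-basis energetics are qualitative;
larger one-particle bases sharpen the numbers but not the structure of
the analysis.

The same pipeline is available as a library:

```python
from etsnocv import MethodSpec, build_system, decompose, nocv_analysis

system = build_system("water2.xyz", "1-3;4-6", charges=(0, 0))
result = decompose(system, MethodSpec("blyp", dispersion="pairwise-bj"))
print(result.terms.kcal("e_int"))        # -9.44...
channels = nocv_analysis(result)["total_channels"]
```

Functionals: `hf`, `lda`/`svwn`, `blyp`, `b3lyp` (a = 0.20), `b2plyp`
(a_X = 0.53, a_C = 0.27) and plain `mp2`. See `docs/methods.md` for the
model details, conventions and limitations.

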