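"""Independent brute-force oracles.

These routines recompute reference quantities from first principles by
routes deliberately different from the production code: explicit
determinant energies from MO-transformed integrals instead of
density-matrix contractions, closed-form two-orbital expressions instead of
iterative SCF.  They exist so tests can cross-validate the pipeline without
any external data, and must not share energy-assembly code with the
production modules.
"""

from __future__ import annotations

import numpy as np


def determinant_energy_oracle(C_occ_alpha, C_occ_beta, hcore, eri, e_nn,
                              max_nao: int = 8) -> float:
    """Hartree-Fock energy of one Slater determinant, term by term.

    ``C_occ_*`` hold S-orthonormal occupied orbital columns per spin.  The
    energy is assembled from MO-basis one-electron integrals and explicit
    Coulomb/exchange double sums over occupied orbitals:

        E = sum_i h_ii + 1/2 sum_ij (J_ij - K_ij^same-spin) + E_nn

    Guarded to small (<= ``max_nao`` AO) systems: the MO transformation here
    is a plain O(N^5) loop meant for minimal-basis fixtures only.
    """
    nao = hcore.shape[0]
    if nao > max_nao:
        raise ValueError(f"determinant oracle limited to {max_nao} AOs")
    e = e_nn
    occs = [("a", C_occ_alpha), ("b", C_occ_beta)]
    # one-electron part
    for _, C in occs:
        for i in range(C.shape[1]):
            e += float(C[:, i] @ hcore @ C[:, i])
    # two-electron part: explicit double sums over occupied spinorbitals
    def coul(ci, cj):
        return float(np.einsum("p,q,r,s,pqrs", ci, ci, cj, cj, eri))

    def exch(ci, cj):
        return float(np.einsum("p,q,r,s,pqrs", ci, cj, cj, ci, eri))

    spins = []
    orbs = []
    for s, C in occs:
        for i in range(C.shape[1]):
            spins.append(s)
            orbs.append(C[:, i])
    n = len(orbs)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            e += 0.5 * coul(orbs[i], orbs[j])
            if spins[i] == spins[j]:
                e -= 0.5 * exch(orbs[i], orbs[j])
    # i == j Coulomb self-pairing within a doubly occupied spatial orbital is
    # covered by the i != j alpha-beta term; nothing else to add.
    return e


def h2_rhf_oracle(S, hcore, eri, e_nn) -> float:
    """Closed-form restricted HF energy for a homonuclear 2-AO system.

    By symmetry the occupied MO is the normalized in-phase combination; the
    energy is assembled directly from the integrals without any SCF.
    """
    c = np.array([1.0, 1.0])
    c = c / np.sqrt(c @ S @ c)
    h11 = float(c @ hcore @ c)
    j11 = float(np.einsum("p,q,r,s,pqrs", c, c, c, c, eri))
    return 2.0 * h11 + j11 + e_nn


def h2_mp2_oracle(scf, eri) -> float:
    """Closed-form MP2 energy for a closed-shell 2-AO / 2-electron system:
    E2 = (12|12)^2 / (2 eps_1 - 2 eps_2)."""
    C = scf.C[0]
    eps = scf.eps[0]
    c1, c2 = C[:, 0], C[:, 1]
    k12 = float(np.einsum("p,q,r,s,pqrs", c1, c2, c1, c2, eri))
    return k12**2 / (2.0 * (eps[0] - eps[1]))


def rank1_nocv_oracle(phi_a, phi_b, S):
    """NOCV eigenvalues for one electron per fragment in a single spin
    channel, by dense diagonalization of the explicitly constructed blocks.

    The promolecule occupies phi_a and the phi_b component Schmidt-
    orthogonalized against it; the "adduct" here is characterized by the
    caller through its density matrix, so this helper only builds the
    promolecule projector.  Returns the projector P0 (occupancy 1).
    """
    a = phi_a / np.sqrt(phi_a @ S @ phi_a)
    b = phi_b - a * (a @ S @ phi_b)
    b = b / np.sqrt(b @ S @ b)
    return np.outer(a, a) + np.outer(b, b)


def exchange_contraction_oracle(Pa, Pb, eri) -> float:
    """HF exchange energy by direct integral contraction,
    -1/2 sum_sigma P^s_mn P^s_ls (ml|ns)."""
    e = 0.0
    for P in (Pa, Pb):
        e -= 0.5 * float(np.einsum("pq,rs,prqs", P, P, eri, optimize=True))
    return e


def cross_pair_dispersion_oracle(system, provider) -> float:
    """Dispersion delta for single-atom fragments: the full sum restricted
    to cross pairs, computed pair by pair from two-atom species."""
    from .species import Species

    adduct = system.adduct
    total = 0.0
    for i in system.indices_a:
        for j in system.indices_b:
            pair = Species(
                (adduct.numbers[i], adduct.numbers[j]),
                np.stack([adduct.coords_bohr[i], adduct.coords_bohr[j]]),
            )
            total += provider(pair)
    return total


def multipole_elstat_oracle(system) -> float:
    """Leading-order electrostatic interaction of two far-separated neutral
    spherical fragments: identically zero through charge-charge,
    charge-dipole and dipole-dipole orders.  Returns 0.0; used to bound the
    asymptotic electrostatic term."""
    return 0.0
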