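"""Promolecule construction.

The promolecule is the antisymmetrized, renormalized juxtaposition of the
frozen fragment determinants at the adduct geometry.  Operationally (for
single determinants) this amounts to Schmidt-orthonormalizing, in the
supermolecule overlap metric, the occupied fragment orbitals — all of A's
(kept), then B's sequentially — per spin channel.  The resulting density
matrix P0 is idempotent in the S metric; the occupied-space projector, and
hence every downstream energy, is independent of the orthogonalization
order even though individual orbitals are not.

Both promolecule reference energies live here: E[rho0] (after
antisymmetrization) and E[rho_A + rho_B] (plain summed frozen densities),
evaluated through the supermolecule engine on the shared grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .system import embed_vectors

DEPENDENCY_THRESHOLD = 1e-8


class LinearDependenceError(RuntimeError):
    pass


def schmidt_orthonormalize(blocks, S, threshold: float = DEPENDENCY_THRESHOLD):
    """Sequential Gram-Schmidt in the S metric over concatenated orbital
    blocks.

    Each block must be internally S-orthonormal; the first block is returned
    unchanged (up to nothing at all: its vectors are already orthonormal and
    are used as-is).  Raises :class:`LinearDependenceError` naming the
    offending orbital if a residual norm falls below ``threshold``.
    """
    cols = []
    provenance = []
    for ib, block in enumerate(blocks):
        block = np.asarray(block, float)
        for k in range(block.shape[1]):
            cols.append(block[:, k].copy())
            provenance.append((ib, k))
    out = []
    for idx, v in enumerate(cols):
        for u in out:
            v = v - u * (u @ S @ v)
        norm2 = float(v @ S @ v)
        if norm2 < threshold:
            ib, k = provenance[idx]
            raise LinearDependenceError(
                f"orbital {k} of block {ib} is linearly dependent on the "
                f"preceding set (residual S-norm^2 = {norm2:.3e})"
            )
        out.append(v / np.sqrt(norm2))
    if not out:
        return np.zeros((S.shape[0], 0)), provenance
    return np.column_stack(out), provenance


@dataclass
class Promolecule:
    """Orthonormalized frozen-fragment reference state.

    ``C0`` holds per-spin occupied orbital coefficients in the supermolecule
    AO basis; ``P0a``/``P0b`` the per-spin density matrices (occupancy 1).
    ``restricted`` marks the closed-shell path where both channels share one
    spatial set.
    """

    restricted: bool
    C0: tuple  # (C0_alpha, C0_beta)
    P0a: np.ndarray
    P0b: np.ndarray
    Pa_sum: np.ndarray  # embedded fragment density sum, per spin
    Pb_sum: np.ndarray
    E_promolecule: float  # E[rho0]
    E_summed: float  # E[rho_A + rho_B]
    provenance: list  # (fragment label, source orbital index) per orbital
    eval_promolecule: object = None  # FockEvaluation at P0
    eval_summed: object = None

    @property
    def P0_spatial(self) -> np.ndarray:
        return self.P0a + self.P0b

    @property
    def P_sum_spatial(self) -> np.ndarray:
        return self.Pa_sum + self.Pb_sum


def build_promolecule(
    scf_a,
    scf_b,
    embedding,
    system,
    engine,
    threshold: float = DEPENDENCY_THRESHOLD,
    order: str = "AB",
) -> Promolecule:
    """Assemble the promolecule from converged fragment SCF solutions.

    ``engine`` is the supermolecule :class:`~etsnocv.backend.Engine`; its
    grid is the shared quadrature for both reference energies.  ``order``
    ("AB" or "BA") fixes the Schmidt sequence; the density matrix is
    order-invariant, the per-orbital provenance is not.
    """
    if not (scf_a.converged and scf_b.converged):
        raise ValueError("fragment SCF solutions must be converged")
    nao = embedding.nao_super
    restricted = scf_a.restricted and scf_b.restricted
    # fragment occupied orbitals per spin, in the adduct spin frame
    spins_a = system.fragment_spins("A")
    spins_b = system.fragment_spins("B")
    C0, P0, Psum, prov_all = [], [], [], []
    for spin in (0, 1):
        blocks, prov = [], []
        frag_order = ("A", "B") if order == "AB" else ("B", "A")
        for label in frag_order:
            scf_f, emb_map, spins = (
                (scf_a, embedding.ao_map_a, spins_a) if label == "A"
                else (scf_b, embedding.ao_map_b, spins_b)
            )
            # orientation swap: fragment's own channel that feeds this
            # adduct spin channel
            own_spin = spin
            if spins != (scf_f.n_alpha, scf_f.n_beta):
                own_spin = 1 - spin  # fragment oriented with excess beta
            nocc = spins[spin]
            C = scf_f.C[own_spin][:, :nocc]
            blocks.append(embed_vectors(C, emb_map, nao))
            prov.extend((label, k) for k in range(nocc))
        C_orth, _ = schmidt_orthonormalize(blocks, engine.S, threshold)
        C0.append(C_orth)
        P0.append(C_orth @ C_orth.T)
        Psum.append(sum(
            (b @ b.T for b in blocks), np.zeros((nao, nao))
        ))
        prov_all.append(prov)
    ne_expected = system.adduct.n_alpha + system.adduct.n_beta
    ne_promol = float(np.einsum("pq,pq", P0[0] + P0[1], engine.S))
    if abs(ne_promol - ne_expected) > 1e-6:
        raise ValueError(
            f"promolecule electron count {ne_promol:.6f} != {ne_expected}"
        )
    ev0 = engine.evaluate_at_density(P0[0], P0[1])
    evs = engine.evaluate_at_density(Psum[0], Psum[1])
    return Promolecule(
        restricted=restricted,
        C0=(C0[0], C0[1]),
        P0a=P0[0], P0b=P0[1],
        Pa_sum=Psum[0], Pb_sum=Psum[1],
        E_promolecule=ev0.energy,
        E_summed=evs.energy,
        provenance=prov_all,
        eval_promolecule=ev0,
        eval_summed=evs,
    )
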