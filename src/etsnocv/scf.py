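"""Self-consistent-field driver (restricted and unrestricted, HF and KS).

A single spin-resolved loop serves RHF/UHF/RKS/UKS: the restricted path
ties the two spin channels to one spatial Fock matrix.  Convergence is
accelerated with Pulay DIIS on the orthonormal-basis [F, PS] commutator,
with light damping on the first iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla


class SCFConvergenceError(RuntimeError):
    def __init__(self, message, history):
        super().__init__(message)
        self.history = history


@dataclass
class SCFSolution:
    """Converged SCF state.

    Per-spin quantities use occupancy-1 density matrices ``Pa``, ``Pb``
    (so Tr(P^sigma S) equals the electron count of that spin channel).  For
    the restricted path ``P_spatial = Pa + Pb`` is the conventional
    occupancy-2 spatial density matrix and the two coefficient sets are
    identical.
    """

    restricted: bool
    C: tuple  # (Ca, Cb) MO coefficient matrices, AO x MO
    eps: tuple  # (eps_a, eps_b)
    occ: tuple  # (occ_a, occ_b) occupation vectors (0/1 per spin)
    Pa: np.ndarray
    Pb: np.ndarray
    S: np.ndarray
    energy: float
    components: dict
    converged: bool
    history: list = field(default_factory=list)

    @property
    def P_spatial(self) -> np.ndarray:
        return self.Pa + self.Pb

    @property
    def n_alpha(self) -> int:
        return int(round(self.occ[0].sum()))

    @property
    def n_beta(self) -> int:
        return int(round(self.occ[1].sum()))

    def occupied_coeffs(self, spin: int) -> np.ndarray:
        """Columns of occupied orbitals for spin channel 0 (alpha) / 1 (beta)."""
        mask = self.occ[spin] > 0.5
        return self.C[spin][:, mask]


def _diis_extrapolate(fock_list, err_list):
    n = len(fock_list)
    B = -np.ones((n + 1, n + 1))
    B[n, n] = 0.0
    for i in range(n):
        for j in range(n):
            B[i, j] = np.vdot(err_list[i], err_list[j])
    rhs = np.zeros(n + 1)
    rhs[n] = -1.0
    try:
        c = np.linalg.solve(B, rhs)[:n]
    except np.linalg.LinAlgError:
        return fock_list[-1]
    out = np.zeros_like(fock_list[-1])
    for ci, f in zip(c, fock_list):
        out += ci * f
    return out


def run_scf_loop(
    engine,
    n_alpha: int,
    n_beta: int,
    restricted: bool,
    e_tol: float = 1e-8,
    p_tol: float = 1e-7,
    max_iter: int = 200,
    diis_size: int = 8,
    damping: float = 0.3,
    n_damp: int = 4,
) -> SCFSolution:
    """Converge the SCF equations for the species held by ``engine``.

    ``engine`` supplies overlap/core-Hamiltonian integrals and a
    ``fock_and_energy(Pa, Pb)`` callback returning per-spin Fock matrices,
    the total energy and its components.
    """
    S = engine.S
    nao = S.shape[0]
    if restricted and n_alpha != n_beta:
        raise ValueError("restricted SCF requires n_alpha == n_beta")
    if n_alpha + n_beta == 0:
        # no electrons: energy is the bare nuclear repulsion
        zero = np.zeros((nao, nao))
        C = np.eye(nao)
        comp = {"kinetic_external": 0.0, "coulomb": 0.0, "xc": 0.0,
                "nuclear_repulsion": engine.enn}
        return SCFSolution(
            restricted=restricted, C=(C, C), eps=(np.zeros(nao), np.zeros(nao)),
            occ=(np.zeros(nao), np.zeros(nao)), Pa=zero, Pb=zero.copy(), S=S,
            energy=engine.enn, components=comp, converged=True, history=[],
        )

    X = sla.fractional_matrix_power(S, -0.5)
    if np.iscomplexobj(X):
        X = X.real
    h = engine.hcore

    def densities_from(Fa, Fb):
        ea, Ca = np.linalg.eigh(X.T @ Fa @ X)
        Ca = X @ Ca
        if restricted:
            eb, Cb = ea, Ca
        else:
            eb, Cb = np.linalg.eigh(X.T @ Fb @ X)
            Cb = X @ Cb
        Pa = Ca[:, :n_alpha] @ Ca[:, :n_alpha].T
        Pb = Cb[:, :n_beta] @ Cb[:, :n_beta].T
        return ea, Ca, eb, Cb, Pa, Pb

    # core-Hamiltonian guess
    _, _, _, _, Pa, Pb = densities_from(h, h)
    history = []
    e_prev = None
    focks, errs = [], []
    converged = False
    for it in range(max_iter):
        Fa, Fb, energy, comp = engine.fock_and_energy(Pa, Pb)
        err_a = X.T @ (Fa @ Pa @ S - S @ Pa @ Fa) @ X
        err_b = X.T @ (Fb @ Pb @ S - S @ Pb @ Fb) @ X
        err = np.concatenate([err_a.ravel(), err_b.ravel()])
        history.append((energy, float(np.max(np.abs(err)))))
        focks.append(np.stack([Fa, Fb]))
        errs.append(err)
        if len(focks) > diis_size:
            focks.pop(0)
            errs.pop(0)
        if len(focks) > 1:
            Fext = _diis_extrapolate(focks, errs)
            Fa_use, Fb_use = Fext[0], Fext[1]
        else:
            Fa_use, Fb_use = Fa, Fb
        ea, Ca, eb, Cb, Pa_new, Pb_new = densities_from(Fa_use, Fb_use)
        if it < n_damp:
            Pa_new = (1 - damping) * Pa_new + damping * Pa
            Pb_new = (1 - damping) * Pb_new + damping * Pb
        dP = max(
            np.sqrt(np.mean((Pa_new - Pa) ** 2)),
            np.sqrt(np.mean((Pb_new - Pb) ** 2)),
        )
        dE = abs(energy - e_prev) if e_prev is not None else np.inf
        Pa, Pb = Pa_new, Pb_new
        e_prev = energy
        if dE < e_tol and dP < p_tol:
            converged = True
            break
    if not converged:
        raise SCFConvergenceError(
            f"SCF did not converge in {max_iter} iterations "
            f"(last dE={dE:.3e}, dP={dP:.3e})",
            history,
        )
    # final clean evaluation at the converged density
    Fa, Fb, energy, comp = engine.fock_and_energy(Pa, Pb)
    ea, Ca, eb, Cb, Pa, Pb = densities_from(Fa, Fb)
    Fa, Fb, energy, comp = engine.fock_and_energy(Pa, Pb)
    nao = S.shape[0]
    occ_a = np.zeros(nao)
    occ_a[:n_alpha] = 1.0
    occ_b = np.zeros(nao)
    occ_b[:n_beta] = 1.0
    return SCFSolution(
        restricted=restricted, C=(Ca, Cb), eps=(ea, eb), occ=(occ_a, occ_b),
        Pa=Pa, Pb=Pb, S=S, energy=energy, components=comp,
        converged=True, history=history,
    )
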