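"""Natural orbitals for chemical valence.

The NOCVs are the eigenfunctions of the density-difference (valence)
operator represented by (dP, S) in the AO basis.  The generalized problem is
solved symmetrically: with the Loewdin transform L = S^(1/2), the spectrum
of L dP L is real and the back-transformed eigenvectors S^(-1/2) U are
S-orthonormal.  For single-determinant adduct and promolecule the spectrum
comes in +-v pairs; each pair (psi_k, psi_-k) is one charge-flow channel
with deformation density v_k (psi_k^2 - psi_-k^2) and energy
(F~_kk - F~_-k-k) v_k.

Restricted-path convention: spatial density matrices carry occupancy 2, so
the eigenvalues v_k reported here are "per spatial orbital pair" and the
channel energies sum directly to the restricted Tr{F~ dP}.  Open-shell
systems are treated per spin channel (occupancy-1 matrices) and summed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

from .units import hartree_to_kcalmol

DEFAULT_CUTOFF = 1e-3
PAIRING_TOL = 1e-7


class PairingError(RuntimeError):
    pass


def _loewdin_factors(S):
    w, V = np.linalg.eigh(S)
    if w.min() <= 1e-10:
        raise np.linalg.LinAlgError("overlap matrix not positive definite")
    s_half = (V * np.sqrt(w)) @ V.T
    s_mhalf = (V / np.sqrt(w)) @ V.T
    return s_half, s_mhalf


def nocv_eigenpairs(dP, S):
    """Eigenvalues and S-normalized eigenvectors of the valence operator.

    Solved as the symmetric problem S^(1/2) dP S^(1/2); eigenvectors are
    back-transformed, S-normalized, phase-fixed (largest-magnitude
    coefficient positive) and ordered by descending eigenvalue.
    """
    dP = np.asarray(dP, float)
    if not np.allclose(dP, dP.T, atol=1e-8):
        raise ValueError("density difference matrix must be symmetric")
    s_half, s_mhalf = _loewdin_factors(S)
    w, U = np.linalg.eigh(s_half @ dP @ s_half)
    C = s_mhalf @ U
    # descending eigenvalue order
    order = np.argsort(-w, kind="stable")
    w = w[order]
    C = C[:, order]
    for k in range(C.shape[1]):
        j = int(np.argmax(np.abs(C[:, k])))
        if C[j, k] < 0:
            C[:, k] = -C[:, k]
    return w, C


@dataclass
class NOCVChannel:
    """One paired charge-flow channel."""

    k: int
    eigenvalue: float  # v_k > 0
    c_plus: np.ndarray  # psi_k (accumulation)
    c_minus: np.ndarray  # psi_-k (depletion)
    spin: str = "restricted"  # "alpha" | "beta" | "restricted"
    energy: float = None  # dE_orb,k in Hartree

    @property
    def energy_kcal(self):
        return None if self.energy is None else hartree_to_kcalmol(self.energy)

    def density_matrix(self) -> np.ndarray:
        """dP_k = v_k (c_k c_k^T - c_-k c_-k^T) (traceless against S)."""
        return self.eigenvalue * (
            np.outer(self.c_plus, self.c_plus)
            - np.outer(self.c_minus, self.c_minus)
        )


@dataclass
class NOCVResult:
    """Channels of one spin block plus completeness diagnostics."""

    channels: list
    eigenvalues: np.ndarray  # full spectrum, descending
    vectors: np.ndarray
    spin: str
    ets2_reference: float = None  # Tr{F~ dP} for this spin block
    channel_sum: float = None  # sum of kept channel energies
    residual: float = None  # ets2_reference - channel_sum
    unpaired_diagnostics: list = field(default_factory=list)
    total_valence: float = None

    @property
    def n_channels(self) -> int:
        return len(self.channels)


def pair_channels(eigenvalues, vectors, spin="restricted",
                  cutoff=DEFAULT_CUTOFF, pairing_tol=PAIRING_TOL,
                  strict=True):
    """Greedy +v/-v pairing of the NOCV spectrum into channels.

    Eigenvalues are matched by magnitude from the two ends of the sorted
    spectrum.  Channels with v below ``cutoff`` are dropped from the list
    (their energy stays in the residual diagnostics).  Unmatched eigenvalues
    above ``pairing_tol`` raise for idempotent inputs (``strict``) or are
    reported in the diagnostics otherwise.
    """
    w = np.asarray(eigenvalues)
    n = len(w)
    channels = []
    unpaired = []
    i, j = 0, n - 1  # w sorted descending: positives at front, negatives at back
    k = 1
    while i <= j:
        if w[i] <= pairing_tol and w[j] >= -pairing_tol:
            break  # remaining spectrum is numerically zero
        if w[i] > pairing_tol and -w[j] > pairing_tol:
            mismatch = abs(w[i] + w[j])
            if mismatch > max(pairing_tol, 1e-6 * abs(w[i])):
                if strict:
                    raise PairingError(
                        f"eigenvalue pairing violated: +{w[i]:.3e} vs "
                        f"{w[j]:.3e} (|sum| = {mismatch:.3e})"
                    )
                unpaired.extend([float(w[i]), float(w[j])])
                i += 1
                j -= 1
                continue
            v = 0.5 * (w[i] - w[j])
            if v >= cutoff:
                channels.append(NOCVChannel(
                    k=k, eigenvalue=float(v),
                    c_plus=vectors[:, i].copy(),
                    c_minus=vectors[:, j].copy(),
                    spin=spin,
                ))
                k += 1
            i += 1
            j -= 1
        elif w[i] > pairing_tol:
            if strict:
                raise PairingError(f"unmatched positive eigenvalue {w[i]:.3e}")
            unpaired.append(float(w[i]))
            i += 1
        else:
            if strict:
                raise PairingError(f"unmatched negative eigenvalue {w[j]:.3e}")
            unpaired.append(float(w[j]))
            j -= 1
    return channels, unpaired


def channel_energies(channels, F_tilde):
    """Attach dE_orb,k = (F~_kk - F~_-k-k) v_k to each channel."""
    for ch in channels:
        f_pp = float(ch.c_plus @ F_tilde @ ch.c_plus)
        f_mm = float(ch.c_minus @ F_tilde @ ch.c_minus)
        ch.energy = (f_pp - f_mm) * ch.eigenvalue
    return channels


def total_valence(P, dP, S) -> float:
    """Nalewajski-Mrozek total valence V = Tr(P dP) in the Loewdin
    (orthogonal) representation."""
    s_half, _ = _loewdin_factors(S)
    Po = s_half @ P @ s_half
    dPo = s_half @ dP @ s_half
    return float(np.einsum("pq,qp", Po, dPo))


def analyze_spin_block(dP, S, F_tilde, P=None, spin="restricted",
                       cutoff=DEFAULT_CUTOFF, strict=True) -> NOCVResult:
    """Full NOCV analysis of one spin block (or the restricted spatial one)."""
    w, C = nocv_eigenpairs(dP, S)
    channels, unpaired = pair_channels(w, C, spin=spin, cutoff=cutoff,
                                       strict=strict)
    ets2 = float(np.einsum("pq,pq", F_tilde, dP))
    channel_energies(channels, F_tilde)
    csum = sum(ch.energy for ch in channels)
    return NOCVResult(
        channels=channels, eigenvalues=w, vectors=C, spin=spin,
        ets2_reference=ets2, channel_sum=csum, residual=ets2 - csum,
        unpaired_diagnostics=unpaired,
        total_valence=None if P is None else total_valence(P, dP, S),
    )


def nocv_analysis(decomp, cutoff=DEFAULT_CUTOFF):
    """NOCV analysis of a finished decomposition.

    Closed-shell restricted runs yield one spatial block (occupancy-2
    convention); open-shell runs yield alpha and beta blocks analyzed
    independently and summed.  For double hybrids the analysis runs on the
    SCF (DFT-part) density difference only, which preserves pairing; the MP2
    difference-density correction is available separately through
    :func:`mp2_deformation_matrix`.

    Returns a dict with per-block :class:`NOCVResult` under keys
    "restricted" or "alpha"/"beta", plus "total_ets2" and "total_channels".
    """
    S = decomp.engine.S
    prom = decomp.promolecule
    scf = decomp.scf_adduct
    out = {}
    if decomp.restricted:
        dP = scf.P_spatial - prom.P0_spatial
        F_tilde = decomp.ts_focks.F_tilde[0]
        res = analyze_spin_block(dP, S, F_tilde, P=scf.P_spatial,
                                 spin="restricted", cutoff=cutoff)
        out["restricted"] = res
        out["total_ets2"] = res.ets2_reference
        out["total_channels"] = list(res.channels)
    else:
        total = 0.0
        chans = []
        for spin, label in ((0, "alpha"), (1, "beta")):
            dP = (scf.Pa - prom.P0a) if spin == 0 else (scf.Pb - prom.P0b)
            P = scf.Pa if spin == 0 else scf.Pb
            res = analyze_spin_block(dP, S, decomp.ts_focks.F_tilde[spin],
                                     P=P, spin=label, cutoff=cutoff)
            out[label] = res
            total += res.ets2_reference
            chans.extend(res.channels)
        out["total_ets2"] = total
        out["total_channels"] = sorted(
            chans, key=lambda c: -c.eigenvalue
        )
    return out


def mp2_deformation_matrix(decomp) -> np.ndarray:
    """MP2 difference-density correction to the deformation density.

    ddP = dP_MP2(adduct) - dP_MP2(A, embedded) - dP_MP2(B, embedded);
    its grid representation is the DDrho_C^MP2 field.  Zero matrix when the
    method carries no MP2 term.
    """
    if not decomp.mp2_densities:
        n = decomp.engine.nao
        return np.zeros((n, n))
    d = decomp.mp2_densities
    return d["adduct"] - d["A"] - d["B"]
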