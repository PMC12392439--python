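"""Backend contract: SCF solutions, energies and Fock matrices at arbitrary
densities, MP2 correlation, and dispersion.

The analysis layer (promolecule / EDA / NOCV) talks to an :class:`Engine`,
which bundles the AO integrals, the exchange-correlation quadrature grid and
the method for one species.  The central operation is
:meth:`Engine.evaluate_at_density`: the total energy functional

    E[P] = Tr(P h) + 1/2 Tr(P J[P]) + a E_X^HF[P] + E_XC^DFT[rho] + E_nn

and its derivative (the Fock matrix) at a density matrix that need not be
idempotent - the promolecule, the summed fragment density and the
transition-state half-sum density are all evaluated through it, on one
shared grid so that quadrature error cancels in energy differences.

Module-level :func:`run_scf` / :func:`evaluate_at_density` /
:func:`mp2_correlation` / :func:`dispersion_energy` expose the same
operations in the species-in / numbers-out form; decomposition runs hold on
to Engines so integrals are computed once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import functionals, integrals
from .basis import build_basis
from .dispersion import get_dispersion_provider
from .grids import MolecularGrid
from .scf import SCFSolution, run_scf_loop
from .species import MethodSpec, Species

DEFAULT_GRID = (40, 12)  # radial points, Gauss-Legendre theta order


@dataclass
class FockEvaluation:
    """Energy functional value and Fock matrices at a supplied density."""

    Fa: np.ndarray
    Fb: np.ndarray
    energy: float
    components: dict  # kinetic_external, coulomb, xc, nuclear_repulsion
    xc_components: dict  # per-term DFT XC energies plus scaled HF exchange

    @property
    def F_spatial(self) -> np.ndarray:
        return self.Fa  # restricted callers: both channels identical

    @property
    def xc(self) -> float:
        return self.components["xc"]


class Engine:
    """Integrals, grid and method context for one species."""

    def __init__(self, species: Species, method: MethodSpec, grid=None,
                 grid_params=DEFAULT_GRID):
        self.species = species
        self.method = method
        self.basis = build_basis(species, method.basis)
        self.nao = self.basis.nao
        self.S, self.kin = integrals.overlap_and_kinetic(self.basis)
        self.Vne = integrals.nuclear_attraction(
            self.basis, species.coords_bohr, np.array(species.numbers, float)
        )
        self.hcore = self.kin + self.Vne
        self.eri = integrals.eri(self.basis)
        self.enn = species.nuclear_repulsion()
        self._ao_cache = None
        if method.has_dft_xc:
            self.grid = grid if grid is not None else MolecularGrid(
                species.numbers, species.coords_bohr, *grid_params
            )
        else:
            self.grid = grid

    # --- building blocks -------------------------------------------------
    def nuclear_operator(self, atom_indices=None) -> np.ndarray:
        """Electron-nuclear attraction operator, optionally for a subset of
        nuclei (the per-fragment V_A, V_B of the electrostatic term)."""
        if atom_indices is None:
            return self.Vne
        idx = list(atom_indices)
        return integrals.nuclear_attraction(
            self.basis,
            self.species.coords_bohr[idx],
            np.array([self.species.numbers[i] for i in idx], float),
        )

    def coulomb(self, P: np.ndarray) -> np.ndarray:
        return np.einsum("pqrs,rs->pq", self.eri, P, optimize=True)

    def exchange(self, P: np.ndarray) -> np.ndarray:
        return np.einsum("prqs,rs->pq", self.eri, P, optimize=True)

    def _grid_ao(self, gradients: bool):
        if self._ao_cache is None or (gradients and self._ao_cache[1] is None):
            ao, grad = (integrals.ao_values(self.basis, self.grid.points, True)
                        if gradients else
                        (integrals.ao_values(self.basis, self.grid.points), None))
            self._ao_cache = (ao, grad)
        return self._ao_cache

    def _xc_dft(self, Pa, Pb, want_fock=True, per_term=False):
        """DFT XC energy (and Kohn-Sham matrix contributions) on the grid."""
        xc_terms = self.method.xc_terms
        if not xc_terms:
            zero = np.zeros_like(Pa)
            return (0.0, zero, zero, {}) if want_fock else (0.0, {})
        need_grad = functionals.needs_gradient(xc_terms)
        ao, grad = self._grid_ao(need_grad)
        w = self.grid.weights
        rho_a = np.einsum("pi,ij,pj->p", ao, Pa, ao, optimize=True)
        rho_b = np.einsum("pi,ij,pj->p", ao, Pb, ao, optimize=True)
        if need_grad:
            ga = 2.0 * np.einsum("pi,ij,pjx->px", ao, Pa, grad, optimize=True)
            gb = 2.0 * np.einsum("pi,ij,pjx->px", ao, Pb, grad, optimize=True)
            saa = np.einsum("px,px->p", ga, ga)
            sab = np.einsum("px,px->p", ga, gb)
            sbb = np.einsum("px,px->p", gb, gb)
        else:
            npts = rho_a.shape[0]
            saa = sab = sbb = np.zeros(npts)
            ga = gb = None
        e = functionals.energy_density(xc_terms, rho_a, rho_b, saa, sab, sbb)
        exc = float(w @ e)
        terms = {}
        if per_term:
            for name, ed in functionals.energy_density_per_term(
                xc_terms, rho_a, rho_b, saa, sab, sbb
            ).items():
                terms[name] = float(w @ ed)
        if not want_fock:
            return exc, terms
        vra, vrb, vsaa, vsab, vsbb = functionals.potentials(
            xc_terms, rho_a, rho_b, saa, sab, sbb
        )
        Va = ao.T @ (w[:, None] * vra[:, None] * ao)
        Vb = ao.T @ (w[:, None] * vrb[:, None] * ao)
        if need_grad:
            vec_a = w[:, None] * (2.0 * vsaa[:, None] * ga + vsab[:, None] * gb)
            vec_b = w[:, None] * (2.0 * vsbb[:, None] * gb + vsab[:, None] * ga)
            Wa = np.einsum("px,pjx->pj", vec_a, grad, optimize=True)
            Wb = np.einsum("px,pjx->pj", vec_b, grad, optimize=True)
            Va += ao.T @ Wa + Wa.T @ ao
            Vb += ao.T @ Wb + Wb.T @ ao
        return exc, 0.5 * (Va + Va.T), 0.5 * (Vb + Vb.T), terms

    def _nuclear_context(self, atom_indices):
        """(hcore, E_nn) restricted to a subset of nuclei (fragment-in-
        supermolecule-integrals references)."""
        if atom_indices is None:
            return self.hcore, self.enn
        idx = list(atom_indices)
        h = self.kin + self.nuclear_operator(idx)
        coords = self.species.coords_bohr
        numbers = self.species.numbers
        enn = 0.0
        for ii, i in enumerate(idx):
            for j in idx[ii + 1:]:
                enn += numbers[i] * numbers[j] / np.linalg.norm(
                    coords[i] - coords[j]
                )
        return h, enn

    # --- energy/Fock at arbitrary density ---------------------------------
    def fock_and_energy(self, Pa, Pb, per_term=False, atom_indices=None):
        a = self.method.hf_exchange_fraction
        hcore, enn = self._nuclear_context(atom_indices)
        Pt = Pa + Pb
        J = self.coulomb(Pt)
        e1 = float(np.einsum("pq,pq", Pt, hcore))
        ej = 0.5 * float(np.einsum("pq,pq", Pt, J))
        Fa = hcore + J
        Fb = hcore + J.copy()
        ex_hf = 0.0
        if a != 0.0:
            Ka = self.exchange(Pa)
            Kb = Ka if Pb is Pa else self.exchange(Pb)
            ex_hf = -0.5 * (
                float(np.einsum("pq,pq", Pa, Ka))
                + float(np.einsum("pq,pq", Pb, Kb))
            )
            Fa -= a * Ka
            Fb -= a * Kb
        exc_dft, Va, Vb, terms = (0.0, 0.0, 0.0, {})
        if self.method.has_dft_xc:
            exc_dft, Va, Vb, terms = self._xc_dft(Pa, Pb, per_term=per_term)
            Fa = Fa + Va
            Fb = Fb + Vb
        xc_total = a * ex_hf + exc_dft
        energy = e1 + ej + xc_total + enn
        comp = {
            "kinetic_external": e1,
            "coulomb": ej,
            "xc": xc_total,
            "nuclear_repulsion": enn,
        }
        xc_comp = dict(terms)
        xc_comp["hf_x_scaled"] = a * ex_hf
        xc_comp["hf_x"] = ex_hf
        return Fa, Fb, energy, comp if not per_term else {**comp, "xc_terms": xc_comp}

    def evaluate_at_density(self, Pa, Pb=None, atom_indices=None) -> FockEvaluation:
        """E[rho] and F[rho] at a (not necessarily idempotent) density.

        A single matrix argument is interpreted as a restricted spatial
        density with occupancy 2 and split evenly over the spin channels.
        """
        if Pb is None:
            Pa = np.asarray(Pa, float)
            Pa, Pb = Pa / 2.0, Pa / 2.0
        for M in (Pa, Pb):
            if M.shape != (self.nao, self.nao):
                raise ValueError("density matrix has wrong dimension")
            if not np.allclose(M, M.T, atol=1e-8):
                raise ValueError("density matrix must be symmetric")
        Fa, Fb, energy, comp = self.fock_and_energy(Pa, Pb, per_term=True,
                                                    atom_indices=atom_indices)
        xc_terms = comp.pop("xc_terms")
        return FockEvaluation(Fa=Fa, Fb=Fb, energy=energy,
                              components=comp, xc_components=xc_terms)

    def xc_energy(self, Pa, Pb, per_term=False):
        """XC energy only (Eq.-7-style evaluations), per Eq. 25/26 assembly."""
        a = self.method.hf_exchange_fraction
        ex_hf = 0.0
        if a != 0.0:
            Ka = self.exchange(Pa)
            Kb = Ka if Pb is Pa else self.exchange(Pb)
            ex_hf = -0.5 * (
                float(np.einsum("pq,pq", Pa, Ka))
                + float(np.einsum("pq,pq", Pb, Kb))
            )
        exc_dft, terms = (0.0, {})
        if self.method.has_dft_xc:
            exc_dft, terms = self._xc_dft(Pa, Pb, want_fock=False,
                                          per_term=per_term)
        if per_term:
            terms = dict(terms)
            terms["hf_x_scaled"] = a * ex_hf
            return a * ex_hf + exc_dft, terms
        return a * ex_hf + exc_dft

    # --- SCF ---------------------------------------------------------------
    def run_scf(self, restricted=None, **kw) -> SCFSolution:
        sp = self.species
        if restricted is None:
            restricted = sp.is_closed_shell and not self.method.force_unrestricted
        return run_scf_loop(self, sp.n_alpha, sp.n_beta, restricted, **kw)


# --- module-level contract functions ---------------------------------------

def run_scf(species: Species, method: MethodSpec, grid=None, **kw) -> SCFSolution:
    """Converged SCF solution for a species (restricted iff closed shell,
    unless the method forces the unrestricted path)."""
    return Engine(species, method, grid=grid).run_scf(**kw)


def evaluate_at_density(densities, species: Species, method: MethodSpec,
                        grid=None) -> FockEvaluation:
    """E[rho] and Fock matrix at an arbitrary density for a fresh engine.

    ``densities`` is a single spatial matrix (restricted, occupancy 2) or a
    pair ``(Pa, Pb)`` of per-spin matrices.
    """
    eng = Engine(species, method, grid=grid)
    if isinstance(densities, (tuple, list)):
        return eng.evaluate_at_density(*densities)
    return eng.evaluate_at_density(densities)


def mp2_correlation(scf: SCFSolution, engine: Engine, with_density=True):
    """MP2 correlation energy (and unrelaxed difference-density matrix).

    Computed with the supplied (converged) orbitals; restricted closed-shell
    only, which covers the double-hybrid use in the decomposition.  The
    density correction is the amplitude-level (unrelaxed) MP2 one-particle
    difference density back-transformed to the AO basis, occupancy-2
    convention, trace zero.
    """
    method = engine.method
    if not method.is_double_hybrid:
        raise ValueError("MP2 correlation requested for a non-double-hybrid "
                         "method; contract violation")
    if method.relaxed_mp2_density:
        raise NotImplementedError("relaxed MP2 difference densities are not "
                                  "implemented; use the unrelaxed variant")
    if not scf.restricted:
        raise NotImplementedError("double-hybrid path supports closed-shell "
                                  "restricted references only")
    C = scf.C[0]
    eps = scf.eps[0]
    nocc = scf.n_alpha
    nao = C.shape[0]
    nvir = C.shape[1] - nocc
    if nocc == 0 or nvir == 0:
        return 0.0, (np.zeros((nao, nao)) if with_density else None)
    Co, Cv = C[:, :nocc], C[:, nocc:]
    # (ia|jb) transformation, small systems: dense einsum
    ovov = np.einsum("pqrs,pi,qa,rj,sb->iajb", engine.eri, Co, Cv, Co, Cv,
                     optimize=True)
    e_o, e_v = eps[:nocc], eps[nocc:]
    denom = (e_o[:, None, None, None] - e_v[None, :, None, None]
             + e_o[None, None, :, None] - e_v[None, None, None, :])
    t = ovov / denom
    e2 = float(np.einsum("iajb,iajb", t, 2.0 * ovov)
               - np.einsum("iajb,ibja", t, ovov))
    if not with_density:
        return e2, None
    # unrelaxed (amplitude) difference density, MO blocks
    d_vv = 2.0 * (2.0 * np.einsum("iajc,ibjc->ab", t, t, optimize=True)
                  - np.einsum("iajc,jbic->ab", t, t, optimize=True))
    d_oo = -2.0 * (2.0 * np.einsum("iakb,jakb->ij", t, t, optimize=True)
                   - np.einsum("iakb,kajb->ij", t, t, optimize=True))
    dP = Co @ d_oo @ Co.T + Cv @ d_vv @ Cv.T
    return e2, dP


def dispersion_energy(species: Species, method: MethodSpec) -> float:
    """Additive dispersion energy for the given geometry (Hartree)."""
    provider = get_dispersion_provider(method.dispersion)
    return provider(species)
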