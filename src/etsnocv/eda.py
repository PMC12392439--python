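"""Extended-transition-state energy decomposition.

The interaction energy of two frozen-geometry fragments is resolved as

    dE_int = dE_elstat + dE_Pauli + dE_orb + dE_disp (+ dE_C^MP2 + corrections)

with the intermediate states

    rho_A + rho_B   (summed frozen fragment densities)
    rho^0           (antisymmetrized promolecule)
    rho             (relaxed adduct density)

All electronic reference energies are evaluated with the supermolecule
integrals and one shared quadrature grid, so the three steps telescope
exactly:

    (E[rho_A+rho_B] - E_A - E_B) + (E[rho^0] - E[rho_A+rho_B])
        + (E[rho] - E[rho^0]) = E_AB - E_A - E_B.

The electrostatic term is also assembled directly from its definition
(fragment densities against the other fragment's nuclei plus cross Coulomb
and cross nuclear repulsion); the difference route minus the XC cross term
must agree, which is asserted as a property test.

The orbital term is reported as the exact difference E[rho] - E[rho^0]
(guaranteeing closure); the first- and second-order transition-state trace
estimates Tr{F^TS dP} and Tr{F~ dP} are carried alongside, the latter being
the quantity the NOCV channel energies sum to.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .backend import Engine, dispersion_energy, mp2_correlation
from .promolecule import Promolecule, build_promolecule
from .species import MethodSpec
from .system import AdductSystem, embed_matrix
from .units import hartree_to_kcalmol


@dataclass
class TransitionStateFocks:
    """Per-spin Fock matrices at rho^TS, rho and rho^0, and their
    2/3-1/6-1/6 combination F~."""

    F_ts: tuple  # (Fa, Fb) at the half-sum density
    F_adduct: tuple
    F_promol: tuple
    F_tilde: tuple
    restricted: bool

    @classmethod
    def build(cls, engine: Engine, Pa, Pb, P0a, P0b, restricted: bool,
              eval_adduct=None, eval_promol=None):
        Pts_a, Pts_b = 0.5 * (Pa + P0a), 0.5 * (Pb + P0b)
        ev_ts = engine.evaluate_at_density(Pts_a, Pts_b)
        ev_ad = eval_adduct or engine.evaluate_at_density(Pa, Pb)
        ev_pm = eval_promol or engine.evaluate_at_density(P0a, P0b)
        f_tilde = tuple(
            (2.0 / 3.0) * fts + (1.0 / 6.0) * fad + (1.0 / 6.0) * fpm
            for fts, fad, fpm in zip(
                (ev_ts.Fa, ev_ts.Fb), (ev_ad.Fa, ev_ad.Fb), (ev_pm.Fa, ev_pm.Fb)
            )
        )
        return cls(
            F_ts=(ev_ts.Fa, ev_ts.Fb),
            F_adduct=(ev_ad.Fa, ev_ad.Fb),
            F_promol=(ev_pm.Fa, ev_pm.Fb),
            F_tilde=f_tilde,
            restricted=restricted,
        )


@dataclass
class EDATerms:
    """All decomposition terms in Hartree, with kcal/mol views."""

    e_prep: float
    e_elstat: float
    e_xc0: float
    e_pauli_tilde: float  # E[rho0] - E[rhoA+rhoB]
    e_pauli: float  # tilde + xc0
    e_orb_exact: float
    e_orb_ets1: float
    e_orb_ets2: float
    e_disp: float
    e_mp2: float
    e_corrections: float
    e_int: float
    e_binding: float
    closure_residual: float
    elstat_route_residual: float
    fragment_energies: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)

    ROW_ORDER = (
        ("e_int", "dE_int"),
        ("e_orb_exact", "dE_orb"),
        ("e_pauli", "dE_Pauli"),
        ("e_elstat", "dE_elstat"),
        ("e_disp", "dE_disp"),
        ("e_mp2", "dE_C_MP2"),
        ("e_corrections", "dE_corrections"),
    )

    def kcal(self, name: str) -> float:
        return hartree_to_kcalmol(getattr(self, name))

    @property
    def e_steric(self) -> float:
        """Combined frozen-density (steric) term, a derived view."""
        return self.e_elstat + self.e_pauli

    def as_dict(self) -> dict:
        out = {k: getattr(self, k) for k in (
            "e_prep", "e_elstat", "e_xc0", "e_pauli_tilde", "e_pauli",
            "e_orb_exact", "e_orb_ets1", "e_orb_ets2", "e_disp", "e_mp2",
            "e_corrections", "e_int", "e_binding", "closure_residual",
            "elstat_route_residual",
        )}
        out["e_steric"] = self.e_steric
        return out


def preparation_energy(system: AdductSystem, method: MethodSpec,
                       scf_kwargs=None) -> tuple:
    """Eq.-4-style preparation energy; (value, available_flag).

    Frozen-geometry fragment energies minus relaxed-geometry fragment
    energies, each from its own SCF in the fragment basis.  Reported as 0
    with a flag when no relaxed geometries are attached.
    """
    if system.relaxed_a is None and system.relaxed_b is None:
        return 0.0, False
    scf_kwargs = scf_kwargs or {}
    e = 0.0
    for frozen, relaxed in ((system.fragment_a, system.relaxed_a),
                            (system.fragment_b, system.relaxed_b)):
        e_frozen = Engine(frozen, method).run_scf(**scf_kwargs).energy
        e_relaxed = (e_frozen if relaxed is None
                     else Engine(relaxed, method).run_scf(**scf_kwargs).energy)
        e += e_frozen - e_relaxed
    return e, True


def electrostatic_energy(Pa_pad, Pb_pad, system: AdductSystem,
                         engine: Engine) -> float:
    """Classical electrostatic interaction of the frozen fragment densities.

    ``Pa_pad``/``Pb_pad`` are spin-summed embedded fragment densities in the
    supermolecule AO basis.  Four contributions: each density in the other
    fragment's nuclear potential, cross nuclear repulsion, and the cross
    Coulomb repulsion of the two densities.
    """
    V_a = engine.nuclear_operator(system.indices_a)
    V_b = engine.nuclear_operator(system.indices_b)
    e_nuc_e = float(np.einsum("pq,pq", Pb_pad, V_a)
                    + np.einsum("pq,pq", Pa_pad, V_b))
    coords = system.adduct.coords_bohr
    numbers = system.adduct.numbers
    e_nn = 0.0
    for i in system.indices_a:
        for j in system.indices_b:
            e_nn += numbers[i] * numbers[j] / np.linalg.norm(coords[i] - coords[j])
    e_ee = float(np.einsum("pq,pq", Pa_pad, engine.coulomb(Pb_pad)))
    return e_nuc_e + e_nn + e_ee


def xc_cross_energy(frag_densities_a, frag_densities_b, engine: Engine) -> float:
    """XC-energy nonadditivity of the frozen densities (per-spin pairs),
    including the scaled exact-exchange cross term for hybrid methods."""
    Pa_a, Pb_a = frag_densities_a
    Pa_b, Pb_b = frag_densities_b
    e_sum = engine.xc_energy(Pa_a + Pa_b, Pb_a + Pb_b)
    e_a = engine.xc_energy(Pa_a, Pb_a)
    e_b = engine.xc_energy(Pa_b, Pb_b)
    return e_sum - e_a - e_b


def pauli_energies(prom: Promolecule, e_xc0: float) -> tuple:
    """(dE~_Pauli, dE_Pauli): raw antisymmetrization cost, and the reported
    Pauli repulsion including the XC cross term."""
    tilde = prom.E_promolecule - prom.E_summed
    return tilde, tilde + e_xc0


def orbital_energy(Pa, Pb, prom: Promolecule, ts: TransitionStateFocks,
                   e_adduct: float) -> tuple:
    """(exact Eq.-12 difference, first-order trace, second-order trace)."""
    exact = e_adduct - prom.E_promolecule
    dPa, dPb = Pa - prom.P0a, Pb - prom.P0b
    ets1 = float(np.einsum("pq,pq", ts.F_ts[0], dPa)
                 + np.einsum("pq,pq", ts.F_ts[1], dPb))
    ets2 = float(np.einsum("pq,pq", ts.F_tilde[0], dPa)
                 + np.einsum("pq,pq", ts.F_tilde[1], dPb))
    return exact, ets1, ets2


def dispersion_delta(system: AdductSystem, method: MethodSpec) -> float:
    return (dispersion_energy(system.adduct, method)
            - dispersion_energy(system.fragment_a, method)
            - dispersion_energy(system.fragment_b, method))


@dataclass
class DecompositionResult:
    terms: EDATerms
    system: AdductSystem
    method: MethodSpec
    engine: Engine  # supermolecule engine (shared integrals and grid)
    scf_adduct: object
    scf_a: object
    scf_b: object
    promolecule: Promolecule
    ts_focks: TransitionStateFocks
    embedding: object
    restricted: bool
    mp2_densities: dict = field(default_factory=dict)


def decompose(system: AdductSystem, method: MethodSpec,
              correction_providers=(), grid_params=None,
              scf_kwargs=None) -> DecompositionResult:
    """Run the full decomposition: three SCFs, promolecule, every term.

    ``correction_providers`` is a sequence of callables mapping a species to
    an additive energy (gCP/short-range-basis style composite corrections);
    their fragment-vs-adduct deltas are grouped into one correction term.
    """
    scf_kwargs = dict(scf_kwargs or {})
    from .backend import DEFAULT_GRID
    gp = grid_params or DEFAULT_GRID

    restricted = system.is_closed_shell and not method.force_unrestricted
    engine = Engine(system.adduct, method, grid_params=gp)
    try:
        scf_ad = engine.run_scf(restricted=restricted, **scf_kwargs)
    except Exception as err:
        raise RuntimeError(f"adduct SCF failed: {err}") from err
    eng_a = Engine(system.fragment_a, method, grid_params=gp)
    eng_b = Engine(system.fragment_b, method, grid_params=gp)
    try:
        scf_a = eng_a.run_scf(restricted=restricted or None, **scf_kwargs)
        scf_b = eng_b.run_scf(restricted=restricted or None, **scf_kwargs)
    except Exception as err:
        raise RuntimeError(f"fragment SCF failed: {err}") from err

    emb = system.build_embedding(method.basis)
    nao = emb.nao_super

    # embedded per-spin fragment densities in the adduct spin frame
    def padded(scf_f, frag):
        ao_map = emb.map_for(frag)
        Pa_f, Pb_f = scf_f.Pa, scf_f.Pb
        spins = system.fragment_spins(frag)
        if spins != (scf_f.n_alpha, scf_f.n_beta):
            Pa_f, Pb_f = Pb_f, Pa_f
        return (embed_matrix(Pa_f, ao_map, nao),
                embed_matrix(Pb_f, ao_map, nao))

    Pa_A, Pb_A = padded(scf_a, "A")
    Pa_B, Pb_B = padded(scf_b, "B")

    # fragment reference energies: supermolecule integrals and grid, but
    # each fragment's own nuclei only (so the three steps telescope exactly)
    ev_a = engine.evaluate_at_density(Pa_A, Pb_A, atom_indices=system.indices_a)
    ev_b = engine.evaluate_at_density(Pa_B, Pb_B, atom_indices=system.indices_b)

    prom = build_promolecule(scf_a, scf_b, emb, system, engine)
    e_elstat = electrostatic_energy(Pa_A + Pb_A, Pa_B + Pb_B, system, engine)
    e_xc0 = xc_cross_energy((Pa_A, Pb_A), (Pa_B, Pb_B), engine)
    e_pauli_tilde, e_pauli = pauli_energies(prom, e_xc0)

    ev_adduct = engine.evaluate_at_density(scf_ad.Pa, scf_ad.Pb)
    ts = TransitionStateFocks.build(
        engine, scf_ad.Pa, scf_ad.Pb, prom.P0a, prom.P0b, restricted,
        eval_adduct=ev_adduct, eval_promol=prom.eval_promolecule,
    )
    e_orb, e_ets1, e_ets2 = orbital_energy(
        scf_ad.Pa, scf_ad.Pb, prom, ts, ev_adduct.energy
    )

    e_disp = dispersion_delta(system, method)

    e_mp2 = 0.0
    mp2_dens = {}
    if method.is_double_hybrid and method.mp2_coefficient != 0.0:
        a_c = method.mp2_coefficient
        e2_ab, dp_ab = mp2_correlation(scf_ad, engine)
        e2_a, dp_a = mp2_correlation(scf_a, eng_a)
        e2_b, dp_b = mp2_correlation(scf_b, eng_b)
        e_mp2 = a_c * (e2_ab - e2_a - e2_b)
        mp2_dens = {
            "adduct": dp_ab,
            "A": embed_matrix(dp_a, emb.ao_map_a, nao),
            "B": embed_matrix(dp_b, emb.ao_map_b, nao),
            "e2": {"adduct": e2_ab, "A": e2_a, "B": e2_b},
        }

    e_corr = 0.0
    for provider in correction_providers:
        e_corr += (provider(system.adduct) - provider(system.fragment_a)
                   - provider(system.fragment_b))

    e_int = e_elstat + e_pauli + e_orb + e_disp + e_mp2 + e_corr
    # supramolecular route with the same (shared-grid) fragment references
    e_frag_ref = ev_a.energy + ev_b.energy
    e_supra = (ev_adduct.energy + e_mp2 + e_disp + e_corr
               + 0.0) - e_frag_ref
    closure = e_int - e_supra

    # Eq.-5/6/7 consistency: direct elstat vs functional-difference route
    e_cross_total = prom.E_summed - e_frag_ref
    elstat_residual = (e_elstat + e_xc0) - e_cross_total

    e_prep, prep_available = preparation_energy(system, method, scf_kwargs)
    if not prep_available:
        warnings.warn(
            "no relaxed fragment geometries supplied; dE_prep reported as 0",
            stacklevel=2,
        )

    terms = EDATerms(
        e_prep=e_prep,
        e_elstat=e_elstat,
        e_xc0=e_xc0,
        e_pauli_tilde=e_pauli_tilde,
        e_pauli=e_pauli,
        e_orb_exact=e_orb,
        e_orb_ets1=e_ets1,
        e_orb_ets2=e_ets2,
        e_disp=e_disp,
        e_mp2=e_mp2,
        e_corrections=e_corr,
        e_int=e_int,
        e_binding=e_prep + e_int,
        closure_residual=closure,
        elstat_route_residual=elstat_residual,
        fragment_energies={
            "adduct_scf": scf_ad.energy,
            "A_scf": scf_a.energy,
            "B_scf": scf_b.energy,
            "A_in_supermolecule_context": ev_a.energy,
            "B_in_supermolecule_context": ev_b.energy,
            "grid_consistency_A": ev_a.energy - scf_a.energy,
            "grid_consistency_B": ev_b.energy - scf_b.energy,
        },
        flags={"prep_available": prep_available},
    )
    return DecompositionResult(
        terms=terms, system=system, method=method, engine=engine,
        scf_adduct=scf_ad, scf_a=scf_a, scf_b=scf_b, promolecule=prom,
        ts_focks=ts, embedding=emb, restricted=restricted,
        mp2_densities=mp2_dens,
    )
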