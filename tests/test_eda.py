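"""Energy decomposition terms: definitions, identities, closure."""

import numpy as np
import pytest

from etsnocv import MethodSpec, Species, make_fixture
from etsnocv.eda import (dispersion_delta, electrostatic_energy,
                         preparation_energy)
from etsnocv.oracles import exchange_contraction_oracle
from etsnocv.system import embed_matrix
from etsnocv.units import hartree_to_kcalmol


def _padded_fragment_densities(d):
    emb = d.embedding
    PA = embed_matrix(d.scf_a.P_spatial, emb.ao_map_a, emb.nao_super)
    PB = embed_matrix(d.scf_b.P_spatial, emb.ao_map_b, emb.nao_super)
    return PA, PB


class TestPreparationEnergy:
    def test_zero_without_relaxed_geometries(self, decomp_he2_hf):
        assert decomp_he2_hf.terms.e_prep == 0.0
        assert decomp_he2_hf.terms.flags["prep_available"] is False

    def test_identical_relaxed_geometry_gives_exact_zero(self):
        sys_ = make_fixture("hf2")
        sys_.relaxed_a = sys_.fragment_a
        e, available = preparation_energy(sys_, MethodSpec("hf"))
        assert available and e == 0.0

    def test_distorted_fragment_costs_energy(self):
        """A fragment frozen away from its relaxed bond length pays a
        strictly positive preparation energy."""
        sys_ = make_fixture("hf2")
        # relaxed H-F near the minimal-basis equilibrium (~0.956 Angstrom);
        # the frozen slice sits at 0.92 Angstrom, higher in energy
        relaxed = Species(
            sys_.fragment_a.numbers,
            sys_.fragment_a.coords_bohr * np.array([[1.0], [0.956 / 0.92]]),
        )
        sys_.relaxed_a = relaxed
        e, _ = preparation_energy(sys_, MethodSpec("hf"))
        assert e > 0.0

    def test_atomic_fragment_is_rigid(self):
        sys_ = make_fixture("he2")
        sys_.relaxed_a = sys_.fragment_a
        sys_.relaxed_b = sys_.fragment_b
        e, _ = preparation_energy(sys_, MethodSpec("hf"))
        assert e == 0.0


class TestElectrostatics:
    def test_swap_symmetry(self, decomp_water2_blyp):
        d = decomp_water2_blyp
        PA, PB = _padded_fragment_densities(d)
        import dataclasses

        swapped = dataclasses.replace(
            d.system,
            fragment_a=d.system.fragment_b, fragment_b=d.system.fragment_a,
            indices_a=d.system.indices_b, indices_b=d.system.indices_a,
        )
        e1 = electrostatic_energy(PA, PB, d.system, d.engine)
        e2 = electrostatic_energy(PB, PA, swapped, d.engine)
        assert e1 == pytest.approx(e2, abs=1e-12)

    def test_asymptotic_neutral_atoms_vanish(self):
        """Two neutral closed-shell atoms at 50 Angstrom: all cross
        multipoles vanish and overlap charge is exponentially small."""
        from etsnocv.eda import decompose

        system = make_fixture("he2", 50.0)
        d = decompose(system, MethodSpec("hf"))
        assert abs(d.terms.e_elstat) < 1e-6

    def test_direct_route_equals_functional_difference_route(
            self, all_decomps):
        """Eq.-6-style assembly vs (E[rho_A+rho_B] - E_A - E_B) - dE_XC0."""
        for label, d in all_decomps.items():
            assert abs(d.terms.elstat_route_residual) < 1e-8, label


class TestXCCross:
    def test_pure_hf_reduces_to_exchange_contraction(self, decomp_he2_hf):
        d = decomp_he2_hf
        emb = d.embedding
        Pa_A = embed_matrix(d.scf_a.Pa, emb.ao_map_a, emb.nao_super)
        Pa_B = embed_matrix(d.scf_b.Pa, emb.ao_map_b, emb.nao_super)
        e_parts = (
            exchange_contraction_oracle(Pa_A + Pa_B, Pa_A + Pa_B, d.engine.eri)
            - exchange_contraction_oracle(Pa_A, Pa_A, d.engine.eri)
            - exchange_contraction_oracle(Pa_B, Pa_B, d.engine.eri)
        )
        assert d.terms.e_xc0 == pytest.approx(e_parts, abs=1e-10)

    def test_nonoverlapping_fragments_no_xc_cross(self, decomp_he2_far_lda):
        assert abs(decomp_he2_far_lda.terms.e_xc0) < 1e-7


class TestOrbitalEnergy:
    def test_zero_deformation_gives_zero(self, decomp_heh_hf):
        from etsnocv.eda import orbital_energy

        d = decomp_heh_hf
        prom = d.promolecule

        class _Stub:
            P0a = d.scf_adduct.Pa
            P0b = d.scf_adduct.Pb
            E_promolecule = d.engine.evaluate_at_density(
                d.scf_adduct.Pa, d.scf_adduct.Pb
            ).energy

        exact, ets1, ets2 = orbital_energy(
            d.scf_adduct.Pa, d.scf_adduct.Pb, _Stub(), d.ts_focks,
            _Stub.E_promolecule,
        )
        assert exact == 0.0
        # traces against dP = 0 vanish identically
        assert ets1 == 0.0 and ets2 == 0.0
        del prom

    def test_hf_midpoint_linearization_is_exact(self, decomp_heh_hf):
        """The HF energy is quadratic in P, so the transition-state trace at
        the half-sum density reproduces E[rho]-E[rho0] exactly (and F~
        collapses onto F^TS)."""
        t = decomp_heh_hf.terms
        assert t.e_orb_ets1 == pytest.approx(t.e_orb_exact, abs=1e-12)
        assert t.e_orb_ets2 == pytest.approx(t.e_orb_exact, abs=1e-12)

    def test_second_order_estimate_beats_first_order(self,
                                                     decomp_water2_blyp,
                                                     decomp_be2_lda):
        """With a nonquadratic XC functional, Tr{F~ dP} is closer to the
        exact E[rho]-E[rho0] than Tr{F^TS dP}, and both are within 5%."""
        for d in (decomp_water2_blyp, decomp_be2_lda):
            t = d.terms
            r1 = abs(t.e_orb_ets1 - t.e_orb_exact)
            r2 = abs(t.e_orb_ets2 - t.e_orb_exact)
            assert r2 < r1
            assert r1 < 0.05 * abs(t.e_orb_exact)
            assert r2 < 0.05 * abs(t.e_orb_exact)


class TestDecomposition:
    def test_telescoping_closure(self, all_decomps):
        """dE_int rebuilt from its terms equals the supramolecular
        difference with shared-grid fragment references, to 1e-9 Ha."""
        for label, d in all_decomps.items():
            assert abs(d.terms.closure_residual) < 1e-9, label

    def test_interaction_equals_term_sum(self, all_decomps):
        for label, d in all_decomps.items():
            t = d.terms
            s = (t.e_elstat + t.e_pauli + t.e_orb_exact + t.e_disp + t.e_mp2
                 + t.e_corrections)
            assert t.e_int == pytest.approx(s, abs=1e-12), label
            assert t.e_binding == pytest.approx(t.e_prep + t.e_int, abs=1e-12)

    def test_pauli_follows_tilde_plus_xc_cross(self, all_decomps):
        for label, d in all_decomps.items():
            t = d.terms
            assert t.e_pauli == pytest.approx(t.e_pauli_tilde + t.e_xc0,
                                              abs=1e-12), label

    def test_noninteracting_limit_all_terms_vanish(self, decomp_he2_far_lda):
        t = decomp_he2_far_lda.terms
        for key, val in t.as_dict().items():
            assert abs(hartree_to_kcalmol(val)) < 0.01, key

    def test_sign_pattern_of_bonding_regimes(self, closed_shell_decomps):
        """Pauli repulsion destabilizes, orbital relaxation stabilizes, and
        hydrogen-bonded/neutral systems have attractive electrostatics."""
        for label, d in closed_shell_decomps.items():
            t = d.terms
            if t.e_pauli_tilde > 1e-8:
                assert t.e_pauli > 0.0, label
            assert t.e_orb_exact <= 1e-12, label
        for label in ("hf2/b3lyp", "water2/blyp", "water2/b2plyp"):
            assert closed_shell_decomps[label].terms.e_elstat < 0.0

    def test_double_hybrid_adds_mp2_line(self, decomp_water2_b2plyp,
                                         decomp_water2_blyp):
        t = decomp_water2_b2plyp.terms
        assert t.e_mp2 != 0.0
        assert t.e_mp2 < 0.0  # correlation stabilizes the hydrogen bond
        assert decomp_water2_blyp.terms.e_mp2 == 0.0

    def test_grid_consistency_of_fragment_references(self, all_decomps):
        """Fragment energy evaluated in the supermolecule context differs
        from its own monomer SCF only by quadrature error (zero for HF)."""
        for label, d in all_decomps.items():
            fe = d.terms.fragment_energies
            tol = 1e-10 if not d.method.has_dft_xc else 5e-4
            assert abs(fe["grid_consistency_A"]) < tol, label
            assert abs(fe["grid_consistency_B"]) < tol, label

    def test_dispersion_delta_null_provider(self):
        assert dispersion_delta(make_fixture("ar2"), MethodSpec("hf")) == 0.0

    def test_stage_failure_is_labelled(self):
        from etsnocv.eda import decompose

        system = make_fixture("he2")
        with pytest.raises(RuntimeError, match="adduct SCF failed"):
            decompose(system, MethodSpec("hf"),
                      scf_kwargs={"max_iter": 1})
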