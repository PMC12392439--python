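"""SCF driver and energy-at-density backend contract."""

import numpy as np
import pytest

from etsnocv import Engine, MethodSpec, Species, mp2_correlation, run_scf
from etsnocv.oracles import h2_mp2_oracle, h2_rhf_oracle


@pytest.fixture(scope="module")
def h2_engine():
    sp = Species((1, 1), [[0, 0, 0], [0, 0, 1.4]])
    return Engine(sp, MethodSpec("hf"))


def test_zero_electron_species_energy_is_nuclear_repulsion():
    proton = Species((1,), [[0, 0, 0]], charge=1)
    sol = run_scf(proton, MethodSpec("hf"))
    assert sol.energy == 0.0  # single nucleus, no electrons, no partner
    assert sol.converged


def test_h2_rhf_matches_closed_form_oracle(h2_engine):
    """Minimal-basis H2: the symmetric-MO closed form assembled directly
    from the integrals agrees with the iterative SCF to 1e-8 Ha."""
    sol = h2_engine.run_scf()
    e_oracle = h2_rhf_oracle(h2_engine.S, h2_engine.hcore, h2_engine.eri,
                             h2_engine.enn)
    assert sol.energy == pytest.approx(e_oracle, abs=1e-8)


@pytest.mark.parametrize("functional", ["hf", "lda"])
def test_density_idempotency_and_normalization(functional):
    he = Species((2,), [[0, 0, 0]])
    sol = run_scf(he, MethodSpec(functional))
    P, S = sol.P_spatial, sol.S
    assert np.allclose((P / 2) @ S @ (P / 2), P / 2, atol=1e-10)
    assert np.einsum("pq,pq", P, S) == pytest.approx(2.0, abs=1e-10)


def test_unrestricted_path_reproduces_restricted_energy():
    he2 = Species((2, 2), [[0, 0, 0], [0, 0, 3.8]])
    e_r = run_scf(he2, MethodSpec("hf")).energy
    e_u = run_scf(he2, MethodSpec("hf", force_unrestricted=True)).energy
    assert e_u == pytest.approx(e_r, abs=1e-7)


def test_scf_nonconvergence_carries_history():
    from etsnocv.scf import SCFConvergenceError

    he = Species((2,), [[0, 0, 0]])
    eng = Engine(he, MethodSpec("hf"))
    with pytest.raises(SCFConvergenceError) as exc:
        eng.run_scf(max_iter=1)
    assert len(exc.value.history) >= 1


def test_unknown_functional_and_basis_are_configuration_errors():
    with pytest.raises(ValueError, match="functional"):
        MethodSpec("m06-2x")
    with pytest.raises(ValueError, match="basis"):
        Engine(Species((1,), [[0, 0, 0]], charge=0, multiplicity=2),
               MethodSpec("hf", basis="def2-qzvp"))


class TestEvaluateAtDensity:
    def test_converged_density_reproduces_scf_energy(self, h2_engine):
        sol = h2_engine.run_scf()
        ev = h2_engine.evaluate_at_density(sol.P_spatial)
        assert ev.energy == pytest.approx(sol.energy, abs=1e-10)

    def test_zero_density_gives_bare_nuclear_repulsion(self, h2_engine):
        z = np.zeros((2, 2))
        ev = h2_engine.evaluate_at_density(z)
        assert ev.energy == h2_engine.enn

    def test_rejects_wrong_dimension_and_asymmetry(self, h2_engine):
        with pytest.raises(ValueError, match="dimension"):
            h2_engine.evaluate_at_density(np.zeros((3, 3)))
        bad = np.array([[0.0, 1.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            h2_engine.evaluate_at_density(bad)

    def test_duplicate_fock_assembly_at_half_sum_density(self):
        """F at the (non-idempotent) half-sum density for an He2 fixture
        matches a from-scratch rebuild of core + Coulomb + exchange."""
        he2 = Species((2, 2), [[0, 0, 0], [0, 0, 3.0]])
        eng = Engine(he2, MethodSpec("hf"))
        sol = eng.run_scf()
        P0 = np.diag([2.0, 0.0])  # some non-SCF reference density
        Pts = 0.5 * (sol.P_spatial + P0)
        ev = eng.evaluate_at_density(Pts)
        # independent assembly: explicit loop contractions of the integrals
        n = eng.nao
        J = np.zeros((n, n))
        K = np.zeros((n, n))
        for p in range(n):
            for q in range(n):
                for r in range(n):
                    for s in range(n):
                        J[p, q] += eng.eri[p, q, r, s] * Pts[r, s]
                        K[p, q] += eng.eri[p, r, q, s] * Pts[r, s]
        F_ref = eng.hcore + J - 0.5 * K
        assert np.allclose(ev.Fa, F_ref, atol=1e-12)

    def test_one_electron_part_is_exactly_linear(self, decomp_he2_hf):
        """kinetic+external of the summed embedded fragment densities equals
        the sum over fragments, in the same supermolecule integrals."""
        d = decomp_he2_hf
        eng = d.engine
        from etsnocv.system import embed_matrix

        emb = d.embedding
        PA = embed_matrix(d.scf_a.P_spatial, emb.ao_map_a, emb.nao_super)
        PB = embed_matrix(d.scf_b.P_spatial, emb.ao_map_b, emb.nao_super)
        e_sum = eng.evaluate_at_density(PA + PB).components["kinetic_external"]
        e_a = eng.evaluate_at_density(PA).components["kinetic_external"]
        e_b = eng.evaluate_at_density(PB).components["kinetic_external"]
        assert e_sum == pytest.approx(e_a + e_b, abs=1e-10)

    def test_hybrid_xc_reassembles_from_components(self, decomp_hf2_b3lyp):
        """a E_X^HF + weighted DFT exchange/correlation pieces re-sum to the
        reported hybrid XC value to 1e-10 Ha."""
        d = decomp_hf2_b3lyp
        ev = d.engine.evaluate_at_density(d.scf_adduct.Pa, d.scf_adduct.Pb)
        parts = ev.xc_components
        total = parts["hf_x_scaled"] + sum(
            v for k, v in parts.items() if k not in ("hf_x_scaled", "hf_x")
        )
        assert total == pytest.approx(ev.xc, abs=1e-10)
        assert parts["hf_x_scaled"] == pytest.approx(
            d.method.hf_exchange_fraction * parts["hf_x"], abs=1e-12
        )

    def test_dft_fock_is_energy_derivative(self, decomp_water2_blyp):
        """Directional derivative of E[P] matches Tr(F D) for the grid-based
        XC potential (finite-difference route)."""
        d = decomp_water2_blyp
        eng = d.engine
        Pa, Pb = d.scf_adduct.Pa, d.scf_adduct.Pb
        rng = np.random.default_rng(3)
        D = rng.standard_normal((eng.nao, eng.nao))
        D = 0.01 * (D + D.T)
        ev = eng.evaluate_at_density(Pa, Pb)
        eps = 1e-5
        ep = eng.fock_and_energy(Pa + eps * D, Pb)[2]
        em = eng.fock_and_energy(Pa - eps * D, Pb)[2]
        lhs = (ep - em) / (2 * eps)
        rhs = float(np.einsum("pq,pq", ev.Fa, D))
        assert lhs == pytest.approx(rhs, abs=5e-7)


class TestMP2:
    def test_h2_matches_two_orbital_closed_form(self):
        sp = Species((1, 1), [[0, 0, 0], [0, 0, 1.4]])
        eng = Engine(sp, MethodSpec("mp2"))
        sol = eng.run_scf()
        e2, dP = mp2_correlation(sol, eng)
        assert e2 == pytest.approx(h2_mp2_oracle(sol, eng.eri), abs=1e-12)
        # the unrelaxed difference density is traceless against S
        assert abs(np.einsum("pq,pq", dP, eng.S)) < 1e-10

    def test_size_consistency_of_mp2(self):
        """Two H2 molecules 50 Angstrom apart: E_C^MP2 equals twice the
        monomer value to 1e-8 Ha."""
        r = 1.4
        shift = 50.0 / 0.529177210903
        mono = Species((1, 1), [[0, 0, 0], [0, 0, r]])
        dim = Species((1, 1, 1, 1),
                      [[0, 0, 0], [0, 0, r],
                       [shift, 0, 0], [shift, 0, r]])
        m = MethodSpec("mp2")
        e_mono, _ = mp2_correlation(Engine(mono, m).run_scf(),
                                    Engine(mono, m), with_density=False)
        eng_d = Engine(dim, m)
        e_dim, _ = mp2_correlation(eng_d.run_scf(), eng_d, with_density=False)
        assert e_dim == pytest.approx(2 * e_mono, abs=1e-8)

    def test_requested_for_pure_functional_is_contract_violation(self):
        sp = Species((1, 1), [[0, 0, 0], [0, 0, 1.4]])
        eng_lda = Engine(sp, MethodSpec("lda"))
        sol = eng_lda.run_scf()
        with pytest.raises(ValueError, match="double-hybrid"):
            mp2_correlation(sol, eng_lda)

    def test_zero_mp2_coefficient_scales_to_zero(self):
        m = MethodSpec("b3lyp")  # hybrid: a_C = 0
        assert m.mp2_coefficient == 0.0
        sp = Species((1, 1), [[0, 0, 0], [0, 0, 1.4]])
        eng = Engine(sp, MethodSpec("mp2"))
        e2, _ = mp2_correlation(eng.run_scf(), eng, with_density=False)
        assert m.mp2_coefficient * e2 == 0.0


class TestDispersion:
    def test_single_atom_is_exactly_zero(self):
        from etsnocv import dispersion_energy

        ar = Species((18,), [[0, 0, 0]])
        assert dispersion_energy(ar, MethodSpec("hf", dispersion="pairwise-bj")) == 0.0

    def test_null_provider_returns_zero_for_any_geometry(self):
        from etsnocv import dispersion_energy

        sys5 = Species((18, 18, 1, 8, 2), np.random.default_rng(1).uniform(
            0, 10, size=(5, 3)), charge=1)
        assert dispersion_energy(sys5, MethodSpec("hf", dispersion="none")) == 0.0

    def test_unknown_model_is_configuration_error(self):
        from etsnocv.dispersion import get_dispersion_provider

        with pytest.raises(ValueError, match="dispersion"):
            get_dispersion_provider("d4")

    def test_delta_equals_cross_pair_sum_for_atomic_fragments(self):
        """For single-atom fragments the intra-fragment terms vanish, so the
        dispersion delta is exactly the cross-pair sum."""
        from etsnocv import make_fixture
        from etsnocv.dispersion import get_dispersion_provider
        from etsnocv.eda import dispersion_delta
        from etsnocv.oracles import cross_pair_dispersion_oracle

        system = make_fixture("ar2")
        method = MethodSpec("hf", dispersion="pairwise-bj")
        provider = get_dispersion_provider("pairwise-bj")
        delta = dispersion_delta(system, method)
        assert delta == pytest.approx(
            cross_pair_dispersion_oracle(system, provider), abs=1e-14
        )
        assert delta < 0.0  # attractive
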