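"""NOCV eigenproblem, pairing, channel energies and spin resolution."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from etsnocv import nocv_analysis, nocv_eigenpairs, pair_channels, total_valence
from etsnocv.nocv import PairingError, analyze_spin_block, channel_energies


class TestEigenpairs:
    def test_two_by_two_analytic_toy(self):
        """Adduct orbital (1,1)/sqrt(2) doubly occupied against promolecule
        orbital (1,0): dP = [[-1,1],[1,1]], eigenvalues +-sqrt(2)."""
        c_ad = np.array([1.0, 1.0]) / np.sqrt(2)
        c_pm = np.array([1.0, 0.0])
        dP = 2 * np.outer(c_ad, c_ad) - 2 * np.outer(c_pm, c_pm)
        assert np.allclose(dP, [[-1, 1], [1, 1]])
        w, C = nocv_eigenpairs(dP, np.eye(2))
        assert np.allclose(sorted(w), [-np.sqrt(2), np.sqrt(2)], atol=1e-12)
        assert np.allclose(C.T @ C, np.eye(2), atol=1e-12)

    def test_zero_deformation_gives_zero_spectrum(self):
        w, _ = nocv_eigenpairs(np.zeros((4, 4)), np.eye(4))
        assert np.allclose(w, 0.0)

    def test_eigenvalue_sum_vanishes_for_particle_conserving_dp(
            self, decomp_water2_blyp):
        d = decomp_water2_blyp
        dP = d.scf_adduct.P_spatial - d.promolecule.P0_spatial
        w, _ = nocv_eigenpairs(dP, d.engine.S)
        assert abs(w.sum()) < 1e-10

    def test_vectors_are_s_normalized_and_phase_fixed(self, decomp_heh_hf):
        d = decomp_heh_hf
        dP = d.scf_adduct.P_spatial - d.promolecule.P0_spatial
        w, C = nocv_eigenpairs(dP, d.engine.S)
        for k in range(C.shape[1]):
            assert C[:, k] @ d.engine.S @ C[:, k] == pytest.approx(1.0, abs=1e-10)
            assert C[np.argmax(np.abs(C[:, k])), k] > 0
        del w

    def test_singular_overlap_rejected(self):
        S = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(np.linalg.LinAlgError):
            nocv_eigenpairs(np.eye(2), S)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 9999), st.integers(3, 7), st.integers(1, 2))
    def test_pairing_property_for_idempotent_projectors(self, seed, n, nocc):
        """dP built from two rank-n_occ S-orthonormal projectors has a
        spectrum in +-v pairs (to 1e-7) for any overlap metric."""
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((n, n))
        S = A @ A.T + n * np.eye(n)
        sinv = np.linalg.cholesky(np.linalg.inv(S))

        def random_projector():
            C = sinv @ np.linalg.qr(rng.standard_normal((n, nocc)))[0]
            return C @ C.T

        dP = random_projector() - random_projector()
        w, C = nocv_eigenpairs(dP, S)
        channels, unpaired = pair_channels(w, C, strict=True)
        assert not unpaired
        for ch in channels:
            assert 0 < ch.eigenvalue <= 1 + 1e-9


class TestPairing:
    def test_spectrum_from_toy_pairs_to_one_channel(self):
        c_ad = np.array([1.0, 1.0]) / np.sqrt(2)
        dP = 2 * np.outer(c_ad, c_ad) - 2 * np.diag([1.0, 0.0])
        w, C = nocv_eigenpairs(dP, np.eye(2))
        channels, unpaired = pair_channels(w, C)
        assert len(channels) == 1 and not unpaired
        assert channels[0].eigenvalue == pytest.approx(np.sqrt(2), abs=1e-12)

    def test_channels_below_cutoff_are_dropped_not_lost(self, decomp_heh_hf):
        d = decomp_heh_hf
        dP = d.scf_adduct.P_spatial - d.promolecule.P0_spatial
        res_all = analyze_spin_block(dP, d.engine.S,
                                     d.ts_focks.F_tilde[0], cutoff=0.0)
        res_cut = analyze_spin_block(dP, d.engine.S,
                                     d.ts_focks.F_tilde[0], cutoff=1e9)
        assert res_cut.n_channels == 0
        # the full orbital energy moves into the residual diagnostics
        assert res_cut.residual == pytest.approx(res_all.ets2_reference,
                                                 abs=1e-12)

    def test_unpaired_spectrum_raises_on_strict_runs(self):
        w = np.array([0.5, 0.0, 0.0])
        C = np.eye(3)
        with pytest.raises(PairingError):
            pair_channels(w, C, strict=True)
        channels, unpaired = pair_channels(w, C, strict=False)
        assert not channels and unpaired == [0.5]

    def test_pairing_invariant_on_all_fixtures(self, all_decomps):
        """Every eigenvalue above 1e-6 has an opposite-sign partner matching
        in magnitude to 1e-7; violation would be a hard failure inside
        pair_channels(strict=True)."""
        for label, d in all_decomps.items():
            S = d.engine.S
            prom = d.promolecule
            scf = d.scf_adduct
            blocks = ([scf.P_spatial - prom.P0_spatial] if d.restricted else
                      [scf.Pa - prom.P0a, scf.Pb - prom.P0b])
            for dP in blocks:
                w, C = nocv_eigenpairs(dP, S)
                channels, unpaired = pair_channels(
                    w, C, cutoff=1e-6, pairing_tol=1e-7, strict=True
                )
                assert not [u for u in unpaired if abs(u) > 1e-6], label


class TestChannelEnergies:
    def test_hand_worked_two_by_two_channel_energy(self):
        c_ad = np.array([1.0, 1.0]) / np.sqrt(2)
        dP = 2 * np.outer(c_ad, c_ad) - 2 * np.diag([1.0, 0.0])
        w, C = nocv_eigenpairs(dP, np.eye(2))
        channels, _ = pair_channels(w, C)
        f1, f2 = -0.9, -0.3
        channel_energies(channels, np.diag([f1, f2]))
        ch = channels[0]
        expect = (
            float(ch.c_plus @ np.diag([f1, f2]) @ ch.c_plus)
            - float(ch.c_minus @ np.diag([f1, f2]) @ ch.c_minus)
        ) * np.sqrt(2)
        assert ch.energy == pytest.approx(expect, abs=1e-14)
        # trace identity: the single channel carries the whole Tr(F dP)
        assert ch.energy == pytest.approx(
            float(np.einsum("pq,pq", np.diag([f1, f2]), dP)), abs=1e-12
        )

    def test_channel_sum_equals_trace_for_all_fixtures(self, all_decomps):
        """With every channel kept, sum_k dE_orb,k = Tr{F~ dP} to 1e-10 Ha
        (trace invariance under the NOCV basis change)."""
        for label, d in all_decomps.items():
            nocv = nocv_analysis(d, cutoff=0.0)
            blocks = [v for k, v in nocv.items()
                      if k in ("restricted", "alpha", "beta")]
            for block in blocks:
                assert abs(block.residual) < 1e-10, label
            assert nocv["total_ets2"] == pytest.approx(
                d.terms.e_orb_ets2, abs=1e-10
            ), label

    def test_channel_density_matrix_is_traceless(self, decomp_water2_blyp):
        d = decomp_water2_blyp
        nocv = nocv_analysis(d)
        S = d.engine.S
        for ch in nocv["total_channels"]:
            assert abs(np.einsum("pq,pq", ch.density_matrix(), S)) < 1e-9


class TestSpinResolved:
    def test_closed_shell_unrestricted_matches_restricted(
            self, decomp_heh_hf, decomp_heh_hf_unrestricted):
        """Forcing a closed-shell system through the spin-resolved path
        reproduces the restricted decomposition."""
        r = nocv_analysis(decomp_heh_hf)
        u = nocv_analysis(decomp_heh_hf_unrestricted)
        assert u["total_ets2"] == pytest.approx(r["total_ets2"], abs=1e-6)
        # alpha and beta channel lists are identical
        va = [c.eigenvalue for c in u["alpha"].channels]
        vb = [c.eigenvalue for c in u["beta"].channels]
        assert np.allclose(va, vb, atol=1e-6)
        ea = [c.energy for c in u["alpha"].channels]
        eb = [c.energy for c in u["beta"].channels]
        assert np.allclose(ea, eb, atol=1e-6)
        assert abs(decomp_heh_hf_unrestricted.terms.e_orb_exact
                   - decomp_heh_hf.terms.e_orb_exact) < 1e-6

    def test_h2_from_atoms_one_sigma_channel_per_spin(self,
                                                      decomp_h2_atoms_hf):
        """Covalent bond formation from two doublets: exactly one
        significant channel per spin, matching a dense diagonalization of
        the explicitly constructed rank-1 projector difference."""
        d = decomp_h2_atoms_hf
        nocv = nocv_analysis(d)
        for spin, P, P0 in (("alpha", d.scf_adduct.Pa, d.promolecule.P0a),
                            ("beta", d.scf_adduct.Pb, d.promolecule.P0b)):
            chans = nocv[spin].channels
            assert len(chans) == 1
            # independent dense route: Loewdin-transform explicitly and
            # diagonalize with the generic symmetric solver
            S = d.engine.S
            w_s, V = np.linalg.eigh(S)
            s_half = (V * np.sqrt(w_s)) @ V.T
            w_ref = np.linalg.eigvalsh(s_half @ (P - P0) @ s_half)
            assert chans[0].eigenvalue == pytest.approx(w_ref.max(),
                                                        abs=1e-10)

    def test_spin_energies_sum_to_total(self, decomp_h2_atoms_hf):
        d = decomp_h2_atoms_hf
        nocv = nocv_analysis(d)
        total = nocv["alpha"].ets2_reference + nocv["beta"].ets2_reference
        assert total == pytest.approx(d.terms.e_orb_ets2, abs=1e-12)


class TestTotalValence:
    def test_zero_deformation(self):
        assert total_valence(np.eye(3), np.zeros((3, 3)), np.eye(3)) == 0.0

    def test_two_by_two_hand_product(self):
        """P = [[1,1],[1,1]], dP = [[-1,1],[1,1]] in an orthonormal basis:
        V = Tr(P dP) = 2."""
        P = np.array([[1.0, 1.0], [1.0, 1.0]])
        dP = np.array([[-1.0, 1.0], [1.0, 1.0]])
        assert total_valence(P, dP, np.eye(2)) == pytest.approx(2.0, abs=1e-12)

    def test_representation_invariance(self, decomp_heh_hf):
        """The metric-weighted trace is identical in the Loewdin and
        canonical-orthogonal representations."""
        d = decomp_heh_hf
        S = d.engine.S
        P = d.scf_adduct.P_spatial
        dP = P - d.promolecule.P0_spatial
        v_loewdin = total_valence(P, dP, S)
        # canonical orthogonalization X = U s^{-1/2}
        w, U = np.linalg.eigh(S)
        X = U / np.sqrt(w)
        Pi = np.linalg.inv(X)  # transforms matrices into the orthogonal rep
        v_canon = float(np.trace((Pi @ P @ Pi.T) @ (Pi @ dP @ Pi.T)))
        assert v_canon == pytest.approx(v_loewdin, abs=1e-10)
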