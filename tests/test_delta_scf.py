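import numpy as np
import pytest

from diabatmd.delta_scf import (ExcitationSpec, OrbitalSelector, ReferenceOrbitals,
                                auto_step_shift, deltascf_solve,
                                imom_select_occupations,
                                lowdin_orbital_weights, promote_electron,
                                step_shift_fock, track_state)
from diabatmd.hamiltonian import ppp_integrals
from diabatmd.scf import dipole_moment, s_squared, scf_solve

from _oracles import determinant_energy


class TestPromoteElectron:
    def test_h2_homo_lumo_spin_flip_determinant(self, h2, h2_ground):
        _, _, ints = h2
        density, ref = promote_electron(h2_ground.orbitals,
                                        ExcitationSpec("alpha", 0, 1), ints)
        # alpha occupies sigma_u, beta keeps sigma_g; <S²> of that
        # two-orbital open-shell determinant is exactly 1
        orb = h2_ground.orbitals
        from diabatmd.scf import OrbitalSet

        promoted = OrbitalSet(orb.c_alpha, orb.c_beta, orb.eps_alpha, orb.eps_beta,
                              np.array([1]), np.array([0]))
        assert s_squared(promoted, ints.overlap) == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(density.d_alpha,
                                   promoted.density().d_alpha, atol=1e-14)

    def test_promote_then_demote_restores_density(self, h2, h2_ground):
        _, _, ints = h2
        orig = h2_ground.orbitals.density()
        _, ref = promote_electron(h2_ground.orbitals, ExcitationSpec("alpha", 0, 1),
                                  ints)
        promoted = h2_ground.orbitals
        from diabatmd.scf import OrbitalSet

        up = OrbitalSet(promoted.c_alpha, promoted.c_beta, promoted.eps_alpha,
                        promoted.eps_beta, np.array([1]), np.array([0]))
        density2, _ = promote_electron(up, ExcitationSpec("alpha", 1, 0), ints)
        np.testing.assert_array_equal(density2.d_alpha, orig.d_alpha)

    def test_same_orbital_rejected(self, h2, h2_ground):
        _, _, ints = h2
        with pytest.raises(ValueError):
            promote_electron(h2_ground.orbitals, ExcitationSpec("alpha", 0, 0), ints)

    def test_labeled_selector_moves_donor_density_to_acceptor(self, gas_toy, tight):
        ints = ppp_integrals(gas_toy.geometry, gas_toy.params)
        gs = scf_solve(ints, 3, 3, mode="restricted", config=tight)
        density, _ = promote_electron(gs.orbitals, gas_toy.ct_spec, ints,
                                      gas_toy.geometry.n_atoms)
        diff = np.diag(density.d_alpha - gs.density.d_alpha)
        # one electron left a >50%-donor orbital for a >50%-acceptor orbital
        assert diff[gas_toy.donor_atoms].sum() < -0.5
        assert diff[[a for a in gas_toy.acceptor_atoms]].sum() > 0.5
        # and the resolved hole orbital really is donor-localized
        w = lowdin_orbital_weights(gs.orbitals.c_alpha, ints.overlap,
                                   ints.basis_centers, gas_toy.geometry.n_atoms)
        donor_w = w[:, gas_toy.donor_atoms].sum(axis=1)
        assert any(donor_w[i] > 0.5 for i in gs.orbitals.occ_alpha)

    def test_selector_no_match_errors(self, h2, h2_ground):
        _, _, ints = h2
        spec = ExcitationSpec("alpha", OrbitalSelector([0], "one_atom"), 1)
        # H2 sigma orbitals are 50/50 delocalized: no orbital > 50% on one atom
        with pytest.raises(ValueError, match="matches no"):
            promote_electron(h2_ground.orbitals, spec, ints)


class TestIMOMSelection:
    def test_identity_reference_selects_reference(self, rng):
        q, _ = np.linalg.qr(rng.standard_normal((6, 6)))
        ref = ReferenceOrbitals(q[:, :3], q[:, :2])
        occ_a, occ_b = imom_select_occupations(q, q, ref, np.eye(6))
        np.testing.assert_array_equal(occ_a, [0, 1, 2])
        np.testing.assert_array_equal(occ_b, [0, 1])

    def test_column_swap_follows_subspace(self, rng):
        q, _ = np.linalg.qr(rng.standard_normal((6, 6)))
        swapped = q.copy()
        swapped[:, [0, 2]] = swapped[:, [2, 0]]
        ref = ReferenceOrbitals(q[:, :3], q[:, :3])
        occ_a, _ = imom_select_occupations(swapped, swapped, ref, np.eye(6))
        np.testing.assert_array_equal(occ_a, [0, 1, 2])

    def test_virtual_mixing_leaves_selection_unchanged(self, rng):
        """Rotations among the virtual orbitals only cannot change which
        orbitals carry reference-space projection: checked against a
        brute-force projection computation over all orbitals."""
        n, nocc = 8, 3
        q, _ = np.linalg.qr(rng.standard_normal((n, n)))
        ref = ReferenceOrbitals(q[:, :nocc], q[:, :nocc])
        rot, _ = np.linalg.qr(rng.standard_normal((n - nocc, n - nocc)))
        mixed = q.copy()
        mixed[:, nocc:] = mixed[:, nocc:] @ rot
        occ_a, _ = imom_select_occupations(mixed, mixed, ref, np.eye(n))
        # brute force: projection of every orbital onto span(ref)
        proj = [np.linalg.norm(ref.c_alpha.T @ mixed[:, j]) for j in range(n)]
        expected = np.sort(np.argsort(proj)[::-1][:nocc])
        np.testing.assert_array_equal(occ_a, expected)


class TestStepShift:
    def test_two_by_two_arithmetic(self):
        f = np.diag([-1.0, 1.0])
        ref = np.array([[0.0], [1.0]])  # reference = second orbital
        fs = step_shift_fock(f, ref, np.eye(2), 10.0)
        eps = np.linalg.eigvalsh(fs)
        # first orbital shifted to -1+10 = 9 > 1: Aufbau occupies the second
        np.testing.assert_allclose(np.sort(eps), [1.0, 9.0], atol=1e-12)

    def test_zero_shift_identity(self, rng):
        f = rng.standard_normal((4, 4))
        f = f + f.T
        ref = np.linalg.qr(rng.standard_normal((4, 2)))[0]
        np.testing.assert_array_equal(step_shift_fock(f, ref, np.eye(4), 0.0), f)

    def test_large_shift_aufbau_matches_projection_selection(self, rng):
        """With a dominating shift, Aufbau on F' occupies exactly the
        orbitals with largest reference projection (brute force check)."""
        n, nocc = 6, 3
        f = rng.standard_normal((n, n))
        f = f + f.T
        ref = np.linalg.qr(rng.standard_normal((n, nocc)))[0]
        fs = step_shift_fock(f, ref, np.eye(n), 50.0)
        _, c = np.linalg.eigh(fs)
        aufbau_occupied = c[:, :nocc]
        # the occupied space after shifting must essentially be span(ref)
        overlap = np.linalg.svd(ref.T @ aufbau_occupied, compute_uv=False)
        np.testing.assert_allclose(overlap, 1.0, atol=1e-2)

    def test_auto_shift_raises_reference_above_everything(self, rng):
        f = rng.standard_normal((5, 5))
        f = f + f.T
        ref = np.linalg.qr(rng.standard_normal((5, 2)))[0]
        sigma = auto_step_shift(f, ref, margin=1.0)
        eps_ref_max = np.diag(ref.T @ f @ ref).max()
        assert sigma >= eps_ref_max - np.linalg.eigvalsh(f).min() + 1.0 - 1e-12


class TestDeltaSCF:
    def test_h2_both_methods_match_determinant_oracle(self, h2, h2_ground, tight):
        _, _, ints = h2
        energies = {}
        for method in ("imom", "step"):
            r = deltascf_solve(ints, ExcitationSpec("alpha", 0, 1), h2_ground,
                               method=method, config=tight)
            assert r.converged and not r.collapsed
            energies[method] = r.energy
            # direct determinant-energy oracle at the converged orbitals
            from diabatmd.hamiltonian import _orthonormalize
            from diabatmd.scf import lowdin_transform

            h_o, eri_o = _orthonormalize(ints)
            x = lowdin_transform(ints.overlap)
            xi = np.linalg.inv(x)
            ca = xi @ r.orbitals.occupied("alpha")
            cb = xi @ r.orbitals.occupied("beta")
            e_ref = determinant_energy(h_o, eri_o, ca, cb,
                                       e_nuc=ints.nuclear_repulsion)
            assert r.energy == pytest.approx(e_ref, abs=1e-10)
        assert energies["imom"] == pytest.approx(energies["step"], abs=1e-8)

    def test_ct_state_dipole_larger_than_ground(self, gas_toy, tight):
        ints = ppp_integrals(gas_toy.geometry, gas_toy.params)
        gs = scf_solve(ints, 3, 3, mode="restricted", config=tight)
        ct = deltascf_solve(ints, gas_toy.ct_spec, gs, method="imom", config=tight)
        zc = gas_toy.params.atom_core_charges(gas_toy.geometry)
        mu_gs = dipole_moment(gs.density, ints, gas_toy.geometry, zc)
        mu_ct = dipole_moment(ct.density, ints, gas_toy.geometry, zc)
        assert np.linalg.norm(mu_ct) > 2.0 * np.linalg.norm(mu_gs)
        assert ct.excitation_energy > 0

    def test_excited_state_is_stationary(self, gas_toy, tight):
        ints = ppp_integrals(gas_toy.geometry, gas_toy.params)
        gs = scf_solve(ints, 3, 3, mode="restricted", config=tight)
        ct = deltascf_solve(ints, gas_toy.ct_spec, gs, method="imom", config=tight)
        assert ct.commutator_norm < 1e-9

    def test_variational_sanity_above_fci(self, gas_toy, tight):
        """The ΔSCF excited energy lies at or above the first FCI excited
        state of the same <Sz>."""
        from diabatmd.hamiltonian import exact_diagonalization

        ints = ppp_integrals(gas_toy.geometry, gas_toy.params)
        gs = scf_solve(ints, 3, 3, mode="restricted", config=tight)
        ct = deltascf_solve(ints, gas_toy.ct_spec, gs, method="imom", config=tight)
        w, _, _ = exact_diagonalization(ints, 3, 3, n_states=2)
        assert ct.energy >= w[1] - 1e-10

    def test_collapse_detected_when_promotion_undone(self, h2, h2_ground, tight):
        _, _, ints = h2
        # hand the solver the ground state itself as reference and guess: it
        # must converge back onto the ground determinant and say so
        ref = ReferenceOrbitals(h2_ground.orbitals.occupied("alpha"),
                                h2_ground.orbitals.occupied("beta"))
        r = deltascf_solve(ints, None, h2_ground, method="imom", config=tight,
                           reference_override=ref,
                           guess_density=h2_ground.density)
        assert r.collapsed


class TestTrackState:
    def test_stationary_geometry_fast_reconvergence(self, gas_toy, tight):
        ints = ppp_integrals(gas_toy.geometry, gas_toy.params)
        gs = scf_solve(ints, 3, 3, mode="restricted", config=tight)
        ct = deltascf_solve(ints, gas_toy.ct_spec, gs, method="imom", config=tight)
        ref, guess = track_state(ct)
        again = deltascf_solve(ints, None, ct, method="imom", config=tight,
                               reference_override=ref, guess_density=guess,
                               ground_reference=gs.orbitals)
        assert again.converged and again.n_iterations <= 2
        assert again.energy == pytest.approx(ct.energy, abs=1e-10)

    def test_collapsed_previous_step_halts(self, h2, h2_ground):
        h2_ground_like = h2_ground
        h2_ground_like.collapsed = True
        with pytest.raises(RuntimeError, match="collapsed"):
            track_state(h2_ground_like)
        h2_ground_like.collapsed = False
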