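import numpy as np
import pytest

from diabatmd.chem_io import EmbeddingSites
from diabatmd.embedding import (EmbeddingContext, multipole_field,
                                multipole_potential, permanent_field,
                                polarization_energy, polarization_matrix,
                                qm_source_charges, solve_induced_dipoles)
from diabatmd.hamiltonian import gaussian_integrals, ppp_integrals
from diabatmd.fixtures import make_small_molecule
from diabatmd.scf import SpinDensityPair, scf_solve


def _random_sites(rng, m, polarizable=True, spread=10.0, quadrupoles=True):
    quad = np.zeros((m, 3, 3))
    if quadrupoles:
        for i in range(m):
            s = rng.normal(0, 0.2, (3, 3))
            s = 0.5 * (s + s.T)
            quad[i] = s - np.trace(s) / 3 * np.eye(3)
    alpha = rng.uniform(1.0, 6.0, m) if polarizable else np.zeros(m)
    return EmbeddingSites(rng.uniform(-spread, spread, (m, 3)),
                          rng.normal(0, 0.3, m), rng.normal(0, 0.3, (m, 3)), quad,
                          alpha, np.full(m, polarizable), np.zeros(m, bool),
                          np.arange(m))


class TestPermanentField:
    def test_point_charge_inverse_square(self):
        s = EmbeddingSites([[0, 0, 0]], [1.0], [[0, 0, 0]], [np.zeros((3, 3))],
                           [0.0], [False], [False], [0])
        E = multipole_field(s, np.array([[0.0, 0.0, 10.0]]))
        np.testing.assert_allclose(E, [[0.0, 0.0, 0.01]], atol=1e-15)

    def test_axial_dipole_field(self):
        mu = 0.7
        s = EmbeddingSites([[0, 0, 0]], [0.0], [[0, 0, mu]], [np.zeros((3, 3))],
                           [0.0], [False], [False], [0])
        r = 3.0
        E = multipole_field(s, np.array([[0.0, 0.0, r]]))
        np.testing.assert_allclose(E[0], [0, 0, 2 * mu / r ** 3], atol=1e-14)

    def test_field_is_minus_gradient_of_potential(self, rng):
        s = _random_sites(rng, 6, polarizable=False, spread=3.0)
        pt = np.array([[6.0, 1.5, -2.0]])
        h = 1e-5
        num = np.zeros(3)
        for k in range(3):
            pp, pm = pt.copy(), pt.copy()
            pp[0, k] += h
            pm[0, k] -= h
            num[k] = -(multipole_potential(s, pp)[0] - multipole_potential(s, pm)[0]) / (2 * h)
        np.testing.assert_allclose(multipole_field(s, pt)[0], num, atol=1e-8)

    def test_same_group_sites_excluded(self, rng):
        s = _random_sites(rng, 4, polarizable=True)
        s.group_id[:] = [0, 0, 1, 1]
        E = permanent_field(s)
        # partner contributions are masked: compare against explicit sum
        for i in range(4):
            expected = np.zeros(3)
            for j in range(4):
                if s.group_id[j] == s.group_id[i]:
                    continue
                single = EmbeddingSites(s.positions[[j]], s.charge[[j]],
                                        s.dipole[[j]], s.quadrupole[[j]], [0.0],
                                        [False], [False], [0])
                expected += multipole_field(single, s.positions[[i]])[0]
            np.testing.assert_allclose(E[i], expected, atol=1e-12)


class TestInducedDipoles:
    def test_single_site_mu_equals_alpha_e(self):
        s = EmbeddingSites([[0, 0, 0]], [0.0], [[0, 0, 0]], [np.zeros((3, 3))],
                           [1.5], [True], [False], [0])
        st = solve_induced_dipoles(s, np.array([[0.0, 0.0, 2.0]]))
        np.testing.assert_allclose(st.induced_dipoles, [[0, 0, 3.0]], atol=1e-12)
        assert polarization_energy(st) == pytest.approx(-3.0, abs=1e-12)

    @pytest.mark.parametrize("r,tol", [(100.0, 1e-4), (1e5, 1e-10)])
    def test_distant_sites_decoupled(self, r, tol, rng):
        """Mutual induction vanishes as α_i α_j / r³ with separation."""
        s = EmbeddingSites([[0, 0, 0], [r, 0, 0]], [0, 0],
                           np.zeros((2, 3)), np.zeros((2, 3, 3)), [2.0, 3.0],
                           [True, True], [False, False], [0, 1])
        E = rng.normal(0, 1, (2, 3))
        st = solve_induced_dipoles(s, E, tol=1e-13)
        dev = np.abs(st.induced_dipoles - s.alpha[:, None] * E).max()
        assert dev < tol
        assert dev < 10 * s.alpha.prod() * np.abs(E).max() * 2 / r ** 3

    @pytest.mark.parametrize("m", [20, 60, 100])
    def test_cg_matches_dense_solve(self, m, rng):
        s = _random_sites(rng, m, spread=1.5 * m ** (1 / 3) * 3)
        E = permanent_field(s)
        st = solve_induced_dipoles(s, E, tol=1e-12)
        dense = np.linalg.solve(polarization_matrix(s), E.ravel()).reshape(m, 3)
        assert np.abs(st.induced_dipoles[st.pol_index] - dense).max() < 1e-9

    def test_variational_identity(self, rng):
        """-½ μ·E equals ½ μᵀ(α⁻¹ - T)μ - μᵀE at the solution."""
        s = _random_sites(rng, 12)
        E = permanent_field(s)
        st = solve_induced_dipoles(s, E, tol=1e-12)
        mu = st.induced_dipoles[st.pol_index].ravel()
        A = polarization_matrix(s)
        direct = 0.5 * mu @ A @ mu - mu @ E.ravel()
        assert polarization_energy(st) == pytest.approx(direct, abs=1e-10)

    def test_epol_nonpositive(self, rng):
        for seed in range(5):
            r2 = np.random.default_rng(seed)
            s = _random_sites(r2, 15)
            st = solve_induced_dipoles(s, permanent_field(s), tol=1e-10)
            assert polarization_energy(st) <= 1e-12

    def test_unconverged_state_rejected(self):
        from diabatmd.embedding import PolarizationState

        st = PolarizationState(np.zeros((1, 3)), np.zeros((1, 3)), False, 1.0)
        with pytest.raises(ValueError, match="not converged"):
            polarization_energy(st)

    def test_frozen_unpolarizable_sites_inert_in_polarization(self, rng):
        """Depolarized frozen sites change E_pol exactly as if absent from
        the polarization system while keeping their permanent fields."""
        s = _random_sites(rng, 10)
        # freeze half: alpha -> 0, polarizable -> False
        frozen = np.arange(10) >= 5
        s_frozen = EmbeddingSites(s.positions, s.charge, s.dipole, s.quadrupole,
                                  np.where(frozen, 0.0, s.alpha),
                                  ~frozen, frozen, s.group_id)
        st = solve_induced_dipoles(s_frozen, permanent_field(s_frozen), tol=1e-12)
        # reference: polarization system containing only the live sites, with
        # the frozen ones acting through their permanent multipoles
        E_live = permanent_field(s_frozen)
        live = EmbeddingSites(s.positions[:5], s.charge[:5], s.dipole[:5],
                              s.quadrupole[:5], s.alpha[:5],
                              np.ones(5, bool), np.zeros(5, bool), s.group_id[:5])
        st_ref = solve_induced_dipoles(live, E_live, tol=1e-12)
        np.testing.assert_allclose(st.induced_dipoles[:5],
                                   st_ref.induced_dipoles, atol=1e-10)
        assert polarization_energy(st) == pytest.approx(polarization_energy(st_ref),
                                                        abs=1e-10)
        assert np.all(st.induced_dipoles[5:] == 0.0)


class TestQMCoupling:
    def test_symmetric_h2_charges_zero(self, h2, h2_ground):
        g, _, ints = h2
        q = qm_source_charges(h2_ground.density, ints, g, g.charges)
        np.testing.assert_allclose(q, [0.0, 0.0], atol=1e-10)

    def test_charge_sum_conservation(self, h2, rng):
        g, _, ints = h2
        from diabatmd.scf import lowdin_transform

        x = lowdin_transform(ints.overlap)
        for _ in range(20):
            qmat, _ = np.linalg.qr(rng.standard_normal((2, 2)))
            ca = x @ qmat[:, :1]
            d = SpinDensityPair(ca @ ca.T, ca @ ca.T)
            q = qm_source_charges(d, ints, g, g.charges)
            assert q.sum() == pytest.approx(0.0, abs=1e-10)

    def test_ct_state_charges_separate(self, gas_toy, tight):
        from diabatmd.delta_scf import deltascf_solve

        ints = ppp_integrals(gas_toy.geometry, gas_toy.params)
        gs = scf_solve(ints, 3, 3, mode="restricted", config=tight)
        ct = deltascf_solve(ints, gas_toy.ct_spec, gs, method="imom", config=tight)
        zc = gas_toy.params.atom_core_charges(gas_toy.geometry)
        q = qm_source_charges(ct.density, ints, gas_toy.geometry, zc)
        # donor fragment ~ +1 relative to its ground-state charge, acceptor ~ -1
        q0 = qm_source_charges(gs.density, ints, gas_toy.geometry, zc)
        assert (q - q0)[gas_toy.donor_atoms].sum() == pytest.approx(1.0, abs=0.2)
        assert (q - q0)[gas_toy.acceptor_atoms].sum() == pytest.approx(-1.0, abs=0.2)


class TestEmbeddingOperator:
    def test_no_sites_no_operator(self, h2, h2_ground):
        g, _, ints = h2
        ctx = EmbeddingContext(EmbeddingSites.empty(), ints, g, g.charges)
        v, e_fixed, e_pol, _ = ctx.build(h2_ground.density)
        assert np.all(v == 0.0) and e_fixed == 0.0 and e_pol == 0.0

    def test_far_anion_shifts_ppp_site_energies(self):
        """A -1 charge far from a PPP dimer raises each site energy ~ +1/r
        (repulsion of the electrons)."""
        g, p = make_small_molecule("ppp_dimer")
        ints = ppp_integrals(g, p)
        r = 50.0
        s = EmbeddingSites([[r, 0.0, 0.0]], [-1.0], [[0, 0, 0]],
                           [np.zeros((3, 3))], [0.0], [False], [False], [0])
        ctx = EmbeddingContext(s, ints, g, p.atom_core_charges(g))
        z = np.zeros((2, 2))
        v, _, _, _ = ctx.build(SpinDensityPair(z, z))
        assert v[0, 0] == pytest.approx(1.0 / r, rel=1e-3)
        assert v[1, 1] == pytest.approx(1.0 / (r - 2.7), rel=1e-3)

    def test_coupled_energy_translational_consistency(self, tight):
        """Finite-difference gradient of the fully coupled H2 + point-charge
        energy with respect to the charge position equals minus the summed
        finite-difference atomic gradients (translational invariance)."""
        g, basis = make_small_molecule("h2")
        base_site = np.array([4.0, 1.0, 0.5])

        def energy(site_pos, coords):
            gg = g.with_coords(coords)
            ints = gaussian_integrals(gg, basis)
            s = EmbeddingSites([site_pos], [0.4], [[0, 0, 0]],
                               [np.zeros((3, 3))], [0.0], [False], [False], [0])
            ctx = EmbeddingContext(s, ints, gg, gg.charges, mode="gaussian",
                                   basis_spec=basis)
            r = scf_solve(ints, 1, 1, mode="restricted", embedding_context=ctx,
                          config=tight)
            assert r.converged
            return r.energy

        h = 1e-4
        grad_site = np.zeros(3)
        for k in range(3):
            sp, sm = base_site.copy(), base_site.copy()
            sp[k] += h
            sm[k] -= h
            grad_site[k] = (energy(sp, g.coords) - energy(sm, g.coords)) / (2 * h)
        grad_atoms = np.zeros(3)
        for a in range(2):
            for k in range(3):
                cp, cm = g.coords.copy(), g.coords.copy()
                cp[a, k] += h
                cm[a, k] -= h
                grad_atoms[k] += (energy(base_site, cp) - energy(base_site, cm)) / (2 * h)
        np.testing.assert_allclose(grad_site, -grad_atoms, atol=1e-6)
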