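import numpy as np
import pytest

from diabatmd.bomd import (HarmonicDriver, MDConfig, MDState, bussi_rescale,
                           load_checkpoint, maxwell_boltzmann_velocities,
                           relax_geometry, run_md, save_checkpoint)
from diabatmd.chem_io import Geometry
from diabatmd.constants import AU_TIME_PER_FS, KB_HARTREE, atomic_mass_me
from diabatmd.fixtures import make_small_molecule
from diabatmd.grassmann import ExtrapolationHistory
from diabatmd.scf import SCFConfig


def _harmonic_state(k=0.5, x0=0.2, seed=0):
    g = Geometry(["H"], [1], [[x0, 0.0, 0.0]])
    driver = HarmonicDriver(k, np.zeros((1, 3)))
    state = MDState(g, np.zeros((1, 3)), None, None, np.random.default_rng(seed))
    return state, driver


class TestForces:
    def test_dimer_minimum_located_by_scan_has_zero_force(self, tight):
        from diabatmd.bomd import PPPDriver

        g, p = make_small_molecule("ppp_dimer")
        drv = PPPDriver(p, None, surface="ground", scf_config=tight)
        rs = np.linspace(2.0, 3.2, 61)
        energies = []
        for r in rs:
            gg = g.with_coords(np.array([[0, 0, 0], [r, 0, 0.0]]))
            energies.append(drv.solve_ground(gg).energy)
        r_min = rs[int(np.argmin(energies))]
        # refine by golden-section-free local relaxation
        gg = g.with_coords(np.array([[0, 0, 0], [r_min, 0, 0.0]]))
        gg = relax_geometry(drv, gg, fmax=1e-8, max_step=0.02)
        res = drv.solve_ground(gg)
        f = drv.forces(gg, res)
        assert np.abs(f).max() < 1e-6

    def test_analytic_matches_finite_difference_both_surfaces(self, gas_toy):
        from diabatmd.bomd import PPPDriver

        cfg = SCFConfig(tol_commutator=1e-11, tol_energy=1e-13)
        for surface in ("ground", "deltascf"):
            drv = gas_toy.driver(surface, scf_config=cfg)
            res = drv.initial_electronic(gas_toy.geometry)
            fa = drv.forces(gas_toy.geometry, res)
            fd = drv.fd_forces(gas_toy.geometry, res, 1e-4)
            assert np.abs(fa - fd).max() < 1e-6

    def test_isolated_system_force_sum_zero(self, gas_toy, tight):
        drv = gas_toy.driver("ground", scf_config=tight)
        drv.restraints = []  # truly isolated
        res = drv.initial_electronic(gas_toy.geometry)
        f = drv.forces(gas_toy.geometry, res)
        np.testing.assert_allclose(f.sum(axis=0), 0.0, atol=1e-9)


class TestVelocityVerlet:
    def test_zero_forces_zero_velocities_static(self):
        state, driver = _harmonic_state(k=0.0, x0=0.3)
        cfg = MDConfig(dt=0.5, n_steps=5)
        frames, final = run_md(state, cfg, driver)
        np.testing.assert_array_equal(final.geometry.coords, state.geometry.coords)

    def test_harmonic_period_matches_analytic(self):
        k = 0.5
        m = atomic_mass_me("H")
        omega = np.sqrt(k / m)
        period_fs = 2 * np.pi / omega / AU_TIME_PER_FS
        dt = period_fs / 100
        state, driver = _harmonic_state(k=k, x0=0.2)
        cfg = MDConfig(dt=dt, n_steps=250)
        frames, _ = run_md(state, cfg, driver)
        x = np.array([f.coords[0, 0] for f in frames])
        e = np.array([f.energy_total for f in frames])
        # bounded energy oscillation
        assert np.abs(e - e[0]).max() < 1e-3 * abs(e[0]) + 1e-8
        # period from the first return to positive maximum
        crossings = np.flatnonzero((x[:-1] < 0) & (x[1:] >= 0))
        measured = (crossings[1] - crossings[0]) * dt
        assert measured == pytest.approx(period_fs, rel=0.01)

    def test_frozen_atom_never_moves(self, gas_toy, tight):
        drv = gas_toy.driver("ground", scf_config=tight)
        g = gas_toy.geometry
        state = MDState(g, np.zeros_like(g.coords), None, ExtrapolationHistory(),
                        np.random.default_rng(0))
        state.electronic = drv.initial_electronic(g, state)
        res = drv.forces(g, state.electronic)
        assert np.abs(res[0]).max() > 1e-8  # nonzero force on the frozen atom
        cfg = MDConfig(dt=0.5, n_steps=10, frozen_atom_indices=(0,))
        frames, final = run_md(state, cfg, drv)
        np.testing.assert_array_equal(final.geometry.coords[0], g.coords[0])
        assert np.all(final.velocities[0] == 0.0)


class TestBussi:
    def test_infinite_tau_is_nve(self):
        rng = np.random.default_rng(1)
        assert bussi_rescale(0.01, 6, 300.0, np.inf, 20.0, rng) == 1.0

    def test_formula_with_pinned_deviates(self):
        """Factor matches a direct evaluation of the rescaling formula when
        the random deviates are pinned."""

        class PinnedRng:
            def standard_normal(self):
                return 0.7

            def gamma(self, shape, scale):
                return 2.3

        ndof, K, T, tau, dt = 6, 0.009, 300.0, 4000.0, 20.0
        lam = bussi_rescale(K, ndof, T, tau, dt, PinnedRng())
        c = np.exp(-dt / tau)
        kbar = 0.5 * ndof * KB_HARTREE * T
        ratio = kbar / (ndof * K)
        expected = np.sqrt(c + (1 - c) * ratio * (0.7 ** 2 + 2.3)
                           + 2 * 0.7 * np.sqrt(c * (1 - c) * ratio))
        assert lam == pytest.approx(expected, abs=1e-14)

    def test_equilibrium_kinetic_energy_sampling(self):
        """10^5-step thermostatted harmonic run: mean kinetic energy within
        two standard errors of (ndof/2) kT."""
        k, T = 0.5, 300.0
        state, driver = _harmonic_state(k=k, x0=0.3, seed=42)
        cfg = MDConfig(dt=0.5, n_steps=100_000, thermostat="bussi",
                       temperature=T, tau=0.01, seed=42)
        frames, _ = run_md(state, cfg, driver)
        ke = np.array([f.kinetic_energy for f in frames[1000:]])
        target = 1.5 * KB_HARTREE * T
        # effective samples from the thermostat time constant
        tau_steps = 0.01 * 1000 / 0.5
        n_eff = len(ke) / (2 * tau_steps)
        se = ke.std() / np.sqrt(n_eff)
        assert abs(ke.mean() - target) < 2 * se


class TestDeterminismAndRestart:
    def test_identical_seeds_identical_trajectories(self, gas_toy, tight):
        def run():
            drv = gas_toy.driver("ground", scf_config=tight)
            g = gas_toy.geometry
            rng = np.random.default_rng(3)
            state = MDState(g, maxwell_boltzmann_velocities(g, 200.0, rng), None,
                            ExtrapolationHistory(), rng)
            state.electronic = drv.initial_electronic(g, state)
            state.history.push(state.electronic.density.d_alpha,
                               state.electronic.density.d_beta, g)
            cfg = MDConfig(dt=0.5, n_steps=25, thermostat="bussi",
                           temperature=200.0, tau=0.05)
            frames, final = run_md(state, cfg, drv)
            return final.geometry.coords
        np.testing.assert_array_equal(run(), run())

    def test_checkpoint_restart_bit_reproducible(self, toy, tmp_path):
        cfg_scf = SCFConfig(tol_commutator=1e-9, tol_energy=1e-11)

        def fresh_state(drv):
            g = toy.geometry
            rng = np.random.default_rng(9)
            state = MDState(g, maxwell_boltzmann_velocities(g, 250.0, rng), None,
                            ExtrapolationHistory(), rng)
            state.electronic = drv.initial_electronic(g, state)
            state.history.push(state.electronic.density.d_alpha,
                               state.electronic.density.d_beta, g)
            return state

        md = dict(dt=0.5, thermostat="bussi", temperature=250.0, tau=0.05)
        # uninterrupted 40 steps
        drv = toy.driver("ground", scf_config=cfg_scf)
        _, straight = run_md(fresh_state(drv), MDConfig(**md, n_steps=40), drv)
        # 20 steps, checkpoint, restart, 20 more
        drv2 = toy.driver("ground", scf_config=cfg_scf)
        _, half = run_md(fresh_state(drv2), MDConfig(**md, n_steps=20), drv2)
        ckpt = tmp_path / "ckpt.npz"
        save_checkpoint(half, ckpt)
        restored = load_checkpoint(ckpt, toy.geometry)
        drv3 = toy.driver("ground", scf_config=cfg_scf)
        _, final = run_md(restored, MDConfig(**md, n_steps=20), drv3)
        assert np.abs(final.geometry.coords - straight.geometry.coords).max() < 1e-12
        assert np.abs(final.velocities - straight.velocities).max() < 1e-12
        assert final.rng.bit_generator.state == straight.rng.bit_generator.state

    def test_sudden_switch_changes_forces(self, gas_toy, tight):
        gs_drv = gas_toy.driver("ground", scf_config=tight)
        ct_drv = gas_toy.driver("deltascf", scf_config=tight)
        g = gas_toy.geometry
        gs = gs_drv.initial_electronic(g)
        ct = ct_drv.initial_electronic(g)
        f_gs = gs_drv.forces(g, gs)
        f_ct = ct_drv.forces(g, ct)
        assert np.linalg.norm(f_gs - f_ct) > 1e-3


class TestMaxwellBoltzmann:
    def test_frozen_zeroed_and_com_removed(self, gas_toy):
        g = gas_toy.geometry
        rng = np.random.default_rng(0)
        v = maxwell_boltzmann_velocities(g, 300.0, rng, frozen=(2,))
        assert np.all(v[2] == 0.0)
        masses = np.array([atomic_mass_me(s) for s in g.symbols])
        moving = [i for i in range(g.n_atoms) if i != 2]
        mom = (masses[moving, None] * v[moving]).sum(axis=0)
        np.testing.assert_allclose(mom, 0.0, atol=1e-12)
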