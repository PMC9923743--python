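"""Born–Oppenheimer MD on ground or ΔSCF-tracked excited surfaces.

Velocity Verlet with an optional Bussi stochastic velocity-rescaling
thermostat; the electronic state is fully re-converged at every step with
the previous step's orbitals as ΔSCF reference and a Grassmann-extrapolated
guess density.  Environment sites are static; frozen QM atoms keep zero
velocity and force.  Every run is bit-reproducible from (seed, config,
inputs), and a checkpoint restart continues the identical arithmetic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .chem_io import EmbeddingSites, Geometry, TrajectoryFrame, write_traj_frame
from .constants import AU_TIME_PER_FS, KB_HARTREE, atomic_mass_me
from .delta_scf import ReferenceOrbitals, deltascf_solve, track_state
from .embedding import (EmbeddingContext, induced_dipole_field, multipole_field,
                        qm_source_charges)
from .grassmann import ExtrapolationHistory
from .hamiltonian import IntegralSet, PPPParams, ohno_gamma_deriv, ppp_integrals
from .scf import (OrbitalSet, SCFConfig, SCFResult, SpinDensityPair, dipole_moment,
                  scf_solve)

log = logging.getLogger("diabatmd")


@dataclass
class MDConfig:
    dt: float = 0.5  # fs
    thermostat: str = "none"  # {none, bussi}
    temperature: float = 300.0  # K
    tau: float = 0.1  # ps
    n_steps: int = 100
    seed: int = 0
    surface: str = "ground"  # {ground, deltascf}
    frozen_atom_indices: tuple = ()
    force_mode: str = "analytic"  # {analytic, finite_difference}
    fd_step: float = 1e-4  # bohr
    guess_mode: str = "grassmann"  # {grassmann, previous, core}
    checkpoint_every: int = 0  # 0: only on demand
    checkpoint_path: str | None = None
    state_label: str = "GS"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.thermostat == "bussi" and self.tau <= 0:
            raise ValueError("bussi thermostat needs tau > 0")


@dataclass
class TrackRestraint:
    """Harmonic tether of one atom to a line segment (anchor_a -> anchor_b):
    E = ½ k d², d = distance to the segment.  Emulates the hydrogen-bond
    chain that confines the mobile proton in the real system; zero force
    anywhere on the track itself."""

    atom_index: int
    anchor_a: np.ndarray
    anchor_b: np.ndarray
    k: float = 0.02  # hartree / bohr²

    def energy_force(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        p = coords[self.atom_index]
        a = np.asarray(self.anchor_a, float)
        b = np.asarray(self.anchor_b, float)
        ab = b - a
        t = float(np.clip((p - a) @ ab / (ab @ ab), 0.0, 1.0))
        d = p - (a + t * ab)
        f = np.zeros_like(coords)
        f[self.atom_index] = -self.k * d
        return 0.5 * self.k * float(d @ d), f


@dataclass
class PositionRestraint:
    """Harmonic tether of one atom to a fixed point: E = ½ k |r - p|².
    Emulates the scaffold holding a residue in place."""

    atom_index: int
    point: np.ndarray
    k: float = 0.05  # hartree / bohr²

    def energy_force(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        d = coords[self.atom_index] - np.asarray(self.point, float)
        f = np.zeros_like(coords)
        f[self.atom_index] = -self.k * d
        return 0.5 * self.k * float(d @ d), f


@dataclass
class MDState:
    geometry: Geometry
    velocities: np.ndarray  # (n, 3) bohr per atomic time unit
    electronic: SCFResult | None
    history: ExtrapolationHistory | None
    rng: np.random.Generator
    step_index: int = 0
    last_induced: np.ndarray | None = None
    ground_reference: OrbitalSet | None = None  # collapse detector reference
    iteration_log: list = field(default_factory=list)  # SCF cycles per MD step


# ---------------------------------------------------------------------------
# drivers


class HarmonicDriver:
    """Isotropic harmonic test potential ½ Σ k |r - r0|²; no electronic
    structure.  Used for integrator and thermostat validation."""

    def __init__(self, k: float, r0: np.ndarray):
        self.k = k
        self.r0 = np.atleast_2d(np.asarray(r0, float))

    def initial_electronic(self, geometry, state=None):
        return None

    def step_electronic(self, geometry, state):
        return None

    def potential_energy(self, geometry, result) -> float:
        return 0.5 * self.k * float(np.sum((geometry.coords - self.r0) ** 2))

    def forces(self, geometry, result, warm_mu=None) -> np.ndarray:
        return -self.k * (geometry.coords - self.r0)

    def frame_fields(self, geometry, result):
        e = self.potential_energy(geometry, result)
        return e, e, 0.0, 0.0, np.zeros(3)


class PPPDriver:
    """Electronic driver for the PPP backend with optional polarizable
    embedding, on the ground (restricted, Aufbau) or ΔSCF-tracked excited
    surface."""

    def __init__(self, params: PPPParams, sites: EmbeddingSites | None = None,
                 surface: str = "ground", dscf_method: str = "imom",
                 scf_config: SCFConfig | None = None,
                 excitation_spec=None, thole_a: float = 0.39,
                 cg_tol: float = 1e-10, step_margin: float = 1.0,
                 guess_mode: str = "grassmann", restraints: list | None = None):
        self.params = params
        self.sites = sites if sites is not None else EmbeddingSites.empty()
        self.surface = surface
        self.dscf_method = dscf_method
        self.scf_config = scf_config or SCFConfig()
        self.excitation_spec = excitation_spec
        self.thole_a = thole_a
        self.cg_tol = cg_tol
        self.step_margin = step_margin
        self.guess_mode = guess_mode  # {grassmann, previous, core}
        self.restraints = restraints or []
        self.ground_reference: OrbitalSet | None = None  # excitation-time GS orbitals

    # -- helpers ------------------------------------------------------------
    def integrals(self, geometry: Geometry) -> IntegralSet:
        return ppp_integrals(geometry, self.params)

    def context(self, geometry: Geometry, integrals: IntegralSet,
                warm_mu: np.ndarray | None = None) -> EmbeddingContext | None:
        if self.sites.n_sites == 0:
            return None
        ctx = EmbeddingContext(self.sites, integrals, geometry,
                               self.params.atom_core_charges(geometry),
                               mode="ppp", thole_a=self.thole_a, cg_tol=self.cg_tol)
        ctx._warm = warm_mu
        return ctx

    def n_electron_pair(self) -> tuple[int, int]:
        ne = self.params.electrons
        if self.surface == "ground":
            if ne % 2:
                raise ValueError("ground-surface driver assumes a closed shell")
            return ne // 2, ne // 2
        return ne // 2 + ne % 2, ne // 2  # before promotion; spin counts unchanged

    # -- electronic solutions ------------------------------------------------
    def solve_ground(self, geometry: Geometry, warm_mu=None,
                     guess="core") -> SCFResult:
        ints = self.integrals(geometry)
        ctx = self.context(geometry, ints, warm_mu)
        na = nb = self.params.electrons // 2
        return scf_solve(ints, na, nb, guess=guess, mode="restricted",
                         embedding_context=ctx, config=self.scf_config)

    def initial_electronic(self, geometry: Geometry, state: MDState | None = None
                           ) -> SCFResult:
        if self.surface == "ground":
            return self.solve_ground(geometry)
        ground = self.solve_ground(geometry)
        ints = self.integrals(geometry)
        ctx = self.context(geometry, ints,
                           ground.pol_state.induced_dipoles if ground.pol_state else None)
        res = deltascf_solve(ints, self.excitation_spec, ground,
                             method=self.dscf_method, embedding_context=ctx,
                             config=self.scf_config, step_margin=self.step_margin)
        self.ground_reference = ground.orbitals
        if state is not None:
            state.ground_reference = ground.orbitals
        return res

    def step_electronic(self, geometry: Geometry, state: MDState) -> SCFResult:
        ints = self.integrals(geometry)
        ctx = self.context(geometry, ints, state.last_induced)
        prev = state.electronic
        if self.surface == "ground":
            if self.guess_mode == "core":
                guess = "core"
            elif self.guess_mode == "grassmann" and state.history is not None \
                    and len(state.history) >= 2:
                guess = state.history.extrapolate(geometry)
            else:
                guess = prev.density
            na = nb = self.params.electrons // 2
            return scf_solve(ints, na, nb, guess=guess, mode="restricted",
                             embedding_context=ctx, config=self.scf_config)
        hist = state.history if self.guess_mode == "grassmann" else None
        reference, guess = track_state(prev, hist, geometry)
        return deltascf_solve(ints, None, prev, method=self.dscf_method,
                              embedding_context=ctx, reference_override=reference,
                              guess_density=guess, config=self.scf_config,
                              step_margin=self.step_margin,
                              ground_reference=state.ground_reference)

    # -- forces ---------------------------------------------------------------
    def restraint_energy_force(self, geometry: Geometry) -> tuple[float, np.ndarray]:
        e = 0.0
        f = np.zeros_like(geometry.coords)
        for r in self.restraints:
            er, fr = r.energy_force(geometry.coords)
            e += er
            f += fr
        return e, f

    def potential_energy(self, geometry: Geometry, result: SCFResult) -> float:
        return result.energy + self.restraint_energy_force(geometry)[0]

    def forces(self, geometry: Geometry, result: SCFResult,
               warm_mu: np.ndarray | None = None) -> np.ndarray:
        f = ppp_forces(geometry, self.params, result.density, self.sites,
                       thole_a=self.thole_a, cg_tol=self.cg_tol,
                       warm_mu=warm_mu)
        return f + self.restraint_energy_force(geometry)[1]

    def fd_forces(self, geometry: Geometry, result: SCFResult,
                  fd_step: float = 1e-4) -> np.ndarray:
        """Central differences of the full self-consistent energy with state
        tracking at the displaced geometries."""
        F = np.zeros((geometry.n_atoms, 3))
        for a in range(geometry.n_atoms):
            for k in range(3):
                e = []
                for sgn in (+1, -1):
                    coords = geometry.coords.copy()
                    coords[a, k] += sgn * fd_step
                    g = geometry.with_coords(coords)
                    ints = self.integrals(g)
                    warm = result.pol_state.induced_dipoles if result.pol_state else None
                    ctx = self.context(g, ints, warm)
                    if self.surface == "ground":
                        na = nb = self.params.electrons // 2
                        r = scf_solve(ints, na, nb, guess=result.density,
                                      mode="restricted", embedding_context=ctx,
                                      config=self.scf_config)
                    else:
                        ref = ReferenceOrbitals(result.orbitals.occupied("alpha"),
                                                result.orbitals.occupied("beta"),
                                                provenance="previous_md_step")
                        r = deltascf_solve(ints, None, result, method=self.dscf_method,
                                           embedding_context=ctx,
                                           reference_override=ref,
                                           guess_density=result.density,
                                           config=self.scf_config,
                                           step_margin=self.step_margin,
                                           ground_reference=self.ground_reference)
                        if self.ground_reference is not None and r.collapsed:
                            raise RuntimeError(
                                f"deltaSCF collapse at displaced geometry atom {a} axis {k}")
                    if not r.converged:
                        raise RuntimeError(
                            f"SCF failure at displaced geometry atom {a} axis {k}")
                    e.append(r.energy + self.restraint_energy_force(g)[0])
                F[a, k] = -(e[0] - e[1]) / (2 * fd_step)
        return F

    def frame_fields(self, geometry: Geometry, result: SCFResult):
        ints = self.integrals(geometry)
        mu = dipole_moment(result.density, ints, geometry,
                           self.params.atom_core_charges(geometry))
        return (self.potential_energy(geometry, result), result.energy_qm,
                result.energy_fixed_elec, result.energy_pol, mu)


def ppp_forces(geometry: Geometry, params: PPPParams, density: SpinDensityPair,
               sites: EmbeddingSites | None = None, thole_a: float = 0.39,
               cg_tol: float = 1e-10, warm_mu: np.ndarray | None = None
               ) -> np.ndarray:
    """Analytic Hellmann–Feynman forces for the PPP backend.

    All geometry dependence enters through the pair distances (hopping t(r),
    Ohno γ(r)) and through the electrostatic coupling of the Löwdin point
    charges to the environment; induced dipoles are at their variational
    optimum, so no response terms are needed.
    """
    sa = params.resolve_site_atoms(geometry)
    n_at = geometry.n_atoms
    coords = geometry.coords
    rvec = coords[:, None] - coords[None, :]
    r = np.linalg.norm(rvec, axis=-1)
    np.fill_diagonal(r, 1.0)
    u = params.atom_u(geometry)
    uavg = 0.5 * (u[:, None] + u[None, :])
    dgam = ohno_gamma_deriv(r, uavg)
    zc = params.atom_core_charges(geometry)
    P = density.total
    Da, Db = density.d_alpha, density.d_beta

    # symmetric atom-pair matrix C[a,b] = dE/dr_ab (full coefficient per
    # unordered pair, stored on both triangles); F_a = -Σ_b C_ab û_ab then
    # distributes each pair's force to both partners with opposite signs.
    C = np.zeros((n_at, n_at))
    # core-core repulsion: Ohno plus the Born-Mayer σ wall (all atom pairs)
    C += np.outer(zc, zc) * dgam
    C += -params.rep_a / params.rep_rho * np.exp(-(r - params.r0) / params.rep_rho)
    ns = len(sa)
    for i in range(ns):
        ai = sa[i]
        # electron-core attraction of site i's population to every other core
        C[ai, :] += -P[i, i] * zc * dgam[ai, :]
        C[:, ai] += -P[i, i] * zc * dgam[:, ai]
        for j in range(i + 1, ns):
            aj = sa[j]
            rij = r[ai, aj]
            t = params.t0 * np.exp(-(rij - params.r0) / params.lam)
            dt = -t / params.lam
            coef = 2.0 * P[i, j] * dt
            coef += (P[i, i] * P[j, j] - Da[i, j] ** 2 - Db[i, j] ** 2) * dgam[ai, aj]
            C[ai, aj] += coef
            C[aj, ai] += coef
    np.fill_diagonal(C, 0.0)
    unit = rvec / r[:, :, None]
    F = -np.einsum("ab,abk->ak", C, unit)

    if sites is not None and sites.n_sites:
        ints = ppp_integrals(geometry, params)
        q = qm_source_charges(density, ints, geometry, zc)
        E_env = multipole_field(sites, coords)
        from .embedding import permanent_field, solve_induced_dipoles
        E_perm = permanent_field(sites, q, coords)
        pol = solve_induced_dipoles(sites, E_perm, tol=cg_tol, thole_a=thole_a,
                                    warm_start=warm_mu)
        E_env = E_env + induced_dipole_field(pol, sites, coords)
        F += q[:, None] * E_env
    return F


def relax_geometry(driver, geometry: Geometry, fmax: float = 1e-4,
                   max_step: float = 0.05, max_iter: int = 500,
                   frozen: tuple = ()) -> Geometry:
    """Local geometry relaxation by step-clamped gradient descent.

    The clamp keeps the search inside the starting basin: the model has no
    exchange repulsion against the environment sites, so unconstrained
    minimizers can leave the physical region.
    """
    g = geometry
    step = max_step
    result = driver.initial_electronic(g)
    warm = result.pol_state.induced_dipoles if result.pol_state is not None else None
    e_prev = driver.potential_energy(g, result)
    frozen = np.asarray(frozen, int)
    for it in range(max_iter):
        f = driver.forces(g, result, warm_mu=warm)
        if len(frozen):
            f[frozen] = 0.0
        fnorm = np.abs(f).max()
        if fnorm < fmax:
            log.info("relaxation converged in %d iterations (maxF=%.2e)", it, fnorm)
            return g
        disp = f * min(1.0, step / fnorm)
        trial = g.with_coords(g.coords + disp)
        trial_result = _relax_solve(driver, trial, result, warm)
        e_trial = driver.potential_energy(trial, trial_result)
        if e_trial <= e_prev + 1e-12:
            g, result, e_prev = trial, trial_result, e_trial
            warm = result.pol_state.induced_dipoles if result.pol_state is not None else None
            step = min(step * 1.2, max_step)
        else:
            step *= 0.5
            if step < 1e-6:
                break
    log.warning("relaxation stopped after %d iterations (maxF=%.2e)", max_iter,
                np.abs(driver.forces(g, result, warm_mu=warm)).max())
    return g


def _relax_solve(driver, geometry, previous, warm):
    state = MDState(geometry=geometry, velocities=np.zeros_like(geometry.coords),
                    electronic=previous, history=None,
                    rng=np.random.default_rng(0), last_induced=warm)
    return driver.step_electronic(geometry, state)


# ---------------------------------------------------------------------------
# thermostat


def bussi_rescale(kinetic: float, ndof: int, temperature: float, tau: float,
                  dt: float, rng: np.random.Generator) -> float:
    """Stochastic velocity-rescaling factor (canonical sampling through
    velocity rescaling).  tau and dt in the same time unit; tau = inf gives
    exactly 1."""
    if kinetic <= 0:
        raise ValueError("kinetic energy must be > 0")
    if ndof < 1:
        raise ValueError("ndof must be >= 1")
    if np.isinf(tau):
        return 1.0
    c = np.exp(-dt / tau)
    kbar = 0.5 * ndof * KB_HARTREE * temperature
    ratio = kbar / (ndof * kinetic)
    r1 = rng.standard_normal()
    chi2 = rng.gamma(0.5 * (ndof - 1), 2.0) if ndof > 1 else 0.0
    alpha2 = c + (1.0 - c) * ratio * (r1 ** 2 + chi2) \
        + 2.0 * r1 * np.sqrt(c * (1.0 - c) * ratio)
    return float(np.sqrt(max(alpha2, 0.0)))


def maxwell_boltzmann_velocities(geometry: Geometry, temperature: float,
                                 rng: np.random.Generator,
                                 frozen: tuple = ()) -> np.ndarray:
    """Seeded Maxwell–Boltzmann draw; frozen atoms zeroed, COM motion of the
    moving atoms removed."""
    masses = np.array([atomic_mass_me(s) for s in geometry.symbols])
    v = rng.standard_normal((geometry.n_atoms, 3)) * np.sqrt(
        KB_HARTREE * temperature / masses)[:, None]
    frozen = np.asarray(frozen, int)
    moving = np.setdiff1d(np.arange(geometry.n_atoms), frozen)
    if len(frozen):
        v[frozen] = 0.0
    mom = (masses[moving, None] * v[moving]).sum(axis=0)
    v[moving] -= mom / masses[moving].sum()
    return v


# ---------------------------------------------------------------------------
# integrator


def kinetic_energy(velocities: np.ndarray, masses: np.ndarray) -> float:
    return 0.5 * float(np.sum(masses[:, None] * velocities ** 2))


def velocity_verlet_step(state: MDState, forces: np.ndarray, config: MDConfig,
                         driver) -> tuple[MDState, np.ndarray]:
    """One velocity-Verlet step; returns the advanced state and the forces
    at the new geometry (electronic state re-converged with tracking)."""
    geom = state.geometry
    masses = np.array([atomic_mass_me(s) for s in geom.symbols])
    dt = config.dt * AU_TIME_PER_FS
    frozen = np.asarray(config.frozen_atom_indices, int)
    f = forces.copy()
    if len(frozen):
        f[frozen] = 0.0
    v_half = state.velocities + 0.5 * dt * f / masses[:, None]
    if len(frozen):
        v_half[frozen] = 0.0
    new_coords = geom.coords + dt * v_half
    new_geom = geom.with_coords(new_coords)

    electronic = driver.step_electronic(new_geom, state)
    if electronic is not None and not electronic.converged:
        raise RuntimeError(
            f"SCF convergence failure at MD step {state.step_index + 1}")
    warm = None
    if electronic is not None and electronic.pol_state is not None:
        warm = electronic.pol_state.induced_dipoles
    if config.force_mode == "analytic":
        f_new = driver.forces(new_geom, electronic, warm_mu=warm)
    else:
        f_new = driver.fd_forces(new_geom, electronic, config.fd_step)
    if len(frozen):
        f_new[frozen] = 0.0
    v_new = v_half + 0.5 * dt * f_new / masses[:, None]
    if len(frozen):
        v_new[frozen] = 0.0

    if config.thermostat == "bussi":
        moving = np.setdiff1d(np.arange(geom.n_atoms), frozen)
        ndof = 3 * len(moving)
        K = kinetic_energy(v_new[moving], masses[moving])
        lam = bussi_rescale(K, ndof, config.temperature,
                            config.tau * 1000.0 * AU_TIME_PER_FS, dt, state.rng)
        v_new[moving] *= lam

    new_state = MDState(geometry=new_geom, velocities=v_new, electronic=electronic,
                        history=state.history, rng=state.rng,
                        step_index=state.step_index + 1,
                        last_induced=warm, ground_reference=state.ground_reference,
                        iteration_log=state.iteration_log)
    if electronic is not None:
        new_state.iteration_log.append(electronic.n_iterations)
    if new_state.history is not None and electronic is not None:
        new_state.history.push(electronic.density.d_alpha, electronic.density.d_beta,
                               new_geom)
    return new_state, f_new


def _make_frame(state: MDState, config: MDConfig, driver,
                masses: np.ndarray) -> TrajectoryFrame:
    e_pot, e_qm, e_fix, e_pol, dip = driver.frame_fields(state.geometry,
                                                         state.electronic)
    ke = kinetic_energy(state.velocities, masses)
    return TrajectoryFrame(
        step_index=state.step_index, time=state.step_index * config.dt,
        symbols=list(state.geometry.symbols), coords=state.geometry.coords.copy(),
        velocities=state.velocities.copy(), energy_total=e_pot + ke,
        energy_qm=e_qm, energy_fixed_elec=e_fix, energy_pol=e_pol,
        kinetic_energy=ke, dipole_moment=np.asarray(dip, float),
        state_label=config.state_label, dt=config.dt)


def run_md(initial: MDState, config: MDConfig, driver,
           traj_path=None) -> tuple[list[TrajectoryFrame], MDState]:
    """Propagate `config.n_steps` steps; returns the frames (including the
    initial one when starting from step 0) and the final state."""
    masses = np.array([atomic_mass_me(s) for s in initial.geometry.symbols])
    state = initial
    frames: list[TrajectoryFrame] = []

    if state.electronic is None and not isinstance(driver, HarmonicDriver):
        raise ValueError("initial electronic state missing")
    warm = None
    if state.electronic is not None and state.electronic.pol_state is not None:
        warm = state.electronic.pol_state.induced_dipoles
    if state.last_induced is not None:
        warm = state.last_induced
    if config.force_mode == "analytic":
        forces = driver.forces(state.geometry, state.electronic, warm_mu=warm)
    else:
        forces = driver.fd_forces(state.geometry, state.electronic, config.fd_step)
    if len(config.frozen_atom_indices):
        forces[np.asarray(config.frozen_atom_indices, int)] = 0.0

    if state.step_index == 0:
        frame = _make_frame(state, config, driver, masses)
        frames.append(frame)
        if traj_path is not None:
            write_traj_frame(frame, traj_path)

    for _ in range(config.n_steps):
        state, forces = velocity_verlet_step(state, forces, config, driver)
        frame = _make_frame(state, config, driver, masses)
        frames.append(frame)
        if traj_path is not None:
            write_traj_frame(frame, traj_path)
        log.info("md step=%d E_total=%.10f maxF=%.3e", state.step_index,
                 frame.energy_total, np.abs(forces).max())
        if config.checkpoint_every and config.checkpoint_path and \
                state.step_index % config.checkpoint_every == 0:
            save_checkpoint(state, config.checkpoint_path)
    return frames, state


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(state: MDState, path) -> None:
    """Single structured binary container with everything needed to continue
    the trajectory bit-reproducibly (rng state serialized explicitly)."""
    data = {
        "step_index": state.step_index,
        "coords": state.geometry.coords,
        "velocities": state.velocities,
        "symbols": np.array(state.geometry.symbols),
        "charges": state.geometry.charges,
        "rng_state": np.array(json.dumps(state.rng.bit_generator.state)),
    }
    el = state.electronic
    if el is not None:
        data.update({
            "d_alpha": el.density.d_alpha, "d_beta": el.density.d_beta,
            "occ_c_alpha": el.orbitals.occupied("alpha"),
            "occ_c_beta": el.orbitals.occupied("beta"),
            "c_alpha": el.orbitals.c_alpha, "c_beta": el.orbitals.c_beta,
            "eps_alpha": el.orbitals.eps_alpha, "eps_beta": el.orbitals.eps_beta,
            "occ_alpha": el.orbitals.occ_alpha, "occ_beta": el.orbitals.occ_beta,
            "energy": el.energy,
        })
    if state.last_induced is not None:
        data["last_induced"] = state.last_induced
    if state.ground_reference is not None:
        data["gref_c_alpha"] = state.ground_reference.c_alpha
        data["gref_c_beta"] = state.ground_reference.c_beta
        data["gref_occ_alpha"] = state.ground_reference.occ_alpha
        data["gref_occ_beta"] = state.ground_reference.occ_beta
    h = state.history
    if h is not None and len(h):
        data["hist_c0_alpha"] = h.c0_alpha
        data["hist_c0_beta"] = h.c0_beta
        data["hist_gammas_alpha"] = np.stack(h.gammas_alpha)
        data["hist_gammas_beta"] = np.stack(h.gammas_beta)
        data["hist_descriptors"] = np.stack(h.descriptors)
        data["hist_capacity"] = h.capacity
    np.savez(path, **data)


def load_checkpoint(path, template: Geometry,
                    history_defaults: dict | None = None) -> MDState:
    z = np.load(path, allow_pickle=False)
    geom = template.with_coords(z["coords"])
    rng = np.random.default_rng()
    rng.bit_generator.state = json.loads(str(z["rng_state"]))
    electronic = None
    if "d_alpha" in z:
        orbitals = OrbitalSet(z["c_alpha"], z["c_beta"], z["eps_alpha"],
                              z["eps_beta"], z["occ_alpha"], z["occ_beta"])
        density = SpinDensityPair(z["d_alpha"], z["d_beta"], basis="AO")
        electronic = SCFResult(energy=float(z["energy"]), orbitals=orbitals,
                               density=density, converged=True, n_iterations=0,
                               commutator_norm=0.0)
    history = None
    if "hist_descriptors" in z:
        history = ExtrapolationHistory(capacity=int(z["hist_capacity"]),
                                       **(history_defaults or {}))
        history.c0_alpha = z["hist_c0_alpha"]
        history.c0_beta = z["hist_c0_beta"]
        history.gammas_alpha = list(z["hist_gammas_alpha"])
        history.gammas_beta = list(z["hist_gammas_beta"])
        history.descriptors = list(z["hist_descriptors"])
    gref = None
    if "gref_c_alpha" in z:
        gref = OrbitalSet(z["gref_c_alpha"], z["gref_c_beta"],
                          np.zeros(z["gref_c_alpha"].shape[1]),
                          np.zeros(z["gref_c_beta"].shape[1]),
                          z["gref_occ_alpha"], z["gref_occ_beta"])
    return MDState(geometry=geom, velocities=z["velocities"], electronic=electronic,
                   history=history, rng=rng, step_index=int(z["step_index"]),
                   last_induced=z["last_induced"] if "last_induced" in z else None,
                   ground_reference=gref)
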