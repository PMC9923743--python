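"""Seeded, self-verifying generators for every test system.

The headline fixture is a donor–bridge–acceptor PPP toy with a mobile
classical proton and a polarizable environment shell: a desk-scale analog
of a flavin-photoreceptor active site in a protein matrix.  Its electronic
structure is arranged so that

* the closed-shell ground state keeps every fragment (donor+proton,
  acceptor) near-neutral,
* the donor→acceptor ΔSCF charge-transfer (CT) state has a much larger
  dipole and exerts a force that pushes the proton from the donor anchor
  toward the acceptor (electron transfer gates proton transfer), and
* the vertical ordering of the locally-excited (LE) and CT states flips as
  the proton moves ~40% along its track, so short excited-state runs reach
  the LE/CT crossing.

Every fixture is generated *and verified*: the generator re-derives these
properties at build time and refuses to hand out a system that violates
them.  All randomness flows from the single spec seed.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np

from .bomd import PositionRestraint, PPPDriver, TrackRestraint, ppp_forces
from .chem_io import EmbeddingSites, Geometry, TrajectoryFrame
from .delta_scf import ExcitationSpec, OrbitalSelector, deltascf_solve
from .embedding import qm_source_charges
from .hamiltonian import PPPParams, exact_diagonalization, fci_dipole, ppp_integrals
from .pcet_analysis import PTDefinition
from .scf import SCFConfig, dipole_moment

log = logging.getLogger("diabatmd")


# ---------------------------------------------------------------------------
# small oracle-verifiable systems


def make_small_molecule(name: str):
    """Fixed fixture systems; returns (Geometry, basis_spec or PPPParams)."""
    from .hamiltonian import STO3G

    if name == "h2":
        g = Geometry(["H", "H"], [1, 1], [[0, 0, 0], [0, 0, 1.4011]])
        return g, STO3G
    if name == "heh_plus":
        g = Geometry(["He", "H"], [2, 1], [[0, 0, 0], [0, 0, 1.4632]], qm_charge=1)
        return g, STO3G
    if name == "h4_chain":
        coords = [[0, 0, 1.8 * i] for i in range(4)]
        g = Geometry(["H"] * 4, [1] * 4, coords)
        return g, STO3G
    if name == "ppp_dimer":
        g = Geometry(["C", "C"], [6, 6], [[0, 0, 0], [2.7, 0, 0]])
        p = PPPParams(site_energies=[0.0, 0.0], hubbard_u=[0.45, 0.45],
                      electrons=2, core_charges=[1.0, 1.0], t0=-0.1, r0=2.7)
        return g, p
    if name == "ppp_4site":
        coords = [[2.5 * i, 0, 0] for i in range(4)]
        g = Geometry(["C"] * 4, [6] * 4, coords)
        p = PPPParams(site_energies=[-0.2, 0.0, 0.0, 0.1],
                      hubbard_u=[0.5, 0.5, 0.5, 0.5],
                      electrons=4, core_charges=[1.0, 1.0, 1.0, 1.0])
        return g, p
    raise ValueError(
        f"unknown fixture {name!r}; valid: h2, heh_plus, h4_chain, ppp_dimer, ppp_4site")


# ---------------------------------------------------------------------------
# the PCET toy


@dataclass
class PCETToySpec:
    seed: int = 1
    n_donor_sites: int = 2
    n_acceptor_sites: int = 2
    n_bridge_sites: int = 1
    site_spacing: float = 2.5  # bohr, intra-fragment
    fragment_gap: float = 3.5  # bohr, edge-to-bridge
    proton_anchor_donor: tuple = (-3.0, 2.4, 0.0)
    proton_anchor_acceptor: tuple = (3.0, 2.4, 0.0)
    epsilon_bias: float | None = None  # None: generation-time scan
    crossing_target: float = 0.4  # fraction of the track where LE/CT flips
    track_restraint_k: float = 0.02  # hartree/bohr², proton tether to the track
    scaffold_k: float = 0.05  # hartree/bohr², π sites tethered to design positions
    env_n_sites: int = 24
    env_radius: float = 14.0  # bohr
    env_alpha_mean: float = 6.0  # bohr^3
    env_charge_scale: float = 0.15  # e
    frozen_beyond: float = 18.0  # bohr

    def __post_init__(self) -> None:
        if np.allclose(self.proton_anchor_donor, self.proton_anchor_acceptor):
            raise ValueError("proton anchors must be distinct")
        if self.env_n_sites and self.env_radius <= 8.0:
            raise ValueError("environment radius must exceed the molecular extent")


@dataclass
class PCETToy:
    geometry: Geometry  # proton at the donor anchor
    params: PPPParams
    sites: EmbeddingSites
    pt_definitions: list
    ct_spec: ExcitationSpec
    le_spec: ExcitationSpec
    proton_index: int
    donor_atoms: list
    acceptor_atoms: list
    proton_track: tuple  # (donor anchor, acceptor anchor), bohr
    epsilon_bias: float = 0.0
    crossing_fraction: float = float("nan")
    restraints: list = field(default_factory=list)

    def driver(self, surface: str = "ground", dscf_method: str = "imom",
               scf_config: SCFConfig | None = None, guess_mode: str = "grassmann"):
        """A ready PPPDriver for this toy (restraints and embedding wired in)."""
        return PPPDriver(self.params, self.sites, surface=surface,
                         dscf_method=dscf_method,
                         scf_config=scf_config or SCFConfig(tol_commutator=1e-9,
                                                            tol_energy=1e-11),
                         excitation_spec=self.ct_spec if surface == "deltascf" else None,
                         restraints=self.restraints, guess_mode=guess_mode)

    def geometry_with_proton_at(self, fraction: float) -> Geometry:
        a, b = (np.asarray(self.proton_track[0]), np.asarray(self.proton_track[1]))
        coords = self.geometry.coords.copy()
        coords[self.proton_index] = a + fraction * (b - a)
        return self.geometry.with_coords(coords)


def _toy_geometry(spec: PCETToySpec):
    nd, nb, na = spec.n_donor_sites, spec.n_bridge_sites, spec.n_acceptor_sites
    xs = []
    # donor block, bridge block, acceptor block along x, centered at origin
    x = 0.0
    for _ in range(nd):
        xs.append(x)
        x += spec.site_spacing
    x += spec.fragment_gap - spec.site_spacing
    for _ in range(nb):
        xs.append(x)
        x += spec.site_spacing
    x += spec.fragment_gap - spec.site_spacing
    for _ in range(na):
        xs.append(x)
        x += spec.site_spacing
    xs = np.array(xs)
    xs -= xs.mean()
    coords = [[xi, 0.0, 0.0] for xi in xs] + [list(spec.proton_anchor_donor)]
    symbols = ["C"] * (nd + nb + na) + ["H"]
    charges = [6] * (nd + nb + na) + [1]
    return Geometry(symbols, charges, coords)


def _toy_params(spec: PCETToySpec, acceptor_bias: float) -> PPPParams:
    nd, nb, na = spec.n_donor_sites, spec.n_bridge_sites, spec.n_acceptor_sites
    # the bridge sits high: a pure superexchange relay, essentially empty
    eps = [-0.30] * nd + [1.0] * nb + [acceptor_bias] * na
    u = [0.50] * nd + [0.60] * nb + [0.45] * na
    # donor holds (2 nd) electrons plus the proton's companion pair slot:
    # cores chosen so donor+proton, bridge and acceptor are separately neutral
    # in the dark ground state (donor cores sum + 1 = donor electron count).
    cores = [1.5] * nd + [0.0] * nb + [1.0] * na
    electrons = 2 * nd + na  # donor doubly filled + acceptor bonding pair
    # with defaults: 4 (donor) + 2 (acceptor) = 6 electrons
    return PPPParams(site_energies=eps, hubbard_u=u, electrons=electrons,
                     core_charges=cores, t0=-0.12, r0=2.5, lam=0.8,
                     site_atoms=np.arange(nd + nb + na), bare_core_u=0.5)


def _toy_environment(spec: PCETToySpec, rng: np.random.Generator) -> EmbeddingSites:
    m = spec.env_n_sites
    if m == 0:
        return EmbeddingSites.empty()
    n_pairs = m // 2
    pos, q, dip, quad, alpha, polz, frozen, group = [], [], [], [], [], [], [], []
    for g in range(n_pairs):
        radius = rng.uniform(spec.env_radius, 1.6 * spec.env_radius)
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        center = radius * u
        axis = rng.standard_normal(3)
        axis /= np.linalg.norm(axis)
        qq = rng.uniform(0.5, 1.0) * spec.env_charge_scale
        for sgn in (+1.0, -1.0):
            p = center + sgn * 0.8 * axis
            pos.append(p)
            q.append(sgn * qq)
            dip.append(rng.normal(0.0, 0.1, 3))
            s = rng.normal(0.0, 0.05, (3, 3))
            s = 0.5 * (s + s.T)
            s -= np.trace(s) / 3.0 * np.eye(3)
            quad.append(s)
            far = np.linalg.norm(p) > spec.frozen_beyond
            frozen.append(far)
            polz.append(not far)
            alpha.append(0.0 if far else spec.env_alpha_mean * rng.uniform(0.8, 1.2))
            group.append(g)
    if m % 2:  # odd leftover: one neutral polarizable site
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        pos.append(spec.env_radius * u)
        q.append(0.0)
        dip.append(rng.normal(0.0, 0.1, 3))
        quad.append(np.zeros((3, 3)))
        frozen.append(False)
        polz.append(True)
        alpha.append(spec.env_alpha_mean)
        group.append(n_pairs)
    return EmbeddingSites(np.array(pos), np.array(q), np.array(dip), np.array(quad),
                          np.array(alpha), np.array(polz), np.array(frozen),
                          np.array(group))


def _fci_le_ct_gap(toy: PCETToy, fraction: float) -> float:
    """E_CT - E_LE from the FCI adiabatic states at one proton position,
    with states classified by their dipole shift along the donor-acceptor
    axis.  Positive: LE below CT."""
    g = toy.geometry_with_proton_at(fraction)
    ints = ppp_integrals(g, toy.params)
    ne = toy.params.electrons
    w, v, dets = exact_diagonalization(ints, ne // 2, ne // 2, n_states=5)
    zc = toy.params.atom_core_charges(g)
    mu0 = fci_dipole(v[:, 0], dets, ints, g, zc)
    axis = g.coords[toy.acceptor_atoms[0]] - g.coords[toy.donor_atoms[0]]
    axis /= np.linalg.norm(axis)
    e_ct = e_le = None
    for k in range(1, v.shape[1]):
        mu = fci_dipole(v[:, k], dets, ints, g, zc)
        shift = abs(float((mu - mu0) @ axis))
        if shift > 5.0 and e_ct is None:
            e_ct = w[k]
        elif shift < 2.0 and e_le is None:
            e_le = w[k]
        if e_ct is not None and e_le is not None:
            break
    if e_ct is None or e_le is None:
        return np.nan
    return float(e_ct - e_le)


def _find_crossing(toy: PCETToy, fractions: np.ndarray) -> float:
    gaps = np.array([_fci_le_ct_gap(toy, f) for f in fractions])
    for i in range(len(fractions) - 1):
        if np.isnan(gaps[i]) or np.isnan(gaps[i + 1]):
            continue
        if gaps[i] > 0 >= gaps[i + 1]:
            # linear interpolation of the sign change
            f = fractions[i] + (fractions[i + 1] - fractions[i]) * gaps[i] / (
                gaps[i] - gaps[i + 1])
            return float(f)
    return np.nan


_TOY_CACHE: dict = {}


def make_pcet_toy(spec: PCETToySpec | None = None) -> PCETToy:
    """Build and verify the donor–bridge–acceptor PCET toy."""
    spec = spec or PCETToySpec()
    key = repr(spec)
    if key in _TOY_CACHE:
        return copy.deepcopy(_TOY_CACHE[key])

    rng = np.random.default_rng(spec.seed)
    geometry = _toy_geometry(spec)
    nd, nb, na = spec.n_donor_sites, spec.n_bridge_sites, spec.n_acceptor_sites
    donor_atoms = list(range(nd))
    acceptor_atoms = list(range(nd + nb, nd + nb + na))
    proton_index = nd + nb + na
    sites = _toy_environment(spec, rng)
    ct_spec = ExcitationSpec("alpha", OrbitalSelector(donor_atoms, "pi_donor"),
                             OrbitalSelector(acceptor_atoms, "pi_acceptor_virt"))
    le_spec = ExcitationSpec("alpha", OrbitalSelector(acceptor_atoms, "pi_acceptor"),
                             OrbitalSelector(acceptor_atoms, "pi_acceptor_virt"))
    pt_defs = [PTDefinition("donor-acceptor", donor_atom_index=nd - 1,
                            hydrogen_atom_index=proton_index,
                            acceptor_atom_index=acceptor_atoms[0])]

    track = (np.array(spec.proton_anchor_donor), np.array(spec.proton_anchor_acceptor))
    restraints = [TrackRestraint(proton_index, track[0], track[1],
                                 spec.track_restraint_k)]
    if spec.scaffold_k > 0:
        restraints += [PositionRestraint(a, geometry.coords[a].copy(), spec.scaffold_k)
                       for a in range(proton_index)]

    def assemble(bias: float) -> PCETToy:
        return PCETToy(geometry=geometry, params=_toy_params(spec, bias),
                       sites=sites, pt_definitions=pt_defs, ct_spec=ct_spec,
                       le_spec=le_spec, proton_index=proton_index,
                       donor_atoms=donor_atoms, acceptor_atoms=acceptor_atoms,
                       proton_track=track, epsilon_bias=bias,
                       restraints=restraints)

    if spec.epsilon_bias is None:
        fractions = np.linspace(0.0, 0.8, 9)
        best, best_err = None, np.inf
        for bias in np.linspace(0.0, 0.24, 13):
            f_cross = _find_crossing(assemble(bias), fractions)
            if np.isnan(f_cross):
                continue
            err = abs(f_cross - spec.crossing_target)
            if err < best_err:
                best, best_err, best_cross = bias, err, f_cross
        if best is None:
            raise RuntimeError("toy generation failed: no epsilon bias produces "
                               "an LE/CT crossing along the proton track")
        bias, f_cross = best, best_cross
    else:
        bias = spec.epsilon_bias
        f_cross = _find_crossing(assemble(bias), np.linspace(0.0, 0.8, 9))
    toy = assemble(bias)
    toy.crossing_fraction = f_cross
    log.info("pcet toy: epsilon bias %.3f, LE/CT crossing at %.2f of the track",
             bias, f_cross)
    _verify_toy(toy)
    _TOY_CACHE[key] = copy.deepcopy(toy)
    return toy


def _verify_toy(toy: PCETToy) -> None:
    """Generation-time verification of the delivered system."""
    cfg = SCFConfig()
    driver = PPPDriver(toy.params, toy.sites, surface="ground", scf_config=cfg)
    ground = driver.solve_ground(toy.geometry)
    if not ground.converged:
        raise RuntimeError("toy verification failed: ground SCF did not converge")
    ints = ppp_integrals(toy.geometry, toy.params)
    zc = toy.params.atom_core_charges(toy.geometry)
    q = qm_source_charges(ground.density, ints, toy.geometry, zc)
    frag_d = q[toy.donor_atoms].sum() + q[toy.proton_index]
    frag_a = q[toy.acceptor_atoms].sum()
    if abs(frag_d) > 0.2 or abs(frag_a) > 0.2:
        raise RuntimeError(
            f"toy verification failed (a): ground-state fragment charges "
            f"donor+H={frag_d:+.3f}, acceptor={frag_a:+.3f} exceed 0.2 e")

    ctx = driver.context(toy.geometry, ints,
                         ground.pol_state.induced_dipoles if ground.pol_state else None)
    ct = deltascf_solve(ints, toy.ct_spec, ground, method="imom",
                        embedding_context=ctx, config=cfg)
    if not ct.converged or ct.collapsed:
        raise RuntimeError("toy verification failed: CT deltaSCF state unusable")
    mu_gs = dipole_moment(ground.density, ints, toy.geometry, zc)
    mu_ct = dipole_moment(ct.density, ints, toy.geometry, zc)
    if np.linalg.norm(mu_ct) < 2.0 * np.linalg.norm(mu_gs):
        raise RuntimeError(
            f"toy verification failed (b): CT dipole {np.linalg.norm(mu_ct):.2f} "
            f"< 2 x GS dipole {np.linalg.norm(mu_gs):.2f}")

    warm = ct.pol_state.induced_dipoles if ct.pol_state else None
    forces = ppp_forces(toy.geometry, toy.params, ct.density, toy.sites,
                        warm_mu=warm)
    track = np.asarray(toy.proton_track[1]) - np.asarray(toy.proton_track[0])
    if float(forces[toy.proton_index] @ track) <= 0.0:
        raise RuntimeError(
            "toy verification failed (c): CT-state force on the proton does not "
            "point from the donor anchor toward the acceptor anchor")


# ---------------------------------------------------------------------------
# scripted trajectories for the analysis module


def make_scripted_trajectory(symbols: list, times_fs: np.ndarray,
                             coords_list, dipoles, dt: float,
                             state_labels=None) -> list:
    """Frames on a dt grid with piecewise-linear coordinates and dipoles
    between script breakpoints (times in fs, coords in bohr)."""
    times_fs = np.asarray(times_fs, float)
    if np.any(np.diff(times_fs) <= 0):
        raise ValueError("script times must be strictly increasing")
    on_grid = np.abs(times_fs / dt - np.round(times_fs / dt)) < 1e-9
    if not np.all(on_grid):
        raise ValueError("script times do not lie on the dt grid")
    coords_list = [np.atleast_2d(np.asarray(c, float)) for c in coords_list]
    dipoles = [np.asarray(d, float) for d in dipoles]
    n_frames = int(round(times_fs[-1] / dt)) + 1
    frames = []
    for k in range(n_frames):
        t = k * dt
        j = int(np.searchsorted(times_fs, t, side="right")) - 1
        j = min(j, len(times_fs) - 2) if len(times_fs) > 1 else 0
        if len(times_fs) == 1:
            c, mu = coords_list[0], dipoles[0]
        else:
            w = (t - times_fs[j]) / (times_fs[j + 1] - times_fs[j])
            c = (1 - w) * coords_list[j] + w * coords_list[j + 1]
            mu = (1 - w) * dipoles[j] + w * dipoles[j + 1]
        frames.append(TrajectoryFrame(
            step_index=k, time=t, symbols=list(symbols), coords=c,
            velocities=np.zeros_like(c), energy_total=0.0, energy_qm=0.0,
            energy_fixed_elec=0.0, energy_pol=0.0, kinetic_energy=0.0,
            dipole_moment=mu,
            state_label=(state_labels[k] if state_labels else "GS"), dt=dt))
    return frames
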