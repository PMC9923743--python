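"""AMOEBA-style polarizable environment.

Permanent multipoles (charge, dipole, traceless Cartesian quadrupole) give
fixed electrostatics; isotropic polarizable sites carry induced point
dipoles solved self-consistently by preconditioned conjugate gradient with
Thole-damped mutual induction.  The QM density couples to the environment
through Löwdin atomic charges (both directions in PPP mode; in Gaussian
mode the environment monopole potential additionally enters through exact
charge-type integrals).  The total energy is defined by the implemented
expression, and forces are obtained by differentiating exactly it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse.linalg import LinearOperator, cg

from .chem_io import EmbeddingSites, Geometry
from .hamiltonian import IntegralSet, _boys_f0, _build_shells
from .scf import SpinDensityPair

log = logging.getLogger("diabatmd")


@dataclass
class PolarizationState:
    induced_dipoles: np.ndarray  # (n_sites, 3), zero on non-polarizable sites
    perm_field: np.ndarray  # (m_pol, 3) field at polarizable sites
    converged: bool
    residual_norm: float
    pol_index: np.ndarray = None  # rows of induced_dipoles that are polarizable
    n_iterations: int = 0
    density_hash: int | None = None

    def __post_init__(self):
        if self.pol_index is None:
            self.pol_index = np.arange(self.perm_field.shape[0])


# ---------------------------------------------------------------------------
# fields and potentials of permanent multipoles


def _pairwise(points_a: np.ndarray, points_b: np.ndarray):
    """rvec[i,j] = a_i - b_j, r[i,j] = |rvec|."""
    rvec = points_a[:, None, :] - points_b[None, :, :]
    r = np.linalg.norm(rvec, axis=-1)
    return rvec, r


def multipole_potential(sites: EmbeddingSites, points: np.ndarray) -> np.ndarray:
    """Potential of the permanent site multipoles at external points (a.u.)."""
    if sites.n_sites == 0 or len(points) == 0:
        return np.zeros(len(points))
    rvec, r = _pairwise(np.atleast_2d(points), sites.positions)
    if np.any(r < 1e-8):
        raise ValueError("evaluation point coincides with an environment site")
    phi = (sites.charge[None, :] / r).sum(axis=1)
    phi += (np.einsum("ijk,jk->ij", rvec, sites.dipole) / r ** 3).sum(axis=1)
    # traceless quadrupole: phi_Q = (1/2) rᵀ Q r / r^5
    rQr = np.einsum("ijk,jkl,ijl->ij", rvec, sites.quadrupole, rvec)
    phi += 0.5 * (rQr / r ** 5).sum(axis=1)
    return phi


def multipole_field(sites: EmbeddingSites, points: np.ndarray,
                    exclude_groups: np.ndarray | None = None) -> np.ndarray:
    """Field of the permanent multipoles at external points.

    exclude_groups: per-point group id; sites sharing that group contribute
    nothing (AMOEBA-style intra-group masking for the polarization field).
    """
    points = np.atleast_2d(points)
    if sites.n_sites == 0 or len(points) == 0:
        return np.zeros((len(points), 3))
    rvec, r = _pairwise(points, sites.positions)
    mask = np.ones_like(r)
    if exclude_groups is not None:
        mask = (sites.group_id[None, :] != np.asarray(exclude_groups)[:, None]).astype(float)
    if np.any((r < 1e-8) & (mask > 0)):
        raise ValueError("evaluation point coincides with an environment site")
    r = np.where(mask > 0, r, 1.0)  # excluded pairs: dummy distance, zero weight
    # charge: E = q r̂ / r²
    E = np.einsum("ij,ijk->ik", mask * sites.charge[None, :] / r ** 3, rvec)
    # dipole: E = (3(μ·r̂)r̂ - μ)/r³
    mu_dot = np.einsum("ijk,jk->ij", rvec, sites.dipole)
    E += np.einsum("ij,ijk->ik", mask * 3.0 * mu_dot / r ** 5, rvec)
    E -= np.einsum("ij,jk->ik", mask / r ** 3, sites.dipole)
    # quadrupole (traceless): E = (5/2)(rᵀQr)r/r^7 - Qr/r^5
    Qr = np.einsum("jkl,ijl->ijk", sites.quadrupole, rvec)
    rQr = np.einsum("ijk,ijk->ij", rvec, Qr)
    E += np.einsum("ij,ijk->ik", mask * 2.5 * rQr / r ** 7, rvec)
    E -= np.einsum("ij,ijk->ik", mask / r ** 5, Qr)
    return E


def point_charge_field(charges: np.ndarray, positions: np.ndarray,
                       points: np.ndarray) -> np.ndarray:
    """Field at `points` from external point charges (e.g. the QM region)."""
    points = np.atleast_2d(points)
    if len(charges) == 0 or len(points) == 0:
        return np.zeros((len(points), 3))
    rvec, r = _pairwise(points, np.atleast_2d(positions))
    if np.any(r < 1e-8):
        raise ValueError("polarizable site coincides with a QM charge")
    return np.einsum("ij,ijk->ik", charges[None, :] / r ** 3, rvec)


def permanent_field(sites: EmbeddingSites, qm_charges: np.ndarray | None = None,
                    qm_positions: np.ndarray | None = None) -> np.ndarray:
    """Total permanent field at the polarizable sites: other-group permanent
    multipoles plus the QM point charges."""
    pol = np.flatnonzero(sites.polarizable)
    pts = sites.positions[pol]
    grp = sites.group_id[pol]
    E = multipole_field(sites, pts, exclude_groups=grp)
    # remove any self-contribution not caught by group masking is unnecessary:
    # every site belongs to exactly one group and masks itself through it.
    if qm_charges is not None and len(qm_charges):
        E += point_charge_field(np.asarray(qm_charges), qm_positions, pts)
    return E


# ---------------------------------------------------------------------------
# induced dipoles


def thole_factors(r: np.ndarray, alpha_i: np.ndarray, alpha_j: np.ndarray,
                  a: float) -> tuple[np.ndarray, np.ndarray]:
    """Exponential-smearing Thole damping factors (λ3, λ5) at effective
    distance u = r/(α_i α_j)^(1/6)."""
    u3 = (r ** 3) / np.sqrt(alpha_i * alpha_j)
    au3 = a * u3
    ex = np.exp(-au3)
    return 1.0 - ex, 1.0 - (1.0 + au3) * ex


def _dipole_interaction(sites: EmbeddingSites, thole_a: float):
    """Dense damped dipole–dipole tensor T (3m_pol × 3m_pol) with intra-group
    pairs excluded; also returns polarizable indices and their alphas."""
    pol = np.flatnonzero(sites.polarizable)
    m = len(pol)
    pos = sites.positions[pol]
    alpha = sites.alpha[pol]
    T = np.zeros((3 * m, 3 * m))
    if m > 1:
        rvec, r = _pairwise(pos, pos)
        grp = sites.group_id[pol]
        same = grp[:, None] == grp[None, :]
        for i in range(m):
            for j in range(m):
                if j == i or same[i, j]:
                    continue
                rr = r[i, j]
                l3, l5 = thole_factors(rr, alpha[i], alpha[j], thole_a)
                v = rvec[i, j]
                tij = l5 * 3.0 * np.outer(v, v) / rr ** 5 - l3 * np.eye(3) / rr ** 3
                T[3 * i:3 * i + 3, 3 * j:3 * j + 3] = tij
    return T, pol, alpha


def polarization_matrix(sites: EmbeddingSites, thole_a: float = 0.39) -> np.ndarray:
    """The dense response matrix A = α⁻¹ - T over polarizable sites."""
    T, pol, alpha = _dipole_interaction(sites, thole_a)
    A = -T
    for i in range(len(pol)):
        A[3 * i:3 * i + 3, 3 * i:3 * i + 3] += np.eye(3) / alpha[i]
    return A


def solve_induced_dipoles(sites: EmbeddingSites, total_perm_field: np.ndarray,
                          tol: float = 1e-8, max_iter: int = 200,
                          thole_a: float = 0.39,
                          warm_start: np.ndarray | None = None) -> PolarizationState:
    """Solve (α⁻¹ - T) μ = E_perm by diagonal-preconditioned CG."""
    pol = np.flatnonzero(sites.polarizable)
    m = len(pol)
    mu_full = np.zeros((sites.n_sites, 3))
    E = np.asarray(total_perm_field, float).reshape(m, 3)
    if m == 0:
        return PolarizationState(mu_full, E, True, 0.0)
    A = polarization_matrix(sites, thole_a)
    b = E.ravel()
    alpha = sites.alpha[pol]
    Minv = np.repeat(alpha, 3)  # preconditioner: apply α (inverse of diagonal)
    x0 = None
    if warm_start is not None:
        x0 = np.asarray(warm_start, float)[pol].ravel()
    op = LinearOperator((3 * m, 3 * m), matvec=lambda x: A @ x)
    pre = LinearOperator((3 * m, 3 * m), matvec=lambda x: Minv * x)
    x, info = cg(op, b, x0=x0, rtol=0.0, atol=tol, maxiter=max_iter, M=pre)
    res = float(np.linalg.norm(A @ x - b))
    if info != 0 or res > max(tol, 1e-12) * max(1.0, np.linalg.norm(b)):
        raise RuntimeError(
            f"induced-dipole CG failed to converge (info={info}, residual={res:.3e}); "
            "check polarizabilities for a polarization catastrophe")
    mu_full[pol] = x.reshape(m, 3)
    return PolarizationState(mu_full, E, True, res, pol_index=pol)


def polarization_energy(state: PolarizationState) -> float:
    """Variational induced-dipole energy E_pol = -½ Σ μ·E_perm (≤ 0 for
    fields from permanent + QM sources)."""
    if not state.converged:
        raise ValueError("polarization state not converged")
    pol_mu = state.induced_dipoles[state.pol_index]
    return -0.5 * float(np.sum(pol_mu * state.perm_field))


def induced_dipole_potential(state: PolarizationState, sites: EmbeddingSites,
                             points: np.ndarray) -> np.ndarray:
    """Potential of the induced dipoles at external points."""
    points = np.atleast_2d(points)
    mu = state.induced_dipoles
    if sites.n_sites == 0 or len(points) == 0:
        return np.zeros(len(points))
    rvec, r = _pairwise(points, sites.positions)
    return (np.einsum("ijk,jk->ij", rvec, mu) / r ** 3).sum(axis=1)


def induced_dipole_field(state: PolarizationState, sites: EmbeddingSites,
                         points: np.ndarray) -> np.ndarray:
    points = np.atleast_2d(points)
    mu = state.induced_dipoles
    if sites.n_sites == 0 or len(points) == 0:
        return np.zeros((len(points), 3))
    rvec, r = _pairwise(points, sites.positions)
    mu_dot = np.einsum("ijk,jk->ij", rvec, mu)
    E = np.einsum("ij,ijk->ik", 3.0 * mu_dot / r ** 5, rvec)
    E -= np.einsum("ij,jk->ik", 1.0 / r ** 3, mu)
    return E


# ---------------------------------------------------------------------------
# QM coupling


def lowdin_populations(density: SpinDensityPair, integrals: IntegralSet,
                       n_atoms: int) -> np.ndarray:
    """Löwdin electron populations per atom (basis functions mapped through
    integrals.basis_centers)."""
    if density.basis == "AO":
        sh = _sqrtm_spd(integrals.overlap)
        p = np.diag(sh @ density.total @ sh)
    else:
        p = np.diag(density.total)
    pops = np.zeros(n_atoms)
    np.add.at(pops, integrals.basis_centers, p)
    return pops


def _sqrtm_spd(s: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(s)
    return v @ np.diag(np.sqrt(w)) @ v.T


def qm_source_charges(density: SpinDensityPair, integrals: IntegralSet,
                      geometry: Geometry, core_charges: np.ndarray) -> np.ndarray:
    """Per-atom point charges q_a = Z_a(core) - Löwdin population; they sum
    to the net QM charge by construction."""
    pops = lowdin_populations(density, integrals, geometry.n_atoms)
    return np.asarray(core_charges, float) - pops


# ---------------------------------------------------------------------------
# the embedding context used inside SCF


class EmbeddingContext:
    """Orchestrates the mutual QM/environment coupling for one geometry.

    `build(density)` returns (v_embed, e_fixed, e_pol, PolarizationState):
    the one-electron embedding operator, the QM↔permanent electrostatic
    energy of the *given* density, and the variational polarization energy
    with induced dipoles re-converged for that density (warm-started from
    the previous call).
    """

    def __init__(self, sites: EmbeddingSites, integrals: IntegralSet,
                 geometry: Geometry, core_charges: np.ndarray,
                 mode: str = "ppp", thole_a: float = 0.39,
                 cg_tol: float = 1e-10, cg_max_iter: int = 200,
                 basis_spec: dict | None = None):
        self.sites = sites
        self.integrals = integrals
        self.geometry = geometry
        self.core_charges = np.asarray(core_charges, float)
        self.mode = mode
        self.thole_a = thole_a
        self.cg_tol = cg_tol
        self.cg_max_iter = cg_max_iter
        self._warm = None
        n_at = geometry.n_atoms
        if sites.n_sites:
            self.phi_perm_at_atoms = multipole_potential(sites, geometry.coords)
        else:
            self.phi_perm_at_atoms = np.zeros(n_at)
        if mode == "gaussian":
            if basis_spec is None:
                raise ValueError("gaussian-mode embedding needs the basis_spec")
            self._shells = _build_shells(geometry, basis_spec)
            self._v_mono = self._monopole_operator()
            self._sh = _sqrtm_spd(integrals.overlap)
        else:
            self._v_mono = None

    # -- Gaussian-mode exact monopole integrals -----------------------------
    def _monopole_operator(self) -> np.ndarray:
        """Exact -Σ_s q_s ∫ φμ φν / |r - R_s| integrals (s-type shells)."""
        from .hamiltonian import _prim_norm
        shells = self._shells
        n = self.integrals.n_basis
        V = np.zeros((n, n))
        if self.sites.n_sites == 0:
            return V
        for i, si in enumerate(shells):
            for j, sj in enumerate(shells):
                if j < i:
                    continue
                AB2 = float(np.dot(si.center - sj.center, si.center - sj.center))
                v = 0.0
                for a, ca in zip(si.exps, si.coefs):
                    na = _prim_norm(a)
                    for b, cb in zip(sj.exps, sj.coefs):
                        nb = _prim_norm(b)
                        p = a + b
                        mu = a * b / p
                        P = (a * si.center + b * sj.center) / p
                        for qs, C in zip(self.sites.charge, self.sites.positions):
                            PC2 = float(np.dot(P - C, P - C))
                            v -= ca * cb * na * nb * qs * (2.0 * np.pi / p) * \
                                np.exp(-mu * AB2) * float(_boys_f0(p * PC2))
                V[i, j] = V[j, i] = v
        return V

    # -----------------------------------------------------------------------
    def update_dipoles(self, density: SpinDensityPair) -> PolarizationState:
        """Converged induced dipoles for a given (fixed) QM density."""
        q = qm_source_charges(density, self.integrals, self.geometry,
                              self.core_charges)
        E_perm = permanent_field(self.sites, q, self.geometry.coords)
        return solve_induced_dipoles(self.sites, E_perm, tol=self.cg_tol,
                                     max_iter=self.cg_max_iter, thole_a=self.thole_a,
                                     warm_start=self._warm)

    def frozen(self, mu: np.ndarray) -> "FrozenPolarizationContext":
        return FrozenPolarizationContext(self, mu)

    def build(self, density: SpinDensityPair):
        sites = self.sites
        geom = self.geometry
        n = self.integrals.n_basis
        if sites.n_sites == 0:
            return np.zeros((n, n)), 0.0, 0.0, PolarizationState(
                np.zeros((0, 3)), np.zeros((0, 3)), True, 0.0)
        q = qm_source_charges(density, self.integrals, geom, self.core_charges)
        E_perm = permanent_field(sites, q, geom.coords)
        state = solve_induced_dipoles(sites, E_perm, tol=self.cg_tol,
                                      max_iter=self.cg_max_iter, thole_a=self.thole_a,
                                      warm_start=self._warm)
        self._warm = state.induced_dipoles.copy()
        e_pol = polarization_energy(state)
        phi_ind = induced_dipole_potential(state, sites, geom.coords)

        if self.mode == "ppp":
            # site-potential × number-operator; everything through Löwdin charges
            phi = self.phi_perm_at_atoms + phi_ind
            e_fixed = float(np.sum(q * self.phi_perm_at_atoms))
            v = np.diag(-phi[self.integrals.basis_centers])
        else:
            # monopoles via exact integrals; dipole/quadrupole + induced via
            # the Löwdin point-charge representation
            phi_mono = _charge_only_potential(sites, geom.coords)
            phi_dq = self.phi_perm_at_atoms - phi_mono
            phi_hi = phi_dq + phi_ind
            e_fixed = float(np.sum(density.total * self._v_mono)) \
                + float(np.sum(self.core_charges * phi_mono)) \
                + float(np.sum(q * phi_dq))
            # v += Σ_a (-phi_hi[a]) d(pop_a)/dD = Σ_a (-phi_hi[a]) S^1/2 P_a S^1/2
            v_hi = np.zeros((n, n))
            for a in range(geom.n_atoms):
                sel = np.flatnonzero(self.integrals.basis_centers == a)
                if len(sel) == 0:
                    continue
                Pa = np.zeros((n, n))
                Pa[sel, sel] = 1.0
                v_hi += (-phi_hi[a]) * (self._sh @ Pa @ self._sh)
            v = self._v_mono + v_hi
        # e_pol couples to the density through the field of the Löwdin charges:
        # dE_pol/dD contributes -phi_ind through the same charge operator,
        # which is already inside `phi` above (ppp) / phi_hi (gaussian).
        return v, e_fixed, e_pol, state


class FrozenPolarizationContext:
    """Embedding context with the induced dipoles held fixed.

    The inner energy functional is Ẽ(D) = E_QM + E_es(D) + ½ μᵀAμ - μᵀE(D):
    variational in D at fixed μ, with the same one-electron operator form as
    the fully coupled context.  Used by the macro-iteration fallback that
    alternates SCF and dipole updates when the simultaneous iteration
    limit-cycles; at the joint fixed point it coincides with the coupled
    solution.
    """

    def __init__(self, parent: EmbeddingContext, mu: np.ndarray):
        self.parent = parent
        self.mu = np.asarray(mu, float)
        sites = parent.sites
        self._state = PolarizationState(self.mu,
                                        np.zeros((int(sites.polarizable.sum()), 3)),
                                        True, 0.0,
                                        pol_index=np.flatnonzero(sites.polarizable))
        A = polarization_matrix(sites, parent.thole_a)
        x = self.mu[self._state.pol_index].ravel()
        self._half_muAmu = 0.5 * float(x @ (A @ x))
        self._phi_ind = induced_dipole_potential(self._state, sites,
                                                 parent.geometry.coords)

    def build(self, density: SpinDensityPair):
        p = self.parent
        sites = p.sites
        n = p.integrals.n_basis
        if sites.n_sites == 0:
            return np.zeros((n, n)), 0.0, 0.0, self._state
        q = qm_source_charges(density, p.integrals, p.geometry, p.core_charges)
        E_perm = permanent_field(sites, q, p.geometry.coords)
        mu_pol = self.mu[self._state.pol_index]
        e_pol = self._half_muAmu - float(np.sum(mu_pol * E_perm))
        if p.mode == "ppp":
            phi = p.phi_perm_at_atoms + self._phi_ind
            e_fixed = float(np.sum(q * p.phi_perm_at_atoms))
            v = np.diag(-phi[p.integrals.basis_centers])
        else:
            phi_mono = _charge_only_potential(sites, p.geometry.coords)
            phi_hi = (p.phi_perm_at_atoms - phi_mono) + self._phi_ind
            e_fixed = float(np.sum(density.total * p._v_mono)) \
                + float(np.sum(p.core_charges * phi_mono)) \
                + float(np.sum(q * (p.phi_perm_at_atoms - phi_mono)))
            v_hi = np.zeros((n, n))
            for a in range(p.geometry.n_atoms):
                sel = np.flatnonzero(p.integrals.basis_centers == a)
                if len(sel) == 0:
                    continue
                Pa = np.zeros((n, n))
                Pa[sel, sel] = 1.0
                v_hi += (-phi_hi[a]) * (p._sh @ Pa @ p._sh)
            v = p._v_mono + v_hi
        return v, e_fixed, e_pol, self._state


def _charge_only_potential(sites: EmbeddingSites, points: np.ndarray) -> np.ndarray:
    rvec, r = _pairwise(np.atleast_2d(points), sites.positions)
    return (sites.charge[None, :] / r).sum(axis=1)


def embedding_operator(sites: EmbeddingSites, state: PolarizationState,
                       integrals: IntegralSet, geometry: Geometry,
                       core_charges: np.ndarray, density: SpinDensityPair,
                       mode: str = "ppp"):
    """One-shot operator build for a *given* converged polarization state.

    Raises if the polarization state is stale with respect to the density
    (hash mismatch).  Returns (v_embed, e_fixed).
    """
    h = density_hash(density)
    if state.density_hash is not None and state.density_hash != h:
        raise ValueError("stale polarization state: density hash mismatch")
    ctx = EmbeddingContext(sites, integrals, geometry, core_charges, mode=mode)
    v, e_fixed, _, _ = ctx.build(density)
    return v, e_fixed


def density_hash(density: SpinDensityPair) -> int:
    return hash((density.d_alpha.tobytes(), density.d_beta.tobytes()))
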