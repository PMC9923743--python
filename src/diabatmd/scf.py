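"""Restricted and unrestricted ground-state SCF with DIIS.

This is the shared engine: the excited-state (ΔSCF) solver reuses the same
Fock build, DIIS machinery and convergence bookkeeping, swapping only the
rule that selects occupied orbitals each cycle.  When an embedding context
is supplied, the induced dipoles of the environment are re-converged inside
every Fock build (warm-started), so the converged state is stationary with
respect to the fully coupled QM + polarization energy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .hamiltonian import IntegralSet

log = logging.getLogger("diabatmd")


@dataclass
class SCFConfig:
    tol_commutator: float = 1e-8
    tol_energy: float = 1e-10
    max_cycles: int = 200
    diis_depth: int = 8
    guess_mix_angle: float = 0.0  # radians of alpha HOMO/LUMO mixing
    damping: float = 0.0  # fraction of the old density kept (disables DIIS)
    retry_damping: float = 0.7  # fallback damping when plain DIIS stalls (0: off)

    def replace(self, **kw) -> "SCFConfig":
        from dataclasses import replace

        return replace(self, **kw)


@dataclass
class SpinDensityPair:
    """α and β one-particle density matrices (AO or orthonormal basis)."""

    d_alpha: np.ndarray
    d_beta: np.ndarray
    basis: str = "AO"  # {AO, orthonormal}

    def validate(self, overlap: np.ndarray | None = None,
                 n_alpha: int | None = None, n_beta: int | None = None) -> None:
        for d in (self.d_alpha, self.d_beta):
            if not np.allclose(d, d.T, atol=1e-12):
                raise ValueError("density not symmetric")
        if n_alpha is not None:
            s = overlap if (overlap is not None and self.basis == "AO") else np.eye(
                self.d_alpha.shape[0])
            for d, ne in ((self.d_alpha, n_alpha), (self.d_beta, n_beta)):
                if abs(np.trace(d @ s) - ne) > 1e-10:
                    raise ValueError("density trace inconsistent with electron count")

    @property
    def total(self) -> np.ndarray:
        return self.d_alpha + self.d_beta

    def copy(self) -> "SpinDensityPair":
        return SpinDensityPair(self.d_alpha.copy(), self.d_beta.copy(), self.basis)


@dataclass
class OrbitalSet:
    c_alpha: np.ndarray
    c_beta: np.ndarray
    eps_alpha: np.ndarray
    eps_beta: np.ndarray
    occ_alpha: np.ndarray  # occupied orbital indices
    occ_beta: np.ndarray

    def density(self) -> SpinDensityPair:
        ca = self.c_alpha[:, self.occ_alpha]
        cb = self.c_beta[:, self.occ_beta]
        return SpinDensityPair(ca @ ca.T, cb @ cb.T, basis="AO")

    def occupied(self, spin: str) -> np.ndarray:
        if spin == "alpha":
            return self.c_alpha[:, self.occ_alpha]
        return self.c_beta[:, self.occ_beta]


@dataclass
class SCFResult:
    energy: float  # total (QM + embedding) energy, hartree
    orbitals: OrbitalSet
    density: SpinDensityPair
    converged: bool
    n_iterations: int
    commutator_norm: float
    energy_qm: float = 0.0
    energy_fixed_elec: float = 0.0
    energy_pol: float = 0.0
    collapsed: bool = False
    excitation_energy: float | None = None
    pol_state: object = None


def lowdin_transform(overlap: np.ndarray) -> np.ndarray:
    """Symmetric orthonormalization X = S^(-1/2); error on near-linear dependence."""
    w, v = np.linalg.eigh(overlap)
    if w.min() < 1e-10:
        raise ValueError(f"overlap near-linear-dependence (min eigenvalue {w.min():.3e})")
    return v @ np.diag(w ** -0.5) @ v.T


def build_fock(density: SpinDensityPair, integrals: IntegralSet,
               v_embed: np.ndarray | float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """UHF Fock pair F_σ = h + J[D] - K[D_σ] + v_embed (chemists' eri)."""
    n = integrals.n_basis
    if density.d_alpha.shape != (n, n):
        raise ValueError("density/integral dimension mismatch")
    dt = density.total
    J = np.einsum("pqrs,rs->pq", integrals.eri, dt, optimize=True)
    Ka = np.einsum("prqs,rs->pq", integrals.eri, density.d_alpha, optimize=True)
    Kb = np.einsum("prqs,rs->pq", integrals.eri, density.d_beta, optimize=True)
    h = integrals.hcore + v_embed
    return h + J - Ka, h + J - Kb


def qm_energy(density: SpinDensityPair, integrals: IntegralSet) -> float:
    """Energy of the determinant (no embedding): Tr[Dh] + 2e terms + E_nuc."""
    fa, fb = build_fock(density, integrals, 0.0)
    h = integrals.hcore
    e = 0.5 * (np.sum(density.d_alpha * (h + fa)) + np.sum(density.d_beta * (h + fb)))
    return e + integrals.nuclear_repulsion


def diis_extrapolate(fock_history: list, error_history: list):
    """Pulay DIIS over stacked (F_alpha, F_beta) pairs.

    Coefficients sum to 1; a singular B-matrix degrades to the latest Fock.
    """
    m = len(fock_history)
    if m == 1:
        return fock_history[-1]
    B = np.empty((m + 1, m + 1))
    B[-1, :] = B[:, -1] = -1.0
    B[-1, -1] = 0.0
    for i in range(m):
        for j in range(m):
            B[i, j] = np.sum(error_history[i] * error_history[j])
    rhs = np.zeros(m + 1)
    rhs[-1] = -1.0
    try:
        c = np.linalg.solve(B, rhs)[:m]
    except np.linalg.LinAlgError:
        return fock_history[-1]
    if not np.all(np.isfinite(c)):
        return fock_history[-1]
    fa = sum(ci * f[0] for ci, f in zip(c, fock_history))
    fb = sum(ci * f[1] for ci, f in zip(c, fock_history))
    return fa, fb


def core_guess(integrals: IntegralSet, n_alpha: int, n_beta: int,
               mix_angle: float = 0.0) -> SpinDensityPair:
    """Deterministic guess from diagonalized hcore, with optional α
    HOMO/LUMO mixing to allow spin-symmetry breaking."""
    X = lowdin_transform(integrals.overlap)
    f = X.T @ integrals.hcore @ X
    _, c = np.linalg.eigh(f)
    c = X @ c
    ca = c.copy()
    if mix_angle != 0.0 and n_alpha < integrals.n_basis:
        h, l = n_alpha - 1, n_alpha
        th = mix_angle
        ch, cl = ca[:, h].copy(), ca[:, l].copy()
        ca[:, h] = np.cos(th) * ch + np.sin(th) * cl
        ca[:, l] = -np.sin(th) * ch + np.cos(th) * cl
    da = ca[:, :n_alpha] @ ca[:, :n_alpha].T
    db = c[:, :n_beta] @ c[:, :n_beta].T
    return SpinDensityPair(da, db, basis="AO")


def _diag_fock(f: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    eps, c = np.linalg.eigh(X.T @ f @ X)
    return eps, X @ c


def _resolve_guess(guess, integrals, n_alpha, n_beta, mode, cfg, X):
    if isinstance(guess, str):
        if guess != "core":
            raise ValueError(f"unknown guess {guess!r}")
        return core_guess(integrals, n_alpha, n_beta,
                          0.0 if mode == "restricted" else cfg.guess_mix_angle)
    density = guess.copy()
    if density.basis != "AO":
        # orthonormal-basis density pairs come from the extrapolator
        Xi = np.linalg.inv(X)
        density = SpinDensityPair(Xi.T @ density.d_alpha @ Xi,
                                  Xi.T @ density.d_beta @ Xi, basis="AO")
    return density


def _scf_loop(integrals, n_alpha, n_beta, density, mode, embedding_context,
              cfg, occupation_selector, fock_transform) -> SCFResult:
    """One SCF attempt: DIIS (or damped fixed-point) iteration to the
    stationary density; the Fock used for diagonalization may be modified
    by `fock_transform` (STEP level shifting)."""
    X = lowdin_transform(integrals.overlap)
    S = integrals.overlap
    fock_hist: list = []
    err_hist: list = []
    e_old = None
    energy = comm = np.inf
    e_qm = e_fixed = e_pol = 0.0
    pol_state = None
    orbitals = None
    converged = False
    it = 0
    for it in range(1, cfg.max_cycles + 1):
        if embedding_context is not None:
            v_embed, e_fixed, e_pol, pol_state = embedding_context.build(density)
        else:
            v_embed = 0.0
        fa, fb = build_fock(density, integrals, v_embed)
        # energy of the current density
        h = integrals.hcore
        ga, gb = fa - h - (v_embed if embedding_context is not None else 0.0), \
            fb - h - (v_embed if embedding_context is not None else 0.0)
        e_qm = 0.5 * (np.sum(density.d_alpha * (2 * h + ga))
                      + np.sum(density.d_beta * (2 * h + gb))) + integrals.nuclear_repulsion
        energy = e_qm + e_fixed + e_pol

        ea = X.T @ (fa @ density.d_alpha @ S - S @ density.d_alpha @ fa) @ X
        eb = X.T @ (fb @ density.d_beta @ S - S @ density.d_beta @ fb) @ X
        comm = max(np.abs(ea).max(), np.abs(eb).max())
        log.debug("scf cycle=%d energy=%.12f comm=%.3e", it, energy, comm)
        de = np.inf if e_old is None else abs(energy - e_old)
        if comm < cfg.tol_commutator and de < cfg.tol_energy:
            converged = True
        e_old = energy

        if it >= 2 and cfg.damping == 0.0:
            fock_hist.append((fa, fb))
            err_hist.append(np.concatenate([ea.ravel(), eb.ravel()]))
            if len(fock_hist) > cfg.diis_depth:
                fock_hist.pop(0)
                err_hist.pop(0)
            fa, fb = diis_extrapolate(fock_hist, err_hist)

        if fock_transform is not None:
            fa_d, fb_d = fock_transform(fa, fb)
        else:
            fa_d, fb_d = fa, fb
        eps_a, ca = _diag_fock(fa_d, X)
        if mode == "restricted":
            eps_b, cb = eps_a, ca
        else:
            eps_b, cb = _diag_fock(fb_d, X)
        if occupation_selector is None:
            occ_a = np.arange(n_alpha)
            occ_b = np.arange(n_beta)
        else:
            occ_a, occ_b = occupation_selector(eps_a, ca, eps_b, cb, it)
        orbitals = OrbitalSet(ca, cb, eps_a, eps_b, np.asarray(occ_a), np.asarray(occ_b))
        new_density = orbitals.density()
        if mode == "restricted":
            new_density = SpinDensityPair(new_density.d_alpha, new_density.d_alpha.copy())
        if converged:
            break
        if cfg.damping > 0.0:
            new_density = SpinDensityPair(
                cfg.damping * density.d_alpha + (1 - cfg.damping) * new_density.d_alpha,
                cfg.damping * density.d_beta + (1 - cfg.damping) * new_density.d_beta)
        density = new_density

    if orbitals is None:
        raise ValueError("scf ran zero cycles")
    return SCFResult(energy=energy, orbitals=orbitals, density=density,
                     converged=converged, n_iterations=it, commutator_norm=comm,
                     energy_qm=e_qm, energy_fixed_elec=e_fixed, energy_pol=e_pol,
                     pol_state=pol_state)


def scf_solve(integrals: IntegralSet, n_alpha: int, n_beta: int,
              guess: SpinDensityPair | str = "core",
              mode: str = "unrestricted",
              embedding_context=None,
              config: SCFConfig | None = None,
              occupation_selector=None,
              fock_transform=None) -> SCFResult:
    """Solve the (embedded) SCF equations.

    `occupation_selector(eps_a, c_a, eps_b, c_b, cycle) -> (occ_a, occ_b)`
    overrides Aufbau occupation (iMOM); `fock_transform(fa, fb)` modifies the
    Fock before diagonalization (STEP level shifting).  In restricted mode
    the β density mirrors α exactly.

    Convergence strategy: plain DIIS, then a heavily damped fixed-point pass,
    then — with an embedding — macro-iterations that alternate SCF at frozen
    induced dipoles with dipole updates (robust when the simultaneous
    density/dipole iteration limit-cycles).  A result that still fails is
    returned flagged, never silently.
    """
    cfg = config or SCFConfig()
    if mode == "restricted" and n_alpha != n_beta:
        raise ValueError("restricted mode requires n_alpha == n_beta")
    X = lowdin_transform(integrals.overlap)
    density = _resolve_guess(guess, integrals, n_alpha, n_beta, mode, cfg, X)

    result = _scf_loop(integrals, n_alpha, n_beta, density, mode,
                       embedding_context, cfg, occupation_selector, fock_transform)
    if result.converged or cfg.damping > 0.0:
        return result
    total_it = result.n_iterations

    if cfg.retry_damping > 0.0:
        log.info("SCF stalled (comm=%.3e); retrying damped", result.commutator_norm)
        retry_cfg = cfg.replace(damping=cfg.retry_damping,
                                max_cycles=max(cfg.max_cycles, 500))
        result = _scf_loop(integrals, n_alpha, n_beta, result.density, mode,
                           embedding_context, retry_cfg, occupation_selector,
                           fock_transform)
        result.n_iterations += total_it
        if result.converged:
            return result
        total_it = result.n_iterations

    if embedding_context is not None and hasattr(embedding_context, "frozen"):
        log.info("SCF still stalled; macro-iterating polarization")
        result = _macro_polarization_solve(integrals, n_alpha, n_beta,
                                           result.density, mode, embedding_context,
                                           cfg, occupation_selector, fock_transform)
        result.n_iterations += total_it
    if not result.converged:
        log.warning("SCF not converged after %d cycles (comm=%.3e)",
                    result.n_iterations, result.commutator_norm)
    return result


def _macro_polarization_solve(integrals, n_alpha, n_beta, density, mode,
                              context, cfg, occupation_selector,
                              fock_transform, max_macro: int = 60,
                              mu_tol: float = 1e-9) -> SCFResult:
    """Alternate SCF at frozen induced dipoles with damped dipole updates."""
    mu = context.update_dipoles(density).induced_dipoles
    result = None
    for macro in range(max_macro):
        frozen = context.frozen(mu)
        inner_cfg = cfg.replace(retry_damping=0.0)
        result = _scf_loop(integrals, n_alpha, n_beta, density, mode, frozen,
                           inner_cfg, occupation_selector, fock_transform)
        if not result.converged:
            damped_cfg = inner_cfg.replace(damping=0.7,
                                           max_cycles=max(cfg.max_cycles, 500))
            result = _scf_loop(integrals, n_alpha, n_beta, result.density, mode,
                               frozen, damped_cfg, occupation_selector,
                               fock_transform)
        density = result.density
        mu_new = context.update_dipoles(density).induced_dipoles
        delta = np.abs(mu_new - mu).max() if mu_new.size else 0.0
        if result.converged and delta < mu_tol:
            # report fully coupled energies at the joint fixed point
            final = _scf_loop(integrals, n_alpha, n_beta, density, mode, context,
                              cfg.replace(max_cycles=2, retry_damping=0.0),
                              occupation_selector, fock_transform)
            final.n_iterations += (macro + 1) * 2
            if final.converged:
                return final
            result = final
            break
        mu = 0.5 * (mu + mu_new)
    result.converged = False
    return result


def dipole_moment(density: SpinDensityPair, integrals: IntegralSet,
                  geometry, core_charges: np.ndarray) -> np.ndarray:
    """Dipole expectation: Σ Z_a R_a - Tr[D r]."""
    mu_el = np.array([np.sum(density.total * integrals.dipole_ops[k]) for k in range(3)])
    nuc = (np.asarray(core_charges)[:, None] * geometry.coords).sum(axis=0)
    return nuc - mu_el


def s_squared(orbitals: OrbitalSet, overlap: np.ndarray) -> float:
    """<S²> of the UHF determinant."""
    ca = orbitals.occupied("alpha")
    cb = orbitals.occupied("beta")
    na, nb = ca.shape[1], cb.shape[1]
    sz = 0.5 * (na - nb)
    ov = ca.T @ overlap @ cb
    return sz * (sz + 1) + nb - float(np.sum(ov ** 2))
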