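"""Grassmann-manifold density-matrix extrapolation for SCF guesses.

Idempotent one-particle density matrices of fixed trace live on a
Grassmann manifold.  Mapping each history density to the tangent space at
a fixed reference (the log map), extrapolating linearly there with
coefficients fitted on a Coulomb-matrix geometry descriptor, and mapping
back (the exp map) yields a guess that is idempotent with exact integer
trace by construction — no purification needed.  Open shells are handled
by extrapolating the α and β densities independently with one shared
coefficient set (a single molecular descriptor).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .chem_io import Geometry

log = logging.getLogger("diabatmd")


def _occupied_orbitals(density: np.ndarray, n_occ: int) -> np.ndarray:
    """Orthonormal occupied orbitals of an (almost) idempotent density."""
    w, v = np.linalg.eigh(density)
    if np.max(np.abs(density @ density - density)) > 1e-8:
        raise ValueError("density not idempotent (orthonormal basis expected)")
    order = np.argsort(-w)
    return v[:, order[:n_occ]]


def grassmann_log(density: np.ndarray, c0: np.ndarray) -> np.ndarray:
    """Map an idempotent orthonormal-basis density to the tangent space at
    span(c0): Γ = U arctan(Σ) Vᵀ from the thin SVD of
    L = (I - C0 C0ᵀ) C (C0ᵀ C)⁻¹."""
    n_occ = c0.shape[1]
    c = _occupied_orbitals(density, n_occ)
    ov = c0.T @ c
    if abs(np.linalg.det(ov)) < 1e-12:
        raise ValueError("reference too far: occupied space orthogonal to C0")
    L = (c - c0 @ ov) @ np.linalg.inv(ov)
    u, s, vt = np.linalg.svd(L, full_matrices=False)
    return u @ np.diag(np.arctan(s)) @ vt


def grassmann_exp(gamma: np.ndarray, c0: np.ndarray) -> np.ndarray:
    """Map a horizontal tangent matrix back to an idempotent density with
    trace equal to c0's column count: D = C Cᵀ with
    C = (C0 V cosΣ + U sinΣ) Vᵀ."""
    if np.max(np.abs(c0.T @ gamma)) > 1e-8:
        raise ValueError("tangent matrix violates horizontality C0ᵀΓ = 0")
    u, s, vt = np.linalg.svd(gamma, full_matrices=False)
    c = (c0 @ vt.T @ np.diag(np.cos(s)) + u @ np.diag(np.sin(s))) @ vt
    return c @ c.T


def principal_angles(gamma: np.ndarray) -> np.ndarray:
    """Principal angles between the mapped subspace and the reference:
    the singular values of Γ."""
    return np.linalg.svd(gamma, compute_uv=False)


def coulomb_descriptor(geometry: Geometry) -> np.ndarray:
    """Flattened upper triangle (diagonal included) of the Coulomb matrix
    M_IJ = Z_I Z_J / r_IJ, M_II = ½ Z_I^2.4, in a fixed atom order."""
    z = geometry.charges
    n = geometry.n_atoms
    if n < 1:
        raise ValueError("empty geometry")
    r = geometry.distance_matrix()
    if n > 1 and np.min(r[np.triu_indices(n, 1)]) < 1e-8:
        raise ValueError("coincident atoms in Coulomb descriptor")
    with np.errstate(divide="ignore"):
        m = np.where(r > 0, np.outer(z, z) / np.where(r > 0, r, 1.0), 0.0)
    np.fill_diagonal(m, 0.5 * z ** 2.4)
    return m[np.triu_indices(n)]


def fit_coefficients(history_descriptors: list[np.ndarray],
                     current_descriptor: np.ndarray,
                     ridge_lambda: float = 1e-10) -> np.ndarray:
    """Ridge-regularized least squares: c = argmin ‖d_now - Σ c_k d_k‖² + λ‖c‖²."""
    G = np.column_stack(history_descriptors)
    A = G.T @ G + ridge_lambda * np.eye(G.shape[1])
    return np.linalg.solve(A, G.T @ np.asarray(current_descriptor, float))


@dataclass
class ExtrapolationHistory:
    """Ring buffer of tangent-space densities with a fixed per-window
    reference; resets (with the latest density as new reference) when the
    newest entry drifts beyond `reset_angle_rad` from the reference."""

    capacity: int = 6
    ridge_lambda: float = 1e-10
    reset_angle_rad: float = 1.0
    c0_alpha: np.ndarray | None = None
    c0_beta: np.ndarray | None = None
    gammas_alpha: list = field(default_factory=list)
    gammas_beta: list = field(default_factory=list)
    descriptors: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.descriptors)

    def push(self, d_alpha: np.ndarray, d_beta: np.ndarray,
             geometry: Geometry) -> None:
        """Append a converged orthonormal-basis spin-density pair."""
        desc = coulomb_descriptor(geometry)
        if self.c0_alpha is None:
            self._reset(d_alpha, d_beta, desc)
            return
        try:
            ga = grassmann_log(d_alpha, self.c0_alpha)
            gb = grassmann_log(d_beta, self.c0_beta)
        except ValueError:
            log.info("grassmann history reset: reference too far")
            self._reset(d_alpha, d_beta, desc)
            return
        angle = max(principal_angles(ga).max(initial=0.0),
                    principal_angles(gb).max(initial=0.0))
        if angle > self.reset_angle_rad:
            log.info("grassmann history reset: drift angle %.3f rad", angle)
            self._reset(d_alpha, d_beta, desc)
            return
        self.gammas_alpha.append(ga)
        self.gammas_beta.append(gb)
        self.descriptors.append(desc)
        while len(self.descriptors) > self.capacity:
            self.gammas_alpha.pop(0)
            self.gammas_beta.pop(0)
            self.descriptors.pop(0)

    def _reset(self, d_alpha, d_beta, desc) -> None:
        na = int(round(np.trace(d_alpha)))
        nb = int(round(np.trace(d_beta)))
        self.c0_alpha = _occupied_orbitals(d_alpha, na)
        self.c0_beta = _occupied_orbitals(d_beta, nb) if nb > 0 else \
            np.zeros((d_beta.shape[0], 0))
        # the reference itself enters the window as a zero tangent matrix
        self.gammas_alpha = [np.zeros((d_alpha.shape[0], na))]
        self.gammas_beta = [np.zeros((d_beta.shape[0], nb))]
        self.descriptors = [desc]

    def extrapolate(self, geometry: Geometry):
        """Extrapolated SpinDensityPair (orthonormal basis) at a new
        geometry; both spins share one coefficient vector."""
        from .scf import SpinDensityPair

        if len(self) < 2:
            raise ValueError("history too short for extrapolation (need >= 2)")
        c = fit_coefficients(self.descriptors, coulomb_descriptor(geometry),
                             self.ridge_lambda)
        ga = sum(ck * g for ck, g in zip(c, self.gammas_alpha))
        gb = sum(ck * g for ck, g in zip(c, self.gammas_beta))
        da = grassmann_exp(ga, self.c0_alpha)
        db = grassmann_exp(gb, self.c0_beta) if self.c0_beta.shape[1] > 0 else \
            np.zeros_like(da)
        return SpinDensityPair(da, db, basis="orthonormal")
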