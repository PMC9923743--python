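"""Excited-state SCF (ΔSCF).

The excited state is a single non-Aufbau determinant optimized with the
same SCF machinery as the ground state.  Collapse onto the ground state is
avoided by changing how occupied orbitals are selected each cycle:

* iMOM — occupy, at every cycle, the orbitals with maximum overlap onto a
  *fixed* reference occupied space (the initial guess; along MD, the
  previous step's converged orbitals);
* STEP — Aufbau SCF on a level-shifted Fock whose complement of the
  tracked occupied space is raised, so the target state fills first.  The
  shift projector starts at the promotion guess and follows the currently
  occupied orbitals, which makes the fixed point a stationary point of the
  unshifted SCF equations.

Both converge to an excited stationary point of the same equations as the
ground state; with a polarizable embedding context the environment response
is state-specific and obtained self-consistently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .hamiltonian import IntegralSet
from .scf import OrbitalSet, SCFConfig, SCFResult, SpinDensityPair, scf_solve

log = logging.getLogger("diabatmd")

COLLAPSE_PROJECTION_TOL = 0.999
SELECTOR_WEIGHT_MIN = 0.5
SELECTOR_AMBIGUITY_MARGIN = 0.05


@dataclass
class OrbitalSelector:
    """Labeled orbital selector: the frontier orbital with > 50% Löwdin
    weight on a named atom group ('pi_donor'-style CT preparation)."""

    atom_indices: list
    label: str = ""


@dataclass
class ExcitationSpec:
    spin: str  # {alpha, beta}
    from_orbital: int | OrbitalSelector
    to_orbital: int | OrbitalSelector


@dataclass
class ReferenceOrbitals:
    """Per-spin occupied reference MO coefficients (S-orthonormal columns)."""

    c_alpha: np.ndarray  # (n, n_alpha)
    c_beta: np.ndarray  # (n, n_beta)
    provenance: str = "initial_guess"  # {initial_guess, previous_md_step}

    def validate(self, overlap: np.ndarray) -> None:
        for c in (self.c_alpha, self.c_beta):
            g = c.T @ overlap @ c
            if not np.allclose(g, np.eye(c.shape[1]), atol=1e-8):
                raise ValueError("reference orbitals not S-orthonormal")


def lowdin_orbital_weights(c: np.ndarray, overlap: np.ndarray,
                           basis_centers: np.ndarray, n_atoms: int) -> np.ndarray:
    """(n_orbitals, n_atoms) Löwdin weight of each orbital on each atom."""
    w, v = np.linalg.eigh(overlap)
    sh = v @ np.diag(np.sqrt(w)) @ v.T
    amp = (sh @ c) ** 2  # (n_basis, n_orb)
    out = np.zeros((c.shape[1], n_atoms))
    for mu, a in enumerate(basis_centers):
        out[:, a] += amp[mu, :]
    return out


def _resolve_selector(selector, orbitals: OrbitalSet, integrals: IntegralSet,
                      spin: str, occupied: bool, n_atoms: int) -> int:
    """Resolve an index or labeled selector to an orbital index."""
    occ = set((orbitals.occ_alpha if spin == "alpha" else orbitals.occ_beta).tolist())
    if isinstance(selector, (int, np.integer)):
        idx = int(selector)
        if occupied and idx not in occ:
            raise ValueError(f"from_orbital {idx} is not occupied")
        if not occupied and idx in occ:
            raise ValueError(f"to_orbital {idx} is not virtual")
        return idx
    c = orbitals.c_alpha if spin == "alpha" else orbitals.c_beta
    eps = orbitals.eps_alpha if spin == "alpha" else orbitals.eps_beta
    weights = lowdin_orbital_weights(c, integrals.overlap, integrals.basis_centers,
                                     n_atoms)
    group_w = weights[:, list(selector.atom_indices)].sum(axis=1)
    pool = [i for i in range(c.shape[1])
            if (i in occ) == occupied and group_w[i] > SELECTOR_WEIGHT_MIN]
    if not pool:
        raise ValueError(
            f"selector {selector.label or selector.atom_indices} matches no "
            f"{'occupied' if occupied else 'virtual'} orbital (> 50% group weight)")
    # frontier choice: highest occupied / lowest virtual among candidates
    pick = max(pool, key=lambda i: eps[i]) if occupied else min(pool, key=lambda i: eps[i])
    for other in pool:
        if other != pick and abs(eps[other] - eps[pick]) < 1e-6 \
                and abs(group_w[other] - group_w[pick]) < SELECTOR_AMBIGUITY_MARGIN:
            raise ValueError(
                f"selector {selector.label or selector.atom_indices} is ambiguous: "
                f"orbitals {pick} and {other} are degenerate with similar weights")
    return pick


def promote_electron(orbitals: OrbitalSet, spec: ExcitationSpec,
                     integrals: IntegralSet, n_atoms: int | None = None
                     ) -> tuple[SpinDensityPair, ReferenceOrbitals]:
    """Build the non-Aufbau guess by moving one electron from an occupied to
    a virtual MO of the given spin; the new occupied set becomes the
    reference."""
    if n_atoms is None:
        n_atoms = int(integrals.basis_centers.max()) + 1
    i_from = _resolve_selector(spec.from_orbital, orbitals, integrals, spec.spin,
                               occupied=True, n_atoms=n_atoms)
    i_to = _resolve_selector(spec.to_orbital, orbitals, integrals, spec.spin,
                             occupied=False, n_atoms=n_atoms)
    if i_from == i_to:
        raise ValueError("excitation moves an electron within the same orbital")
    occ_a = orbitals.occ_alpha.tolist()
    occ_b = orbitals.occ_beta.tolist()
    occ = occ_a if spec.spin == "alpha" else occ_b
    occ.remove(i_from)
    occ.append(i_to)
    occ.sort()
    new = OrbitalSet(orbitals.c_alpha, orbitals.c_beta, orbitals.eps_alpha,
                     orbitals.eps_beta, np.array(occ_a, int), np.array(occ_b, int))
    density = new.density()
    reference = ReferenceOrbitals(new.occupied("alpha"), new.occupied("beta"))
    return density, reference


def imom_select_occupations(c_new_alpha: np.ndarray, c_new_beta: np.ndarray,
                            reference: ReferenceOrbitals, overlap: np.ndarray,
                            eps_alpha: np.ndarray | None = None,
                            eps_beta: np.ndarray | None = None
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Select, per spin, the orbitals with maximal projection onto the
    reference occupied space: p_j = ||C_refᵀ S c_j||₂.

    Ties within 1e-8 are broken toward lower orbital energy and logged.
    """
    out = []
    for c_new, c_ref, eps in ((c_new_alpha, reference.c_alpha, eps_alpha),
                              (c_new_beta, reference.c_beta, eps_beta)):
        n_occ = c_ref.shape[1]
        proj = np.linalg.norm(c_ref.T @ overlap @ c_new, axis=0)
        order = np.argsort(-proj, kind="stable")
        chosen = list(order[:n_occ])
        if n_occ < len(proj):
            last_in = proj[order[n_occ - 1]]
            first_out = proj[order[n_occ]]
            if abs(last_in - first_out) < 1e-8 and eps is not None:
                cand = [j for j in range(len(proj)) if abs(proj[j] - last_in) < 1e-8]
                keep = [j for j in chosen if abs(proj[j] - last_in) >= 1e-8]
                cand.sort(key=lambda j: eps[j])
                chosen = keep + cand[: n_occ - len(keep)]
                log.info("iMOM projection tie broken by orbital energy")
        out.append(np.sort(np.array(chosen, int)))
    return out[0], out[1]


def step_shift_fock(fock: np.ndarray, c_ref_occ: np.ndarray, overlap: np.ndarray,
                    shift: float) -> np.ndarray:
    """STEP level shift: F' = F + shift (S - S C_ref C_refᵀ S); the
    complement of the reference occupied space is raised by `shift` so
    Aufbau filling of F' occupies the tracked state."""
    if shift < 0:
        raise ValueError("shift must be >= 0")
    proj = overlap @ c_ref_occ @ c_ref_occ.T @ overlap
    return fock + shift * (overlap - proj)


def auto_step_shift(fock: np.ndarray, c_ref_occ: np.ndarray,
                    margin: float = 1.0) -> float:
    """Shift that guarantees the reference space lowest after shifting:
    (max reference-occupied level - min level) + margin."""
    eps_ref = np.diag(c_ref_occ.T @ fock @ c_ref_occ)
    eps_min = np.linalg.eigvalsh(fock).min()  # lower bound on any level
    return max(0.0, float(eps_ref.max() - eps_min)) + margin


def collapse_projections(orbitals: OrbitalSet, ground: OrbitalSet,
                         overlap: np.ndarray) -> dict:
    """Per-spin projections of the converged occupied orbitals onto the
    ground-state occupied space."""
    out = {}
    for spin in ("alpha", "beta"):
        c = orbitals.occupied(spin)
        g = ground.occupied(spin)
        out[spin] = np.linalg.norm(g.T @ overlap @ c, axis=0)
    return out


def is_collapsed(orbitals: OrbitalSet, ground: OrbitalSet, overlap: np.ndarray,
                 tol: float = COLLAPSE_PROJECTION_TOL) -> bool:
    proj = collapse_projections(orbitals, ground, overlap)
    return all(np.all(p > tol) for p in proj.values())


def deltascf_solve(integrals: IntegralSet, spec: ExcitationSpec | None,
                   ground: SCFResult, method: str = "imom",
                   embedding_context=None,
                   reference_override: ReferenceOrbitals | None = None,
                   guess_density: SpinDensityPair | None = None,
                   config: SCFConfig | None = None,
                   step_margin: float = 1.0,
                   ground_reference: OrbitalSet | None = None) -> SCFResult:
    """Converge the excited determinant and return it with its excitation
    energy E_ES - E_GS.

    Along MD, pass `reference_override` (previous step's converged occupied
    MOs) and a `guess_density` (extrapolated); `ground_reference` supplies
    the occupied space used by the collapse detector (defaults to
    `ground.orbitals`).
    """
    if method not in ("imom", "step"):
        raise ValueError(f"unknown deltascf method {method!r}")
    S = integrals.overlap
    n_atoms = int(integrals.basis_centers.max()) + 1
    if reference_override is not None:
        reference = reference_override
        if guess_density is None:
            raise ValueError("reference_override requires a guess density")
        density0 = guess_density
    else:
        if not ground.converged:
            raise ValueError("ground state not converged")
        density0, reference = promote_electron(ground.orbitals, spec, integrals,
                                               n_atoms)
    reference.validate(S)
    n_alpha = reference.c_alpha.shape[1]
    n_beta = reference.c_beta.shape[1]

    state = {"ref_a": reference.c_alpha, "ref_b": reference.c_beta}

    def selector(eps_a, ca, eps_b, cb, cycle):
        occ_a, occ_b = imom_select_occupations(ca, cb, ReferenceOrbitals(
            state["ref_a"], state["ref_b"]), S, eps_a, eps_b)
        return occ_a, occ_b

    if method == "imom":
        result = scf_solve(integrals, n_alpha, n_beta, guess=density0,
                           mode="unrestricted", embedding_context=embedding_context,
                           config=config, occupation_selector=selector)
    else:
        result = _step_solve(integrals, n_alpha, n_beta, density0, reference,
                             embedding_context, config, step_margin)

    gref = ground_reference
    if gref is None and ground is not None and hasattr(ground, "orbitals"):
        gref = ground.orbitals
    if gref is not None:
        result.collapsed = is_collapsed(result.orbitals, gref, S)
        if result.collapsed:
            log.warning("deltaSCF solution collapsed onto the ground-state determinant")
    if ground is not None and hasattr(ground, "energy"):
        result.excitation_energy = result.energy - ground.energy
    return result


def _step_solve(integrals, n_alpha, n_beta, density0, reference,
                embedding_context, config, step_margin) -> SCFResult:
    """STEP: Aufbau SCF on the level-shifted Fock with the *fixed* initial
    reference projector, which locks the iterations onto the target state
    (the excited determinant is a saddle of the SCF functional, so a
    tracked/annealed projector would slide off it), followed by a
    maximum-overlap refinement stage that converges the unshifted SCF
    equations to stationarity from the STEP solution."""
    S = integrals.overlap
    cfg = config or SCFConfig()

    def transform(fa, fb):
        out = []
        for c_ref, f in ((reference.c_alpha, fa), (reference.c_beta, fb)):
            shift = auto_step_shift(f, c_ref, margin=step_margin)
            out.append(step_shift_fock(f, c_ref, S, shift))
        return out[0], out[1]

    # stage 1: damped shifted-Aufbau iterations toward the target subspace
    stage1_cfg = cfg.replace(damping=0.3, max_cycles=60, retry_damping=0.0)
    stage1 = scf_solve(integrals, n_alpha, n_beta, guess=density0,
                       mode="unrestricted", embedding_context=embedding_context,
                       config=stage1_cfg, fock_transform=transform)

    # stage 2: converge the unshifted equations, holding the state by maximum
    # overlap with the stage-1 occupied space
    ref2 = ReferenceOrbitals(stage1.orbitals.occupied("alpha"),
                             stage1.orbitals.occupied("beta"))

    def selector(eps_a, ca, eps_b, cb, cycle):
        return imom_select_occupations(ca, cb, ref2, S, eps_a, eps_b)

    result = scf_solve(integrals, n_alpha, n_beta, guess=stage1.density,
                       mode="unrestricted", embedding_context=embedding_context,
                       config=cfg, occupation_selector=selector)
    result.n_iterations += stage1.n_iterations
    return result


def track_state(previous: SCFResult, history=None,
                current_geometry=None) -> tuple[ReferenceOrbitals, SpinDensityPair]:
    """Reference orbitals and guess density for the next MD step.

    Reference = the previous step's converged occupied MOs; the guess is the
    Grassmann extrapolation when the history holds >= 2 entries, otherwise
    the previous converged density.  A collapsed previous step halts the
    trajectory (the MD driver treats the raised error as a halt signal).
    """
    if not previous.converged:
        raise RuntimeError("previous electronic step not converged: halting")
    if previous.collapsed:
        raise RuntimeError("previous deltaSCF step collapsed: halting trajectory")
    reference = ReferenceOrbitals(previous.orbitals.occupied("alpha"),
                                  previous.orbitals.occupied("beta"),
                                  provenance="previous_md_step")
    guess = previous.density.copy()
    if history is not None and len(history) >= 2 and current_geometry is not None:
        guess = history.extrapolate(current_geometry)
    return reference, guess
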