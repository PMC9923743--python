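"""Electronic-structure backends sharing one integral contract.

Two providers are implemented:

* an ab initio provider restricted to contracted s-type Gaussians, with
  closed-form overlap/kinetic/attraction/repulsion integrals (Boys F0);
* a Pariser–Parr–Pople (PPP) π-electron model with distance-dependent
  hopping and Ohno-interpolated two-center repulsion, which provides the
  donor–bridge–acceptor systems with well separated locally-excited and
  charge-transfer states and analytic geometry derivatives for MD.

A dense full-CI routine over the same integrals serves as the exact
reference throughout the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.special import erf

from .chem_io import Geometry

# ---------------------------------------------------------------------------
# Integral contract


@dataclass
class IntegralSet:
    """One-geometry integrals in a common AO contract.

    eri is stored as the full n^4 tensor in chemists' notation (ij|kl).
    dipole_ops are matrix elements of the position operator; the electronic
    dipole is -Tr[D r].
    """

    overlap: np.ndarray
    hcore: np.ndarray
    eri: np.ndarray
    dipole_ops: np.ndarray  # (3, n, n)
    nuclear_repulsion: float
    basis_centers: np.ndarray  # atom index per basis function

    @property
    def n_basis(self) -> int:
        return self.overlap.shape[0]

    def validate(self) -> None:
        s = self.overlap
        if not np.allclose(s, s.T, atol=1e-12):
            raise ValueError("overlap not symmetric")
        if np.linalg.eigvalsh(s).min() <= 1e-10:
            raise ValueError("overlap not positive definite")
        e = self.eri
        for perm in (e.transpose(1, 0, 2, 3), e.transpose(0, 1, 3, 2), e.transpose(2, 3, 0, 1)):
            if not np.allclose(e, perm, atol=1e-12):
                raise ValueError("eri lacks 8-fold symmetry")


# ---------------------------------------------------------------------------
# s-type Gaussian provider


def _boys_f0(t: np.ndarray) -> np.ndarray:
    """F0(t) = (1/2) sqrt(pi/t) erf(sqrt(t)), with the t→0 limit handled."""
    t = np.asarray(t, dtype=float)
    out = np.ones_like(t)
    small = t < 1e-12
    ts = np.where(small, 1.0, t)
    out = np.where(small, 1.0 - t / 3.0, 0.5 * np.sqrt(np.pi / ts) * erf(np.sqrt(ts)))
    return out


@dataclass
class _Shell:
    atom: int
    center: np.ndarray
    exps: np.ndarray
    coefs: np.ndarray  # contraction coefficients on normalized primitives


def _prim_norm(a: float) -> float:
    return (2.0 * a / np.pi) ** 0.75


def _build_shells(geometry: Geometry, basis_spec: dict) -> list[_Shell]:
    shells = []
    for ia, sym in enumerate(geometry.symbols):
        if sym not in basis_spec:
            raise ValueError(f"no basis entry for element {sym!r}")
        for contraction in basis_spec[sym]:
            exps = np.array([p[0] for p in contraction], float)
            coefs = np.array([p[1] for p in contraction], float)
            shells.append(_Shell(ia, geometry.coords[ia], exps, coefs))
    # normalize each contraction so <g|g> = 1
    for sh in shells:
        norm = 0.0
        for ai, ci in zip(sh.exps, sh.coefs):
            for aj, cj in zip(sh.exps, sh.coefs):
                sij = (np.pi / (ai + aj)) ** 1.5 * _prim_norm(ai) * _prim_norm(aj)
                norm += ci * cj * sij
        sh.coefs = sh.coefs / np.sqrt(norm)
    return shells


def gaussian_integrals(geometry: Geometry, basis_spec: dict) -> IntegralSet:
    """Closed-form integrals for contracted s-type Gaussian bases.

    basis_spec maps element symbol -> list of contractions, each a list of
    (exponent, coefficient) pairs on normalized primitives.
    """
    shells = _build_shells(geometry, basis_spec)
    n = len(shells)
    S = np.zeros((n, n))
    T = np.zeros((n, n))
    V = np.zeros((n, n))
    R = np.zeros((3, n, n))
    for i, si in enumerate(shells):
        for j, sj in enumerate(shells):
            if j < i:
                continue
            AB2 = float(np.dot(si.center - sj.center, si.center - sj.center))
            s = t = v = 0.0
            r = np.zeros(3)
            for a, ca in zip(si.exps, si.coefs):
                na = _prim_norm(a)
                for b, cb in zip(sj.exps, sj.coefs):
                    nb = _prim_norm(b)
                    p = a + b
                    mu = a * b / p
                    pref = ca * cb * na * nb
                    s_ab = (np.pi / p) ** 1.5 * np.exp(-mu * AB2)
                    P = (a * si.center + b * sj.center) / p
                    s += pref * s_ab
                    t += pref * mu * (3.0 - 2.0 * mu * AB2) * s_ab
                    r += pref * s_ab * P
                    for Zc, C in zip(geometry.charges, geometry.coords):
                        PC2 = float(np.dot(P - C, P - C))
                        v -= pref * Zc * (2.0 * np.pi / p) * np.exp(-mu * AB2) * \
                            float(_boys_f0(p * PC2))
            S[i, j] = S[j, i] = s
            T[i, j] = T[j, i] = t
            V[i, j] = V[j, i] = v
            R[:, i, j] = R[:, j, i] = r
    eri = np.zeros((n, n, n, n))
    for i, si in enumerate(shells):
        for j, sj in enumerate(shells):
            if j > i:
                continue
            AB2 = float(np.dot(si.center - sj.center, si.center - sj.center))
            for k, sk in enumerate(shells):
                for l, sl in enumerate(shells):
                    if l > k or (k, l) > (i, j):
                        continue
                    CD2 = float(np.dot(sk.center - sl.center, sk.center - sl.center))
                    val = 0.0
                    for a, ca in zip(si.exps, si.coefs):
                        for b, cb in zip(sj.exps, sj.coefs):
                            p = a + b
                            P = (a * si.center + b * sj.center) / p
                            eab = np.exp(-a * b / p * AB2)
                            for c, cc in zip(sk.exps, sk.coefs):
                                for d, cd in zip(sl.exps, sl.coefs):
                                    q = c + d
                                    Q = (c * sk.center + d * sl.center) / q
                                    ecd = np.exp(-c * d / q * CD2)
                                    PQ2 = float(np.dot(P - Q, P - Q))
                                    pref = (ca * cb * cc * cd * _prim_norm(a) * _prim_norm(b)
                                            * _prim_norm(c) * _prim_norm(d))
                                    val += pref * 2.0 * np.pi ** 2.5 / (
                                        p * q * np.sqrt(p + q)) * eab * ecd * \
                                        float(_boys_f0(p * q / (p + q) * PQ2))
                    for (ii, jj) in ((i, j), (j, i)):
                        for (kk, ll) in ((k, l), (l, k)):
                            eri[ii, jj, kk, ll] = eri[kk, ll, ii, jj] = val
    e_nuc = 0.0
    for a, b in combinations(range(geometry.n_atoms), 2):
        e_nuc += geometry.charges[a] * geometry.charges[b] / np.linalg.norm(
            geometry.coords[a] - geometry.coords[b])
    centers = np.array([sh.atom for sh in shells], int)
    ints = IntegralSet(S, T + V, eri, R, e_nuc, centers)
    ints.validate()
    return ints


# standard STO-3G s-contractions for the two elements the test set uses
STO3G = {
    "H": [[(3.42525091, 0.15432897), (0.62391373, 0.53532814), (0.16885540, 0.44463454)]],
    "He": [[(6.36242139, 0.15432897), (1.15892300, 0.53532814), (0.31364979, 0.44463454)]],
}


# ---------------------------------------------------------------------------
# PPP provider


@dataclass
class PPPParams:
    """Pariser–Parr–Pople π-electron parameters.

    One basis function per π site; `site_atoms` maps site -> atom index,
    atoms not listed are bare cores (charge from `bare_core_charges` or the
    nuclear charge) interacting through the same Ohno γ, screened by
    `bare_core_u`.  Hopping decays exponentially: t(r) = t0 exp(-(r-r0)/lam).
    A Born–Mayer core–core repulsion rep_a·exp(-(r-r0)/rep_rho) between π
    sites balances the hopping attraction so bonds have a genuine minimum
    (the σ-skeleton the π model does not describe explicitly).
    """

    site_energies: np.ndarray  # (ns,) hartree
    hubbard_u: np.ndarray  # (ns,) hartree
    electrons: int
    core_charges: np.ndarray  # (ns,) core charge of each π site
    t0: float = -0.12
    r0: float = 2.5  # bohr
    lam: float = 0.8  # bohr
    rep_a: float = 0.08  # hartree, Born-Mayer amplitude at r0
    rep_rho: float = 0.4  # bohr, Born-Mayer decay
    ohno: bool = True
    site_atoms: np.ndarray | None = None  # default: all atoms are sites
    bare_core_u: float = 0.5  # screening U for atoms without a basis function
    bare_core_charges: dict = field(default_factory=dict)  # atom idx -> charge

    def __post_init__(self) -> None:
        self.site_energies = np.asarray(self.site_energies, float)
        self.hubbard_u = np.asarray(self.hubbard_u, float)
        self.core_charges = np.asarray(self.core_charges, float)
        if self.site_atoms is not None:
            self.site_atoms = np.asarray(self.site_atoms, int)
        if np.any(self.hubbard_u <= 0):
            raise ValueError("all Hubbard U must be > 0")
        ns = len(self.site_energies)
        if self.electrons > 2 * ns:
            raise ValueError("more electrons than spin-orbitals")

    def n_sites(self) -> int:
        return len(self.site_energies)

    def resolve_site_atoms(self, geometry: Geometry) -> np.ndarray:
        if self.site_atoms is None:
            if geometry.n_atoms != self.n_sites():
                raise ValueError("site count != atom count and no site_atoms map")
            return np.arange(geometry.n_atoms)
        return self.site_atoms

    def atom_u(self, geometry: Geometry) -> np.ndarray:
        """Per-atom screening U: the site U on π sites, bare_core_u elsewhere."""
        u = np.full(geometry.n_atoms, self.bare_core_u)
        u[self.resolve_site_atoms(geometry)] = self.hubbard_u
        return u

    def atom_core_charges(self, geometry: Geometry) -> np.ndarray:
        """Per-atom core charge (π cores from params, bare cores from Z)."""
        z = geometry.charges.copy()
        sa = self.resolve_site_atoms(geometry)
        z[sa] = self.core_charges
        for ia, q in self.bare_core_charges.items():
            z[ia] = q
        return z


def ohno_gamma(r: np.ndarray, u_avg: np.ndarray) -> np.ndarray:
    """Ohno interpolation γ(r) = U / sqrt(1 + (U r)^2), atomic units."""
    return u_avg / np.sqrt(1.0 + (u_avg * r) ** 2)


def ohno_gamma_deriv(r: np.ndarray, u_avg: np.ndarray) -> np.ndarray:
    """dγ/dr for the Ohno form."""
    return -(u_avg ** 3) * r / (1.0 + (u_avg * r) ** 2) ** 1.5


def _atom_gamma(geometry: Geometry, params: PPPParams) -> np.ndarray:
    """γ between every atom pair (π sites and bare cores alike)."""
    u = params.atom_u(geometry)
    u_avg = 0.5 * (u[:, None] + u[None, :])
    r = geometry.distance_matrix()
    g = ohno_gamma(r, u_avg)
    np.fill_diagonal(g, u)
    return g


def ppp_integrals(geometry: Geometry, params: PPPParams) -> IntegralSet:
    """PPP integrals: identity overlap, exponential hopping, Ohno repulsion."""
    sa = params.resolve_site_atoms(geometry)
    ns = params.n_sites()
    r = geometry.distance_matrix()
    if ns > 1 and np.min(r[np.ix_(sa, sa)][np.triu_indices(ns, 1)]) < 1e-3:
        raise ValueError("PPP sites closer than 1e-3 bohr")
    g_atom = _atom_gamma(geometry, params)
    gamma = g_atom[np.ix_(sa, sa)]
    zc = params.atom_core_charges(geometry)

    h = np.zeros((ns, ns))
    rs = r[np.ix_(sa, sa)]
    off = params.t0 * np.exp(-(rs - params.r0) / params.lam)
    h += off - np.diag(np.diag(off))
    # on-site: ε_i minus attraction to every other core (π and bare)
    for i, ai in enumerate(sa):
        attr = 0.0
        for c in range(geometry.n_atoms):
            if c == ai:
                continue
            attr -= zc[c] * g_atom[ai, c]
        h[i, i] = params.site_energies[i] + attr

    eri = np.zeros((ns, ns, ns, ns))
    for i in range(ns):
        for j in range(ns):
            eri[i, i, j, j] = gamma[i, j]

    dip = np.zeros((3, ns, ns))
    for k in range(3):
        dip[k] = np.diag(geometry.coords[sa, k])

    e_core = 0.0
    for a, b in combinations(range(geometry.n_atoms), 2):
        e_core += zc[a] * zc[b] * g_atom[a, b]
        # Born-Mayer σ-core repulsion (all atom pairs: balances the hopping
        # attraction between sites and keeps bare cores at bonded distances)
        e_core += params.rep_a * np.exp(-(r[a, b] - params.r0) / params.rep_rho)

    ints = IntegralSet(np.eye(ns), h, eri, dip, e_core, sa.copy())
    ints.validate()
    return ints


# ---------------------------------------------------------------------------
# Dense full CI over the integral contract (reference oracle)


def _lowdin_x(overlap: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(overlap)
    if w.min() < 1e-10:
        raise ValueError("overlap near-singular")
    return v @ np.diag(w ** -0.5) @ v.T


def _orthonormalize(integrals: IntegralSet) -> tuple[np.ndarray, np.ndarray]:
    """Return (h', eri') in the Löwdin-orthonormalized basis."""
    X = _lowdin_x(integrals.overlap)
    h = X.T @ integrals.hcore @ X
    eri = np.einsum("pi,qj,pqrs,rk,sl->ijkl", X, X, integrals.eri, X, X, optimize=True)
    return h, eri


def _phase(occ: tuple, p: int, q: int) -> int:
    """Sign of moving an electron p->q in an ordered occupation tuple."""
    lo, hi = (p, q) if p < q else (q, p)
    n_between = sum(1 for o in occ if lo < o < hi)
    return -1 if n_between % 2 else 1


def _sc_matrix_element(da, db, ka, kb, h, eri):
    """Slater–Condon matrix element between determinants (da,db) and (ka,kb),
    each a sorted tuple of spatial-orbital indices per spin."""
    sa_diff = (set(da) - set(ka), set(ka) - set(da))
    sb_diff = (set(db) - set(kb), set(kb) - set(db))
    nda, ndb = len(sa_diff[0]), len(sb_diff[0])
    if nda + ndb > 2:
        return 0.0
    if nda + ndb == 0:
        e = sum(h[p, p] for p in da) + sum(h[p, p] for p in db)
        for spin_occ, same in ((da, True), (db, True)):
            for p in spin_occ:
                for q in spin_occ:
                    e += 0.5 * (eri[p, p, q, q] - eri[p, q, q, p])
        for p in da:
            for q in db:
                e += eri[p, p, q, q]
        return e
    if nda + ndb == 1:
        if nda == 1:
            (p,), (q,) = sa_diff
            occ, other = da, db
        else:
            (p,), (q,) = sb_diff
            occ, other = db, da
        val = h[p, q]
        for r in occ:
            if r != p:
                val += eri[p, q, r, r] - eri[p, r, r, q]
        for r in other:
            val += eri[p, q, r, r]
        return _phase(occ, p, q) * val
    # double excitation
    if nda == 2:
        (p1, p2) = sorted(sa_diff[0])
        (q1, q2) = sorted(sa_diff[1])
        sign = _double_phase(da, (p1, p2), (q1, q2))
        return sign * (eri[p1, q1, p2, q2] - eri[p1, q2, p2, q1])
    if ndb == 2:
        (p1, p2) = sorted(sb_diff[0])
        (q1, q2) = sorted(sb_diff[1])
        sign = _double_phase(db, (p1, p2), (q1, q2))
        return sign * (eri[p1, q1, p2, q2] - eri[p1, q2, p2, q1])
    # one alpha + one beta
    (pa,), (qa,) = sa_diff
    (pb,), (qb,) = sb_diff
    return _phase(da, pa, qa) * _phase(db, pb, qb) * eri[pa, qa, pb, qb]


def _double_phase(occ, removed, added):
    """Fermionic sign for a same-spin double excitation, by sequential moves."""
    occ = list(occ)
    sign = 1
    for p, q in zip(removed, added):
        sign *= _phase(tuple(occ), p, q)
        occ.remove(p)
        occ.append(q)
        occ.sort()
    return sign


def fci_determinants(n_orb: int, n_alpha: int, n_beta: int):
    da = list(combinations(range(n_orb), n_alpha))
    db = list(combinations(range(n_orb), n_beta))
    return [(a, b) for a in da for b in db]


def exact_diagonalization(integrals: IntegralSet, n_alpha: int, n_beta: int,
                          n_states: int = 6):
    """Dense full CI: lowest eigenvalues/eigenvectors in the determinant basis.

    Returns (energies, vectors, determinants); energies include the
    core/nuclear repulsion.  The determinant basis is the full product of
    alpha and beta occupation tuples in the Löwdin-orthonormal orbital basis.
    """
    n = integrals.n_basis
    dets = fci_determinants(n, n_alpha, n_beta)
    ndet = len(dets)
    if ndet > 10 ** 6:
        raise ValueError(f"determinant space too large ({ndet})")
    h, eri = _orthonormalize(integrals)
    H = np.zeros((ndet, ndet))
    for I, (da, db) in enumerate(dets):
        for J in range(I, ndet):
            ka, kb = dets[J]
            v = _sc_matrix_element(da, db, ka, kb, h, eri)
            H[I, J] = H[J, I] = v
    w, v = np.linalg.eigh(H)
    k = min(n_states, ndet)
    return w[:k] + integrals.nuclear_repulsion, v[:, :k], dets


def fci_one_rdm(vector: np.ndarray, dets, n_orb: int) -> np.ndarray:
    """Spin-summed one-particle density matrix of a CI vector, in the
    orthonormal orbital basis used by exact_diagonalization."""
    rdm = np.zeros((n_orb, n_orb))
    index = {d: i for i, d in enumerate(dets)}
    for I, (da, db) in enumerate(dets):
        ci = vector[I]
        if abs(ci) < 1e-14:
            continue
        for p in da:
            rdm[p, p] += ci * ci
        for p in db:
            rdm[p, p] += ci * ci
        # single excitations
        for spin, occ in ((0, da), (1, db)):
            for p in occ:
                for q in range(n_orb):
                    if q in occ:
                        continue
                    new = tuple(sorted([o for o in occ if o != p] + [q]))
                    key = (new, db) if spin == 0 else (da, new)
                    J = index.get(key)
                    if J is None:
                        continue
                    rdm[q, p] += _phase(occ, p, q) * ci * vector[J]
    return rdm


def fci_dipole(vector: np.ndarray, dets, integrals: IntegralSet,
               geometry: Geometry, core_charges: np.ndarray) -> np.ndarray:
    """Dipole expectation of a CI vector: nuclear/core part minus electron part."""
    n = integrals.n_basis
    rdm = fci_one_rdm(vector, dets, n)
    X = _lowdin_x(integrals.overlap)
    mu = np.array([np.sum(rdm * (X.T @ integrals.dipole_ops[k] @ X)) for k in range(3)])
    nuc = (core_charges[:, None] * geometry.coords).sum(axis=0)
    return nuc - mu
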