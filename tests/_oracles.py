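"""Independent reference implementations used only by the test suite.

Everything here is written from scratch against the textbook definitions,
deliberately avoiding the package's code paths: a plain fixed-point SCF
with explicit loops, and a spin-orbital full CI built by operator
application on occupation bitstrings.
"""

from __future__ import annotations

import numpy as np


def textbook_scf(hcore, eri, overlap, n_alpha, n_beta, e_nuc=0.0,
                 restricted=True, max_iter=2000, mix=0.3, tol=1e-12):
    """Plain Roothaan fixed-point SCF with density mixing (no DIIS).

    eri in chemists' notation (ij|kl).  Returns the converged total energy.
    """
    n = hcore.shape[0]
    w, v = np.linalg.eigh(overlap)
    X = v @ np.diag(w ** -0.5) @ v.T

    def fock(d_tot, d_spin):
        F = hcore.copy()
        for p in range(n):
            for q in range(n):
                for r in range(n):
                    for s in range(n):
                        F[p, q] += d_tot[r, s] * eri[p, q, r, s]
                        F[p, q] -= d_spin[r, s] * eri[p, r, q, s]
        return F

    def density(F, nocc):
        e, c = np.linalg.eigh(X.T @ F @ X)
        c = X @ c
        occ = c[:, :nocc]
        return occ @ occ.T

    da = density(hcore, n_alpha)
    db = da.copy() if restricted else density(hcore, n_beta)
    e_old = None
    for _ in range(max_iter):
        fa = fock(da + db, da)
        fb = fa if restricted else fock(da + db, db)
        e = 0.5 * (np.sum(da * (hcore + fa)) + np.sum(db * (hcore + fb)))
        da_new = density(fa, n_alpha)
        db_new = da_new.copy() if restricted else density(fb, n_beta)
        da = mix * da + (1 - mix) * da_new
        db = mix * db + (1 - mix) * db_new
        if e_old is not None and abs(e - e_old) < tol:
            break
        e_old = e
    return e + e_nuc


def _bit_positions(bits, n):
    return [i for i in range(n) if bits >> i & 1]


def _apply_annihilate(bits, p):
    if not (bits >> p & 1):
        return None, 0
    sign = (-1) ** bin(bits & ((1 << p) - 1)).count("1")
    return bits & ~(1 << p), sign


def _apply_create(bits, p):
    if bits >> p & 1:
        return None, 0
    sign = (-1) ** bin(bits & ((1 << p) - 1)).count("1")
    return bits | (1 << p), sign


def spinorbital_fci(hcore, eri, n_alpha, n_beta, e_nuc=0.0, n_states=3):
    """Full CI by operator application on spin-orbital bitstrings.

    Spin-orbital p of spatial orbital i: alpha = 2i, beta = 2i+1.  hcore and
    chemists' eri are in an orthonormal spatial basis.
    """
    n = hcore.shape[0]
    nso = 2 * n
    from itertools import combinations

    states = []
    for occ_a in combinations(range(n), n_alpha):
        for occ_b in combinations(range(n), n_beta):
            bits = 0
            for i in occ_a:
                bits |= 1 << (2 * i)
            for i in occ_b:
                bits |= 1 << (2 * i + 1)
            states.append(bits)
    index = {s: i for i, s in enumerate(states)}
    dim = len(states)
    H = np.zeros((dim, dim))

    def spatial(p):
        return p // 2

    def same_spin(p, q):
        return (p % 2) == (q % 2)

    for I, bits in enumerate(states):
        # one-electron
        for p in range(nso):
            for q in range(nso):
                if not same_spin(p, q) or hcore[spatial(p), spatial(q)] == 0.0:
                    continue
                b1, s1 = _apply_annihilate(bits, q)
                if b1 is None:
                    continue
                b2, s2 = _apply_create(b1, p)
                if b2 is None:
                    continue
                H[index[b2], I] += s1 * s2 * hcore[spatial(p), spatial(q)]
        # two-electron: ½ Σ_pqrs (pq|rs) a†_p a†_r a_s a_q  (chemists')
        for p in range(nso):
            for q in range(nso):
                if not same_spin(p, q):
                    continue
                for r in range(nso):
                    for s in range(nso):
                        if not same_spin(r, s):
                            continue
                        val = eri[spatial(p), spatial(q), spatial(r), spatial(s)]
                        if val == 0.0:
                            continue
                        b1, s1 = _apply_annihilate(bits, q)
                        if b1 is None:
                            continue
                        b2, s2 = _apply_annihilate(b1, s)
                        if b2 is None:
                            continue
                        b3, s3 = _apply_create(b2, r)
                        if b3 is None:
                            continue
                        b4, s4 = _apply_create(b3, p)
                        if b4 is None:
                            continue
                        H[index[b4], I] += 0.5 * s1 * s2 * s3 * s4 * val
    w = np.linalg.eigvalsh(H)
    return w[:n_states] + e_nuc


def determinant_energy(hcore, eri, c_occ_a, c_occ_b, e_nuc=0.0):
    """Direct expectation value of a single determinant given occupied
    orbital coefficients per spin (orthonormal basis)."""
    da = c_occ_a @ c_occ_a.T
    db = c_occ_b @ c_occ_b.T
    dt = da + db
    e = np.sum(dt * hcore)
    e += 0.5 * np.einsum("pqrs,pq,rs->", eri, dt, dt)
    e -= 0.5 * np.einsum("prqs,pq,rs->", eri, da, da)
    e -= 0.5 * np.einsum("prqs,pq,rs->", eri, db, db)
    return e + e_nuc


def hubbard_dimer_ground_energy(t, u):
    """Closed-form 2-site, 2-electron Hubbard ground energy
    ½(U - sqrt(U² + 16 t²)) relative to the ε=0, no-repulsion reference."""
    return 0.5 * (u - np.sqrt(u ** 2 + 16 * t ** 2))
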