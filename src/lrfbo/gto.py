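"""Gaussian-type-orbital math: AO evaluation and analytic one-electron integrals.

All integrals are first formed over "raw" contracted Cartesian functions

    Theta_comp(r) = sum_k c'_k  x^lx y^ly z^lz  exp(-a_k |r-A|^2)

where ``c'_k`` already includes the axial primitive normalization, and are
then mapped to the final AO basis (normalized real-spherical harmonics, or
normalized Cartesian components) by a block-diagonal transform built in
:func:`build_transform`. One-electron integrals use the McMurchie–Davidson
Hermite expansion.
"""

from __future__ import annotations

import math

import numpy as np

from .basis import Shell

# ---------------------------------------------------------------------------
# Cartesian component orders (Molden convention) and solid-harmonic tables
# ---------------------------------------------------------------------------

CART_COMPONENTS = {
    0: [(0, 0, 0)],
    1: [(1, 0, 0), (0, 1, 0), (0, 0, 1)],
    2: [(2, 0, 0), (0, 2, 0), (0, 0, 2), (1, 1, 0), (1, 0, 1), (0, 1, 1)],
    3: [
        (3, 0, 0), (0, 3, 0), (0, 0, 3), (1, 2, 0), (2, 1, 0),
        (2, 0, 1), (1, 0, 2), (0, 1, 2), (0, 2, 1), (1, 1, 1),
    ],
}

# Real solid harmonics over monomials, Molden AO order m = 0, +1, -1, +2, -2, ...
# Overall scale is irrelevant (each AO is renormalized numerically).
SPH_OVER_CART = {
    0: [{(0, 0, 0): 1.0}],
    1: [{(1, 0, 0): 1.0}, {(0, 1, 0): 1.0}, {(0, 0, 1): 1.0}],
    2: [
        {(0, 0, 2): 2.0, (2, 0, 0): -1.0, (0, 2, 0): -1.0},
        {(1, 0, 1): 1.0},
        {(0, 1, 1): 1.0},
        {(2, 0, 0): 1.0, (0, 2, 0): -1.0},
        {(1, 1, 0): 1.0},
    ],
    3: [
        {(0, 0, 3): 2.0, (2, 0, 1): -3.0, (0, 2, 1): -3.0},
        {(1, 0, 2): 4.0, (3, 0, 0): -1.0, (1, 2, 0): -1.0},
        {(0, 1, 2): 4.0, (2, 1, 0): -1.0, (0, 3, 0): -1.0},
        {(2, 0, 1): 1.0, (0, 2, 1): -1.0},
        {(1, 1, 1): 1.0},
        {(3, 0, 0): 1.0, (1, 2, 0): -3.0},
        {(2, 1, 0): 3.0, (0, 3, 0): -1.0},
    ],
}


def double_factorial(n: int) -> int:
    return 1 if n <= 0 else math.prod(range(n, 0, -2))


def primitive_axial_norm(alpha: float, l: int) -> float:
    """Norm constant of an axial Cartesian primitive x^l exp(-a r^2)."""
    return (
        (2 * alpha / math.pi) ** 0.75
        * (4 * alpha) ** (l / 2)
        / math.sqrt(double_factorial(2 * l - 1))
    )


def scaled_coefficients(shell: Shell) -> np.ndarray:
    """Contraction coefficients scaled onto unnormalized monomial primitives."""
    return shell.coefficients * np.array(
        [primitive_axial_norm(a, shell.l) for a in shell.exponents]
    )


def n_cart(l: int) -> int:
    return (l + 1) * (l + 2) // 2


# ---------------------------------------------------------------------------
# McMurchie–Davidson Hermite expansion coefficients (scalar python; used for
# one-electron integrals where shell-pair counts are small)
# ---------------------------------------------------------------------------

def e_table(la: int, lb: int, pa: float, pb: float, p: float) -> np.ndarray:
    """Hermite expansion coefficients E[i, j, t] for one dimension.

    pa, pb are P-A and P-B components; p the combined exponent. The Gaussian
    product prefactor exp(-q Qx^2) is NOT included here (applied per pair).
    """
    E = np.zeros((la + 1, lb + 1, la + lb + 1))
    E[0, 0, 0] = 1.0
    inv2p = 1.0 / (2.0 * p)
    for i in range(1, la + 1):
        for t in range(i + 1):
            val = pa * E[i - 1, 0, t]
            if t > 0:
                val += inv2p * E[i - 1, 0, t - 1]
            if t + 1 <= i - 1:
                val += (t + 1) * E[i - 1, 0, t + 1]
            E[i, 0, t] = val
    for j in range(1, lb + 1):
        for i in range(la + 1):
            for t in range(i + j + 1):
                val = pb * E[i, j - 1, t]
                if t > 0:
                    val += inv2p * E[i, j - 1, t - 1]
                if t + 1 <= i + j - 1:
                    val += (t + 1) * E[i, j - 1, t + 1]
                E[i, j, t] = val
    return E


def _pair_1d_tables(sh_a: Shell, sh_b: Shell, ka: int, kb: int, extra: int = 0):
    """E tables per dimension for one primitive pair, plus p and prefactor."""
    a = sh_a.exponents[ka]
    b = sh_b.exponents[kb]
    p = a + b
    P = (a * sh_a.center + b * sh_b.center) / p
    AB = sh_a.center - sh_b.center
    pref = math.exp(-a * b / p * float(AB @ AB))
    tables = []
    for d in range(3):
        tables.append(
            e_table(sh_a.l, sh_b.l + extra, P[d] - sh_a.center[d], P[d] - sh_b.center[d], p)
        )
    return tables, p, P, pref


def raw_overlap_block(sh_a: Shell, sh_b: Shell) -> np.ndarray:
    """Overlap of raw contracted Cartesian functions of two shells."""
    ca, cb = scaled_coefficients(sh_a), scaled_coefficients(sh_b)
    comps_a, comps_b = CART_COMPONENTS[sh_a.l], CART_COMPONENTS[sh_b.l]
    out = np.zeros((len(comps_a), len(comps_b)))
    for ka in range(len(ca)):
        for kb in range(len(cb)):
            (Ex, Ey, Ez), p, _, pref = _pair_1d_tables(sh_a, sh_b, ka, kb)
            fac = ca[ka] * cb[kb] * pref * (math.pi / p) ** 1.5
            for ia, (ax, ay, az) in enumerate(comps_a):
                for ib, (bx, by, bz) in enumerate(comps_b):
                    out[ia, ib] += fac * Ex[ax, bx, 0] * Ey[ay, by, 0] * Ez[az, bz, 0]
    return out


def raw_kinetic_block(sh_a: Shell, sh_b: Shell) -> np.ndarray:
    """Kinetic energy integrals over raw contracted Cartesian functions."""
    ca, cb = scaled_coefficients(sh_a), scaled_coefficients(sh_b)
    comps_a, comps_b = CART_COMPONENTS[sh_a.l], CART_COMPONENTS[sh_b.l]
    out = np.zeros((len(comps_a), len(comps_b)))
    for ka in range(len(ca)):
        for kb in range(len(cb)):
            b = sh_b.exponents[kb]
            E3, p, _, pref = _pair_1d_tables(sh_a, sh_b, ka, kb, extra=2)
            s1 = math.sqrt(math.pi / p)
            fac = ca[ka] * cb[kb] * pref * s1**3

            def S(E, i, j):
                return E[i, j, 0] if j >= 0 else 0.0

            def T1(E, i, j):
                val = -2.0 * b * b * S(E, i, j + 2) + b * (2 * j + 1) * S(E, i, j)
                if j >= 2:
                    val -= 0.5 * j * (j - 1) * S(E, i, j - 2)
                return val

            for ia, A in enumerate(comps_a):
                for ib, B in enumerate(comps_b):
                    sx, sy, sz = (S(E3[d], A[d], B[d]) for d in range(3))
                    tx, ty, tz = (T1(E3[d], A[d], B[d]) for d in range(3))
                    out[ia, ib] += fac * (tx * sy * sz + sx * ty * sz + sx * sy * tz)
    return out


def raw_dipole_blocks(sh_a: Shell, sh_b: Shell) -> np.ndarray:
    """Dipole (x, y, z about the origin) over raw Cartesian functions."""
    ca, cb = scaled_coefficients(sh_a), scaled_coefficients(sh_b)
    comps_a, comps_b = CART_COMPONENTS[sh_a.l], CART_COMPONENTS[sh_b.l]
    out = np.zeros((3, len(comps_a), len(comps_b)))
    for ka in range(len(ca)):
        for kb in range(len(cb)):
            E3, p, P, pref = _pair_1d_tables(sh_a, sh_b, ka, kb)
            fac = ca[ka] * cb[kb] * pref * (math.pi / p) ** 1.5
            for ia, A in enumerate(comps_a):
                for ib, B in enumerate(comps_b):
                    s = [E3[d][A[d], B[d], 0] for d in range(3)]
                    for d in range(3):
                        E = E3[d]
                        m = E[A[d], B[d], 1] if 1 < E.shape[2] else 0.0
                        md = m + P[d] * E[A[d], B[d], 0]
                        others = [s[e] for e in range(3) if e != d]
                        out[d, ia, ib] += fac * md * others[0] * others[1]
    return out


# ---------------------------------------------------------------------------
# AO transform (raw Cartesian -> normalized spherical/Cartesian AOs)
# ---------------------------------------------------------------------------

def shell_transform(shell: Shell, raw_S: np.ndarray) -> np.ndarray:
    """(ncart, nfunc) block mapping raw Cartesian functions to final AOs."""
    comps = CART_COMPONENTS[shell.l]
    if shell.pure or shell.l < 2:
        T0 = np.zeros((len(comps), 2 * shell.l + 1))
        for m, terms in enumerate(SPH_OVER_CART[shell.l]):
            for comp, coef in terms.items():
                T0[comps.index(comp), m] = coef
    else:
        T0 = np.eye(len(comps))
    norms = np.sqrt(np.einsum("cm,cd,dm->m", T0, raw_S, T0))
    return T0 / norms


def build_transform(shells: list[Shell]) -> tuple[np.ndarray, np.ndarray]:
    """Full block-diagonal transform plus bookkeeping offsets.

    Returns (T, cart_offsets) where T has shape (ncart_total, nao_total).
    """
    ncart = sum(n_cart(sh.l) for sh in shells)
    nao = sum(sh.nfunc for sh in shells)
    T = np.zeros((ncart, nao))
    ic = iao = 0
    for sh in shells:
        raw_S = raw_overlap_block(sh, sh)
        blk = shell_transform(sh, raw_S)
        T[ic:ic + blk.shape[0], iao:iao + blk.shape[1]] = blk
        ic += blk.shape[0]
        iao += blk.shape[1]
    return T, np.array([n_cart(sh.l) for sh in shells])


def _assemble(shells, block_fn) -> np.ndarray:
    sizes = [n_cart(sh.l) for sh in shells]
    offs = np.concatenate([[0], np.cumsum(sizes)])
    M = np.zeros((offs[-1], offs[-1]))
    for i, sa in enumerate(shells):
        for j, sb in enumerate(shells):
            if j < i:
                continue
            blk = block_fn(sa, sb)
            M[offs[i]:offs[i + 1], offs[j]:offs[j + 1]] = blk
            if j > i:
                M[offs[j]:offs[j + 1], offs[i]:offs[i + 1]] = blk.T
    return M


def overlap_matrix(shells: list[Shell], T: np.ndarray | None = None) -> np.ndarray:
    if T is None:
        T, _ = build_transform(shells)
    S_raw = _assemble(shells, raw_overlap_block)
    return T.T @ S_raw @ T


def kinetic_matrix(shells: list[Shell], T: np.ndarray | None = None) -> np.ndarray:
    if T is None:
        T, _ = build_transform(shells)
    T_raw = _assemble(shells, raw_kinetic_block)
    return T.T @ T_raw @ T


def dipole_matrices(shells: list[Shell], T: np.ndarray | None = None) -> np.ndarray:
    if T is None:
        T, _ = build_transform(shells)
    sizes = [n_cart(sh.l) for sh in shells]
    offs = np.concatenate([[0], np.cumsum(sizes)])
    M = np.zeros((3, offs[-1], offs[-1]))
    for i, sa in enumerate(shells):
        for j, sb in enumerate(shells):
            blk = raw_dipole_blocks(sa, sb)
            M[:, offs[i]:offs[i + 1], offs[j]:offs[j + 1]] = blk
    return np.einsum("ca,xcd,db->xab", T, M, T)


# ---------------------------------------------------------------------------
# AO evaluation on point grids
# ---------------------------------------------------------------------------

def eval_raw_shell(shell: Shell, points: np.ndarray, deriv: bool = False):
    """Values (and gradients) of a shell's raw Cartesian functions at points."""
    rel = points - shell.center  # (n, 3)
    r2 = np.einsum("ni,ni->n", rel, rel)
    coefs = scaled_coefficients(shell)
    expo = np.exp(-np.multiply.outer(shell.exponents, r2))  # (k, n)
    radial = coefs @ expo  # (n,)
    dradial = -2.0 * (coefs * shell.exponents) @ expo  # (n,), d/dr2
    comps = CART_COMPONENTS[shell.l]
    n = points.shape[0]
    vals = np.empty((n, len(comps)))
    grads = np.empty((n, 3, len(comps))) if deriv else None
    lmax = shell.l
    # powers[d][e] = rel[:, d]**e
    powers = [[np.ones(n)] for _ in range(3)]
    for d in range(3):
        for e in range(1, lmax + 1):
            powers[d].append(powers[d][-1] * rel[:, d])

    for ic, comp in enumerate(comps):
        mono = powers[0][comp[0]] * powers[1][comp[1]] * powers[2][comp[2]]
        vals[:, ic] = mono * radial
        if deriv:
            for d in range(3):
                e = comp[d]
                g = rel[:, d] * mono * dradial
                if e > 0:
                    oth = [powers[k][comp[k]] for k in range(3) if k != d]
                    g = g + e * powers[d][e - 1] * oth[0] * oth[1] * radial
                grads[:, d, ic] = g
    return (vals, grads) if deriv else vals


def eval_aos(shells: list[Shell], points: np.ndarray, T: np.ndarray | None = None,
             deriv: bool = False, chunk: int = 50000):
    """AO values at points, shape (npoints, nao); optionally also gradients."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError("points must have shape (n, 3)")
    if not np.all(np.isfinite(points)):
        raise ValueError("points must be finite")
    if T is None:
        T, _ = build_transform(shells)
    nao = T.shape[1]
    n = points.shape[0]
    out = np.empty((n, nao))
    gout = np.empty((n, 3, nao)) if deriv else None
    for start in range(0, n, chunk):
        pts = points[start:start + chunk]
        raw_vals = []
        raw_grads = []
        for sh in shells:
            res = eval_raw_shell(sh, pts, deriv=deriv)
            if deriv:
                raw_vals.append(res[0])
                raw_grads.append(res[1])
            else:
                raw_vals.append(res)
        V = np.concatenate(raw_vals, axis=1)
        out[start:start + chunk] = V @ T
        if deriv:
            G = np.concatenate(raw_grads, axis=2)
            gout[start:start + chunk] = np.einsum("ndc,ca->nda", G, T)
    return (out, gout) if deriv else out
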