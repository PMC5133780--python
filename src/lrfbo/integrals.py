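"""Two-electron and nuclear-attraction integrals (McMurchie–Davidson, numba).

Integrals are computed over the raw contracted Cartesian functions of
:mod:`lrfbo.gto` and transformed to the final AO basis afterwards. Shell
data is flattened into plain arrays so the hot loops jit-compile cleanly.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .basis import Shell
from .gto import CART_COMPONENTS, n_cart, scaled_coefficients

_COMP_OFFSETS = np.array([0, 1, 4, 10, 20])
_COMPS_FLAT = np.array(
    [c for l in range(4) for c in CART_COMPONENTS[l]], dtype=np.int64
)


def flatten_shells(shells: list[Shell]):
    """Pack shell data into flat arrays for the numba kernels."""
    ls = np.array([sh.l for sh in shells], dtype=np.int64)
    nprim = np.array([len(sh.exponents) for sh in shells], dtype=np.int64)
    ptr = np.concatenate([[0], np.cumsum(nprim)])[:-1].astype(np.int64)
    exps = np.concatenate([sh.exponents for sh in shells]).astype(np.float64)
    coefs = np.concatenate([scaled_coefficients(sh) for sh in shells]).astype(np.float64)
    centers = np.array([sh.center for sh in shells], dtype=np.float64)
    cart_off = np.concatenate([[0], np.cumsum([n_cart(sh.l) for sh in shells])]).astype(np.int64)
    return ls, nprim, ptr, exps, coefs, centers, cart_off


@njit(cache=True)
def _boys(mmax, T, out):
    if T < 1e-13:
        for m in range(mmax + 1):
            out[m] = 1.0 / (2 * m + 1)
        return
    if T < 35.0:
        # convergent series at m = mmax, then downward recursion
        term = 1.0 / (2 * mmax + 1)
        acc = term
        k = 1
        while True:
            term *= 2.0 * T / (2 * mmax + 2 * k + 1)
            acc += term
            if term < 1e-17 * acc or k > 200:
                break
            k += 1
        emt = math.exp(-T)
        out[mmax] = acc * emt
        for m in range(mmax - 1, -1, -1):
            out[m] = (2.0 * T * out[m + 1] + emt) / (2 * m + 1)
    else:
        out[0] = 0.5 * math.sqrt(math.pi / T) * math.erf(math.sqrt(T))
        emt = math.exp(-T)
        for m in range(mmax):
            out[m + 1] = ((2 * m + 1) * out[m] - emt) / (2.0 * T)


@njit(cache=True)
def _fill_e(la, lb, pa, pb, p, E):
    """E[i, j, t] Hermite coefficients for one dimension (prefactor excluded)."""
    inv2p = 1.0 / (2.0 * p)
    for i in range(la + 1):
        for j in range(lb + 1):
            for t in range(la + lb + 1):
                E[i, j, t] = 0.0
    E[0, 0, 0] = 1.0
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


@njit(cache=True)
def _fill_r(ltot, alpha, X, Y, Z, R4):
    """Hermite Coulomb repulsion tensor R4[n, t, u, v] via MD recursion."""
    T = alpha * (X * X + Y * Y + Z * Z)
    fm = np.empty(ltot + 1)
    _boys(ltot, T, fm)
    fac = 1.0
    for n in range(ltot + 1):
        R4[n, 0, 0, 0] = fac * fm[n]
        fac *= -2.0 * alpha
    for s in range(1, ltot + 1):
        for t in range(s + 1):
            for u in range(s - t + 1):
                v = s - t - u
                for n in range(ltot - s + 1):
                    if t > 0:
                        val = X * R4[n + 1, t - 1, u, v]
                        if t > 1:
                            val += (t - 1) * R4[n + 1, t - 2, u, v]
                    elif u > 0:
                        val = Y * R4[n + 1, t, u - 1, v]
                        if u > 1:
                            val += (u - 1) * R4[n + 1, t, u - 2, v]
                    else:
                        val = Z * R4[n + 1, t, u, v - 1]
                        if v > 1:
                            val += (v - 1) * R4[n + 1, t, u, v - 2]
                    R4[n, t, u, v] = val


@njit(cache=True)
def _eri_cart(ls, nprim, ptr, exps, coefs, centers, cart_off,
              comp_off, comps, screen):
    ns = ls.shape[0]
    ncart = cart_off[ns]
    G = np.zeros((ncart, ncart, ncart, ncart))
    Eb = np.empty((3, 4, 4, 7))
    Ek = np.empty((3, 4, 4, 7))
    R4 = np.empty((13, 13, 13, 13))
    twopi52 = 2.0 * math.pi ** 2.5
    for i in range(ns):
        la = ls[i]
        for j in range(i + 1):
            lb = ls[j]
            AB2 = 0.0
            for d in range(3):
                AB2 += (centers[i, d] - centers[j, d]) ** 2
            for k in range(i + 1):
                lc = ls[k]
                lmax_l = j if k == i else k
                for l in range(lmax_l + 1):
                    ld = ls[l]
                    CD2 = 0.0
                    for d in range(3):
                        CD2 += (centers[k, d] - centers[l, d]) ** 2
                    ltot = la + lb + lc + ld
                    na, nb = comp_off[la + 1] - comp_off[la], comp_off[lb + 1] - comp_off[lb]
                    nc, nd = comp_off[lc + 1] - comp_off[lc], comp_off[ld + 1] - comp_off[ld]
                    blk = np.zeros((na, nb, nc, nd))
                    any_prim = False
                    for pa_ in range(nprim[i]):
                        ai = exps[ptr[i] + pa_]
                        ci = coefs[ptr[i] + pa_]
                        for pb_ in range(nprim[j]):
                            aj = exps[ptr[j] + pb_]
                            cj = coefs[ptr[j] + pb_]
                            p = ai + aj
                            Kab = math.exp(-ai * aj / p * AB2)
                            if abs(ci * cj) * Kab < screen:
                                continue
                            Px = (ai * centers[i, 0] + aj * centers[j, 0]) / p
                            Py = (ai * centers[i, 1] + aj * centers[j, 1]) / p
                            Pz = (ai * centers[i, 2] + aj * centers[j, 2]) / p
                            _fill_e(la, lb, Px - centers[i, 0], Px - centers[j, 0], p, Eb[0])
                            _fill_e(la, lb, Py - centers[i, 1], Py - centers[j, 1], p, Eb[1])
                            _fill_e(la, lb, Pz - centers[i, 2], Pz - centers[j, 2], p, Eb[2])
                            for pc_ in range(nprim[k]):
                                ak = exps[ptr[k] + pc_]
                                ck = coefs[ptr[k] + pc_]
                                for pd_ in range(nprim[l]):
                                    al = exps[ptr[l] + pd_]
                                    cl = coefs[ptr[l] + pd_]
                                    q = ak + al
                                    Kcd = math.exp(-ak * al / q * CD2)
                                    cc = ci * cj * ck * cl * Kab * Kcd
                                    if abs(cc) < screen:
                                        continue
                                    Qx = (ak * centers[k, 0] + al * centers[l, 0]) / q
                                    Qy = (ak * centers[k, 1] + al * centers[l, 1]) / q
                                    Qz = (ak * centers[k, 2] + al * centers[l, 2]) / q
                                    _fill_e(lc, ld, Qx - centers[k, 0], Qx - centers[l, 0], q, Ek[0])
                                    _fill_e(lc, ld, Qy - centers[k, 1], Qy - centers[l, 1], q, Ek[1])
                                    _fill_e(lc, ld, Qz - centers[k, 2], Qz - centers[l, 2], q, Ek[2])
                                    alpha = p * q / (p + q)
                                    _fill_r(ltot, alpha, Px - Qx, Py - Qy, Pz - Qz, R4)
                                    pref = cc * twopi52 / (p * q * math.sqrt(p + q))
                                    any_prim = True
                                    for ia in range(na):
                                        ax = comps[comp_off[la] + ia, 0]
                                        ay = comps[comp_off[la] + ia, 1]
                                        az = comps[comp_off[la] + ia, 2]
                                        for ib in range(nb):
                                            bx = comps[comp_off[lb] + ib, 0]
                                            by = comps[comp_off[lb] + ib, 1]
                                            bz = comps[comp_off[lb] + ib, 2]
                                            for ic in range(nc):
                                                cx = comps[comp_off[lc] + ic, 0]
                                                cy = comps[comp_off[lc] + ic, 1]
                                                cz = comps[comp_off[lc] + ic, 2]
                                                for id_ in range(nd):
                                                    dx = comps[comp_off[ld] + id_, 0]
                                                    dy = comps[comp_off[ld] + id_, 1]
                                                    dz = comps[comp_off[ld] + id_, 2]
                                                    val = 0.0
                                                    for t in range(ax + bx + 1):
                                                        ebx = Eb[0, ax, bx, t]
                                                        if ebx == 0.0:
                                                            continue
                                                        for u in range(ay + by + 1):
                                                            eby = Eb[1, ay, by, u]
                                                            if eby == 0.0:
                                                                continue
                                                            for v in range(az + bz + 1):
                                                                ebz = Eb[2, az, bz, v]
                                                                if ebz == 0.0:
                                                                    continue
                                                                acc = 0.0
                                                                for tt in range(cx + dx + 1):
                                                                    ekx = Ek[0, cx, dx, tt]
                                                                    if ekx == 0.0:
                                                                        continue
                                                                    for uu in range(cy + dy + 1):
                                                                        eky = Ek[1, cy, dy, uu]
                                                                        if eky == 0.0:
                                                                            continue
                                                                        for vv in range(cz + dz + 1):
                                                                            ekz = Ek[2, cz, dz, vv]
                                                                            if ekz == 0.0:
                                                                                continue
                                                                            sgn = 1.0 if (tt + uu + vv) % 2 == 0 else -1.0
                                                                            acc += sgn * ekx * eky * ekz * R4[0, t + tt, u + uu, v + vv]
                                                                acc *= ebx * eby * ebz
                                                                val += acc
                                                    blk[ia, ib, ic, id_] += pref * val
                    if not any_prim:
                        continue
                    oa, ob = cart_off[i], cart_off[j]
                    oc, od = cart_off[k], cart_off[l]
                    for ia in range(na):
                        for ib in range(nb):
                            for ic in range(nc):
                                for id_ in range(nd):
                                    v = blk[ia, ib, ic, id_]
                                    G[oa + ia, ob + ib, oc + ic, od + id_] = v
                                    G[ob + ib, oa + ia, oc + ic, od + id_] = v
                                    G[oa + ia, ob + ib, od + id_, oc + ic] = v
                                    G[ob + ib, oa + ia, od + id_, oc + ic] = v
                                    G[oc + ic, od + id_, oa + ia, ob + ib] = v
                                    G[od + id_, oc + ic, oa + ia, ob + ib] = v
                                    G[oc + ic, od + id_, ob + ib, oa + ia] = v
                                    G[od + id_, oc + ic, ob + ib, oa + ia] = v
    return G


@njit(cache=True)
def _nuclear_cart(ls, nprim, ptr, exps, coefs, centers, cart_off,
                  comp_off, comps, nuc_xyz, nuc_z):
    ns = ls.shape[0]
    ncart = cart_off[ns]
    V = np.zeros((ncart, ncart))
    E3 = np.empty((3, 4, 4, 7))
    R4 = np.empty((13, 13, 13, 13))
    for i in range(ns):
        la = ls[i]
        na = comp_off[la + 1] - comp_off[la]
        for j in range(i + 1):
            lb = ls[j]
            nb = comp_off[lb + 1] - comp_off[lb]
            AB2 = 0.0
            for d in range(3):
                AB2 += (centers[i, d] - centers[j, d]) ** 2
            blk = np.zeros((na, nb))
            for pa_ in range(nprim[i]):
                ai = exps[ptr[i] + pa_]
                ci = coefs[ptr[i] + pa_]
                for pb_ in range(nprim[j]):
                    aj = exps[ptr[j] + pb_]
                    cj = coefs[ptr[j] + pb_]
                    p = ai + aj
                    Kab = math.exp(-ai * aj / p * AB2)
                    cc = ci * cj * Kab
                    if abs(cc) < 1e-16:
                        continue
                    Px = (ai * centers[i, 0] + aj * centers[j, 0]) / p
                    Py = (ai * centers[i, 1] + aj * centers[j, 1]) / p
                    Pz = (ai * centers[i, 2] + aj * centers[j, 2]) / p
                    _fill_e(la, lb, Px - centers[i, 0], Px - centers[j, 0], p, E3[0])
                    _fill_e(la, lb, Py - centers[i, 1], Py - centers[j, 1], p, E3[1])
                    _fill_e(la, lb, Pz - centers[i, 2], Pz - centers[j, 2], p, E3[2])
                    pref = cc * 2.0 * math.pi / p
                    for inuc in range(nuc_z.shape[0]):
                        _fill_r(la + lb, p,
                                Px - nuc_xyz[inuc, 0], Py - nuc_xyz[inuc, 1],
                                Pz - nuc_xyz[inuc, 2], R4)
                        zfac = -nuc_z[inuc] * pref
                        for ia in range(na):
                            ax = comps[comp_off[la] + ia, 0]
                            ay = comps[comp_off[la] + ia, 1]
                            az = comps[comp_off[la] + ia, 2]
                            for ib in range(nb):
                                bx = comps[comp_off[lb] + ib, 0]
                                by = comps[comp_off[lb] + ib, 1]
                                bz = comps[comp_off[lb] + ib, 2]
                                val = 0.0
                                for t in range(ax + bx + 1):
                                    for u in range(ay + by + 1):
                                        for v in range(az + bz + 1):
                                            e = E3[0, ax, bx, t] * E3[1, ay, by, u] * E3[2, az, bz, v]
                                            if e != 0.0:
                                                val += e * R4[0, t, u, v]
                                blk[ia, ib] += zfac * val
            oa, ob = cart_off[i], cart_off[j]
            for ia in range(na):
                for ib in range(nb):
                    V[oa + ia, ob + ib] = blk[ia, ib]
                    V[ob + ib, oa + ia] = blk[ia, ib]
    return V


def eri_tensor(shells: list[Shell], T: np.ndarray, screen: float = 1e-14) -> np.ndarray:
    """Full (ao ao | ao ao) tensor in chemists' notation."""
    ls, nprim, ptr, exps, coefs, centers, cart_off = flatten_shells(shells)
    G = _eri_cart(ls, nprim, ptr, exps, coefs, centers, cart_off,
                  _COMP_OFFSETS, _COMPS_FLAT, screen)
    for axis in range(4):
        G = np.tensordot(G, T, axes=([0], [0]))
    return G


def nuclear_attraction(shells: list[Shell], T: np.ndarray,
                       nuc_xyz: np.ndarray, nuc_z: np.ndarray) -> np.ndarray:
    ls, nprim, ptr, exps, coefs, centers, cart_off = flatten_shells(shells)
    V = _nuclear_cart(ls, nprim, ptr, exps, coefs, centers, cart_off,
                      _COMP_OFFSETS, _COMPS_FLAT,
                      np.asarray(nuc_xyz, float), np.asarray(nuc_z, float))
    return T.T @ V @ T


def nuclear_repulsion(nuc_xyz: np.ndarray, nuc_z: np.ndarray) -> float:
    e = 0.0
    for i in range(len(nuc_z)):
        for j in range(i):
            e += nuc_z[i] * nuc_z[j] / np.linalg.norm(nuc_xyz[i] - nuc_xyz[j])
    return e
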