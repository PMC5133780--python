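"""Analytic model wavefunctions for engine-free testing.

These fixtures are real Gaussian-basis wavefunctions — they satisfy every
container invariant exactly by construction and can be evaluated at points,
serialized to Molden, and pushed through the whole response pipeline —
but their orbital energies are synthetic, chosen only to be well-separated.
"""

from __future__ import annotations

import math

import numpy as np

from . import gto
from .basis import Shell
from .molecule import Molecule
from .wavefunction import WavefunctionData


def _wfn_from(mol, shells, C, eps, nocc, note):
    T, _ = gto.build_transform(shells)
    S = gto.overlap_matrix(shells, T)
    occ = np.zeros(C.shape[1])
    occ[:nocc] = 2.0
    return WavefunctionData(mol=mol, shells=shells, C=C, eps=np.asarray(eps, float),
                            occ=occ, S=S, method={"backend": "model", "note": note})


def make_h2_minimal(ao_overlap: float = 0.6593) -> WavefunctionData:
    """Symmetric two-AO, two-electron model with tunable AO overlap.

    Two unit-exponent 1s Gaussians at the distance that makes their overlap
    equal ``ao_overlap``; bonding MO occupied (eps = -0.5), antibonding
    virtual (eps = +0.5). The Mayer bond order is exactly 1 for any overlap,
    and the bond-order response vanishes identically: the single pair's
    bonding-antibonding product contributes no net off-diagonal response.
    """
    s = float(ao_overlap)
    if not 0.0 < s < 1.0:
        raise ValueError(f"ao_overlap must lie in (0, 1), got {s}")
    # <g(1)|g(1)> overlap of two normalized a=1 s-Gaussians at distance R
    R = math.sqrt(-2.0 * math.log(s))
    mol = Molecule(("H", "H"), np.array([[0.0, 0.0, 0.0], [0.0, 0.0, R]]))
    shells = [Shell(0, np.array([1.0]), np.array([1.0]), mol.coords[i], i)
              for i in range(2)]
    C = np.column_stack([
        np.array([1.0, 1.0]) / math.sqrt(2.0 * (1.0 + s)),
        np.array([1.0, -1.0]) / math.sqrt(2.0 * (1.0 - s)),
    ])
    return _wfn_from(mol, shells, C, [-0.5, 0.5], nocc=1,
                     note=f"h2-minimal s={s}")


def make_random_model(n_ao: int, n_occ: int, seed: int) -> WavefunctionData:
    """Seeded random s-Gaussian model wavefunction with exact invariants.

    n_ao centers in a ~2 Bohr cluster, one s AO each; the MO matrix is the
    S^-1/2-orthogonalized image of a seeded random matrix and the orbital
    energies increase strictly with gaps >= 0.05 hartree.
    """
    if not (0 < n_occ < n_ao <= 12):
        raise ValueError("require 0 < n_occ < n_ao <= 12")
    rng = np.random.default_rng(seed)
    centers = rng.normal(scale=1.2, size=(n_ao, 3))
    exps = rng.uniform(0.5, 1.8, size=n_ao)
    symbols = tuple("H" for _ in range(n_ao))
    mol = Molecule(symbols, centers, charge=n_ao - 2 * n_occ)
    shells = [Shell(0, np.array([exps[i]]), np.array([1.0]), mol.coords[i], i)
              for i in range(n_ao)]
    T, _ = gto.build_transform(shells)
    S = gto.overlap_matrix(shells, T)
    M = rng.normal(size=(n_ao, n_ao))
    # S-orthogonalization: C = M (M^T S M)^{-1/2}
    A = M.T @ S @ M
    aval, avec = np.linalg.eigh(A)
    C = M @ avec @ np.diag(aval**-0.5) @ avec.T
    gaps = 0.05 + rng.uniform(0.0, 0.1, size=n_ao - 1)
    eps = np.concatenate([[-1.0], -1.0 + np.cumsum(gaps)])
    occ = np.zeros(n_ao)
    occ[:n_occ] = 2.0
    return WavefunctionData(mol=mol, shells=shells, C=C, eps=eps, occ=occ, S=S,
                            method={"backend": "model",
                                    "note": f"random n_ao={n_ao} n_occ={n_occ} seed={seed}"})


def make_ethylene_like() -> WavefunctionData:
    """Planar two-center model with one occupied pi MO.

    Two centers on the x axis, each carrying an s shell and a p shell; the
    occupied space is the s-bonding (sigma) and pz-bonding (pi) combination
    with respect to the z = 0 plane. The symmetry blocks (s/px, py, pz) are
    mutually S-orthogonal, so normalizing each symmetry-adapted column gives
    exact orthonormal MOs.
    """
    mol = Molecule(("He", "He"), np.array([[-0.7, 0.0, 0.0], [0.7, 0.0, 0.0]]))
    shells = []
    for i in range(2):
        shells.append(Shell(0, np.array([0.9]), np.array([1.0]), mol.coords[i], i))
        shells.append(Shell(1, np.array([0.7]), np.array([1.0]), mol.coords[i], i))
    # AO order per center: s, px, py, pz -> total 8
    T, _ = gto.build_transform(shells)
    S = gto.overlap_matrix(shells, T)

    def col(vals):
        v = np.zeros(8)
        for idx, c in vals:
            v[idx] = c
        return v

    s1, x1, y1, z1 = 0, 1, 2, 3
    s2, x2, y2, z2 = 4, 5, 6, 7
    guesses = [
        col([(s1, 1), (s2, 1)]),          # sigma bond (occ)
        col([(z1, 1), (z2, 1)]),          # pi bond (occ)
        col([(s1, 1), (s2, -1)]),         # sigma*
        col([(z1, 1), (z2, -1)]),         # pi*
        col([(x1, 1), (x2, 1)]),          # sigma (p along axis)
        col([(x1, 1), (x2, -1)]),
        col([(y1, 1), (y2, 1)]),          # in-plane pi-like, even under z-mirror
        col([(y1, 1), (y2, -1)]),
    ]
    C = np.zeros((8, 8))
    for k, g in enumerate(guesses):
        C[:, k] = g
    # symmetric orthogonalization within the (s, px) block; other blocks are
    # already orthogonal by symmetry, normalize all columns against S
    A = C.T @ S @ C
    aval, avec = np.linalg.eigh(A)
    C = C @ avec @ np.diag(aval**-0.5) @ avec.T
    eps = np.array([-1.0, -0.6, 0.3, 0.5, 0.7, 0.9, 1.1, 1.3])
    return _wfn_from(mol, shells, C, eps, nocc=2, note="ethylene-like")
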