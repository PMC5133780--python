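"""Density-matrix algebra: P, Q = PS, Mayer bond orders, Mulliken charges.

The Mayer bond order B_IJ = sum_{mu in I, nu in J} Q_munu Q_numu is the
density-matrix bond multiplicity the response engine differentiates.
Diagonal (I = J) entries are kept: the pointwise sum rule over all atom
pairs, including the diagonal, is what vanishes identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .basis import AOBasisMap
from .molecule import Molecule
from .wavefunction import WavefunctionData

_DIFFUSE_MARKERS = ("+", "aug")


@dataclass(frozen=True)
class DensityMatrices:
    """One-particle density matrix P and the Q = P S product."""

    P: np.ndarray
    Q: np.ndarray

    def validate(self, n_electrons: int, S: np.ndarray,
                 tol: float = 1e-8) -> None:
        if not np.allclose(self.P, self.P.T, atol=1e-8):
            raise ValueError("density matrix is not symmetric")
        tr = np.trace(self.Q)
        if abs(tr - n_electrons) > tol:
            raise ValueError(f"Tr(PS) = {tr} != electron count {n_electrons}")
        psp = self.P @ S @ self.P
        if np.abs(psp - 2.0 * self.P).max() > max(1e-6, 100 * tol):
            raise ValueError("closed-shell density is not idempotent (PSP != 2P)")


def density_matrix(wfn: WavefunctionData) -> DensityMatrices:
    """P = sum_occ 2 c_i c_i^T and Q = P S for a closed-shell wavefunction.

    The electron-count tolerance scales with the wavefunction's own MO
    orthonormality residual (file-precision wavefunctions carry rounding
    at the last stored digit; an exact wavefunction is held to 1e-8).
    """
    Cocc = wfn.C[:, wfn.occupied]
    P = 2.0 * Cocc @ Cocc.T
    dm = DensityMatrices(P=P, Q=q_matrix(P, wfn.S))
    resid = np.abs(Cocc.T @ wfn.S @ Cocc - np.eye(Cocc.shape[1])).max()
    tol = max(1e-8, 5.0 * Cocc.shape[1] * resid)
    dm.validate(wfn.mol.n_electrons, wfn.S, tol=tol)
    return dm


def q_matrix(P: np.ndarray, S: np.ndarray) -> np.ndarray:
    P = np.asarray(P, float)
    S = np.asarray(S, float)
    if P.shape != S.shape or P.shape[0] != P.shape[1]:
        raise ValueError("P and S must be conformable square matrices")
    return P @ S


@dataclass(frozen=True)
class BondOrderTable:
    """Symmetric atom x atom Mayer bond-order matrix (diagonal included)."""

    values: np.ndarray  # (natom, natom)
    labels: tuple[str, ...]

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def bonded_pairs(self, threshold: float = 0.3) -> list[tuple[int, int]]:
        """Atom pairs I < J with B_IJ above the reporting threshold."""
        n = self.values.shape[0]
        return [(i, j) for i in range(n) for j in range(i + 1, n)
                if self.values[i, j] > threshold]

    def to_csv(self, path) -> None:
        self.as_dataframe().to_csv(path)


def _atom_blocks(aomap: AOBasisMap, natom: int) -> list[np.ndarray]:
    return [aomap.aos_of_atom(a) for a in range(natom)]


def mayer_bond_orders(Q: np.ndarray, aomap: AOBasisMap, mol: Molecule) -> BondOrderTable:
    """B_IJ = sum_{mu in I, nu in J} Q_munu Q_numu for all pairs incl. I = J."""
    if Q.shape[0] != aomap.nao:
        raise ValueError("AO map does not cover the Q matrix dimension")
    natom = mol.natom
    QQt = Q * Q.T  # elementwise Q_munu * Q_numu
    B = np.zeros((natom, natom))
    blocks = _atom_blocks(aomap, natom)
    for i in range(natom):
        for j in range(natom):
            B[i, j] = QQt[np.ix_(blocks[i], blocks[j])].sum()
    labels = tuple(mol.atom_label(i) for i in range(natom))
    return BondOrderTable(0.5 * (B + B.T), labels)


def mulliken_charges(Q: np.ndarray, aomap: AOBasisMap, mol: Molecule) -> np.ndarray:
    """q_A = Z_A - sum_{mu in A} Q_mumu (gross atomic populations)."""
    if Q.shape[0] != aomap.nao:
        raise ValueError("AO map does not cover the Q matrix dimension")
    pops = np.array([Q.diagonal()[aomap.aos_of_atom(a)].sum()
                     for a in range(mol.natom)])
    return np.array(mol.atomic_numbers, float) - pops


def warn_if_diffuse(basis_name: str) -> None:
    """Mulliken populations degrade badly with diffuse functions; warn."""
    if any(m in basis_name.lower() for m in _DIFFUSE_MARKERS):
        warnings.warn(
            f"basis {basis_name!r} contains diffuse functions; Mulliken-type "
            "population analysis (and descriptors built on it) is unreliable "
            "with diffuse augmentation", stacklevel=2)
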