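"""Closed-shell wavefunction container with hard validation.

Every producer (the built-in SCF engine, the Molden reader, the analytic
model fixtures) returns a :class:`WavefunctionData`; every consumer may rely
on the invariants checked in :meth:`WavefunctionData.validate`:
orthonormality of the MOs against the AO overlap, the electron count, and
restricted double occupations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import AOBasisMap, Shell, build_ao_map
from .molecule import Molecule, UnsupportedSystemError


@dataclass
class WavefunctionData:
    """Restricted closed-shell MOs over a Gaussian AO basis."""

    mol: Molecule
    shells: list[Shell]
    C: np.ndarray          # (nao, nmo) MO coefficients
    eps: np.ndarray        # (nmo,) orbital energies, hartree
    occ: np.ndarray        # (nmo,) occupation numbers (2 or 0)
    S: np.ndarray          # (nao, nao) AO overlap
    ao_map: AOBasisMap = None
    method: dict = field(default_factory=dict)
    energy: float | None = None

    def __post_init__(self):
        self.C = np.asarray(self.C, float)
        self.eps = np.asarray(self.eps, float)
        self.occ = np.asarray(self.occ, float)
        self.S = np.asarray(self.S, float)
        if self.ao_map is None:
            self.ao_map = build_ao_map(self.shells)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self, ortho_tol: float = 1e-6) -> None:
        nao, nmo = self.C.shape
        if self.S.shape != (nao, nao):
            raise ValueError("overlap matrix does not match AO dimension")
        if self.ao_map.nao != nao:
            raise ValueError("AO->atom map does not cover the AO basis")
        if not np.allclose(self.S, self.S.T, atol=1e-10):
            raise ValueError("overlap matrix is not symmetric")
        if np.linalg.eigvalsh(self.S).min() <= 0:
            raise ValueError("overlap matrix is not positive definite")
        resid = np.abs(self.C.T @ self.S @ self.C - np.eye(nmo)).max()
        if resid > ortho_tol:
            raise ValueError(
                f"MOs are not orthonormal against S (residual {resid:.2e} > "
                f"{ortho_tol:.0e}); corrupt input or mismatched convention"
            )
        if not np.all(np.isin(self.occ, (0.0, 2.0))):
            raise UnsupportedSystemError(
                "occupations must be 0 or 2 (restricted closed shell)"
            )
        if abs(self.occ.sum() - self.mol.n_electrons) > 1e-8:
            raise ValueError(
                f"occupations sum to {self.occ.sum()}, expected "
                f"{self.mol.n_electrons} electrons"
            )
        if self.eps.shape != (nmo,):
            raise ValueError("orbital energy vector has wrong length")

    # -- convenience --------------------------------------------------------
    @property
    def nao(self) -> int:
        return self.C.shape[0]

    @property
    def nmo(self) -> int:
        return self.C.shape[1]

    @property
    def n_occ(self) -> int:
        return int(round(self.occ.sum() / 2))

    @property
    def occupied(self) -> np.ndarray:
        return np.flatnonzero(self.occ > 1.0)

    @property
    def virtual(self) -> np.ndarray:
        return np.flatnonzero(self.occ < 1.0)

    def eval_mos(self, points: np.ndarray, mo_indices=None) -> np.ndarray:
        """MO amplitudes at Cartesian points (Bohr); shape (npoints, nmo_sel)."""
        from .gto import eval_aos

        ao = eval_aos(self.shells, np.asarray(points, float))
        C = self.C if mo_indices is None else self.C[:, mo_indices]
        return ao @ C
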