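"""Molecular geometry container and XYZ input.

Coordinates are stored in Bohr. XYZ files are read in Angstrom, the
universal convention for that format. The closed-shell restriction of the
whole package is enforced here: any molecule with multiplicity other than 1
is rejected up front.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .elements import symbol_to_z
from .units import ANGSTROM_TO_BOHR


class UnsupportedSystemError(ValueError):
    """Raised for systems outside the closed-shell restricted scope."""


@dataclass(frozen=True)
class Molecule:
    """A molecule: element symbols, coordinates (Bohr), charge, multiplicity."""

    symbols: tuple[str, ...]
    coords: np.ndarray  # (natom, 3), Bohr
    charge: int = 0
    multiplicity: int = 1
    atomic_numbers: tuple[int, ...] = field(init=False)

    def __post_init__(self):
        if len(self.symbols) == 0:
            raise ValueError("a molecule needs at least one atom")
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (len(self.symbols), 3):
            raise ValueError(
                f"coordinate array shape {coords.shape} does not match "
                f"{len(self.symbols)} atoms"
            )
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        object.__setattr__(self, "coords", coords)
        zs = tuple(symbol_to_z(s) for s in self.symbols)
        object.__setattr__(self, "atomic_numbers", zs)
        object.__setattr__(
            self, "symbols", tuple(s.strip().capitalize() for s in self.symbols)
        )
        if self.multiplicity != 1:
            raise UnsupportedSystemError(
                "only closed-shell (multiplicity 1) systems are supported; "
                f"got multiplicity {self.multiplicity}"
            )
        if self.n_electrons % 2 != 0:
            raise UnsupportedSystemError(
                f"odd electron count ({self.n_electrons}) cannot be closed-shell"
            )

    @property
    def natom(self) -> int:
        return len(self.symbols)

    @property
    def n_electrons(self) -> int:
        return int(sum(self.atomic_numbers) - self.charge)

    def atom_label(self, i: int) -> str:
        """1-based label in input order, e.g. 'O1', 'H2'."""
        return f"{self.symbols[i]}{i + 1}"

    def distance_matrix(self) -> np.ndarray:
        d = self.coords[:, None, :] - self.coords[None, :, :]
        return np.linalg.norm(d, axis=-1)

    def translated(self, shift) -> "Molecule":
        return Molecule(self.symbols, self.coords + np.asarray(shift, float),
                        self.charge, self.multiplicity)


def load_xyz(path) -> Molecule:
    """Read a standard XYZ file (Angstrom).

    The comment line may carry ``charge=<int>`` and ``multiplicity=<int>``
    tokens; absent those, a neutral singlet is assumed.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    try:
        natom = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ValueError(f"{path}: line 1 must start with the atom count") from None
    if len(lines) < 2 + natom:
        raise ValueError(f"{path}: expected {natom} atom lines, file too short")

    charge, multiplicity = 0, 1
    for tok in lines[1].split():
        low = tok.lower()
        if low.startswith("charge="):
            charge = int(tok.split("=", 1)[1])
        elif low.startswith("multiplicity=") or low.startswith("mult="):
            multiplicity = int(tok.split("=", 1)[1])

    symbols, coords = [], []
    for ln in range(2, 2 + natom):
        parts = lines[ln].split()
        if len(parts) < 4:
            raise ValueError(f"{path}: malformed atom line {ln + 1}: {lines[ln]!r}")
        sym = parts[0]
        symbol_to_z(sym)  # validates; raises for unknown elements
        try:
            xyz = [float(p) for p in parts[1:4]]
        except ValueError:
            raise ValueError(
                f"{path}: non-numeric coordinate on line {ln + 1}: {lines[ln]!r}"
            ) from None
        symbols.append(sym)
        coords.append(xyz)

    coords_bohr = np.asarray(coords, float) * ANGSTROM_TO_BOHR
    return Molecule(tuple(symbols), coords_bohr, charge, multiplicity)


def dump_xyz(mol: Molecule, path, comment: str = "") -> None:
    """Write a molecule to XYZ (Angstrom), embedding charge/multiplicity."""
    tokens = f"charge={mol.charge} multiplicity={mol.multiplicity}"
    if comment:
        tokens = f"{comment} {tokens}"
    with open(path, "w") as fh:
        fh.write(f"{mol.natom}\n{tokens}\n")
        for sym, xyz in zip(mol.symbols, mol.coords / ANGSTROM_TO_BOHR):
            fh.write(f"{sym:<3s} {xyz[0]:18.10f} {xyz[1]:18.10f} {xyz[2]:18.10f}\n")
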