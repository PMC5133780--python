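"""Gaussian basis sets: text-file parsing and per-molecule shell lists.

Basis files live in ``lrfbo/data/basis`` in a small line-oriented format::

    element O
    S 6
      8588.5000000   0.0018951
      ...
    D 1
      1.2920000      1.0000000
    end

Contraction coefficients follow the universal published convention: they
multiply *normalized* primitives. Shared-exponent SP blocks of Pople sets
are written as separate S and P shells with identical exponents, which is
numerically identical.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .molecule import Molecule

L_LABELS = "spdfgh"
L_OF_LABEL = {c: i for i, c in enumerate(L_LABELS)}


@dataclass(frozen=True)
class Shell:
    """One contracted shell on one atomic center."""

    l: int
    exponents: np.ndarray
    coefficients: np.ndarray  # normalized-primitive convention
    center: np.ndarray  # (3,), Bohr
    atom_index: int
    pure: bool = True  # spherical (2l+1) vs Cartesian components

    @property
    def nfunc(self) -> int:
        if self.pure or self.l < 2:
            return 2 * self.l + 1
        return (self.l + 1) * (self.l + 2) // 2


@dataclass(frozen=True)
class AOBasisMap:
    """Per-AO metadata: owning atom, angular label, shell index."""

    atom_of_ao: np.ndarray  # int, (nao,)
    l_label_of_ao: tuple[str, ...]
    shell_of_ao: np.ndarray  # int, (nao,)

    @property
    def nao(self) -> int:
        return self.atom_of_ao.size

    def aos_of_atom(self, atom: int) -> np.ndarray:
        return np.flatnonzero(self.atom_of_ao == atom)


def _basis_dir():
    return resources.files("lrfbo").joinpath("data").joinpath("basis")


def available_basis_sets() -> list[str]:
    return sorted(
        p.name[: -len(".txt")] for p in _basis_dir().iterdir() if p.name.endswith(".txt")
    )


def _normalize_name(name: str) -> str:
    name = name.lower().replace("**", "ss").replace("*", "s").replace("+", "p")
    return re.sub(r"[^a-z0-9]", "", name)


def parse_basis_text(text: str) -> dict[str, list[tuple[int, np.ndarray, np.ndarray]]]:
    """Parse the basis file format into {element: [(l, exps, coefs), ...]}."""
    table: dict[str, list] = {}
    element = None
    lines = [ln.split("!")[0].strip() for ln in text.splitlines()]
    i = 0
    while i < len(lines):
        ln = lines[i]
        i += 1
        if not ln:
            continue
        low = ln.lower()
        if low.startswith("element"):
            element = ln.split()[1].capitalize()
            table[element] = []
        elif low == "end":
            element = None
        else:
            m = re.fullmatch(r"([SPDFspdf])\s+(\d+)", ln)
            if not m:
                raise ValueError(f"cannot parse basis line: {ln!r}")
            if element is None:
                raise ValueError("shell block outside an element block")
            l = L_OF_LABEL[m.group(1).lower()]
            nprim = int(m.group(2))
            exps, coefs = [], []
            for _ in range(nprim):
                parts = lines[i].split()
                i += 1
                exps.append(float(parts[0]))
                coefs.append(float(parts[1]))
            table[element].append((l, np.array(exps), np.array(coefs)))
    return table


def load_basis_table(name: str):
    """Load a shipped basis set by name (e.g. '6-311G**', 'STO-3G')."""
    want = _normalize_name(name)
    for p in _basis_dir().iterdir():
        if p.name.endswith(".txt") and _normalize_name(p.name[:-4]) == want:
            return parse_basis_text(p.read_text())
    raise ValueError(
        f"basis set {name!r} not in the shipped library "
        f"(available: {', '.join(available_basis_sets())})"
    )


def build_shells(mol: Molecule, basis_name: str, pure: bool = True) -> list[Shell]:
    """Assign shells of a named basis set to every atom of a molecule."""
    table = load_basis_table(basis_name)
    shells: list[Shell] = []
    for ia, sym in enumerate(mol.symbols):
        if sym not in table:
            raise ValueError(
                f"basis {basis_name!r} has no entry for element {sym}; "
                "heavier elements need basis data that is not shipped"
            )
        for l, exps, coefs in table[sym]:
            shells.append(Shell(l, exps, coefs, mol.coords[ia], ia, pure=pure))
    return shells


def build_ao_map(shells: list[Shell]) -> AOBasisMap:
    atoms, labels, shell_ids = [], [], []
    for isig, sh in enumerate(shells):
        for _ in range(sh.nfunc):
            atoms.append(sh.atom_index)
            labels.append(L_LABELS[sh.l])
            shell_ids.append(isig)
    return AOBasisMap(np.array(atoms, dtype=int), tuple(labels), np.array(shell_ids, dtype=int))
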