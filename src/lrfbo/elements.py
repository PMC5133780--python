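"""Periodic-table lookups used across the package.

Only a modest element range is needed (organic main group plus the
halogens); anything outside the table raises rather than guessing.
"""

from __future__ import annotations

_SYMBOLS = [
    "H", "He",
    "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar",
    "K", "Ca", "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
    "Ga", "Ge", "As", "Se", "Br", "Kr",
    "Rb", "Sr", "Y", "Zr", "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd",
    "In", "Sn", "Sb", "Te", "I", "Xe",
    "Cs", "Ba", "La", "Ce", "Pr", "Nd", "Pm", "Sm", "Eu", "Gd", "Tb", "Dy",
    "Ho", "Er", "Tm", "Yb", "Lu", "Hf", "Ta", "W", "Re", "Os", "Ir", "Pt",
    "Au", "Hg", "Tl", "Pb", "Bi", "Po", "At", "Rn",
]

SYMBOL_TO_Z = {s: i + 1 for i, s in enumerate(_SYMBOLS)}
Z_TO_SYMBOL = {z: s for s, z in SYMBOL_TO_Z.items()}

#: Bragg–Slater atomic radii in Angstrom (Slater's empirical set; hydrogen
#: enlarged to 0.35 A as is customary in molecular quadrature schemes).
BRAGG_SLATER_RADII = {
    "H": 0.35, "He": 0.31,
    "Li": 1.45, "Be": 1.05, "B": 0.85, "C": 0.70, "N": 0.65, "O": 0.60,
    "F": 0.50, "Ne": 0.38,
    "Na": 1.80, "Mg": 1.50, "Al": 1.25, "Si": 1.10, "P": 1.00, "S": 1.00,
    "Cl": 1.00, "Ar": 0.71,
    "K": 2.20, "Ca": 1.80, "Fe": 1.40, "Cu": 1.35, "Zn": 1.35,
    "Br": 1.15, "Kr": 0.88,
    "I": 1.40, "Xe": 1.08,
    "Pt": 1.35, "Au": 1.35,
}


def symbol_to_z(symbol: str) -> int:
    """Atomic number for an element symbol (case-normalized)."""
    key = symbol.strip().capitalize()
    try:
        return SYMBOL_TO_Z[key]
    except KeyError:
        raise ValueError(f"unknown element symbol: {symbol!r}") from None


def bragg_slater_radius_bohr(symbol: str) -> float:
    """Bragg–Slater radius in Bohr, defaulting to 1.0 A for unlisted elements."""
    from .units import ANGSTROM_TO_BOHR

    key = symbol.strip().capitalize()
    return BRAGG_SLATER_RADII.get(key, 1.0) * ANGSTROM_TO_BOHR
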