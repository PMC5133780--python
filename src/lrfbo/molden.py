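"""Molden-format wavefunction exchange (read and write).

Molden carries geometry, the Gaussian basis and MO coefficients in one
portable text file, which makes it the natural interchange format for
precomputed wavefunctions. Only restricted closed-shell files are
accepted: any beta-spin block or fractional occupation is rejected. The
AO overlap matrix is always recomputed analytically from the parsed basis
and the MO orthonormality is validated before a wavefunction is returned,
so a corrupt file or a mismatched angular-momentum convention fails loudly
rather than producing silently wrong descriptors.

Conventions: [5D]/[7F] flags select real-spherical d/f shells (the order
m = 0, +1, -1, +2, -2, ...); without them d/f shells are Cartesian in the
Molden component order. p shells are always (x, y, z).
"""

from __future__ import annotations

import numpy as np

from . import gto
from .basis import Shell, build_ao_map
from .elements import Z_TO_SYMBOL, symbol_to_z
from .molecule import Molecule, UnsupportedSystemError
from .units import ANGSTROM_TO_BOHR
from .wavefunction import WavefunctionData

_L_OF_CHAR = {"s": 0, "p": 1, "d": 2, "f": 3}


def write_molden(wfn: WavefunctionData, path, precision: int = 10) -> None:
    """Serialize a closed-shell wavefunction to a Molden file."""
    mol = wfn.mol
    fmt = f"%.{precision}e"
    with open(path, "w") as fh:
        fh.write("[Molden Format]\n[Title]\n written by lrfbo\n")
        fh.write("[Atoms] AU\n")
        for ia, sym in enumerate(mol.symbols):
            x, y, z = mol.coords[ia]
            fh.write(f"{sym:<3s} {ia + 1:4d} {mol.atomic_numbers[ia]:4d} "
                     f"{x:18.10f} {y:18.10f} {z:18.10f}\n")
        fh.write("[GTO]\n")
        for ia in range(mol.natom):
            fh.write(f"  {ia + 1} 0\n")
            for sh in wfn.shells:
                if sh.atom_index != ia:
                    continue
                label = "spdf"[sh.l]
                fh.write(f" {label}   {len(sh.exponents)} 1.00\n")
                for a, c in zip(sh.exponents, sh.coefficients):
                    fh.write(f"   {fmt % a}  {fmt % c}\n")
            fh.write("\n")
        if any(sh.pure for sh in wfn.shells):
            fh.write("[5D]\n[7F]\n")
        fh.write("[MO]\n")
        for m in range(wfn.nmo):
            fh.write(" Sym= A\n")
            fh.write(f" Ene= {fmt % wfn.eps[m]}\n")
            fh.write(" Spin= Alpha\n")
            fh.write(f" Occup= {wfn.occ[m]:.6f}\n")
            for mu in range(wfn.nao):
                fh.write(f" {mu + 1:4d}  {fmt % wfn.C[mu, m]}\n")


def read_molden(path, ortho_tol: float = 1e-4) -> WavefunctionData:
    """Parse a Molden file into a validated closed-shell wavefunction."""
    with open(path) as fh:
        text = fh.read()
    lines = text.splitlines()

    # split into sections
    sections: dict[str, list[str]] = {}
    flags = set()
    current = None
    for ln in lines:
        stripped = ln.strip()
        if stripped.startswith("["):
            tag = stripped.split("]")[0].strip("[ ").lower()
            rest = stripped.split("]", 1)[1].strip() if "]" in stripped else ""
            if tag in ("5d", "7f", "9g", "5d7f", "5d10f"):
                flags.add(tag)
                current = None
                continue
            current = tag
            sections[current] = [rest] if rest else []
        elif current is not None:
            sections[current].append(ln)
    if "molden format" not in sections and "molden" not in " ".join(lines[:2]).lower():
        raise ValueError(f"{path}: missing [Molden Format] header")
    for req in ("atoms", "gto", "mo"):
        if req not in sections:
            raise ValueError(f"{path}: missing [{req.upper()}] section")

    pure = "5d" in flags or "5d7f" in flags

    # [Atoms]
    atom_lines = [ln for ln in sections["atoms"] if ln.strip()]
    unit = "au"
    if atom_lines and atom_lines[0].strip().lower() in ("au", "angs", "(au)", "(angs)"):
        unit = atom_lines.pop(0).strip().lower().strip("()")
    # unit may also ride on the section header line
    hdr = sections["atoms"][0].strip().lower() if sections["atoms"] else ""
    if hdr in ("au", "angs"):
        unit = hdr
        atom_lines = [ln for ln in sections["atoms"][1:] if ln.strip()]
    symbols, coords = [], []
    for ln in atom_lines:
        parts = ln.split()
        if len(parts) < 6:
            raise ValueError(f"{path}: malformed [Atoms] line: {ln!r}")
        sym = parts[0]
        z = int(parts[2])
        if symbol_to_z(sym) != z:
            sym = Z_TO_SYMBOL[z]
        symbols.append(sym)
        coords.append([float(p) for p in parts[3:6]])
    coords = np.asarray(coords)
    if unit == "angs":
        coords = coords * ANGSTROM_TO_BOHR

    # [GTO]
    shells: list[Shell] = []
    glines = [ln for ln in sections["gto"]]
    i = 0
    atom_idx = None
    while i < len(glines):
        ln = glines[i].strip()
        i += 1
        if not ln:
            atom_idx = None
            continue
        parts = ln.split()
        if atom_idx is None:
            atom_idx = int(parts[0]) - 1
            continue
        ltok = parts[0].lower()
        if ltok == "sp":
            nprim = int(parts[1])
            exps, cs, cp = [], [], []
            for _ in range(nprim):
                p = glines[i].replace("D", "E").replace("d", "e").split()
                i += 1
                exps.append(float(p[0]))
                cs.append(float(p[1]))
                cp.append(float(p[2]))
            for l, cc in ((0, cs), (1, cp)):
                shells.append(Shell(l, np.array(exps), np.array(cc),
                                    coords[atom_idx], atom_idx, pure=pure))
            continue
        if ltok not in _L_OF_CHAR:
            raise ValueError(f"{path}: unsupported shell type {ltok!r}")
        nprim = int(parts[1])
        exps, cc = [], []
        for _ in range(nprim):
            p = glines[i].replace("D", "E").replace("d", "e").split()
            i += 1
            exps.append(float(p[0]))
            cc.append(float(p[1]))
        shells.append(Shell(_L_OF_CHAR[ltok], np.array(exps), np.array(cc),
                            coords[atom_idx], atom_idx, pure=pure))

    # [MO]
    eps, occs, cols = [], [], []
    cur_coeffs = {}
    cur = {"ene": 0.0, "occ": 0.0, "spin": "alpha"}

    def flush():
        if cur_coeffs:
            if cur["spin"] != "alpha":
                raise UnsupportedSystemError(
                    f"{path}: beta-spin orbitals present; only restricted "
                    "closed-shell files are supported")
            eps.append(cur["ene"])
            occs.append(cur["occ"])
            cols.append(dict(cur_coeffs))

    for ln in sections["mo"]:
        s = ln.strip()
        if not s:
            continue
        low = s.lower()
        if low.startswith(("sym=", "ene=", "spin=", "occup=")):
            key, val = s.split("=", 1)
            key = key.strip().lower()
            if key == "ene":
                flush()
                cur_coeffs.clear()
                cur["ene"] = float(val)
            elif key == "occup":
                cur["occ"] = float(val)
            elif key == "spin":
                cur["spin"] = val.strip().lower()
        else:
            parts = s.split()
            cur_coeffs[int(parts[0]) - 1] = float(parts[1])
    flush()

    nao = sum(sh.nfunc for sh in shells)
    C = np.zeros((nao, len(cols)))
    for m, col in enumerate(cols):
        for mu, v in col.items():
            if mu >= nao:
                raise ValueError(f"{path}: MO coefficient index {mu + 1} exceeds "
                                 f"AO count {nao} (wrong d/f convention?)")
            C[mu, m] = v

    occ = np.asarray(occs, float)
    if np.any(np.abs(occ - np.round(occ)) > 1e-6) or np.any((occ != 0) & (np.abs(occ - 2) > 1e-6)):
        raise UnsupportedSystemError(
            f"{path}: fractional or single occupations found; only restricted "
            "closed-shell wavefunctions are supported")
    occ = np.round(occ)

    charge = int(round(sum(symbol_to_z(s) for s in symbols) - occ.sum()))
    mol = Molecule(tuple(symbols), coords, charge=charge, multiplicity=1)
    T, _ = gto.build_transform(shells)
    S = gto.overlap_matrix(shells, T)

    wfn = WavefunctionData.__new__(WavefunctionData)
    wfn.mol = mol
    wfn.shells = shells
    wfn.C = C
    wfn.eps = np.asarray(eps, float)
    wfn.occ = occ
    wfn.S = S
    wfn.ao_map = build_ao_map(shells)
    wfn.method = {"backend": "molden", "source": str(path), "pure": pure}
    wfn.energy = None
    try:
        wfn.validate(ortho_tol=ortho_tol)
    except ValueError as exc:
        raise ValueError(
            f"{path}: wavefunction failed validation against the recomputed "
            f"overlap ({exc}); the file may be corrupt or use a different "
            "normalization/angular convention") from None
    return wfn
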