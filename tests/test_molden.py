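"""Molden exchange: round trips, convention handling, corruption detection."""

import numpy as np
import pytest

from lrfbo import density_matrix, mayer_bond_orders
from lrfbo.basis import Shell, build_ao_map
from lrfbo.gto import build_transform, overlap_matrix
from lrfbo.molden import read_molden, write_molden
from lrfbo.molecule import Molecule, UnsupportedSystemError
from lrfbo.wavefunction import WavefunctionData


def test_round_trip_preserves_wavefunction(tmp_path, water_wfn):
    p = tmp_path / "water.molden"
    write_molden(water_wfn, p, precision=12)
    back = read_molden(p)
    np.testing.assert_allclose(back.C, water_wfn.C, atol=1e-8)
    np.testing.assert_allclose(back.eps, water_wfn.eps, atol=1e-8)
    np.testing.assert_array_equal(back.occ, water_wfn.occ)
    assert back.mol.symbols == water_wfn.mol.symbols


def test_round_trip_preserves_bond_orders(tmp_path, water_wfn):
    p = tmp_path / "water.molden"
    write_molden(water_wfn, p, precision=12)
    back = read_molden(p)
    b1 = mayer_bond_orders(density_matrix(water_wfn).Q, water_wfn.ao_map,
                           water_wfn.mol).values
    b2 = mayer_bond_orders(density_matrix(back).Q, back.ao_map, back.mol).values
    np.testing.assert_allclose(b1, b2, atol=1e-6)


def test_model_wavefunction_round_trip(tmp_path, ethylene_model):
    p = tmp_path / "eth.molden"
    write_molden(ethylene_model, p, precision=12)
    back = read_molden(p)
    np.testing.assert_allclose(back.C, ethylene_model.C, atol=1e-10)


def _one_atom_d_wfn(pure: bool):
    sym, nfunc = ("Ne", 5) if pure else ("Mg", 6)
    mol = Molecule((sym,), np.zeros((1, 3)))
    shells = [Shell(2, np.array([0.9]), np.array([1.0]), mol.coords[0], 0,
                    pure=pure)]
    T, _ = build_transform(shells)
    S = overlap_matrix(shells, T)
    sval, svec = np.linalg.eigh(S)
    C = svec / np.sqrt(sval)
    occ = np.full(nfunc, 2.0)
    eps = np.linspace(-1.0, 0.0, nfunc)
    return WavefunctionData(mol=mol, shells=shells, C=C, eps=eps, occ=occ, S=S,
                            ao_map=build_ao_map(shells))


@pytest.mark.parametrize("pure,expected_nao", [(True, 5), (False, 6)])
def test_d_shell_convention_sets_ao_count(tmp_path, pure, expected_nao):
    """[5D] files give 5 AOs per d shell; Cartesian files give 6."""
    wfn = _one_atom_d_wfn(pure)
    p = tmp_path / "d.molden"
    write_molden(wfn, p, precision=12)
    text = p.read_text()
    assert ("[5D]" in text) == pure
    back = read_molden(p)
    assert back.nao == expected_nao
    np.testing.assert_allclose(back.C, wfn.C, atol=1e-10)


def test_corrupt_coefficients_fail_validation(tmp_path, ethylene_model):
    p = tmp_path / "bad.molden"
    write_molden(ethylene_model, p, precision=12)
    lines = p.read_text().splitlines()
    for i, ln in enumerate(lines):
        if ln.strip().startswith("1 ") and "e" in ln:  # first MO coefficient
            lines[i] = "  1  4.75"
            break
    p.write_text("\n".join(lines))
    with pytest.raises(ValueError, match="validation"):
        read_molden(p)


def test_beta_spin_block_rejected(tmp_path, ethylene_model):
    p = tmp_path / "beta.molden"
    write_molden(ethylene_model, p, precision=12)
    p.write_text(p.read_text().replace("Spin= Alpha", "Spin= Beta", 1))
    with pytest.raises(UnsupportedSystemError, match="closed-shell"):
        read_molden(p)


def test_fractional_occupation_rejected(tmp_path, ethylene_model):
    p = tmp_path / "frac.molden"
    write_molden(ethylene_model, p, precision=12)
    p.write_text(p.read_text().replace("Occup= 2.000000", "Occup= 1.000000", 1))
    with pytest.raises(UnsupportedSystemError, match="occupations"):
        read_molden(p)


def test_missing_sections_reported(tmp_path):
    p = tmp_path / "empty.molden"
    p.write_text("[Molden Format]\n[Atoms] AU\nH 1 1 0 0 0\n")
    with pytest.raises(ValueError, match="GTO"):
        read_molden(p)
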