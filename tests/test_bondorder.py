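"""Density-matrix algebra: closed forms, conservation laws, equivariance."""

import numpy as np
import pytest

from lrfbo import (density_matrix, make_h2_minimal, make_random_model,
                   mayer_bond_orders, mulliken_charges, q_matrix)
from lrfbo.bondorder import warn_if_diffuse
from lrfbo.wavefunction import WavefunctionData


@pytest.mark.parametrize("s", [0.2, 0.5, 0.8])
def test_h2_minimal_closed_forms(s):
    """P = ones/(1+s), Q = ones, B(H-H) = 1 exactly, for any AO overlap."""
    wfn = make_h2_minimal(s)
    dm = density_matrix(wfn)
    np.testing.assert_allclose(dm.P, np.ones((2, 2)) / (1 + s), atol=1e-12)
    np.testing.assert_allclose(dm.Q, np.ones((2, 2)), atol=1e-12)
    bo = mayer_bond_orders(dm.Q, wfn.ao_map, wfn.mol)
    assert bo.values[0, 1] == pytest.approx(1.0, abs=1e-12)


def test_q_matrix_identity_and_shape_check():
    np.testing.assert_array_equal(q_matrix(np.eye(3), np.eye(3)), np.eye(3))
    with pytest.raises(ValueError, match="conformable"):
        q_matrix(np.eye(3), np.eye(4))


def test_electron_count_and_trace_identities(water_wfn, water_response):
    dm = water_response["dm"]
    assert np.trace(dm.Q) == pytest.approx(10.0, abs=1e-8)
    bo = mayer_bond_orders(dm.Q, water_wfn.ao_map, water_wfn.mol)
    # sum over ALL atom pairs including diagonal equals Tr(Q^2)
    assert bo.values.sum() == pytest.approx(np.trace(dm.Q @ dm.Q), abs=1e-8)
    # ... which is 2 x electron count for an idempotent closed-shell density
    assert bo.values.sum() == pytest.approx(2 * 10.0, abs=1e-6)


def test_water_oh_bonds_symmetric(water_wfn, water_response):
    bo = mayer_bond_orders(water_response["dm"].Q, water_wfn.ao_map, water_wfn.mol)
    assert bo.values[0, 1] == pytest.approx(bo.values[0, 2], abs=1e-6)
    assert 0.7 < bo.values[0, 1] < 1.2  # a single covalent O-H bond


def test_bond_order_permutation_equivariance():
    """Relabeling atoms permutes the table without changing its content."""
    wfn = make_random_model(6, 2, seed=9)
    dm = density_matrix(wfn)
    bo = mayer_bond_orders(dm.Q, wfn.ao_map, wfn.mol).values
    perm = np.array([3, 1, 5, 0, 2, 4])  # new order of old atoms
    # one s AO per atom here, so the AO permutation equals the atom permutation
    from lrfbo.basis import Shell, build_ao_map
    from lrfbo.molecule import Molecule

    mol2 = Molecule(tuple(wfn.mol.symbols[p] for p in perm),
                    wfn.mol.coords[perm], wfn.mol.charge)
    shells2 = [Shell(0, wfn.shells[p].exponents, wfn.shells[p].coefficients,
                     mol2.coords[i], i) for i, p in enumerate(perm)]
    wfn2 = WavefunctionData(mol=mol2, shells=shells2, C=wfn.C[perm],
                            eps=wfn.eps, occ=wfn.occ,
                            S=wfn.S[np.ix_(perm, perm)])
    bo2 = mayer_bond_orders(density_matrix(wfn2).Q, wfn2.ao_map, wfn2.mol).values
    np.testing.assert_allclose(bo2, bo[np.ix_(perm, perm)], atol=1e-10)


def test_mulliken_charges_conservation_and_symmetry(water_wfn, water_response):
    q = mulliken_charges(water_response["dm"].Q, water_wfn.ao_map, water_wfn.mol)
    assert q.sum() == pytest.approx(0.0, abs=1e-8)
    assert q[1] == pytest.approx(q[2], abs=1e-6)
    assert q[0] < 0 < q[1]  # polar O-H bonds: negative O, positive H


def test_h2_charges_vanish():
    wfn = make_h2_minimal(0.4)
    q = mulliken_charges(density_matrix(wfn).Q, wfn.ao_map, wfn.mol)
    np.testing.assert_allclose(q, 0.0, atol=1e-8)


def test_bond_order_csv_labels(tmp_path, water_wfn, water_response):
    bo = mayer_bond_orders(water_response["dm"].Q, water_wfn.ao_map, water_wfn.mol)
    out = tmp_path / "bo.csv"
    bo.to_csv(out)
    header = out.read_text().splitlines()[0]
    assert header.split(",")[1:] == ["O1", "H2", "H3"]


def test_diffuse_basis_warning():
    with pytest.warns(UserWarning, match="diffuse"):
        warn_if_diffuse("6-311++G**")
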