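"""Reflection-parity classification and channel decomposition."""

import numpy as np
import pytest

from lrfbo import (build_pair_basis, build_partitioned_grid, density_matrix,
                   lrf_density_condensed, pair_bond_weights, region_overlaps)
from lrfbo.molecule import Molecule, load_xyz
from lrfbo.sigma_pi import (MolecularPlane, classify_orbitals,
                            decompose_response, detect_molecular_plane)
from tests.conftest import data_path

Z_PLANE = MolecularPlane(np.zeros(3), np.array([0.0, 0.0, 1.0]), 0.0,
                         is_linear=True)


def test_water_plane_found_with_all_atoms_in_it():
    mol = Molecule(("O", "H", "H"),
                   np.array([[0.0, 0, 0], [0, 1.43, 1.11], [0, -1.43, 1.11]]))
    pl = detect_molecular_plane(mol)
    assert pl is not None and not pl.is_linear
    dev = np.abs((mol.coords - pl.point) @ pl.normal)
    assert dev.max() < 1e-6


def test_trienol_planar_hexanol_not():
    tri = load_xyz(data_path("geometries", "hexatrienol.xyz"))
    hexa = load_xyz(data_path("geometries", "hexan-1-ol.xyz"))
    assert detect_molecular_plane(tri) is not None
    assert detect_molecular_plane(hexa) is None  # sp3 chain


def test_diatomic_gets_linear_flag():
    mol = Molecule(("H", "H"), np.array([[0.0, 0, 0], [0, 0, 1.4]]))
    pl = detect_molecular_plane(mol)
    assert pl.is_linear
    assert abs(pl.normal @ np.array([0.0, 0, 1.0])) < 1e-10  # contains axis


def test_ethylene_model_has_exactly_one_occupied_pi(ethylene_model):
    labels = classify_orbitals(ethylene_model, Z_PLANE)
    occ_labels = [labels.labels[i] for i in ethylene_model.occupied]
    assert occ_labels.count("pi") == 1
    assert len(labels.labels) == ethylene_model.nmo  # every MO labelled once
    assert set(labels.labels) <= {"sigma", "pi", "mixed"}


def test_parity_scores_match_bruteforce_reflection(ethylene_model, rng):
    """Labelled orbitals really are even/odd under the explicit mirror."""
    labels = classify_orbitals(ethylene_model, Z_PLANE)
    pts = rng.normal(scale=1.2, size=(40, 3))
    psi = ethylene_model.eval_mos(pts)
    psi_ref = ethylene_model.eval_mos(Z_PLANE.reflect(pts))
    for m, lab in enumerate(labels.labels):
        if lab == "sigma":
            np.testing.assert_allclose(psi_ref[:, m], psi[:, m], atol=1e-10)
        elif lab == "pi":
            np.testing.assert_allclose(psi_ref[:, m], -psi[:, m], atol=1e-10)


def test_tilted_plane_produces_mixed_labels_with_warning(ethylene_model):
    tilted = MolecularPlane(np.zeros(3),
                            np.array([0.0, np.sin(0.6), np.cos(0.6)]), 0.0)
    with pytest.warns(UserWarning, match="mixed"):
        labels = classify_orbitals(ethylene_model, tilted)
    assert len(labels.mixed_indices()) > 0


def test_channel_additivity_is_exact_and_cross_vanishes(ethylene_model):
    dm = density_matrix(ethylene_model)
    pairs = build_pair_basis(ethylene_model)
    w = pair_bond_weights(ethylene_model, dm, pairs)
    g = build_partitioned_grid(ethylene_model.mol, 40, 110)
    ov = region_overlaps(ethylene_model, g)
    labels = classify_orbitals(ethylene_model, Z_PLANE)

    total_d = lrf_density_condensed(pairs, ov)
    ch_d = decompose_response("density", labels, pairs, ov)
    summed = sum(t.values for t in ch_d.values())
    np.testing.assert_allclose(summed, total_d.values, atol=1e-14)
    # in-plane atoms have mirror-symmetric cells: the cross channel vanishes
    assert np.abs(ch_d["cross"].values).max() < 1e-3

    from lrfbo import lrf_bo_condensed
    total_b = lrf_bo_condensed(w, pairs, ov)
    ch_b = decompose_response("bond_order", labels, pairs, ov, weights=w)
    summed_b = sum(t.values for t in ch_b.values())
    np.testing.assert_allclose(summed_b, total_b.values, atol=1e-14)


def test_bond_order_decomposition_requires_weights(ethylene_model):
    pairs = build_pair_basis(ethylene_model)
    g = build_partitioned_grid(ethylene_model.mol, 30, 110)
    ov = region_overlaps(ethylene_model, g)
    labels = classify_orbitals(ethylene_model, Z_PLANE)
    with pytest.raises(ValueError, match="weights"):
        decompose_response("bond_order", labels, pairs, ov)
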