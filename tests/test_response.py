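"""The response engine: pair structure, exact identities, oracle agreement."""

import numpy as np
import pytest

from lrfbo import (build_pair_basis, build_partitioned_grid, density_matrix,
                   lrf_bo_condensed, lrf_bo_pointwise, lrf_density_condensed,
                   make_random_model, pair_bond_weights, region_overlaps,
                   sum_rule_report)
from lrfbo.response import (DegenerateGapError, pointwise_total_residual)


def test_pair_enumeration_and_denominators(water_wfn):
    pairs = build_pair_basis(water_wfn)
    assert pairs.npair == 5 * (water_wfn.nmo - 5)
    assert np.all(pairs.denom < 0)  # eps_occ < eps_virt for the ground state


def test_degenerate_homo_lumo_gap_is_a_hard_error(random_model):
    import copy

    wfn = copy.copy(random_model)
    eps = random_model.eps.copy()
    eps[3] = eps[2] + 1e-9  # close the gap between HOMO (2) and LUMO (3)
    wfn.eps = eps
    with pytest.raises(DegenerateGapError, match="degeneracy threshold"):
        build_pair_basis(wfn)


def test_energy_window_truncation_is_recorded(water_wfn):
    full = build_pair_basis(water_wfn)
    trunc = build_pair_basis(water_wfn, energy_window=2.0)
    assert trunc.npair < full.npair
    assert trunc.metadata["n_truncated"] == full.npair - trunc.npair


def test_pair_weight_trace_identity_and_symmetry(water_response):
    w = water_response["weights"].w
    # sum over ALL atom pairs (incl. diagonal) vanishes for every pair
    assert np.abs(w.sum(axis=(1, 2))).max() < 1e-10
    np.testing.assert_allclose(w, w.transpose(0, 2, 1), atol=1e-12)


def test_h2_bond_response_vanishes_everywhere(h2_model, rng):
    dm = density_matrix(h2_model)
    pairs = build_pair_basis(h2_model)
    w = pair_bond_weights(h2_model, dm, pairs)
    assert np.abs(w.w[:, 0, 1]).max() < 1e-12
    pts = rng.normal(scale=1.5, size=(12, 3))
    vals = lrf_bo_pointwise(h2_model, dm, pairs, w, pts, [(0, 1)])
    assert np.abs(vals).max() < 1e-12
    g = build_partitioned_grid(h2_model.mol, 30, 110)
    tbl = lrf_bo_condensed(w, pairs, region_overlaps(h2_model, g))
    assert np.abs(tbl.values[0, 1, :]).max() < 1e-12


def test_factorized_equals_unfactorized_pointwise(water_wfn, water_response, rng):
    dm, pairs, w = (water_response[k] for k in ("dm", "pairs", "weights"))
    pts = rng.normal(scale=1.5, size=(20, 3))
    atom_pairs = [(0, 1), (0, 2), (1, 2), (0, 0)]
    a = lrf_bo_pointwise(water_wfn, dm, pairs, w, pts, atom_pairs)
    b = lrf_bo_pointwise(water_wfn, dm, pairs, w, pts, atom_pairs,
                         unfactorized=True)
    np.testing.assert_allclose(a, b, atol=1e-10)


def test_pointwise_total_sum_vanishes(water_wfn, water_response, rng):
    """Sum over all atom pairs incl. I=J of dB_IJ/dv(r) is an exact zero."""
    dm, pairs, w = (water_response[k] for k in ("dm", "pairs", "weights"))
    pts = rng.normal(scale=2.0, size=(10, 3))
    assert pointwise_total_residual(water_wfn, dm, pairs, w, pts) < 1e-9


def test_condensed_row_sums_vanish_to_grid_accuracy(water_response):
    tbl = lrf_bo_condensed(water_response["weights"], water_response["pairs"],
                           water_response["overlaps"])
    assert np.abs(tbl.row_sums()).max() < 2e-2
    # symmetric under I <-> J
    np.testing.assert_allclose(tbl.values, tbl.values.transpose(1, 0, 2),
                               atol=1e-12)


def test_water_c2v_symmetry_of_response(water_response):
    tbl = lrf_bo_condensed(water_response["weights"], water_response["pairs"],
                           water_response["overlaps"])
    # dB(O-H1)/dv(H2) = dB(O-H2)/dv(H1) by C2v symmetry
    assert tbl.values[0, 1, 2] == pytest.approx(tbl.values[0, 2, 1], abs=1e-3)
    # the bonded-cell response is negative, the remote-cell one positive
    assert tbl.values[0, 1, 1] < 0 < tbl.values[0, 1, 2]
    assert tbl.values[0, 1, 0] > 0


def test_density_response_symmetric_with_nonpositive_diagonal(random_model):
    dm = density_matrix(random_model)
    pairs = build_pair_basis(random_model)
    g = build_partitioned_grid(random_model.mol, 50, 194)
    ov = region_overlaps(random_model, g)
    tbl = lrf_density_condensed(pairs, ov)
    np.testing.assert_allclose(tbl.values, tbl.values.T, atol=1e-10)
    assert np.all(np.diag(tbl.values) <= 1e-12)


def test_sum_rule_report_flags_and_fields(water_wfn, water_response, rng):
    tbl = lrf_bo_condensed(water_response["weights"], water_response["pairs"],
                           water_response["overlaps"])
    rep = sum_rule_report(tbl, water_wfn, water_response["dm"],
                          water_response["pairs"], water_response["weights"],
                          sample_points=rng.normal(scale=2.0, size=(8, 3)))
    assert rep["max_row_residual"] < 2e-2
    assert rep["flagged"] is False
    assert rep["max_pointwise_total"] < 1e-9


def test_condensed_rejects_mismatched_mo_spaces(water_response, random_model):
    pairs = build_pair_basis(random_model)  # 8-MO pair basis
    with pytest.raises(ValueError, match="MO space"):
        lrf_bo_condensed(water_response["weights"], pairs,
                         water_response["overlaps"])


def test_bit_reproducible_condensation(random_model):
    dm = density_matrix(random_model)
    pairs = build_pair_basis(random_model)
    w = pair_bond_weights(random_model, dm, pairs)
    g1 = build_partitioned_grid(random_model.mol, 30, 110)
    g2 = build_partitioned_grid(random_model.mol, 30, 110)
    t1 = lrf_bo_condensed(w, pairs, region_overlaps(random_model, g1))
    t2 = lrf_bo_condensed(w, pairs, region_overlaps(random_model, g2))
    np.testing.assert_array_equal(t1.values, t2.values)
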