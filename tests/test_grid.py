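"""Wigner-Seitz partitioned quadrature: counts, ownership, completeness."""

import math

import numpy as np
import pytest

from lrfbo import build_partitioned_grid, make_random_model, region_overlaps
from lrfbo.grid import (angular_quadrature, radial_quadrature,
                        region_overlaps_crosscheck, wigner_seitz_owner)
from lrfbo.molecule import Molecule


@pytest.fixture(scope="module")
def water_mol():
    return Molecule(("O", "H", "H"),
                    np.array([[0.0, 0, 0], [0, 1.43, 1.11], [0, -1.43, 1.11]]))


def test_point_count_is_natom_x_radial_x_angular(water_mol):
    g = build_partitioned_grid(water_mol, 75, 302)
    assert g.points.shape == (3 * 75 * 302, 3)
    assert g.base_weights.shape == (3 * 75 * 302,)


def test_unsupported_lebedev_order_lists_choices(water_mol):
    with pytest.raises(ValueError, match="302"):
        build_partitioned_grid(water_mol, 75, 300)
    with pytest.raises(ValueError, match="at least 10"):
        build_partitioned_grid(water_mol, 5, 302)


def test_midpoint_tie_breaks_to_lowest_index():
    mol = Molecule(("H", "H"), np.array([[0.0, 0, 0], [0, 0, 1.4]]))
    owner = wigner_seitz_owner(mol, np.array([[0.0, 0.0, 0.7]]))
    assert owner[0] == 0


def test_ownership_invariant_under_rigid_translation(water_mol, rng):
    pts = rng.normal(scale=2.0, size=(50, 3))
    shift = np.array([3.3, -1.1, 0.7])
    o1 = wigner_seitz_owner(water_mol, pts)
    o2 = wigner_seitz_owner(water_mol.translated(shift), pts + shift)
    np.testing.assert_array_equal(o1, o2)


def test_effective_weights_are_hard(water_mol):
    """Hard cells: every weight is either 0 or exactly the base weight."""
    g = build_partitioned_grid(water_mol, 30, 110)
    eff = g.effective_weights
    assert np.all((eff == 0.0) | (eff == g.base_weights))
    # each atom keeps points in its own cell
    for ia in range(3):
        assert np.any((g.center == ia) & (eff > 0))


def test_radial_quadrature_integrates_gaussian():
    """integral_0^inf exp(-r^2) r^2 dr = sqrt(pi)/4."""
    r, w = radial_quadrature(75, 1.0)
    assert w @ np.exp(-r**2) == pytest.approx(math.sqrt(math.pi) / 4, rel=1e-10)


def test_angular_quadrature_integrates_harmonics():
    pts, w = angular_quadrature(302)
    assert w.sum() == pytest.approx(4 * math.pi, rel=1e-12)
    # x^2 over the sphere: 4 pi / 3
    assert w @ pts[:, 0] ** 2 == pytest.approx(4 * math.pi / 3, rel=1e-12)


def test_cell_completeness_for_atom_centered_gaussians(water_mol):
    """A normalized s-Gaussian on each atom integrates to ~1 over the
    union of hard cells (the cells tile space)."""
    g = build_partitioned_grid(water_mol, 75, 302)
    eff = g.effective_weights
    live = eff > 0
    for ia in range(3):
        d2 = ((g.points[live] - water_mol.coords[ia]) ** 2).sum(1)
        alpha = 1.0
        val = (alpha / math.pi) ** 1.5 * np.exp(-alpha * d2)
        assert eff[live] @ val == pytest.approx(1.0, abs=1e-3)


def test_region_overlap_residual_shrinks_with_refinement(random_model):
    resids = []
    for n_rad, order in [(30, 110), (50, 194), (75, 302)]:
        g = build_partitioned_grid(random_model.mol, n_rad, order)
        resids.append(region_overlaps(random_model, g).orthonormality_residual())
    # non-increasing within 10% at each standard refinement step
    assert resids[1] <= 1.1 * resids[0]
    assert resids[2] <= 1.1 * resids[1]
    assert resids[2] < 2e-2


def test_region_overlaps_symmetry_and_completeness(h2_model):
    g = build_partitioned_grid(h2_model.mol, 50, 194)
    ov = region_overlaps(h2_model, g)
    np.testing.assert_allclose(ov.G, ov.G.transpose(0, 2, 1), atol=1e-14)
    # homonuclear mirror symmetry: |G| blocks agree between the two atoms
    np.testing.assert_allclose(np.abs(ov.G[0]), np.abs(ov.G[1]), atol=2e-3)
    assert ov.orthonormality_residual() < 2e-2


def test_crosscheck_estimate_agrees_with_production_path(random_model):
    """The owner-binned average over all centers' grids is an independent
    (coarser) estimate of the same cell integrals; the two routes agree
    within the discretization error of the coarser one."""
    g = build_partitioned_grid(random_model.mol, 50, 194)
    ov = region_overlaps(random_model, g)
    alt = region_overlaps_crosscheck(random_model, g)
    alt_resid = np.abs(alt.sum(axis=0) - np.eye(alt.shape[1])).max()
    tol = 3 * max(ov.orthonormality_residual(), alt_resid, 1e-3)
    assert np.abs(alt - ov.G).max() < tol


def test_grid_rejects_foreign_molecule(random_model, h2_model):
    g = build_partitioned_grid(h2_model.mol, 30, 110)
    with pytest.raises(ValueError, match="different molecule"):
        region_overlaps(random_model, g)
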