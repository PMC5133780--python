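"""Sign semantics, ranking, and the Hammett regression layer."""

import numpy as np
import pytest

from lrfbo.analysis import (HammettRecord, hammett_report, interpret_sign,
                            linear_fit, rank_leaving_groups)
from lrfbo.response import CondensedLRF


@pytest.mark.parametrize("value,pert,expected", [
    (+1.5, "repulsive", "increase"),
    (+1.5, "attractive", "decrease"),
    (-1.5, "repulsive", "decrease"),
    (-1.5, "attractive", "increase"),
])
def test_sign_table_all_four_cells(value, pert, expected):
    assert interpret_sign(value, pert) == expected


def test_sign_edge_cases():
    assert interpret_sign(0.0, "repulsive") == "no first-order change"
    with pytest.raises(ValueError, match="finite"):
        interpret_sign(np.nan, "repulsive")
    with pytest.raises(ValueError, match="repulsive"):
        interpret_sign(1.0, "sideways")


def _bond_table(values, labels):
    n = len(labels)
    v = np.zeros((n, n, n))
    for (i, j, l), x in values.items():
        v[i, j, l] = v[j, i, l] = x
    return CondensedLRF("bond_order", v, tuple(labels))


def test_ranking_orders_by_self_perturbation_with_index_ties():
    tbl = _bond_table({(0, 1, 1): 6.0, (0, 2, 2): 2.1, (0, 3, 3): 6.0},
                      ["Pt1", "Cl2", "N3", "Cl4"])
    ranked = rank_leaving_groups(tbl, [(0, 1), (0, 2), (0, 3)])
    assert [e["ligand"] for e in ranked] == ["Cl2", "Cl4", "N3"]
    assert [e["rank"] for e in ranked] == [1, 2, 3]
    # pure function: repeated evaluation gives the identical ranking
    assert ranked == rank_leaving_groups(tbl, [(0, 1), (0, 2), (0, 3)])


def test_ranking_validates_input():
    tbl = _bond_table({(0, 1, 1): 1.0}, ["A1", "B2"])
    with pytest.raises(ValueError, match="not present"):
        rank_leaving_groups(tbl, [(0, 5)])
    single = rank_leaving_groups(tbl, [(0, 1)])
    assert len(single) == 1 and single[0]["rank"] == 1
    from lrfbo.response import CondensedLRF as C
    dens = C("density", np.zeros((2, 2)), ("A1", "B2"))
    with pytest.raises(ValueError, match="bond-order"):
        rank_leaving_groups(dens, [(0, 1)])


def test_linear_fit_exact_on_collinear_points():
    fit = linear_fit([1.0, 2.0, 3.0], [5.0, 7.0, 9.0])
    assert fit["slope"] == pytest.approx(2.0, abs=1e-12)
    assert fit["intercept"] == pytest.approx(3.0, abs=1e-12)
    assert fit["r2"] == pytest.approx(1.0, abs=1e-12)
    assert fit["predict"](4.0) == pytest.approx(11.0)


def test_linear_fit_null_permutation_gives_low_r2():
    rng = np.random.default_rng(7)
    x = np.linspace(0, 1, 20)
    y = rng.permutation(x)
    assert linear_fit(x, y)["r2"] < 0.3


def test_linear_fit_r2_invariant_under_affine_rescaling():
    rng = np.random.default_rng(3)
    x = rng.normal(size=12)
    y = 2 * x + rng.normal(scale=0.3, size=12)
    r2a = linear_fit(x, y)["r2"]
    r2b = linear_fit(5.0 * x - 1.7, y)["r2"]
    assert r2a == pytest.approx(r2b, abs=1e-12)


def test_linear_fit_rejects_degenerate_input():
    with pytest.raises(ValueError, match="degenerate"):
        linear_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError, match="at least 3"):
        linear_fit([1.0, 2.0], [1.0, 2.0])


def test_charged_substituents_are_refused():
    with pytest.raises(ValueError, match="charge"):
        HammettRecord("NMe3+", "para", 0.82, {"H4": -1.0}, charge=1)


def test_hammett_report_structure_and_flags():
    rng = np.random.default_rng(11)
    records = []
    for pos in ("meta", "para"):
        for k in range(6):
            x = float(rng.normal())
            records.append(HammettRecord(
                f"X{pos}{k}", pos, sigma=0.8 * x + 0.1,
                descriptors={"H4": x, "C5": 1e-4 * x}))
    rep = hammett_report(records)
    # every (site, position) combination appears exactly once
    assert sorted(map(tuple, rep[["site", "position"]].values.tolist())) == [
        ("C5", "meta"), ("C5", "para"), ("H4", "meta"), ("H4", "para")]
    h4 = rep[rep.site == "H4"]
    assert (h4.r2 > 0.99).all()
    assert not h4.negligible_descriptor.any()
    # the tiny-magnitude site correlates equally well but is flagged
    assert rep[rep.site == "C5"].negligible_descriptor.all()


def test_hammett_report_degenerate_and_missing_site_errors():
    recs = [HammettRecord(f"A{k}", "meta", 0.1 * k, {"H4": 1.0})
            for k in range(4)]
    with pytest.raises(ValueError, match="degenerate"):
        hammett_report(recs)
    recs2 = [HammettRecord("A", "meta", 0.1, {"H4": 1.0, "C5": 0.2}),
             HammettRecord("B", "meta", 0.2, {"H4": 2.0}),
             HammettRecord("C", "meta", 0.3, {"H4": 3.0})]
    with pytest.raises(ValueError, match="missing"):
        hammett_report(recs2)
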