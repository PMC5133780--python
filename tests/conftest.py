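"""Shared fixtures: model wavefunctions, the water SCF run, shipped data."""

from importlib import resources

import numpy as np
import pytest

from lrfbo import (build_pair_basis, build_partitioned_grid, density_matrix,
                   make_ethylene_like, make_h2_minimal, make_random_model,
                   pair_bond_weights, region_overlaps)
from lrfbo.molden import read_molden
from lrfbo.molecule import load_xyz
from lrfbo.scf import run_scf


def data_path(*parts) -> str:
    p = resources.files("lrfbo").joinpath("data")
    for part in parts:
        p = p.joinpath(part)
    return str(p)


@pytest.fixture(scope="session")
def h2_model():
    return make_h2_minimal(0.5)


@pytest.fixture(scope="session")
def random_model():
    return make_random_model(8, 3, seed=42)


@pytest.fixture(scope="session")
def ethylene_model():
    return make_ethylene_like()


@pytest.fixture(scope="session")
def water_wfn():
    """B3LYP(VWN5)/6-311G** water at the shipped optimized geometry."""
    mol = load_xyz(data_path("geometries", "water.xyz"))
    return run_scf(mol, basis="6-311G**", method="b3lyp", b3lyp_flavor="vwn5")


@pytest.fixture(scope="session")
def water_response(water_wfn):
    """Density matrices, default grid, overlaps, pairs and weights for water."""
    dm = density_matrix(water_wfn)
    grid = build_partitioned_grid(water_wfn.mol, 75, 302)
    ov = region_overlaps(water_wfn, grid)
    pairs = build_pair_basis(water_wfn)
    weights = pair_bond_weights(water_wfn, dm, pairs)
    return {"dm": dm, "grid": grid, "overlaps": ov, "pairs": pairs,
            "weights": weights}


@pytest.fixture(scope="session")
def trienol_wfn():
    return read_molden(data_path("wavefunctions", "hexatrienol-b3lyp-sto3g.molden"))


@pytest.fixture(scope="session")
def hexanol_wfn():
    return read_molden(data_path("wavefunctions", "hexan-1-ol-b3lyp-sto3g.molden"))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
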