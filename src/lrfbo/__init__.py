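"""lrfbo: linear response functions of Mayer bond orders and density.

Real-space reactivity descriptors for closed-shell molecules: how every
Mayer bond order (and the atom-condensed electron density) responds to a
virtual local potential applied over an atom's Wigner–Seitz cell, computed
from the uncoupled orbital response of a converged single-determinant
wavefunction, with sigma/pi decomposition and a Hammett-regression
analysis layer.
"""

from .analysis import (HammettRecord, hammett_report, interpret_sign,
                       linear_fit, rank_leaving_groups)
from .basis import AOBasisMap, Shell
from .bondorder import (BondOrderTable, DensityMatrices, density_matrix,
                        mayer_bond_orders, mulliken_charges, q_matrix)
from .fixtures import make_ethylene_like, make_h2_minimal, make_random_model
from .grid import (PartitionedGrid, RegionOverlapTensor,
                   build_partitioned_grid, region_overlaps)
from .molden import read_molden, write_molden
from .molecule import Molecule, UnsupportedSystemError, dump_xyz, load_xyz
from .response import (CondensedLRF, DegenerateGapError, PairBasis,
                       PairWeights, build_pair_basis, lrf_bo_condensed,
                       lrf_bo_pointwise, lrf_density_condensed,
                       pair_bond_weights, sum_rule_report)
from .scf import SCFConvergenceError, optimize_geometry, run_scf
from .sigma_pi import (MolecularPlane, OrbitalSymmetryLabels,
                       classify_orbitals, decompose_response,
                       detect_molecular_plane)
from .wavefunction import WavefunctionData

__version__ = "0.1.0"

__all__ = [name for name in dir() if not name.startswith("_")]


def eval_mos(wfn: WavefunctionData, points) -> "np.ndarray":  # noqa: F821
    """MO amplitudes of a wavefunction at Cartesian points (Bohr)."""
    return wfn.eval_mos(points)
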