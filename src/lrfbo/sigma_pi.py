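"""Sigma/pi classification of MOs by reflection parity and channel splitting.

For a planar molecule every MO of the closed-shell determinant is (up to
numerical noise) either even (sigma) or odd (pi) under reflection through
the molecular plane. The parity score of an MO is the reflection overlap

    s_i = integral psi_i(r) psi_i(sigma_h r) dr   in [-1, 1],

evaluated by Becke-weighted quadrature; +1 is perfectly even, -1 perfectly
odd. Orbitals below the purity threshold in |score| are labelled 'mixed'
and reported rather than force-classified. Response tables are split at
the occupied-virtual pair level: a pair contributes to the pi channel when
both orbitals are pi, to sigma when both are sigma, and to the cross
channel otherwise, so sigma + pi + cross = total holds exactly by
construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grid import RegionOverlapTensor
from .molecule import Molecule
from .response import (CondensedLRF, PairBasis, PairWeights, lrf_bo_condensed,
                       lrf_density_condensed)
from .units import ANGSTROM_TO_BOHR
from .wavefunction import WavefunctionData

PURITY_THRESHOLD = 0.95


@dataclass(frozen=True)
class MolecularPlane:
    point: np.ndarray   # (3,), Bohr
    normal: np.ndarray  # (3,), unit
    rms: float          # Bohr, out-of-plane RMS of the fitted atoms
    is_linear: bool = False

    def reflect(self, pts: np.ndarray) -> np.ndarray:
        d = (pts - self.point) @ self.normal
        return pts - 2.0 * d[:, None] * self.normal


@dataclass(frozen=True)
class OrbitalSymmetryLabels:
    plane: MolecularPlane
    labels: tuple[str, ...]      # per MO: 'sigma' | 'pi' | 'mixed'
    scores: np.ndarray           # per MO reflection-parity score in [-1, 1]

    def mixed_indices(self) -> np.ndarray:
        return np.flatnonzero(np.array(self.labels) == "mixed")


def detect_molecular_plane(mol: Molecule, tol_angstrom: float = 1e-3
                           ) -> MolecularPlane | None:
    """Best-fit mirror plane through the heavy atoms (all atoms if < 3 heavy).

    Returns None when the molecule is not planar within the tolerance; for
    collinear molecules, returns a plane containing the axis with the
    ``is_linear`` flag set (sigma/pi remains well defined there).
    """
    if mol.natom < 2:
        raise ValueError("plane detection needs at least 2 atoms")
    heavy = [i for i, z in enumerate(mol.atomic_numbers) if z > 1]
    idx = heavy if len(heavy) >= 3 else list(range(mol.natom))
    pts = mol.coords[idx]
    centroid = pts.mean(axis=0)
    u, s, vt = np.linalg.svd(pts - centroid, full_matrices=True)
    sv = np.zeros(3)
    sv[:len(s)] = s
    n = len(idx)
    if sv[1] < 1e-8 * max(sv[0], 1.0) or len(idx) == 2:
        # collinear: any plane containing the axis; pick one deterministically
        axis = vt[0] if len(s) else np.array([0.0, 0.0, 1.0])
        trial = np.array([1.0, 0.0, 0.0])
        if abs(axis @ trial) > 0.9:
            trial = np.array([0.0, 1.0, 0.0])
        normal = np.cross(axis, trial)
        normal /= np.linalg.norm(normal)
        return MolecularPlane(centroid, normal, 0.0, is_linear=True)
    normal = vt[2]
    rms = float(np.sqrt(np.mean(((pts - centroid) @ normal) ** 2)))
    if rms > tol_angstrom * ANGSTROM_TO_BOHR:
        return None
    return MolecularPlane(centroid, normal / np.linalg.norm(normal), rms)


def classify_orbitals(wfn: WavefunctionData, plane: MolecularPlane,
                      purity_threshold: float = PURITY_THRESHOLD,
                      grid_size: tuple[int, int] = (40, 110)
                      ) -> OrbitalSymmetryLabels:
    """Reflection-parity scores and sigma/pi/mixed labels for every MO."""
    from .scf import becke_xc_grid

    pts, w = becke_xc_grid(wfn.mol, *grid_size)
    psi = wfn.eval_mos(pts)
    psi_ref = wfn.eval_mos(plane.reflect(pts))
    norm = np.einsum("g,gm,gm->m", w, psi, psi)
    cross = np.einsum("g,gm,gm->m", w, psi, psi_ref)
    scores = cross / norm
    labels = []
    for s in scores:
        if s >= purity_threshold:
            labels.append("sigma")
        elif s <= -purity_threshold:
            labels.append("pi")
        else:
            labels.append("mixed")
    labels = tuple(labels)
    mixed = [i for i, l in enumerate(labels) if l == "mixed"]
    if mixed:
        warnings.warn(
            f"{len(mixed)} MO(s) have impure reflection parity and are "
            f"labelled 'mixed': indices {mixed}", stacklevel=2)
    return OrbitalSymmetryLabels(plane, labels, scores)


def _channel_masks(labels: OrbitalSymmetryLabels, pairs: PairBasis):
    lab = np.array(labels.labels)
    li, lj = lab[pairs.occ_idx], lab[pairs.virt_idx]
    sig = (li == "sigma") & (lj == "sigma")
    pi = (li == "pi") & (lj == "pi")
    cross = ~(sig | pi)
    return {"sigma": sig, "pi": pi, "cross": cross}


def decompose_response(kind: str, labels: OrbitalSymmetryLabels,
                       pairs: PairBasis, overlaps: RegionOverlapTensor,
                       weights: PairWeights | None = None,
                       atom_labels=None) -> dict[str, CondensedLRF]:
    """Split a condensed response into sigma / pi / cross channels.

    kind: 'bond_order' (requires weights) or 'density'. The channels
    partition the occupied-virtual pairs, so they sum to the total table
    exactly. Pairs involving 'mixed' orbitals land in the cross channel and
    their weight fraction is attached as a contamination estimate.
    """
    masks = _channel_masks(labels, pairs)
    mixed_frac = float(np.mean(
        np.isin(pairs.occ_idx, labels.mixed_indices())
        | np.isin(pairs.virt_idx, labels.mixed_indices())))
    out: dict[str, CondensedLRF] = {}
    for channel, mask in masks.items():
        md = {"mixed_pair_fraction": mixed_frac}
        if kind == "bond_order":
            if weights is None:
                raise ValueError("bond-order decomposition needs pair weights")
            out[channel] = lrf_bo_condensed(weights, pairs, overlaps,
                                            labels=atom_labels, channel=channel,
                                            pair_mask=mask.astype(float),
                                            metadata=md)
        elif kind == "density":
            out[channel] = lrf_density_condensed(pairs, overlaps,
                                                 labels=atom_labels,
                                                 channel=channel,
                                                 pair_mask=mask.astype(float),
                                                 metadata=md)
        else:
            raise ValueError(f"unknown response kind {kind!r}")
    return out
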