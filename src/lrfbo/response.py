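"""The linear-response engine for Mayer bond orders and electron density.

Uncoupled (independent-particle) first-order response: a local external
potential delta-v mixes occupied orbital psi_i with virtual psi_j with
amplitude psi_i(r) psi_j(r) / (eps_i - eps_j). Propagating that through
Q = PS and the Mayer bond order B_IJ gives, per occupied-virtual pair, a
bond-resolved weight w^(ij)_IJ; condensing the perturbation over an atom's
Wigner–Seitz cell reduces to the region overlaps G[L, i, j]. The spin sum
of the restricted closed-shell determinant is a global factor 2.

Production path (factorized):

    dB_IJ/dv(L) = 2 sum_ij d_ij * w^(ij)_IJ * G[L, i, j]
    drho(K)/dv(L) = 4 sum_ij d_ij * G[K, i, j] * G[L, i, j]

A deliberately unfactorized pointwise path (build the Q-response matrix at
each point, then contract with Q) is retained as a brute-force oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bondorder import DensityMatrices
from .grid import RegionOverlapTensor
from .wavefunction import WavefunctionData

SPIN_FACTOR = 2.0
DEGENERACY_THRESHOLD = 1e-6  # hartree


class DegenerateGapError(ValueError):
    """Occupied-virtual orbital-energy gap below threshold: response diverges."""


@dataclass(frozen=True)
class PairBasis:
    """All occupied x virtual MO pairs with energy denominators 1/(eps_i-eps_j)."""

    occ_idx: np.ndarray       # (npair,)
    virt_idx: np.ndarray      # (npair,)
    denom: np.ndarray         # (npair,), hartree^-1, all negative
    metadata: dict = field(default_factory=dict)

    @property
    def npair(self) -> int:
        return self.denom.size


def build_pair_basis(wfn: WavefunctionData, energy_window: float | None = None,
                     degeneracy_threshold: float = DEGENERACY_THRESHOLD) -> PairBasis:
    """Enumerate occupied-virtual pairs; optionally truncate by gap energy."""
    occ, virt = wfn.occupied, wfn.virtual
    oi, vj = np.meshgrid(occ, virt, indexing="ij")
    oi, vj = oi.ravel(), vj.ravel()
    gaps = wfn.eps[oi] - wfn.eps[vj]
    if np.abs(gaps).min() <= degeneracy_threshold:
        k = int(np.abs(gaps).argmin())
        raise DegenerateGapError(
            f"occupied-virtual gap |eps_{oi[k]} - eps_{vj[k]}| = "
            f"{abs(gaps[k]):.3e} hartree is below the degeneracy threshold "
            f"{degeneracy_threshold:.0e}; the uncoupled response diverges")
    meta = {"energy_window": energy_window}
    if energy_window is not None:
        keep = np.abs(gaps) <= energy_window
        oi, vj, gaps = oi[keep], vj[keep], gaps[keep]
        meta["n_truncated"] = int((~keep).sum())
    return PairBasis(oi, vj, 1.0 / gaps, meta)


@dataclass(frozen=True)
class PairWeights:
    """Bond-resolved response weights w^(ij)_IJ for every pair and atom pair."""

    w: np.ndarray  # (npair, natom, natom), symmetric in the atom indices

    @property
    def npair(self) -> int:
        return self.w.shape[0]

    @property
    def natom(self) -> int:
        return self.w.shape[1]


def _atom_segments(wfn: WavefunctionData) -> np.ndarray:
    """AO start offsets per atom; requires atom-contiguous AO ordering."""
    atom_of_ao = wfn.ao_map.atom_of_ao
    if np.any(np.diff(atom_of_ao) < 0):
        raise ValueError("AO ordering must be grouped by atom")
    return np.searchsorted(atom_of_ao, np.arange(wfn.mol.natom))


def pair_q_response(wfn: WavefunctionData, i: int, j: int) -> np.ndarray:
    """M^(ij)_munu = sum_eta (C_jmu C_ieta + C_imu C_jeta) S_etanu."""
    ci, cj = wfn.C[:, i], wfn.C[:, j]
    si, sj = wfn.S @ ci, wfn.S @ cj
    return np.outer(cj, si) + np.outer(ci, sj)


def pair_bond_weights(wfn: WavefunctionData, dm: DensityMatrices,
                      pairs: PairBasis) -> PairWeights:
    """w^(ij)_IJ = sum_{mu in I, nu in J} (M_munu Q_numu + Q_munu M_numu)."""
    Q = dm.Q
    if Q.shape[0] != wfn.nao:
        raise ValueError("density matrices do not match the wavefunction")
    seg = _atom_segments(wfn)
    natom = wfn.mol.natom
    SC = wfn.S @ wfn.C
    w = np.empty((pairs.npair, natom, natom))
    for n in range(pairs.npair):
        i, j = pairs.occ_idx[n], pairs.virt_idx[n]
        M = np.outer(wfn.C[:, j], SC[:, i]) + np.outer(wfn.C[:, i], SC[:, j])
        A = M * Q.T + Q * M.T
        rows = np.add.reduceat(A, seg, axis=0)
        w[n] = np.add.reduceat(rows, seg, axis=1)
    return PairWeights(0.5 * (w + w.transpose(0, 2, 1)))


@dataclass(frozen=True)
class CondensedLRF:
    """Atom-condensed response table with provenance metadata.

    kind 'bond_order': values[I, J, L] = dB_IJ/dv(L)
    kind 'density':    values[K, L]    = drho(K)/dv(L)
    """

    kind: str
    values: np.ndarray
    labels: tuple[str, ...]
    channel: str = "total"
    metadata: dict = field(default_factory=dict)

    @property
    def natom(self) -> int:
        return self.values.shape[-1]

    def bond(self, i: int, j: int) -> np.ndarray:
        """Row dB_IJ/dv(L) over all perturbation atoms L (bond-order kind)."""
        if self.kind != "bond_order":
            raise ValueError("bond() applies to bond-order tables")
        return self.values[i, j, :]

    def row_sums(self) -> np.ndarray:
        """sum_L of each row; exactly zero in the continuum limit."""
        return self.values.sum(axis=-1)

    def to_long_frame(self) -> pd.DataFrame:
        recs = []
        n = self.natom
        if self.kind == "bond_order":
            for i in range(n):
                for j in range(i, n):
                    for l in range(n):
                        recs.append((self.labels[i], self.labels[j],
                                     self.labels[l], self.channel,
                                     self.values[i, j, l]))
            cols = ["atom_I", "atom_J", "perturb_atom_L", "channel", "value"]
        else:
            for k in range(n):
                for l in range(n):
                    recs.append((self.labels[k], self.labels[l], self.channel,
                                 self.values[k, l]))
            cols = ["atom_K", "perturb_atom_L", "channel", "value"]
        return pd.DataFrame(recs, columns=cols)


def lrf_bo_condensed(weights: PairWeights, pairs: PairBasis,
                     overlaps: RegionOverlapTensor, labels=None,
                     channel: str = "total", pair_mask=None,
                     metadata: dict | None = None) -> CondensedLRF:
    """dB_IJ/dv(L) = 2 sum_pairs d_ij w^(ij)_IJ G[L, i, j]."""
    G = overlaps.G
    if G.shape[1] <= max(pairs.virt_idx.max(), pairs.occ_idx.max()) \
            or weights.npair != pairs.npair:
        raise ValueError("pair basis, weights and region overlaps do not "
                         "describe the same MO space")
    g_pairs = G[:, pairs.occ_idx, pairs.virt_idx]          # (natom, npair)
    d = pairs.denom if pair_mask is None else pairs.denom * pair_mask
    vals = SPIN_FACTOR * np.einsum("n,nIJ,Ln->IJL", d, weights.w, g_pairs,
                                   optimize=True)
    labels = labels or tuple(str(i + 1) for i in range(vals.shape[0]))
    md = dict(metadata or {})
    md.setdefault("grid", overlaps.grid_spec)
    md.setdefault("pair_metadata", pairs.metadata)
    return CondensedLRF("bond_order", vals, tuple(labels), channel, md)


def lrf_density_condensed(pairs: PairBasis, overlaps: RegionOverlapTensor,
                          labels=None, channel: str = "total", pair_mask=None,
                          metadata: dict | None = None) -> CondensedLRF:
    """drho(K)/dv(L) = 4 sum_pairs d_ij G[K, i, j] G[L, i, j].

    The factor 4 is the spin sum (2) times the two equivalent orderings of
    the density-matrix response evaluated at coincident points.
    """
    G = overlaps.G
    g_pairs = G[:, pairs.occ_idx, pairs.virt_idx]
    d = pairs.denom if pair_mask is None else pairs.denom * pair_mask
    vals = 2.0 * SPIN_FACTOR * np.einsum("n,Kn,Ln->KL", d, g_pairs, g_pairs,
                                         optimize=True)
    labels = labels or tuple(str(i + 1) for i in range(vals.shape[0]))
    md = dict(metadata or {})
    md.setdefault("grid", overlaps.grid_spec)
    return CondensedLRF("density", vals, tuple(labels), channel, md)


# ---------------------------------------------------------------------------
# pointwise evaluation: factorized production form and brute-force oracle
# ---------------------------------------------------------------------------

def lrf_bo_pointwise(wfn: WavefunctionData, dm: DensityMatrices,
                     pairs: PairBasis, weights: PairWeights,
                     points: np.ndarray, atom_pairs: list[tuple[int, int]],
                     unfactorized: bool = False) -> np.ndarray:
    """dB_IJ/dv(r) at arbitrary points for selected atom pairs (I, J).

    The default factorized path contracts precomputed pair weights with MO
    product amplitudes. With ``unfactorized=True`` the Q-matrix response is
    assembled element-by-element at every point and contracted with Q — an
    independent route kept as a numerical oracle.
    """
    points = np.asarray(points, float)
    psi = wfn.eval_mos(points)
    out = np.empty((points.shape[0], len(atom_pairs)))
    if not unfactorized:
        prod = psi[:, pairs.occ_idx] * psi[:, pairs.virt_idx]  # (npts, npair)
        amp = prod * pairs.denom[None, :]
        for col, (I, J) in enumerate(atom_pairs):
            out[:, col] = SPIN_FACTOR * amp @ weights.w[:, I, J]
        return out

    seg = _atom_segments(wfn)
    bounds = list(seg) + [wfn.nao]
    Q = dm.Q
    for g in range(points.shape[0]):
        dQ = np.zeros_like(Q)
        for n in range(pairs.npair):
            i, j = pairs.occ_idx[n], pairs.virt_idx[n]
            dQ += (SPIN_FACTOR * psi[g, i] * psi[g, j] * pairs.denom[n]) \
                * pair_q_response(wfn, i, j)
        A = dQ * Q.T + Q * dQ.T
        for col, (I, J) in enumerate(atom_pairs):
            out[g, col] = A[bounds[I]:bounds[I + 1], bounds[J]:bounds[J + 1]].sum()
    return out


def pointwise_total_residual(wfn: WavefunctionData, dm: DensityMatrices,
                             pairs: PairBasis, weights: PairWeights,
                             points: np.ndarray) -> float:
    """max over points of |sum over ALL atom pairs (incl. I=J) of dB_IJ/dv(r)|.

    Vanishes identically for an idempotent closed-shell density (the pair
    weights sum to zero by MO orthonormality), independent of any grid.
    """
    natom = weights.natom
    all_pairs = [(i, j) for i in range(natom) for j in range(natom)]
    vals = lrf_bo_pointwise(wfn, dm, pairs, weights, points, all_pairs)
    return float(np.abs(vals.sum(axis=1)).max())


def sum_rule_report(tbl: CondensedLRF, wfn: WavefunctionData | None = None,
                    dm: DensityMatrices | None = None,
                    pairs: PairBasis | None = None,
                    weights: PairWeights | None = None,
                    sample_points: np.ndarray | None = None,
                    row_tol: float = 2e-2) -> dict:
    """Residual diagnostics for the integral and pointwise sum rules."""
    rows = tbl.row_sums()
    report = {
        "max_row_residual": float(np.abs(rows).max()),
        "row_tolerance": row_tol,
        "flagged": bool(np.abs(rows).max() > row_tol),
        "kind": tbl.kind,
        "channel": tbl.channel,
    }
    if sample_points is not None and None not in (wfn, dm, pairs, weights):
        report["max_pointwise_total"] = pointwise_total_residual(
            wfn, dm, pairs, weights, sample_points)
    return report
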