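"""Descriptor interpretation and regression layer.

Sign semantics of the bond-order response, leaving-group ranking for
square-planar substitution chemistry, and the linear-free-energy-style
regression of descriptor values against literature Hammett substituent
constants. Hammett sigma values are experimental input data here — they
are never computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .response import CondensedLRF


def interpret_sign(value: float, perturbation_sign: str) -> str:
    """Direction of the bond-order change for a signed local perturbation.

    A positive response value with a repulsive (electron-destabilizing)
    perturbation increases the bond order; flipping either the sign of the
    value or the sign of the perturbation flips the direction.
    """
    if not np.isfinite(value):
        raise ValueError("response value must be finite")
    signs = {"repulsive": 1.0, "attractive": -1.0}
    try:
        s = signs[perturbation_sign]
    except KeyError:
        raise ValueError("perturbation_sign must be 'repulsive' or 'attractive'") from None
    prod = value * s
    if prod > 0:
        return "increase"
    if prod < 0:
        return "decrease"
    return "no first-order change"


def rank_leaving_groups(tbl: CondensedLRF, bonds: list[tuple[int, int]]
                        ) -> list[dict]:
    """Rank metal-ligand bonds by the self-perturbation response dB(M-X)/dv(X).

    A larger positive value means an electrophilic attack on X loosens the
    M-X bond more strongly, i.e. X is the more labile leaving group. Ties
    break on the ligand atom index.
    """
    if tbl.kind != "bond_order":
        raise ValueError("ranking requires a bond-order response table")
    natom = tbl.natom
    entries = []
    for metal, lig in bonds:
        if not (0 <= metal < natom and 0 <= lig < natom):
            raise ValueError(f"bond ({metal}, {lig}) not present in the table")
        entries.append({
            "metal": tbl.labels[metal], "ligand": tbl.labels[lig],
            "value": float(tbl.values[metal, lig, lig]),
            "_tie": lig,
        })
    entries.sort(key=lambda e: (-e["value"], e["_tie"]))
    for rank, e in enumerate(entries, start=1):
        e["rank"] = rank
        del e["_tie"]
    return entries


def linear_fit(x, y) -> dict:
    """Ordinary least squares y = slope*x + intercept with R^2.

    R^2 is the squared Pearson correlation; the returned dict includes a
    ``predict`` callable mapping a new descriptor value to its estimate.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need at least 3 points for a regression")
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: descriptor values are all equal")
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": float(res.rvalue**2),
        "stderr": float(res.stderr),
        "n": int(x.size),
        "predict": lambda xnew: res.slope * np.asarray(xnew, float) + res.intercept,
    }


@dataclass(frozen=True)
class HammettRecord:
    """One substituted-scaffold data point for the Hammett regression."""

    substituent: str
    position: str                 # 'meta' | 'para' | 'none'
    sigma: float                  # literature Hammett constant
    descriptors: dict = field(default_factory=dict)  # site label -> dB value
    charge: int = 0
    provenance: str = ""

    def __post_init__(self):
        if self.position not in ("meta", "para", "none"):
            raise ValueError(f"position must be meta/para/none, got {self.position!r}")
        if self.charge != 0:
            raise ValueError(
                f"substituent {self.substituent!r} carries net charge "
                f"{self.charge}; charged substituents are excluded (their "
                "descriptors would require fluctuating hydrated clusters)")


def hammett_report(records: list[HammettRecord],
                   negligible_threshold: float = 0.05) -> pd.DataFrame:
    """Per-site, per-position regressions of sigma against the descriptor.

    Meta and para sets are always fit separately. Sites whose regression
    looks good (high R^2) while the descriptor magnitudes are negligible
    are flagged: correlation without leverage is not a useful predictor.
    """
    if not records:
        raise ValueError("no records")
    sites = sorted({s for r in records for s in r.descriptors})
    if not sites:
        raise ValueError("records carry no descriptor values")
    rows = []
    for position in ("meta", "para"):
        subset = [r for r in records if r.position == position]
        if len(subset) < 3:
            continue
        for site in sites:
            missing = [r.substituent for r in subset if site not in r.descriptors]
            if missing:
                raise ValueError(f"site {site!r} missing for records: {missing}")
            x = np.array([r.descriptors[site] for r in subset])
            y = np.array([r.sigma for r in subset])
            fit = linear_fit(x, y)
            max_abs = float(np.abs(x).max())
            rows.append({
                "site": site, "position": position, "n": fit["n"],
                "slope": fit["slope"], "intercept": fit["intercept"],
                "r2": fit["r2"], "max_abs_descriptor": max_abs,
                "negligible_descriptor": bool(
                    fit["r2"] > 0.6 and max_abs < negligible_threshold),
            })
    if not rows:
        raise ValueError("need at least 3 records in a meta or para set")
    return pd.DataFrame(rows)
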