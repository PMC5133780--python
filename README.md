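# lrfbo — linear response functions of bond order and density

`lrfbo` computes **real-space reactivity descriptors** for closed-shell
molecules: how every Mayer bond order, and the atom-condensed electron
density, responds to a *virtual local potential* applied over an atom's
region of space. It is aimed at computational and physical-organic chemists
who want bond-resolved response descriptors — which bond loosens when an
electrophile approaches this atom? which ligand is the best leaving group?
does a substituent effect propagate inductively or by resonance? — without
running explicit reaction simulations.

## The descriptors

For a restricted single-determinant wavefunction (Hartree–Fock or
Kohn–Sham orbitals ψ, energies ε), first-order perturbation theory gives
the uncoupled response of the one-particle density matrix to a local
potential δv(r). Expanded over atomic orbitals with MO coefficients C and
AO overlap S, the response of the Q-matrix (Q = PS, P the spin-summed
density matrix) is

    δQ_μν/δv(r) = Σ_σ Σ_i^occ Σ_j^virt  ψ_j(r)ψ_i(r)/(ε_i − ε_j)
                  · Σ_η (C_jμ C_iη + C_iμ C_jη) S_ην ,

and the **bond-order response** follows from the Mayer bond order
B_IJ = Σ_{μ∈I, ν∈J} Q_μν Q_νμ:

    δB_IJ/δv(r) = Σ_{μ∈I, ν∈J} ( δQ_μν/δv(r) Q_νμ + Q_μν δQ_νμ/δv(r) ).

To attach the perturbation to an *atom* rather than a point, the kernel is
integrated over the atom's **Wigner–Seitz cell** — the region closer to
that nucleus than to any other, bounded by the perpendicular-bisector
planes to the neighboring atoms. The integration is a hard (non-fuzzy)
Euler–Maclaurin (radial) × Lebedev (angular) quadrature, so the
perturbation stays strictly localized:

    δB_IJ/δv(L) = ∫_{cell L} δB_IJ/δv(r) dr .

The same condensation applied to both arguments of the density response
gives the atom-condensed density response δρ(K)/δv(L). Two exact sum rules
diagnose every run: the all-pairs sum Σ_IJ δB_IJ/δv(r) = 0 holds pointwise
to machine precision for an idempotent closed-shell density, and every
per-bond row Σ_L δB_IJ/δv(L) = 0 holds to grid accuracy.

A positive δB_IJ/δv(L) means a repulsive (electron-destabilizing)
perturbation at L *strengthens* the I–J bond; sign conventions, σ/π
decomposition by reflection parity for planar systems, leaving-group
ranking, and a Hammett-constant regression layer are built on top.

The package carries its own restricted SCF engine (RHF and B3LYP with
selectable VWN3/VWN5 correlation flavor, McMurchie–Davidson integrals,
numba-accelerated) plus a plain-text Gaussian basis library, and reads and
writes Molden files for wavefunction exchange with other codes.

## Worked example: water

```python
from importlib import resources
from lrfbo import (density_matrix, mayer_bond_orders, build_partitioned_grid,
                   region_overlaps, build_pair_basis, pair_bond_weights,
                   lrf_bo_condensed, interpret_sign, load_xyz, run_scf)

xyz = resources.files("lrfbo") / "data" / "geometries" / "water.xyz"
mol = load_xyz(str(xyz))                       # B3LYP/6-311G** optimized
wfn = run_scf(mol, basis="6-311G**", method="b3lyp", b3lyp_flavor="vwn5")

dm = density_matrix(wfn)
bo = mayer_bond_orders(dm.Q, wfn.ao_map, mol)

grid = build_partitioned_grid(mol, n_radial=75, lebedev_order=302)
overlaps = region_overlaps(wfn, grid)
pairs = build_pair_basis(wfn)
weights = pair_bond_weights(wfn, dm, pairs)
tbl = lrf_bo_condensed(weights, pairs, overlaps)
```

prints (via the obvious `print` statements):

```
E(B3LYP/6-311G**) = -76.420509 hartree
Mayer B(O1-H2)    = 0.9698
dB(O1-H2)/dv(O1) = +0.8130
dB(O1-H2)/dv(H2) = -0.9601
dB(O1-H2)/dv(H3) = +0.1482
row sum = +0.00115
repulsive dv on O1 -> increase of B(O1-H2)
```

Reading the table: a repulsive potential over the oxygen cell strengthens
both O–H bonds (+0.81 each); the same perturbation over one hydrogen
weakens *its own* bond strongly (−0.96) while slightly strengthening the
other one (+0.15) — the signature of a proton-abstraction mode. The three
values sum to ~0 (grid accuracy), as they must: a homogeneous potential
shift cannot change any bond order. See `docs/methods.md` for the
normalization convention of these values and how it relates to reference
values in the literature.

The same pipeline is available from the shell:

```bash
lrfbo run --xyz my.xyz --basis "6-311G**" --density --outdir out/
lrfbo validate wavefunction.molden
lrfbo hammett --records records.csv --bond 14-15
```

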