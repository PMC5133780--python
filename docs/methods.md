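# Methods

This note records the model, the numerical choices, and the limits of
validity of the `lrfbo` implementation, at the level of detail a user would
need to judge what a computed number means.

## Response model

The engine computes the *uncoupled* (independent-particle) first-order
response of a restricted closed-shell single determinant. A local external
potential δv(r) mixes each occupied spatial orbital ψ_i into each virtual
ψ_j with amplitude ψ_i(r)ψ_j(r)/(ε_i − ε_j); the change of the AO density
matrix follows by expanding over the MO coefficients. Assumptions baked in:

- **Closed shell only.** Spin enters as a global factor 2 (both spin
  channels respond identically); multiplicities ≠ 1 are rejected at the
  door, by the `Molecule` container itself.
- **Uncoupled response.** No coupled-perturbed self-consistency: the
  Coulomb/exchange-correlation relaxation of the potential is neglected.
  This is a descriptor definition, not an approximation to be converged
  away — the self-consistent response is a different (screened, generally
  smaller) quantity and is deliberately out of scope.
- **Frozen AOs.** The perturbation models an approaching reagent or
  environment, not a nuclear displacement, so basis functions do not move.
- **Non-degenerate gaps.** Any occupied–virtual gap below 10⁻⁶ hartree is
  a hard `DegenerateGapError`: the perturbative denominator diverges and no
  silent regularization would be honest.

The production path is factorized: per occupied–virtual pair (i, j) a
bond-resolved weight w^(ij)_IJ is contracted from the pair's Q-matrix
response and Q itself; condensation then needs only the per-cell MO-pair
overlaps G[L, i, j]. Cost is O(N_pair·N_atom² + N_grid·N_MO²) instead of
evaluating the kernel at every grid point for every bond. The literal
element-by-element route (build δQ at a point, contract with Q) is kept as
`lrf_bo_pointwise(..., unfactorized=True)` and serves as a brute-force
oracle in the tests; the two agree to ~10⁻¹⁰ on all fixtures.

### Normalization convention

All condensed values are in atomic units: the response of a dimensionless
bond order per unit (hartree) local potential, i.e. hartree⁻¹. The
closed-shell spin sum is applied **exactly once**, as the overall factor 2
in the pair sum. This normalization is fixed by the defining equations and
verified against an independent finite-difference oracle (first-order
perturbed orbitals under a cell-indicator potential, rebuild P, difference
the Mayer bond order): analytic and finite-difference values agree to four
digits. Reference values reported in the literature for this descriptor
family can differ by a *global factor of ~2* depending on how the spin sum
and the spin-summed density matrix are book-kept (or whether the potential
is taken per rydberg); the water worked example in this convention gives
+0.813/−0.960/+0.148 where reported literature analogues are
1.456/−1.758/+0.303. Every scale-invariant statement — signs, sum rules,
orderings, monotone trends, correlation coefficients, regression R² — is
unaffected by this choice, and comparisons across molecules computed with
this package are internally consistent.

## Wigner–Seitz condensation

Each atom's integration domain is its Voronoi cell: the region closer to
that nucleus than to any other ("all perpendicular bisectors with the
neighboring atoms"). The cells are **hard** — a grid point is either inside
or outside — because the point of the descriptor is a perturbation strictly
localized to one atomic region; fuzzy (Becke-switched) cells would leak the
perturbation onto neighboring atoms. Consequences and choices:

- Every atom carries its own Euler–Maclaurin × Lebedev single-center grid
  covering all of space; points outside the atom's own cell get effective
  weight zero. The union of cells tiles space, so Σ_L G[L] ≈ identity; the
  residual of that identity is the partition's quadrature error and is
  attached to every `RegionOverlapTensor` as a diagnostic.
- Boundary ties (measure zero) go to the lowest atom index.
- Outer cells are unbounded; the radial map covers [0, ∞) and orbital
  products decay, so no truncation radius is needed or used.
- No grid pruning: pruning interacts unpredictably with hard boundaries.
- A cross-check estimator (`region_overlaps_crosscheck`) bins the union of
  all centers' points by owner and averages; it is coarser (far centers
  sample a foreign cell badly) but independent, and the two routes agree
  within the coarser route's own discretization error.

### Quadrature

- **Radial:** Murray–Handy–Laming map r = R x²/(1−x)², x = i/(n+1), with
  the element's Bragg–Slater radius as scale R (hydrogen 0.35 Å). Weights
  include the r² Jacobian.
- **Angular:** Lebedev grids (from `scipy.integrate.lebedev_rule`),
  selected by point count; 302 points integrates spherical harmonics to
  degree 29.
- **Defaults:** 75 × 302 per atom. With hard cell boundaries the error is
  dominated by the boundary surface, not the integrand smoothness; at the
  default grid the MO-orthonormality residual is ~10⁻²–10⁻³ and per-bond
  row sums of the condensed response vanish to ~10⁻³. The boundary error is
  **not monotone** between adjacent grid steps (the Lebedev point pattern
  re-samples the boundary differently); convergence checks therefore double
  the grid (75×302 → 150×590) rather than stepping to the next order.
- The pointwise all-pairs sum rule is grid-independent and holds to ~10⁻¹⁴;
  it validates the wavefunction and pair algebra, while the row-sum rule
  validates the partition quadrature. The two together localize any error.

## The SCF backend

The package includes its own restricted SCF engine:

- **Integrals:** McMurchie–Davidson Hermite expansions for overlap,
  kinetic, nuclear attraction, dipole and two-electron repulsion over
  contracted Cartesian Gaussians (numba-compiled hot loops; dense in-memory
  ERI tensor), with spherical-harmonic (or Cartesian) AO transforms applied
  at the contracted level. Validated against closed-form minimal-basis H₂
  values and full-space quadrature.
- **Functionals:** Slater + Becke-88 exchange, VWN (functional V or the
  RPA-fit functional III) and Lee–Yang–Parr correlation, combined in the
  standard three-parameter hybrid mix (a₀, aₓ, a_c) = (0.20, 0.72, 0.81)
  with 20 % exact exchange. The `b3lyp_flavor` switch selects VWN5
  (default) or VWN3 inside the hybrid and is recorded in the method
  metadata, since codes differ in this convention. Functional derivatives
  are generated symbolically (sympy) and verified against finite
  differences and uniform-electron-gas correlation energies.
- **XC quadrature:** Becke-weighted (fuzzy, size-adjusted) molecular grid,
  default 60 × 194 — fuzzy cells are correct here because this integral is
  a smooth total, unlike the condensation domains above.
- **SCF:** core-Hamiltonian guess, DIIS (depth 10), energy and density
  convergence to 10⁻⁹/3×10⁻⁵ by default; final orbitals from the
  unextrapolated Fock at the converged density.
- **Geometries:** a numerical-gradient optimizer (BFGS / scalar search) is
  included and practical to ~5 atoms. The shipped water/HF/HCl geometries
  were optimized with it at B3LYP(VWN5)/6-311G** (water r(OH) = 0.963 Å,
  θ = 103.0°; r(HF) = 0.920 Å; r(HCl) = 1.285 Å).

### Basis library

Plain-text files ship the standard published STO-3G (H, C, N, O, F) and
6-311G** (H, C, N, O, F, Cl; McLean–Chandler sp set for Cl) data in the
normalized-primitive coefficient convention. Transcription was validated
against well-known totals: RHF/STO-3G H₂ at 1.4 a₀ = −1.116714 Eh with the
textbook integral table reproduced to 4 decimals; RHF/6-311G** water and
HCl within a few mEh of literature values; B3LYP bond lengths and the
water dipole (2.06 D) in the expected ranges. **No heavy-element data**
(Br, I, or effective core potentials for transition metals) is included —
analyses that need them (the full hydrogen-halide series beyond HCl,
square-planar Pt complexes) cannot currently be computed, and the
corresponding end-to-end tests say so explicitly rather than being skipped.

## σ/π decomposition

For a molecule with a mirror plane (heavy-atom RMS out-of-plane deviation
< 10⁻³ Å; least-squares plane via SVD), each MO gets a reflection-parity
score s_i = ∫ψ_i(r)ψ_i(σ_h r)dr ∈ [−1, 1], evaluated on a Becke grid. This
equals the signed fraction of the MO norm carried by reflection-even minus
reflection-odd AO components, but needs no basis-dependent bookkeeping.
Orbitals with |s| ≥ 0.95 are labelled σ (+) or π (−); anything less pure is
`mixed`, warned about, and never force-classified. Channels are assigned at
the occupied–virtual **pair** level — π·π → π channel, σ·σ → σ, anything
else → cross — so σ + π + cross = total holds exactly by construction. For
in-plane atoms the cells are mirror-symmetric and the cross channel
integrates to ~0, which makes the pair-level convention agree with
occupied-orbital-only splitting on condensed values; the cross channel is
reported anyway so the choice is auditable. Collinear molecules get a
flagged axial plane (σ/π remain meaningful, though the two π components
split into even and odd with respect to the chosen plane).

## Synthetic models and shipped wavefunctions

The test fixtures are real Gaussian-basis wavefunctions with synthetic
energies: a tunable-overlap H₂ minimal model (closed forms: B = 1 exactly,
bond response exactly zero — note the *diagonal* self-terms B_II do respond;
only the bond entry is null), seeded random s-Gaussian clusters (exact
orthonormality by Löwdin construction), and a planar two-center model with
one occupied π MO. They exercise every response and symmetry code path
without an SCF run. What they do **not** emulate: realistic energy spectra,
core/valence structure, or basis-set incompleteness effects — so fixture
tests establish algebraic correctness, not chemical accuracy.

The conjugated-chain analyses use shipped B3LYP/STO-3G Molden
wavefunctions of hexan-1-ol (MMFF94-relaxed) and planar all-trans
hexa-1,3,5-trien-1-ol (idealized bond lengths/angles). At these
conditions the qualitative claims — π-channel density response peaking at
the odd chain carbons, σ channel decaying monotonically like the saturated
analogue (Spearman ρ = 1.0), exact channel additivity — are reproduced;
quantitative values at this minimal basis should not be compared to
polarized-basis results. Even-carbon π responses are ≈ 0 there, so their
signs are numerical noise and are not asserted.

## Determinism and numerical conventions

- Identical inputs and grid settings give bit-identical outputs; no global
  random state (fixture seeds are explicit arguments, the CLI's diagnostic
  sample points use a fixed generator).
- Orthonormality gates: 10⁻⁶ on CᵀSC for engine-produced wavefunctions,
  10⁻⁴ for Molden files (last-digit rounding of stored coefficients);
  electron-count tolerance scales with the measured orthonormality
  residual.
- Virtual-space truncation is off by default; an optional energy window
  exists and is recorded in the pair-basis metadata and outputs.
- Mulliken populations degrade with diffuse functions; a warning fires when
  the basis name carries diffuse markers.

## Known limitations

- Restricted closed-shell only; no open-shell generalization.
- Uncoupled response only; no orbital relaxation, no frequency dependence.
- The absolute descriptor scale follows this package's convention (see
  above); cross-package comparisons must check the spin-sum convention
  first.
- Heavy elements require basis/ECP data the library does not ship.
- The geometry optimizer is finite-difference and small-molecule only.
- Exactly reproducing third-party condensed values to all digits would
  additionally require matching their (usually unstated) grid sizes and
  radial maps; hard-boundary quadrature differences of a few per cent
  persist between reasonable grids.
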