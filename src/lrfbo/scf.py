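"""Restricted SCF engine: Hartree–Fock and B3LYP Kohn–Sham.

This is the package's quantum-chemistry backend: a conventional
closed-shell SCF over the analytic Gaussian integrals of
:mod:`lrfbo.integrals`, with DIIS convergence acceleration and, for the
hybrid functional, exchange–correlation quadrature on a Becke-weighted
Euler–Maclaurin x Lebedev molecular grid. Dense two-electron integrals are
kept in memory, which is appropriate for the molecule sizes this package
targets (up to a few hundred AOs).
"""

from __future__ import annotations

import numpy as np

from . import gto, integrals, xc
from .basis import build_shells
from .elements import bragg_slater_radius_bohr
from .grid import angular_quadrature, radial_quadrature
from .molecule import Molecule, UnsupportedSystemError
from .wavefunction import WavefunctionData


class SCFConvergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Becke-weighted XC quadrature grid (fuzzy cells, standard for SCF energies;
# distinct from the hard Wigner–Seitz partition used for condensation)
# ---------------------------------------------------------------------------

def becke_xc_grid(mol: Molecule, n_radial: int = 60, lebedev_order: int = 194):
    ang_pts, ang_w = angular_quadrature(lebedev_order)
    radii = np.array([bragg_slater_radius_bohr(s) for s in mol.symbols])
    all_pts, all_w = [], []
    for ia in range(mol.natom):
        rad, rad_w = radial_quadrature(n_radial, radii[ia])
        pts = (mol.coords[ia] + rad[:, None, None] * ang_pts[None, :, :]).reshape(-1, 3)
        w0 = (rad_w[:, None] * ang_w[None, :]).ravel()
        all_pts.append(pts)
        all_w.append(w0 * _becke_cell_weights(mol, radii, pts, ia))
    return np.concatenate(all_pts), np.concatenate(all_w)


def _becke_cell_weights(mol, radii, pts, ia):
    natom = mol.natom
    if natom == 1:
        return np.ones(len(pts))
    dist = np.linalg.norm(pts[:, None, :] - mol.coords[None, :, :], axis=2)
    P = np.ones((natom, len(pts)))
    for i in range(natom):
        for j in range(natom):
            if i == j:
                continue
            Rij = np.linalg.norm(mol.coords[i] - mol.coords[j])
            mu = (dist[:, i] - dist[:, j]) / Rij
            chi = radii[i] / radii[j]
            u = (chi - 1.0) / (chi + 1.0)
            a = np.clip(u / (u * u - 1.0), -0.5, 0.5)
            nu = mu + a * (1.0 - mu * mu)
            f = nu
            for _ in range(3):
                f = 1.5 * f - 0.5 * f**3
            P[i] *= 0.5 * (1.0 - f)
    return P[ia] / P.sum(axis=0)


# ---------------------------------------------------------------------------
# SCF driver
# ---------------------------------------------------------------------------

def run_scf(mol: Molecule, basis: str = "6-311G**", method: str = "b3lyp",
            b3lyp_flavor: str = "vwn5", conv_tol: float = 1e-9,
            max_cycles: int = 120, xc_grid: tuple[int, int] = (60, 194),
            optimize: bool = False, verbose: bool = False) -> WavefunctionData:
    """Converge a restricted closed-shell SCF and return the wavefunction.

    method: 'hf' or 'b3lyp'; b3lyp_flavor selects the VWN correlation
    variant inside the hybrid ('vwn5' or 'vwn3') and is recorded in the
    returned method metadata. With ``optimize=True`` the geometry is first
    relaxed to a stationary point (numerical gradients; small molecules).
    """
    if optimize:
        mol = optimize_geometry(mol, basis=basis, method=method,
                                b3lyp_flavor=b3lyp_flavor, verbose=verbose)
    if mol.multiplicity != 1:
        raise UnsupportedSystemError("run_scf handles closed-shell singlets only")
    method = method.lower()
    if method not in ("hf", "b3lyp"):
        raise ValueError(f"unknown method {method!r}")
    xckind = None if method == "hf" else ("b3lyp5" if b3lyp_flavor == "vwn5" else "b3lyp3")
    hyb = 1.0 if method == "hf" else xc.exact_exchange_fraction(xckind)

    shells = build_shells(mol, basis)
    T, _ = gto.build_transform(shells)
    S = gto.overlap_matrix(shells, T)
    Hcore = gto.kinetic_matrix(shells, T) + integrals.nuclear_attraction(
        shells, T, mol.coords, np.array(mol.atomic_numbers, float))
    eri = integrals.eri_tensor(shells, T)
    enuc = integrals.nuclear_repulsion(mol.coords, np.array(mol.atomic_numbers, float))

    nocc = mol.n_electrons // 2
    nao = S.shape[0]

    # symmetric orthogonalization with linear-dependency guard
    sval, svec = np.linalg.eigh(S)
    keep = sval > 1e-10
    X = svec[:, keep] / np.sqrt(sval[keep])

    if xckind is not None:
        grid_pts, grid_w = becke_xc_grid(mol, *xc_grid)
        ao_vals, ao_grads = gto.eval_aos(shells, grid_pts, T, deriv=True)

    def fock_and_energy(D):
        J = np.einsum("pqrs,rs->pq", eri, D, optimize=True)
        K = np.einsum("prqs,rs->pq", eri, D, optimize=True)
        F = Hcore + 2.0 * J - hyb * K
        E = np.einsum("pq,pq->", D, 2.0 * Hcore + 2.0 * J - hyb * K)
        if xckind is not None:
            rho = 2.0 * np.einsum("gp,pq,gq->g", ao_vals, D, ao_vals, optimize=True)
            drho = 4.0 * np.einsum("gdp,pq,gq->gd", ao_grads, D, ao_vals, optimize=True)
            sigma = np.einsum("gd,gd->g", drho, drho)
            e, vr, vs = xc.eval_xc(rho, sigma, xckind)
            E += float(grid_w @ e)
            wvr = grid_w * vr
            Vxc = np.einsum("g,gp,gq->pq", wvr, ao_vals, ao_vals, optimize=True)
            wvs = 2.0 * grid_w * vs
            tmp = np.einsum("g,gd,gdp->gp", wvs, drho, ao_grads, optimize=True)
            half = np.einsum("gp,gq->pq", tmp, ao_vals, optimize=True)
            Vxc += half + half.T
            F = F + Vxc
        return F, E + enuc

    # core-Hamiltonian initial guess
    e0, c0 = np.linalg.eigh(X.T @ Hcore @ X)
    C = X @ c0
    D = C[:, :nocc] @ C[:, :nocc].T

    diis_F, diis_e = [], []
    E_old, D_old = 0.0, D
    for cycle in range(1, max_cycles + 1):
        F, E = fock_and_energy(D)
        err = F @ D @ S - S @ D @ F
        err = X.T @ err @ X
        diis_F.append(F)
        diis_e.append(err)
        if len(diis_F) > 10:
            diis_F.pop(0)
            diis_e.pop(0)
        if len(diis_F) > 1:
            n = len(diis_F)
            B = -np.ones((n + 1, n + 1))
            B[n, n] = 0.0
            for i in range(n):
                for j in range(n):
                    B[i, j] = np.vdot(diis_e[i], diis_e[j])
            rhs = np.zeros(n + 1)
            rhs[n] = -1.0
            try:
                coef = np.linalg.solve(B, rhs)[:n]
                F = sum(c * Fi for c, Fi in zip(coef, diis_F))
            except np.linalg.LinAlgError:
                pass
        eps, cmo = np.linalg.eigh(X.T @ F @ X)
        C = X @ cmo
        D = C[:, :nocc] @ C[:, :nocc].T
        dE = E - E_old
        dD = np.abs(D - D_old).max()
        if verbose:
            print(f"  cycle {cycle:3d}  E = {E: .10f}  dE = {dE: .2e}  dD = {dD: .2e}")
        if abs(dE) < conv_tol and dD < np.sqrt(conv_tol):
            break
        E_old, D_old = E, D
    else:
        raise SCFConvergenceError(
            f"SCF did not converge in {max_cycles} cycles (last dE = {dE:.2e})")

    # final diagonalization of the unextrapolated Fock at converged density
    F, E = fock_and_energy(D)
    eps, cmo = np.linalg.eigh(X.T @ F @ X)
    C = X @ cmo
    occ = np.zeros(C.shape[1])
    occ[:nocc] = 2.0

    meta = {"functional": method, "basis": basis, "backend": "lrfbo-internal-scf",
            "b3lyp_flavor": b3lyp_flavor if method == "b3lyp" else None,
            "xc_grid": xc_grid, "energy": E}
    return WavefunctionData(mol=mol, shells=shells, C=C, eps=eps, occ=occ,
                            S=S, method=meta, energy=E)


# ---------------------------------------------------------------------------
# geometry optimization (finite-difference gradients over a small number of
# Cartesian degrees of freedom; intended for the few-atom molecules the
# descriptor studies use)
# ---------------------------------------------------------------------------

def optimize_geometry(mol: Molecule, basis: str = "6-311G**", method: str = "b3lyp",
                      b3lyp_flavor: str = "vwn5", step: float = 5e-3,
                      gtol: float = 3e-4, maxiter: int = 60,
                      verbose: bool = False) -> Molecule:
    """Minimize the SCF energy over Cartesian coordinates (BFGS, numerical
    gradients). Practical up to ~5 atoms; larger systems should be given
    pre-relaxed geometries."""
    from scipy.optimize import minimize

    x0 = mol.coords.ravel().copy()

    def energy(x):
        m = Molecule(mol.symbols, x.reshape(-1, 3), mol.charge, mol.multiplicity)
        wfn = run_scf(m, basis=basis, method=method, b3lyp_flavor=b3lyp_flavor)
        if verbose:
            print(f"  E({np.round(x, 4)}) = {wfn.energy:.8f}")
        return wfn.energy

    res = minimize(energy, x0, method="BFGS",
                   options={"gtol": gtol, "maxiter": maxiter,
                            "eps": step, "finite_diff_rel_step": None})
    return Molecule(mol.symbols, res.x.reshape(-1, 3), mol.charge, mol.multiplicity)
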