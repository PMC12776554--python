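"""1D planar nonlinear Poisson-Boltzmann membrane electrostatics.

Solves the reduced-potential equation

    d/dz ( eps_r(z) du/dz ) = eps_sol * kappa^2 * sinh(u)      (solution)
                            = 0                                 (slab)

on a z grid spanning both bulk regions, with Dirichlet boundaries
(u = u_int intracellular, u = u_ext = 0 extracellular), a low-dielectric
hydrophobic slab (default 29.2 A thick, eps 2) between two electrolyte
regions (eps 80, symmetric monovalent ionic strength I).  kappa is the
inverse Debye length of the solution.  An intracellular "vestibule" region
can be designated a conductor (the potential held at u_int up to a
configurable top), the 1D analogue of filling the hydrated cytoplasmic cavity
with the effective charge density

    n_eff = 2e-27 * N_A * I * sinh(u)        [A^-3]

which propagates the applied boundary potential through the inner solvent
space.  This planar solver is an acknowledged approximation to a full 3D
membrane PB calculation: it yields qualitatively correct potential profiles
and field fractions, not structure-specific energies.

Field fractions (electrical distances) are read off the converged profile as
d(z) = (u(z) - u_int)/(u_ext - u_int), monotone from 0 (intracellular) to 1
(extracellular) in this geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded

from .constants import CONSTANTS, kT_joule
from .pathway_profiles import PathSpline, Profile1D


def n_eff(ionic_strength_M: float, u: float) -> float:
    """Effective cytoplasmic charge density (A^-3): 2e-27 * N_A * I * sinh(u)."""
    return 2e-27 * CONSTANTS.N_A * ionic_strength_M * math.sinh(u)


def debye_length(ionic_strength_M: float, eps_r: float = 80.0,
                 temperature: float = 298.15) -> float:
    """Debye screening length in angstrom for a symmetric 1:1 electrolyte."""
    n = ionic_strength_M * 1e3 * CONSTANTS.N_A  # ions/m^3 per species
    kappa2 = 2.0 * n * CONSTANTS.e**2 / (CONSTANTS.eps0 * eps_r
                                         * kT_joule(temperature))
    return 1.0 / math.sqrt(kappa2) * 1e10


@dataclass
class SlabSystem:
    """Planar membrane system for the 1D PB solver.

    z in angstrom, increasing extracellular; the hydrophobic slab occupies
    [slab_bottom, slab_bottom + slab_thickness].  ``vestibule_top`` extends
    the intracellular boundary potential (conductor treatment) up to that z;
    use -inf for no vestibule.
    """

    z_min: float = -80.0
    z_max: float = 80.0
    slab_bottom: float = -14.6
    slab_thickness: float = 29.2
    eps_solution: float = 80.0
    eps_slab: float = 2.0
    ionic_strength_M: float = 0.1
    u_int: float = -1.0
    u_ext: float = 0.0
    temperature: float = 298.15
    vestibule_top: float = -np.inf
    grid_spacing: float = 0.2

    def __post_init__(self):
        if self.eps_solution <= 0 or self.eps_slab <= 0:
            raise ValueError("dielectric constants must be positive")
        lam = debye_length(self.ionic_strength_M, self.eps_solution,
                           self.temperature)
        pad_lo = self.slab_bottom - self.z_min
        pad_hi = self.z_max - (self.slab_bottom + self.slab_thickness)
        if min(pad_lo, pad_hi) < 5.0 * lam:
            raise ValueError(
                f"grid must span both bulks by >= 5 Debye lengths ({lam:.1f} A)")


@dataclass
class PotentialProfile:
    """Converged reduced potential u(z) and derived field fraction d(z)."""

    z: np.ndarray
    u: np.ndarray
    u_int: float
    u_ext: float

    @property
    def d(self) -> np.ndarray:
        if self.u_int == self.u_ext:
            return np.zeros_like(self.u)
        return (self.u - self.u_int) / (self.u_ext - self.u_int)

    def field_fraction(self, z_site: float) -> float:
        if not (self.z[0] <= z_site <= self.z[-1]):
            raise ValueError(f"site z={z_site} outside the solved grid")
        return float(np.interp(z_site, self.z, self.d))


def solve_pb_1d(system: SlabSystem, max_iter: int = 200,
                tol: float = 1e-9) -> PotentialProfile:
    """Damped-Newton finite-difference solution of the 1D nonlinear PB equation.

    Second-order accurate; converged residual of the discretized equation is
    below ``tol`` (dimensionless, per grid point).  Raises on non-convergence.
    """
    h = system.grid_spacing
    z = np.arange(system.z_min, system.z_max + 0.5 * h, h)
    n = z.size
    slab_lo = system.slab_bottom
    slab_hi = system.slab_bottom + system.slab_thickness
    in_slab = (z >= slab_lo) & (z <= slab_hi)
    fixed = (z <= system.vestibule_top) & ~in_slab  # conductor region
    eps = np.where(in_slab, system.eps_slab, system.eps_solution)
    # midpoint (interface) dielectric: harmonic mean preserves flux continuity
    eps_mid = 2.0 * eps[:-1] * eps[1:] / (eps[:-1] + eps[1:])
    lam = debye_length(system.ionic_strength_M, system.eps_solution,
                       system.temperature)
    kappa2 = 1.0 / lam**2
    source = np.where(in_slab | fixed, 0.0, system.eps_solution * kappa2)

    # initial guess: linear interpolation between the boundaries
    u = system.u_int + (system.u_ext - system.u_int) * (z - z[0]) / (z[-1] - z[0])
    u[0] = system.u_int
    u[-1] = system.u_ext
    u[fixed] = system.u_int

    interior = np.ones(n, bool)
    interior[[0, -1]] = False
    interior[fixed] = False

    def residual(uv: np.ndarray) -> np.ndarray:
        r = np.zeros(n)
        lap = (eps_mid[1:] * (uv[2:] - uv[1:-1])
               - eps_mid[:-1] * (uv[1:-1] - uv[:-2])) / h**2
        r[1:-1] = lap - source[1:-1] * np.sinh(uv[1:-1])
        r[~interior] = 0.0
        return r

    r = residual(u)
    rnorm = np.abs(r).max()
    for _ in range(max_iter):
        if rnorm < tol:
            break
        # tridiagonal Jacobian in banded storage: ab[0, j] = J[j-1, j],
        # ab[1, j] = J[j, j], ab[2, j] = J[j+1, j].  Fixed (Dirichlet /
        # conductor) points get identity rows with zero rhs, so their Newton
        # step is exactly zero and column couplings need no special handling.
        ab = np.zeros((3, n))
        ab[1, :] = 1.0
        rhs = np.zeros(n)
        idx = np.flatnonzero(interior)
        ab[1, idx] = -(eps_mid[idx] + eps_mid[idx - 1]) / h**2 \
            - source[idx] * np.cosh(u[idx])
        ab[0, idx + 1] = eps_mid[idx] / h**2      # J[i, i+1]
        ab[2, idx - 1] = eps_mid[idx - 1] / h**2  # J[i, i-1]
        rhs[idx] = -r[idx]
        step = solve_banded((1, 1), ab, rhs)
        # damped acceptance: halve the step until the residual decreases
        alpha = 1.0
        for _ in range(30):
            trial = u + alpha * step
            trial[~interior] = u[~interior]
            r_trial = residual(trial)
            if np.abs(r_trial).max() < rnorm:
                u, r, rnorm = trial, r_trial, np.abs(r_trial).max()
                break
            alpha *= 0.5
        else:
            raise RuntimeError("PB Newton iteration stalled")
    else:
        raise RuntimeError(f"PB solver did not converge (residual {rnorm:.2e})")
    return PotentialProfile(z=z, u=u, u_int=system.u_int, u_ext=system.u_ext)


def field_fraction(profile: PotentialProfile, z_site: float) -> float:
    """Fraction of the membrane potential dropped below ``z_site``: 0 in the
    intracellular bulk, 1 in the extracellular bulk."""
    return profile.field_fraction(z_site)


def debye_huckel_halfspace(z: np.ndarray, u0: float,
                           ionic_strength_M: float, eps_r: float = 80.0,
                           temperature: float = 298.15) -> np.ndarray:
    """Linearized (Debye-Huckel) closed form u(z) = u0 * exp(-z/lambda_D) for
    an electrolyte half-space with surface potential u0 at z = 0."""
    lam = debye_length(ionic_strength_M, eps_r, temperature)
    return u0 * np.exp(-np.asarray(z, float) / lam)


def ca_perturbation_profile(path: PathSpline, ca_positions: np.ndarray,
                            lambda_D: float = 8.0, eps_eff: float = 40.0,
                            temperature: float = 298.15) -> Profile1D:
    """Screened-Coulomb estimate of bound Ca2+ contributions to the Cl- profile.

    dG(s) = sum_Ca z_Cl * z_Ca * e^2 / (4 pi eps0 eps_eff r) * exp(-r/lambda_D)
    in kT per unit Cl- charge, with r the distance from each path node to each
    Ca2+.  Attractive (negative) for Cl- everywhere.  Subtracting this from a
    2-Ca profile approximates the 1-Ca/0-Ca profiles; a stand-in for the full
    3D PB perturbation.
    """
    if lambda_D <= 0 or eps_eff <= 0:
        raise ValueError("screening length and dielectric must be positive")
    ca_positions = np.atleast_2d(np.asarray(ca_positions, float))
    r = np.linalg.norm(path.nodes[:, None, :] - ca_positions[None, :, :], axis=2)
    if np.any(r < 1e-9):
        raise ValueError("a Ca2+ position coincides with a path node")
    z_cl, z_ca = -1.0, 2.0
    # e^2/(4 pi eps0) in J*m -> kT*A via kT(T) and 1e10 A/m
    coupling = CONSTANTS.e**2 / (4.0 * np.pi * CONSTANTS.eps0) \
        / kT_joule(temperature) * 1e10  # kT * A
    dg = (z_cl * z_ca * coupling / (eps_eff * r) * np.exp(-r / lambda_D)).sum(axis=1)
    return Profile1D(s=path.s, values=dg, kind="free_energy",
                     bin_width=path.node_spacing)
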