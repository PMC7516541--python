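"""Mean-field electrostatics and density-dependent permittivity.

The Poisson solve, the nonlinear Poisson-Boltzmann (PB) reference solver, the
analytic Gouy-Chapman 1:1 closed form, the Clausius-Mossotti and Oleksy-Hansen
local-permittivity models built on the weighted (coarse-grained) solvent
density, and the electroosmotic-velocity diagnostic.

Reduced units: z in nm, psi in k_B T/e, densities in nm^-3, sigma in e/nm^2.
The Poisson equation then reads

    d/dz [ eps_r(z) dpsi/dz ] = -4 pi lambda_B0 rho_q(z)

with lambda_B0 the vacuum Bjerrum length at the working temperature, the
Neumann wall condition eps_r(0) psi'(0+) = -4 pi lambda_B0 sigma and a far
Dirichlet anchor psi(L) = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.linalg import solve_banded

from . import constants as const
from .bulk import BulkState
from .model import Grid

__all__ = [
    "DielectricModel",
    "FlowSpec",
    "weighted_solvent_density",
    "clausius_mossotti_eps",
    "oleksy_hansen_eps",
    "solve_poisson",
    "solve_pb",
    "poisson_boltzmann_newton",
    "gouy_chapman_potential",
    "eo_velocity",
]


# ---------------------------------------------------------------------------
# dielectric models


def weighted_solvent_density(rho0: np.ndarray, d0: float, grid: Grid) -> np.ndarray:
    """Spherical volume average of the solvent profile, reduced to planar form.

    rho~0(z) = (6/d0^3) int rho0(z') [d0^2/4 - (z - z')^2] Theta(d0/2 - |z-z'|) dz'

    The discrete kernel is renormalized so a uniform input is preserved exactly.
    The profile is extended with its edge values on both sides (a masked
    solvent profile is already zero at the wall edge; the bulk value continues
    past z = L).
    """
    if d0 <= 0.0:
        raise ValueError("solvent diameter must be positive")
    h = grid.spacing
    K = max(1, int(round(0.5 * d0 / h)))
    s = h * np.arange(-K, K + 1)
    w = (6.0 / d0**3) * np.clip(0.25 * d0**2 - s**2, 0.0, None)
    w[0] *= 0.5
    w[-1] *= 0.5
    tot = h * float(np.sum(w))
    w /= tot
    padded = np.concatenate([np.full(K, rho0[0]), rho0, np.full(K, rho0[-1])])
    return h * np.correlate(padded, w, mode="valid")


def clausius_mossotti_eps(rho0_tilde: np.ndarray, m2_over_kT: float) -> np.ndarray:
    """Clausius-Mossotti permittivity from the weighted solvent density.

    eps_r = (1 + (8 pi/9) (m^2/k_B T) rho~0) / (1 - (4 pi/9) (m^2/k_B T) rho~0)

    `m2_over_kT` is the squared dipole moment over k_B T, in nm^3. Diverges
    (polarization catastrophe) as rho~0 -> 9 k_B T/(4 pi m^2) from below.
    """
    y = (4.0 * math.pi / 9.0) * m2_over_kT * np.asarray(rho0_tilde, dtype=float)
    denom = 1.0 - y
    if np.any(denom <= 0.0):
        raise ValueError("Clausius-Mossotti polarization catastrophe: density too high")
    return (1.0 + 2.0 * y) / denom


def oleksy_hansen_eps(
    rho0_tilde: np.ndarray,
    d0: float,
    a: float,
    rho_mid_reduced: float,
    f_T: float,
) -> np.ndarray:
    """Oleksy-Hansen sigmoidal permittivity.

    eps_r(z) = 1 + f(T) / (1 + exp[-a (rho~0 d0^3 - rho_mid d0^3)])

    with f(T) = 88 - 0.37 T in the temperature convention of the source model
    (a reduced temperature; see DielectricModel). `rho_mid_reduced` is the
    gas-liquid midpoint density in units of d0^-3.
    """
    if a <= 0.0 or rho_mid_reduced <= 0.0:
        raise ValueError("steepness a and midpoint density must be positive")
    if f_T <= 0.0:
        raise ValueError(f"permittivity amplitude f(T) = {f_T:g} must be positive")
    x = np.asarray(rho0_tilde, dtype=float) * d0**3 - rho_mid_reduced
    return 1.0 + f_T / (1.0 + np.exp(-a * x))


@dataclass
class DielectricModel:
    """Configuration of the permittivity model.

    kind = "uniform": eps_r everywhere.
    kind = "clausius_mossotti": m2_over_kT (nm^3) on the weighted solvent density.
    kind = "oleksy_hansen": steepness `a`, reduced midpoint density `rho_mid`,
    amplitude f(T) = f_coeff0 - f_coeff1 * T_model with T_model the model's
    reduced temperature (f(298 K) would be negative, so the kelvin convention
    is opt-in and validated).
    """

    kind: str = "uniform"
    eps_r: float = 78.5
    m2_over_kT: float = 0.0
    a: float = 4.0
    rho_mid: float = 0.35
    f_coeff0: float = 88.0
    f_coeff1: float = 0.37
    t_model: float = 1.0

    def f_T(self) -> float:
        return self.f_coeff0 - self.f_coeff1 * self.t_model

    def eps_profile(self, rho0_tilde: Optional[np.ndarray], d0: float, n_nodes: int) -> np.ndarray:
        if self.kind == "uniform":
            if self.eps_r <= 0.0:
                raise ValueError("uniform eps_r must be positive")
            return np.full(n_nodes, self.eps_r)
        if rho0_tilde is None:
            raise ValueError(f"dielectric model {self.kind!r} needs a solvent profile")
        if self.kind == "clausius_mossotti":
            return clausius_mossotti_eps(rho0_tilde, self.m2_over_kT)
        if self.kind == "oleksy_hansen":
            return oleksy_hansen_eps(rho0_tilde, d0, self.a, self.rho_mid, self.f_T())
        raise ValueError(f"unknown dielectric model {self.kind!r}")


# ---------------------------------------------------------------------------
# Poisson / PB solvers


def _interface_eps(eps_r: np.ndarray) -> np.ndarray:
    """Harmonic-mean permittivities at the N-1 cell interfaces."""
    a, b = eps_r[:-1], eps_r[1:]
    return 2.0 * a * b / (a + b)


def solve_poisson(
    rho_e: np.ndarray,
    eps_r: np.ndarray,
    sigma: float,
    grid: Grid,
    temperature: float = 298.15,
    psi_far: float = 0.0,
) -> np.ndarray:
    """Solve the variable-coefficient Poisson equation on the grid.

    Neumann wall condition carrying the surface charge, Dirichlet far anchor
    psi(L) = psi_far. Second-order finite volumes with harmonic-mean interface
    permittivities. Returns psi in k_B T/e; psi[0] is the surface potential.
    """
    n = grid.n_nodes
    if rho_e.shape != (n,) or eps_r.shape != (n,):
        raise ValueError("rho_e and eps_r must be nodal arrays on the grid")
    if np.any(eps_r <= 0.0):
        raise ValueError("permittivity must be positive everywhere")
    h = grid.spacing
    lam0 = const.vacuum_bjerrum_length_nm(temperature)
    s = 4.0 * math.pi * lam0 * rho_e
    w = _interface_eps(eps_r)

    ab = np.zeros((3, n))
    rhs = np.zeros(n)
    # node 0 (half cell, Neumann): w0 (psi1 - psi0) = -h^2 s0 / 2 - h * 4 pi lam0 sigma
    ab[1, 0] = -w[0]
    ab[0, 1] = w[0]
    rhs[0] = -0.5 * h**2 * s[0] - h * 4.0 * math.pi * lam0 * sigma
    # interior
    ab[0, 2:] = w[1:]
    ab[1, 1:-1] = -(w[:-1] + w[1:])
    ab[2, 0:-2] = w[:-1]
    rhs[1:-1] = -(h**2) * s[1:-1]
    # far node Dirichlet (ab[0,-1] is row n-2's coupling to it and stays w[-1])
    ab[1, -1] = 1.0
    ab[2, -2] = 0.0
    rhs[-1] = psi_far
    return solve_banded((1, 1), ab, rhs)


def poisson_boltzmann_newton(
    weights: np.ndarray,
    valences: np.ndarray,
    eps_r: np.ndarray,
    sigma: float,
    grid: Grid,
    temperature: float = 298.15,
    psi0: Optional[np.ndarray] = None,
    tol: float = 1.0e-12,
    max_iter: int = 100,
) -> np.ndarray:
    """Damped Newton solve of the generalized PB equation.

    Solves d/dz(eps_r psi') = -4 pi lam0 sum_i q_i w_i(z) exp(-q_i psi) with the
    Neumann wall charge and psi(L) = 0. `weights` (M, N) are the Boltzmann
    prefactors: the bulk densities for classical PB, or the frozen short-range
    part of the Euler-Lagrange update for the semi-implicit cDFT step (zero
    inside hard-core masks).

    Raises RuntimeError on non-convergence.
    """
    n = grid.n_nodes
    h = grid.spacing
    lam0 = const.vacuum_bjerrum_length_nm(temperature)
    pref = 4.0 * math.pi * lam0
    w_if = _interface_eps(eps_r)
    psi = np.zeros(n) if psi0 is None else psi0.copy()
    psi[-1] = 0.0
    q = valences[:, None]
    cell = np.full(n, h**2)
    cell[0] = 0.5 * h**2

    def charge_terms(p: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        ex = np.exp(np.clip(-q * p[None, :], -300.0, 300.0))
        rho_q = np.sum(q * weights * ex, axis=0)
        drho = -np.sum(q**2 * weights * ex, axis=0)
        return rho_q, drho

    def residual(p: np.ndarray) -> np.ndarray:
        rho_q, _ = charge_terms(p)
        f = np.zeros(n)
        f[0] = w_if[0] * (p[1] - p[0]) + cell[0] * pref * rho_q[0] + h * pref * sigma
        f[1:-1] = (
            w_if[:-1] * p[:-2]
            - (w_if[:-1] + w_if[1:]) * p[1:-1]
            + w_if[1:] * p[2:]
            + cell[1:-1] * pref * rho_q[1:-1]
        )
        f[-1] = p[-1]
        return f

    f = residual(psi)
    norm = float(np.max(np.abs(f)))
    scale = max(1.0, abs(pref * sigma * h))
    for _ in range(max_iter):
        if norm < tol * scale:
            return psi
        _, drho = charge_terms(psi)
        ab = np.zeros((3, n))
        ab[1, 0] = -w_if[0] + cell[0] * pref * drho[0]
        ab[0, 1] = w_if[0]
        ab[0, 2:] = w_if[1:]
        ab[1, 1:-1] = -(w_if[:-1] + w_if[1:]) + cell[1:-1] * pref * drho[1:-1]
        ab[2, 0:-2] = w_if[:-1]
        ab[1, -1] = 1.0
        ab[2, -2] = 0.0
        step = solve_banded((1, 1), ab, -f)
        t = 1.0
        for _ in range(40):
            trial = psi + t * step
            f_trial = residual(trial)
            n_trial = float(np.max(np.abs(f_trial)))
            if n_trial < norm or n_trial < tol * scale:
                break
            t *= 0.5
        psi, f, norm = trial, f_trial, n_trial
    raise RuntimeError(f"PB Newton did not converge: residual {norm:.3e}")


def solve_pb(
    bulk: BulkState,
    sigma: float,
    grid: Grid,
    tol: float = 1.0e-12,
    max_iter: int = 100,
) -> Tuple[np.ndarray, np.ndarray]:
    """Nonlinear Poisson-Boltzmann solution for point ions at uniform eps_r.

    Returns (psi, rho) with psi in k_B T/e and rho the (M, N) Boltzmann ion
    profiles rho_i = rho_ib exp(-q_i psi). Global electroneutrality
    int rho_e dz = -sigma holds to the far-field truncation error.
    """
    mix = bulk.mixture
    n = grid.n_nodes
    weights = np.repeat(mix.bulk_densities[:, None], n, axis=1)
    eps = np.full(n, bulk.eps_r)
    psi = poisson_boltzmann_newton(
        weights, mix.valences, eps, sigma, grid, mix.temperature, tol=tol, max_iter=max_iter
    )
    rho = mix.bulk_densities[:, None] * np.exp(
        np.clip(-mix.valences[:, None] * psi[None, :], -300.0, 300.0)
    )
    return psi, rho


def gouy_chapman_potential(psi0: float, kappa: float, grid: Grid) -> np.ndarray:
    """Closed-form nonlinear PB potential for a symmetric monovalent electrolyte.

    psi(z) = 2 ln[(1 + g e^{-kz})/(1 - g e^{-kz})], g = tanh(psi0/4), with psi
    in k_B T/e. Monotone and sign-definite.
    """
    g = math.tanh(0.25 * psi0)
    if abs(g) >= 1.0:
        raise ValueError("surface potential out of range")
    e = g * np.exp(-kappa * grid.z)
    return 2.0 * np.log((1.0 + e) / (1.0 - e))


# ---------------------------------------------------------------------------
# electroosmotic diagnostic


@dataclass(frozen=True)
class FlowSpec:
    """Slip-plane position (nm) and the velocity-per-potential prefactor
    (applied field x eps eps0 / viscosity), in arbitrary consistent units."""

    z_slip: float
    prefactor: float = 1.0


def eo_velocity(psi: np.ndarray, flow: FlowSpec, grid: Grid) -> np.ndarray:
    """Electroosmotic velocity profile u(z) = -prefactor * (psi(z) - psi(z_slip)).

    The sign of the far-field (centreline) velocity flips when the slip plane
    sits in a charge-inverted (sign-reversed) region of the potential.
    """
    if flow.z_slip < 0.0 or flow.z_slip > grid.length:
        raise ValueError("slip plane outside the grid")
    psi_hs = float(np.interp(flow.z_slip, grid.z, psi))
    return -flow.prefactor * (psi - psi_hs)
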