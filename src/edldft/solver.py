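"""Euler-Lagrange fixed-point machinery for the inhomogeneous electrolyte.

The equilibrium profiles satisfy

    rho_i(z) = rho_ib exp( -[ Dmu_HS,i + q_i psi + Dmu_LJ,i + Dmu_SC,i
                              + V_i^ext ] / k_B T )

with psi from the Poisson equation whose wall boundary condition carries the
surface charge. These are solved by damped Picard iteration on the densities.

Each iteration refreshes the Poisson solve. By default this is done
*semi-implicitly*: the short-range fields Dmu_HS/LJ/SC are frozen, and psi is
obtained from an inner Newton solve of the Poisson equation with the Boltzmann
closure rho_i = w_i(z) exp(-q_i psi), w_i the frozen short-range Boltzmann
factor. The fixed point is identical to the literal explicit update
(psi from the previous densities), but the long-wavelength Coulomb stiffness
— which otherwise forces the mixing parameter below ~(kappa L)^-2 — is
removed, so modest mixing converges in hundreds rather than many thousands of
iterations. Set electrostatics="explicit" to recover the literal update.

The charge-regulated solve wraps this in an outer loop that re-samples the
surface proton activity and relaxes sigma toward its mass-action value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional

import numpy as np

from . import constants as const
from .bulk import BulkState
from .chemistry import SurfaceChemistry, surface_proton_activity, update_sigma
from .electrostatics import (
    DielectricModel,
    poisson_boltzmann_newton,
    solve_pb,
    solve_poisson,
    weighted_solvent_density,
)
from .functionals import FunctionalWorkspace, fmt_mu, lj_meanfield_mu, sc_mu, fmt_phi, weighted_densities
from .model import (
    ExternalPotential,
    Fields,
    Grid,
    Mixture,
    charge_density,
    hard_wall_potential,
    lj93_wall_potential,
)

__all__ = [
    "SolverConfig",
    "Solution",
    "ConvergenceError",
    "build_external_potentials",
    "euler_lagrange_profiles",
    "picard_solve",
    "charge_regulated_solve",
    "decompose_profile",
]

_EXP_CAP = 700.0


class ConvergenceError(RuntimeError):
    """Raised in strict mode when an iteration fails to converge."""

    def __init__(self, message: str, residual_history: Optional[List[float]] = None):
        super().__init__(message)
        self.residual_history = residual_history or []


@dataclass
class SolverConfig:
    """Numerical settings for the Picard / charge-regulation iterations.

    mixing : Picard mixing parameter alpha in (0, 1].
    tolerance : convergence threshold on the relative L-infinity fixed-point
        residual max_i max_z |rho_trial - rho| / rho_ib.
    cr_damping / cr_tolerance : damping and threshold (relative to e*N_s) of
        the outer surface-charge update.
    hs_on / lj_on / sc_on : functional toggles; all off reduces the solver to
        Poisson-Boltzmann with hard cores.
    initial_guess : "pb_seed" seeds psi (and Boltzmann densities) from the
        point-ion PB solution at the same sigma; "bulk" starts flat.
    electrostatics : "implicit" (inner Newton with Boltzmann closure) or
        "explicit" (potential from the previous densities).
    """

    mixing: float = 0.1
    tolerance: float = 1.0e-8
    max_iter: int = 20000
    cr_damping: float = 0.5
    cr_tolerance: float = 1.0e-8
    cr_max_outer: int = 200
    hs_on: bool = True
    lj_on: bool = True
    sc_on: bool = False
    dielectric: DielectricModel = dc_field(default_factory=DielectricModel)
    initial_guess: str = "pb_seed"
    electrostatics: str = "implicit"
    min_mixing: float = 1.0e-4
    strict: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.mixing <= 1.0:
            raise ValueError("mixing must be in (0, 1]")
        if self.tolerance <= 0.0:
            raise ValueError("tolerance must be positive")
        if self.electrostatics not in ("implicit", "explicit"):
            raise ValueError("electrostatics must be 'implicit' or 'explicit'")


@dataclass
class Solution:
    """A converged (or best-effort) EDL solution.

    surface_excess maps species name to Gamma_i = int (rho_i - rho_ib) dz in
    nm^-2. sigma in e/nm^2, psi0 in k_B T/e. `electroneutrality` is the
    relative defect |int rho_e dz + sigma| / max(|sigma|, eps).
    """

    mixture: Mixture
    grid: Grid
    fields: Fields
    bulk: BulkState
    sigma: float
    psi0: float
    converged: bool
    iterations: int
    residual_history: List[float]
    omega_history: List[float]
    electroneutrality: float
    config: SolverConfig
    v_ext: List[ExternalPotential]
    psi0_history: List[float] = dc_field(default_factory=list)
    overflow_clips: int = 0
    cr_residual: Optional[float] = None
    cr_outer_iterations: int = 0
    h_surface_molar: Optional[float] = None

    @property
    def rho_e(self) -> np.ndarray:
        return charge_density(self.fields, self.mixture)

    @property
    def surface_excess(self) -> Dict[str, float]:
        out = {}
        for i, sp in enumerate(self.mixture.species):
            out[sp.name] = self.grid.trapz(self.fields.rho[i] - sp.bulk_density)
        return out

    def summary(self) -> Dict[str, object]:
        return {
            "sigma_e_per_nm2": self.sigma,
            "sigma_C_per_m2": const.sigma_reduced_to_si(self.sigma),
            "psi0_kT_per_e": self.psi0,
            "psi0_mV": self.psi0 * const.thermal_voltage_mV(self.mixture.temperature),
            "converged": self.converged,
            "iterations": self.iterations,
            "final_residual": (self.residual_history[-1] if self.residual_history else None),
            "electroneutrality_defect": self.electroneutrality,
            "surface_excess_per_nm2": self.surface_excess,
            "cr_residual": self.cr_residual,
            "cr_outer_iterations": self.cr_outer_iterations,
            "surface_pH": (
                -math.log10(self.h_surface_molar) if self.h_surface_molar else None
            ),
        }


def build_external_potentials(mixture: Mixture, grid: Grid) -> List[ExternalPotential]:
    """Per-species wall potentials from each species' wall_kind."""
    out = []
    for sp in mixture.species:
        if sp.wall_kind == "lj93":
            out.append(lj93_wall_potential(sp, grid))
        else:
            out.append(hard_wall_potential(sp, grid))
    return out


def _short_range_mu(
    fields: Fields,
    mixture: Mixture,
    bulk: BulkState,
    ws: FunctionalWorkspace,
    cfg: SolverConfig,
) -> np.ndarray:
    """Sum of the enabled non-electrostatic Delta-mu operators, (M, N) in k_B T."""
    mu = np.zeros_like(fields.rho)
    if cfg.hs_on:
        mu += fmt_mu(fields, mixture, ws)
    if cfg.lj_on and ws.lj_kernels:
        mu += lj_meanfield_mu(fields, mixture, ws)
    if cfg.sc_on and bulk.gamma > 0.0:
        mu += sc_mu(fields, bulk, ws)
    return mu


def euler_lagrange_profiles(
    fields: Fields,
    mixture: Mixture,
    bulk: BulkState,
    cfg: SolverConfig,
    v_ext: Optional[List[ExternalPotential]] = None,
    ws: Optional[FunctionalWorkspace] = None,
) -> np.ndarray:
    """One explicit Euler-Lagrange update: trial densities from the current
    fields (densities *and* potential), zero inside the hard-core masks."""
    if v_ext is None:
        v_ext = build_external_potentials(mixture, fields.grid)
    if ws is None:
        ws = FunctionalWorkspace(mixture, fields.grid, bulk)
    mu_sr = _short_range_mu(fields, mixture, bulk, ws, cfg)
    trial = np.zeros_like(fields.rho)
    for i, sp in enumerate(mixture.species):
        expo = -(mu_sr[i] + sp.valence * fields.psi + v_ext[i].values)
        expo = np.clip(expo, -_EXP_CAP, _EXP_CAP)
        trial[i] = sp.bulk_density * np.exp(expo)
        trial[i][v_ext[i].mask] = 0.0
    return trial


def _electroneutrality_defect(
    fields: Fields, mixture: Mixture, sigma: float
) -> float:
    grid = fields.grid
    rho_e = charge_density(fields, mixture)
    total = grid.trapz(rho_e)
    scale = max(abs(sigma), 1.0e-12)
    return abs(total + sigma) / scale


def _omega_per_area(
    fields: Fields,
    mixture: Mixture,
    bulk: BulkState,
    ws: FunctionalWorkspace,
    cfg: SolverConfig,
    v_ext: List[ExternalPotential],
    sigma: float,
) -> float:
    """Grand potential per unit area relative to the bulk reservoir (k_B T/nm^2).

    Diagnostic only (constant offsets from the fixed-domain hard-sphere
    reference are irrelevant: the quantity is tracked along the iteration)."""
    grid = fields.grid
    rho_b = mixture.bulk_densities
    dev = fields.rho - rho_b[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(fields.rho > 0.0, fields.rho / rho_b[:, None], 1.0)
        ideal = fields.rho * np.log(ratio) - dev
    omega = float(sum(grid.trapz(ideal[i]) for i in range(mixture.n_species)))
    if cfg.hs_on:
        n = weighted_densities(fields, mixture, ws)
        phi = fmt_phi(n)
        from .bulk import hs_phi_bulk

        phi_b = hs_phi_bulk(mixture, rho_b)
        omega += grid.spacing * float(np.sum(phi - phi_b))
        omega -= float(np.sum(ws.mu_hs_bulk * np.array([grid.trapz(dev[i]) for i in range(mixture.n_species)])))
    if cfg.lj_on and ws.lj_kernels:
        mu_lj = lj_meanfield_mu(fields, mixture, ws)
        omega += 0.5 * float(sum(grid.trapz(dev[i] * mu_lj[i]) for i in range(mixture.n_species)))
    if cfg.sc_on and bulk.gamma > 0.0:
        mu_sc_arr = sc_mu(fields, bulk, ws)
        omega += 0.5 * float(sum(grid.trapz(dev[i] * mu_sc_arr[i]) for i in range(mixture.n_species)))
    for i in range(mixture.n_species):
        omega += grid.trapz(fields.rho[i] * v_ext[i].values)
    rho_e = charge_density(fields, mixture)
    omega += 0.5 * (grid.trapz(rho_e * fields.psi) + sigma * fields.psi[0])
    return omega


def _initial_fields(
    mixture: Mixture,
    grid: Grid,
    bulk: BulkState,
    cfg: SolverConfig,
    sigma: float,
    v_ext: List[ExternalPotential],
) -> Fields:
    fields = Fields.bulk(mixture, grid, eps_r=bulk.eps_r)
    if cfg.initial_guess == "pb_seed" and abs(sigma) > 0.0 and bulk.kappa > 0.0:
        psi, _ = solve_pb(bulk, sigma, grid)
        fields.psi = psi
        for i, sp in enumerate(mixture.species):
            expo = np.clip(-sp.valence * psi, -_EXP_CAP, _EXP_CAP)
            fields.rho[i] = sp.bulk_density * np.exp(expo)
    for i in range(mixture.n_species):
        fields.rho[i][v_ext[i].mask] = 0.0
    return fields


def _solvent_eps_profile(
    fields: Fields, mixture: Mixture, cfg: SolverConfig
) -> np.ndarray:
    """Permittivity profile from the previous iteration's solvent density."""
    model = cfg.dielectric
    if model.kind == "uniform":
        return np.full(fields.grid.n_nodes, model.eps_r)
    solv = mixture.solvent
    if solv is None:
        raise ValueError("density-dependent dielectric needs a solvent species")
    idx = mixture.index(solv.name)
    rho_t = weighted_solvent_density(fields.rho[idx], solv.diameter, fields.grid)
    return model.eps_profile(rho_t, solv.diameter, fields.grid.n_nodes)


def bulk_eps_r(mixture: Mixture, dielectric: DielectricModel) -> float:
    """Bulk relative permittivity implied by the dielectric model."""
    if dielectric.kind == "uniform":
        return dielectric.eps_r
    solv = mixture.solvent
    if solv is None:
        raise ValueError("density-dependent dielectric needs a solvent species")
    val = dielectric.eps_profile(
        np.array([solv.bulk_density]), solv.diameter, 1
    )
    return float(val[0])


def picard_solve(
    mixture: Mixture,
    grid: Grid,
    sigma: float,
    cfg: SolverConfig,
    bulk: Optional[BulkState] = None,
    initial: Optional[Fields] = None,
    ws: Optional[FunctionalWorkspace] = None,
    track_omega: bool = False,
) -> Solution:
    """Damped Picard solve of the Euler-Lagrange equations at fixed sigma.

    Deterministic for fixed inputs. Returns a Solution; in strict mode a
    non-converged run raises ConvergenceError instead.
    """
    if bulk is None:
        # BulkState construction enforces the restricted-model (equal ion
        # diameter) requirement whenever sc_on asks for the MSA kernel
        bulk = BulkState(mixture, bulk_eps_r(mixture, cfg.dielectric))
    v_ext = build_external_potentials(mixture, grid)
    if ws is None:
        ws = FunctionalWorkspace(mixture, grid, bulk)
    fields = initial.copy() if initial is not None else _initial_fields(
        mixture, grid, bulk, cfg, sigma, v_ext
    )

    alpha = cfg.mixing
    residuals: List[float] = []
    psi0s: List[float] = []
    omegas: List[float] = []
    clips = 0
    rho_b = mixture.bulk_densities
    valences = mixture.valences
    rising = 0
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        eps_prof = _solvent_eps_profile(fields, mixture, cfg)
        mu_sr = _short_range_mu(fields, mixture, bulk, ws, cfg)
        expo = -(mu_sr + np.stack([v.values for v in v_ext]))
        n_over = int(np.sum(np.abs(expo) > _EXP_CAP))
        if n_over:
            clips += n_over
            expo = np.clip(expo, -_EXP_CAP, _EXP_CAP)
        weights = rho_b[:, None] * np.exp(expo)
        for i, v in enumerate(v_ext):
            weights[i][v.mask] = 0.0

        if cfg.electrostatics == "implicit":
            psi = poisson_boltzmann_newton(
                weights, valences, eps_prof, sigma, grid, mixture.temperature,
                psi0=fields.psi,
            )
        else:
            rho_e = charge_density(fields, mixture)
            psi = solve_poisson(rho_e, eps_prof, sigma, grid, mixture.temperature)

        trial = weights * np.exp(
            np.clip(-valences[:, None] * psi[None, :], -_EXP_CAP, _EXP_CAP)
        )
        resid = float(np.max(np.abs(trial - fields.rho) / rho_b[:, None]))
        residuals.append(resid)
        psi0s.append(float(psi[0]))

        fields.rho = (1.0 - alpha) * fields.rho + alpha * trial
        fields.psi = psi
        fields.eps_r = eps_prof

        if track_omega:
            omegas.append(
                _omega_per_area(fields, mixture, bulk, ws, cfg, v_ext, sigma)
            )

        if resid < cfg.tolerance:
            converged = True
            break
        if len(residuals) >= 2 and resid > residuals[-2]:
            rising += 1
            if rising >= 3 and alpha > cfg.min_mixing:
                alpha = max(0.5 * alpha, cfg.min_mixing)
                rising = 0
        else:
            rising = 0

    defect = _electroneutrality_defect(fields, mixture, sigma)
    sol = Solution(
        mixture=mixture,
        grid=grid,
        fields=fields,
        bulk=bulk,
        sigma=sigma,
        psi0=float(fields.psi[0]),
        converged=converged,
        iterations=it,
        residual_history=residuals,
        omega_history=omegas,
        electroneutrality=defect,
        config=cfg,
        v_ext=v_ext,
        psi0_history=psi0s,
        overflow_clips=clips,
    )
    if cfg.strict and not converged:
        raise ConvergenceError(
            f"Picard did not converge in {cfg.max_iter} iterations "
            f"(last residual {residuals[-1]:.3e})",
            residuals,
        )
    return sol


def charge_regulated_solve(
    mixture: Mixture,
    grid: Grid,
    chem: SurfaceChemistry,
    cfg: SolverConfig,
    bulk: Optional[BulkState] = None,
) -> Solution:
    """Outer charge-regulation loop around the Picard solver.

    Each outer pass solves the profiles at the current sigma (warm-started from
    the previous pass, with an inner tolerance that tightens as sigma
    converges), samples the surface proton activity, and relaxes sigma toward
    its mass-action value. A period-2 oscillation in the sigma updates halves
    the damping, up to 6 times.
    """
    ih = mixture.index(chem.proton)
    proton = mixture.species[ih]
    if bulk is None:
        bulk = BulkState(mixture, bulk_eps_r(mixture, cfg.dielectric))
    ws = FunctionalWorkspace(mixture, grid, bulk)
    v_ext = build_external_potentials(mixture, grid)

    h_bulk = const.per_nm3_to_molar(proton.bulk_density)
    sigma = chem.sigma_mass_action(h_bulk)
    damping = cfg.cr_damping
    halvings = 0
    fields: Optional[Fields] = None
    deltas: List[float] = []
    sol: Optional[Solution] = None
    h_s = h_bulk
    cr_res = math.inf

    for outer in range(1, cfg.cr_max_outer + 1):
        inner_cfg_tol = max(cfg.tolerance, min(1.0e-4, 1.0e-2 * cr_res / max(chem.n_sites, 1e-12)))
        inner = SolverConfig(**{**cfg.__dict__, "tolerance": inner_cfg_tol, "strict": False})
        sol = picard_solve(
            mixture, grid, sigma, inner, bulk=bulk, initial=fields, ws=ws
        )
        fields = sol.fields
        h_s = surface_proton_activity(
            fields.rho[ih], grid, proton.radius, chem, v_ext[ih]
        )
        sigma_new, cr_res = update_sigma(sigma, h_s, chem, damping)
        deltas.append(sigma_new - sigma)
        # period-2 oscillation: successive updates of alternating sign
        if (
            len(deltas) >= 4
            and all(deltas[-k] * deltas[-k - 1] < 0.0 for k in (1, 2, 3))
        ):
            if halvings >= 6:
                if cfg.strict:
                    raise ConvergenceError(
                        "charge-regulation loop oscillates despite damping halvings"
                    )
                break
            damping *= 0.5
            halvings += 1
            deltas.clear()
        sigma = sigma_new
        if cr_res / max(chem.n_sites, 1.0e-300) < cfg.cr_tolerance:
            break

    # final pass at full tolerance and the settled sigma
    final_cfg = SolverConfig(**{**cfg.__dict__, "strict": cfg.strict})
    sol = picard_solve(mixture, grid, sigma, final_cfg, bulk=bulk, initial=fields, ws=ws)
    h_s = surface_proton_activity(
        sol.fields.rho[ih], grid, proton.radius, chem, v_ext[ih]
    )
    _, cr_res = update_sigma(sigma, h_s, chem, 1.0)
    sol.cr_residual = cr_res / max(chem.n_sites, 1.0e-300)
    sol.cr_outer_iterations = outer
    sol.h_surface_molar = h_s
    return sol


def decompose_profile(sol: Solution) -> Dict[str, np.ndarray]:
    """Per-species decomposition of the potential-of-mean-force balance.

    Returns aligned profiles {log: -kT ln(rho/rho_b), hs, q_psi, sc, lj, v_ext}
    (each (M, N), in k_B T) and verifies the Euler-Lagrange identity

        q_i dPsi = -kT ln(rho_i/rho_ib) - Dmu_HS - Dmu_SC - Dmu_LJ - V_ext

    node by node wherever the density is nonzero; the residual, weighted back
    to density scale, must stay below the solver tolerance.
    """
    if not sol.converged:
        raise ValueError(
            "decomposition requires a converged solution "
            f"(residual {sol.residual_history[-1] if sol.residual_history else 'n/a'})"
        )
    mixture, cfg = sol.mixture, sol.config
    ws = FunctionalWorkspace(mixture, sol.grid, sol.bulk)
    zeros = np.zeros_like(sol.fields.rho)
    hs = fmt_mu(sol.fields, mixture, ws) if cfg.hs_on else zeros.copy()
    lj = (
        lj_meanfield_mu(sol.fields, mixture, ws)
        if cfg.lj_on and ws.lj_kernels
        else zeros.copy()
    )
    sc = (
        sc_mu(sol.fields, sol.bulk, ws)
        if cfg.sc_on and sol.bulk.gamma > 0.0
        else zeros.copy()
    )
    rho_b = mixture.bulk_densities[:, None]
    with np.errstate(divide="ignore"):
        log_term = -np.log(np.where(sol.fields.rho > 0.0, sol.fields.rho / rho_b, 1.0))
    q_psi = mixture.valences[:, None] * sol.fields.psi[None, :]
    v_ext = np.stack([v.values for v in sol.v_ext])
    mask = np.stack([v.mask for v in sol.v_ext])

    resid = q_psi - (log_term - hs - sc - lj - v_ext)
    # convert the log-space residual to the density-space Picard metric
    weight = np.where(mask | (sol.fields.rho <= 0.0), 0.0, sol.fields.rho / rho_b)
    worst = float(np.max(np.abs(resid) * weight))
    tol = 50.0 * max(cfg.tolerance, 1.0e-12)
    if worst > tol:
        raise ValueError(
            f"Euler-Lagrange identity violated: weighted residual {worst:.3e} > {tol:.3e}"
        )
    return {
        "log": log_term,
        "hs": hs,
        "q_psi": q_psi,
        "sc": sc,
        "lj": lj,
        "v_ext": v_ext,
        "identity_residual": resid,
    }
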