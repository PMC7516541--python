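"""Homogeneous-fluid reference quantities.

Debye screening, the restricted-MSA screening parameter Gamma, and bulk excess
chemical potentials / pressure that are exactly the uniform limits of the
inhomogeneous functionals — this consistency is what makes density profiles
relax to their bulk values far from the wall.

All quantities in reduced units: lengths nm, energies k_B T, charges e.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict

import numpy as np

from . import constants as const
from .model import Mixture

__all__ = ["BulkState", "debye_kappa", "msa_gamma", "hs_mu_excess", "hs_pressure_excess"]

_MAX_PACKING = 0.74


def debye_kappa(mixture: Mixture, eps_r: float) -> float:
    """Inverse Debye length kappa in nm^-1.

    kappa^2 = 4 pi lambda_B sum_i q_i^2 rho_ib with lambda_B the Bjerrum length
    at the mixture temperature. Returns 0 for an ion-free mixture.
    """
    lam_b = const.bjerrum_length_nm(eps_r, mixture.temperature)
    s = 0.0
    for sp in mixture.species:
        if sp.bulk_density < 0.0:
            raise ValueError(f"species {sp.name!r}: negative bulk density")
        s += sp.valence**2 * sp.bulk_density
    return math.sqrt(4.0 * math.pi * lam_b * s)


def msa_gamma(kappa: float, d: float) -> float:
    """Restricted-MSA screening parameter Gamma = (sqrt(1 + 2*kappa*d) - 1)/(2d).

    Valid for the restricted model (all ions share diameter d). Gamma < kappa/2
    always; Gamma -> kappa/2 as kappa*d -> 0 (the Debye-Hueckel limit).
    """
    if d <= 0.0:
        raise ValueError("ion diameter must be positive")
    if kappa < 0.0:
        raise ValueError("kappa must be >= 0")
    return (math.sqrt(1.0 + 2.0 * kappa * d) - 1.0) / (2.0 * d)


def _common_ion_diameter(mixture: Mixture) -> float:
    d_ions = {s.diameter for s in mixture.species if s.valence != 0}
    if len(d_ions) > 1:
        raise ValueError(
            "the MSA screening-correlation model is restricted to equal ion "
            f"diameters; got {sorted(d_ions)} — run with sc disabled or use "
            "equal-diameter ions"
        )
    return d_ions.pop() if d_ions else 0.0


def hs_mu_excess(mixture: Mixture, rho: np.ndarray) -> np.ndarray:
    """Scaled-particle (PY-compressibility) hard-sphere excess chemical potentials.

    Analytic uniform limit of the Rosenfeld functional: beta*mu_i^HS =
    sum_alpha dPhi/dn_alpha * dn_alpha/drho_i evaluated at the bulk weighted
    densities. rho is the per-species density vector in nm^-3.
    """
    d = mixture.diameters
    n3 = float(np.sum(math.pi / 6.0 * d**3 * rho))
    if n3 >= 1.0 - 1.0e-6:
        raise ValueError(f"bulk packing fraction {n3:.6f} too close to 1: diverging")
    n2 = float(np.sum(math.pi * d**2 * rho))
    n1 = float(np.sum(0.5 * d * rho))
    n0 = float(np.sum(rho))
    om = 1.0 - n3
    dphi0 = -math.log(om)
    dphi1 = n2 / om
    dphi2 = n1 / om + n2**2 / (8.0 * math.pi * om**2)
    dphi3 = n0 / om + n1 * n2 / om**2 + n2**3 / (12.0 * math.pi * om**3)
    return dphi0 + dphi1 * (0.5 * d) + dphi2 * (math.pi * d**2) + dphi3 * (math.pi / 6.0 * d**3)


def hs_phi_bulk(mixture: Mixture, rho: np.ndarray) -> float:
    """Rosenfeld free-energy density (in k_B T/nm^3) of the uniform mixture."""
    d = mixture.diameters
    n3 = float(np.sum(math.pi / 6.0 * d**3 * rho))
    n2 = float(np.sum(math.pi * d**2 * rho))
    n1 = float(np.sum(0.5 * d * rho))
    n0 = float(np.sum(rho))
    om = 1.0 - n3
    return -n0 * math.log(om) + n1 * n2 / om + n2**3 / (24.0 * math.pi * om**2)


def hs_pressure_excess(mixture: Mixture, rho: np.ndarray) -> float:
    """Excess hard-sphere pressure (k_B T/nm^3) via P = sum rho_i mu_i - f."""
    mu = hs_mu_excess(mixture, rho)
    return float(np.sum(rho * mu)) - hs_phi_bulk(mixture, rho)


def _lj_integral(eps: float, d: float) -> float:
    """3D integral of the LJ pair energy over r > d: -32 pi eps d^3 / 9 (k_B T nm^3)."""
    return -32.0 * math.pi * eps * d**3 / 9.0


@dataclass
class BulkState:
    """Bulk thermodynamic state of a mixture at uniform relative permittivity.

    Attributes
    ----------
    kappa : inverse Debye length (nm^-1)
    lambda_b : Bjerrum length (nm)
    gamma : restricted-MSA screening parameter (nm^-1); 0 for ion-free mixtures
    mu_hs, mu_sc, mu_lj : per-species excess chemical potentials (k_B T)
    pressure : total bulk pressure (k_B T / nm^3)
    """

    mixture: Mixture
    eps_r: float
    kappa: float = field(init=False)
    lambda_b: float = field(init=False)
    gamma: float = field(init=False)
    ion_diameter: float = field(init=False)
    mu_hs: np.ndarray = field(init=False)
    mu_sc: np.ndarray = field(init=False)
    mu_lj: np.ndarray = field(init=False)
    pressure: float = field(init=False)

    def __post_init__(self) -> None:
        mix = self.mixture
        rho = mix.bulk_densities
        eta = mix.packing_fraction
        if eta >= _MAX_PACKING:
            raise ValueError(f"total packing fraction {eta:.3f} exceeds {_MAX_PACKING}")
        self.lambda_b = const.bjerrum_length_nm(self.eps_r, mix.temperature)
        self.kappa = debye_kappa(mix, self.eps_r)
        self.ion_diameter = _common_ion_diameter(mix)
        if self.kappa > 0.0 and self.ion_diameter > 0.0:
            self.gamma = msa_gamma(self.kappa, self.ion_diameter)
        else:
            self.gamma = 0.0

        self.mu_hs = hs_mu_excess(mix, rho)

        q = mix.valences
        gd = self.gamma * self.ion_diameter
        self.mu_sc = -self.lambda_b * q**2 * self.gamma / (1.0 + gd)

        m = mix.n_species
        a = np.zeros((m, m))
        for i in range(m):
            for j in range(m):
                eps = mix.pair_epsilon[i, j]
                if eps > 0.0:
                    d_ij = 0.5 * (mix.species[i].diameter + mix.species[j].diameter)
                    a[i, j] = _lj_integral(eps, d_ij)
        self.mu_lj = a @ rho

        p_id = float(np.sum(rho))
        p_hs = hs_pressure_excess(mix, rho)
        p_lj = 0.5 * float(rho @ a @ rho)
        p_sc = -self.gamma**3 / (3.0 * math.pi)
        self.pressure = p_id + p_hs + p_lj + p_sc

    @property
    def mu_excess(self) -> np.ndarray:
        """Total per-species excess chemical potential (k_B T)."""
        return self.mu_hs + self.mu_sc + self.mu_lj

    def summary(self) -> Dict[str, object]:
        mix = self.mixture
        return {
            "temperature_K": mix.temperature,
            "eps_r_bulk": self.eps_r,
            "debye_length_nm": (1.0 / self.kappa if self.kappa > 0 else math.inf),
            "bjerrum_length_nm": self.lambda_b,
            "msa_gamma_per_nm": self.gamma,
            "packing_fraction": mix.packing_fraction,
            "pressure_kT_per_nm3": self.pressure,
            "mu_excess_kT": {
                s.name: {
                    "hs": float(self.mu_hs[i]),
                    "sc": float(self.mu_sc[i]),
                    "lj": float(self.mu_lj[i]),
                    "total": float(self.mu_excess[i]),
                }
                for i, s in enumerate(mix.species)
            },
        }
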