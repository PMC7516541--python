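"""Charge-regulation surface chemistry: the 2-pK amphoteric site model.

A surface site A can exist as AH2+ (protonated), AH (neutral) or A-
(deprotonated), with mass-action constants

    AH2+  <=>  AH + H+     K+ = 10^{-pK+}
    AH    <=>  A-  + H+    K- = 10^{-pK-}

so the surface charge sigma = e N_s (f+ - f-) is set by the proton activity
*at the surface*, not prescribed. The proton is an explicit solution species;
its surface activity is sampled from its density profile (contact value,
narrow-window average, or the cavity y-function).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from . import constants as const
from .model import ExternalPotential, Grid

__all__ = [
    "SiteFractions",
    "SurfaceChemistry",
    "site_fractions",
    "sigma_from_fractions",
    "surface_proton_activity",
    "update_sigma",
]


@dataclass(frozen=True)
class SiteFractions:
    """Populations of the three site states; f_plus + f_neutral + f_minus = 1."""

    f_plus: float
    f_neutral: float
    f_minus: float

    @property
    def net(self) -> float:
        return self.f_plus - self.f_minus


def site_fractions(h_s: float, pk_plus: float, pk_minus: float) -> SiteFractions:
    """Mass-action site fractions at surface proton activity h_s (mol/L).

    f+ = (h/K+)/D, f0 = 1/D, f- = (K-/h)/D with D = 1 + h/K+ + K-/h.
    At h_s = sqrt(K+ K-) the surface is at its point of zero charge.
    """
    if h_s <= 0.0:
        raise ValueError("surface proton activity must be positive")
    # work in log10 space to stay finite for extreme pK values
    lg_h = math.log10(h_s)
    a_plus = 10.0 ** (lg_h + pk_plus)  # h/K+
    a_minus = 10.0 ** (-(lg_h + pk_minus))  # K-/h
    d = 1.0 + a_plus + a_minus
    return SiteFractions(a_plus / d, 1.0 / d, a_minus / d)


def sigma_from_fractions(fr: SiteFractions, n_sites: float) -> float:
    """Surface charge sigma = N_s (f+ - f-) in e/nm^2 for N_s in nm^-2."""
    return n_sites * fr.net


@dataclass
class SurfaceChemistry:
    """2-pK site model parameters.

    Parameters
    ----------
    n_sites : float
        Ionizable site density N_s in nm^-2.
    pk_plus, pk_minus : float
        pK+ < pK- for a well-posed amphoteric site; the point of zero charge
        sits at pH = (pK+ + pK-)/2.
    proton : str
        Name of the proton species in the mixture.
    sampling : {"window", "contact", "yfunction"}
        How the surface proton activity is read off the profile. Default is a
        density average over a narrow window of width `window_width` (in nm;
        defaults to half the proton diameter) starting at contact.
    """

    n_sites: float
    pk_plus: float
    pk_minus: float
    proton: str = "H"
    sampling: str = "window"
    window_width: Optional[float] = None
    y_wall_position: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_sites <= 0.0:
            raise ValueError("site density must be positive")
        if self.pk_plus >= self.pk_minus:
            raise ValueError("need pK+ < pK- for an amphoteric site")
        if self.sampling not in ("window", "contact", "yfunction"):
            raise ValueError(f"unknown sampling mode {self.sampling!r}")

    @property
    def pzc_pH(self) -> float:
        return 0.5 * (self.pk_plus + self.pk_minus)

    def sigma_mass_action(self, h_s: float) -> float:
        return sigma_from_fractions(site_fractions(h_s, self.pk_plus, self.pk_minus), self.n_sites)

    def sigma_bounds(self) -> Tuple[float, float]:
        return (-self.n_sites, self.n_sites)


def surface_proton_activity(
    rho_h: np.ndarray,
    grid: Grid,
    contact_z: float,
    chem: SurfaceChemistry,
    v_ext: Optional[ExternalPotential] = None,
) -> float:
    """Surface proton activity h_s in mol/L from the proton density profile.

    contact mode: rho_H at the contact plane (z = d_H/2).
    window mode: mean of rho_H over [contact, contact + w].
    yfunction mode: the cavity function y(z) = rho exp(V_ext/kT) evaluated at
    the effective hard-wall position (defaults to the contact plane); for an
    ideal gas in an external field all three agree with the bulk activity.
    """
    # interpolate only over the physical (unmasked) region: the profile jumps
    # from 0 to its contact value exactly at the contact plane, so nodes inside
    # the exclusion zone must not enter the interpolation
    k0 = int(np.searchsorted(grid.z, contact_z - 1.0e-12 * grid.spacing))
    z = grid.z[k0:]
    prof = rho_h[k0:]
    mode = chem.sampling
    if mode == "contact":
        val = float(np.interp(contact_z, z, prof))
    elif mode == "window":
        w = chem.window_width
        if w is None:
            w = contact_z  # half the proton diameter
        if contact_z + w > grid.length:
            raise ValueError("sampling window extends past the grid")
        if w <= 0.0:
            val = float(np.interp(contact_z, z, prof))
        else:
            zz = np.linspace(contact_z, contact_z + w, 33)
            val = float(np.trapezoid(np.interp(zz, z, prof), zz) / w)
    else:  # yfunction
        if v_ext is None:
            raise ValueError("yfunction sampling needs the proton external potential")
        y = np.where(v_ext.mask, 0.0, rho_h * np.exp(np.clip(v_ext.values, None, 300.0)))
        z_eff = chem.y_wall_position if chem.y_wall_position is not None else contact_z
        val = float(np.interp(z_eff, z, y[k0:]))
    if val <= 0.0:
        raise ValueError("sampled surface proton density is not positive")
    return const.per_nm3_to_molar(val)


def update_sigma(
    sigma: float, h_s: float, chem: SurfaceChemistry, damping: float
) -> Tuple[float, float]:
    """Damped mass-action update of the surface charge.

    sigma_new = (1 - a) sigma + a sigma_ma(h_s); returns (sigma_new, residual)
    with residual = |sigma_ma - sigma| the charge-regulation defect in e/nm^2.
    """
    if not 0.0 < damping <= 1.0:
        raise ValueError("damping must be in (0, 1]")
    target = chem.sigma_mass_action(h_s)
    return (1.0 - damping) * sigma + damping * target, abs(target - sigma)
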