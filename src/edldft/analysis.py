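"""Post-processing diagnostics on converged solutions."""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
from scipy.signal import find_peaks

from .model import charge_density
from .solver import Solution

__all__ = ["charge_layering_period", "potential_is_monotone"]


def charge_layering_period(
    sol: Solution,
    d0: Optional[float] = None,
    window_diameters: float = 5.0,
) -> Tuple[float, np.ndarray]:
    """Mean spacing of successive local maxima of rho_e(z) near the wall.

    Looks for local maxima of the fluid charge density within
    `window_diameters` solvent diameters of the wall and returns
    (mean peak-to-peak spacing in units of d0, peak positions in nm).
    d0 defaults to the mixture's solvent diameter.

    Solvent packing imprints an oscillation of period ~= 1 d0 on the charge
    density, so the expected value for a layered EDL is ~1.
    """
    if d0 is None:
        solv = sol.mixture.solvent
        if solv is None:
            raise ValueError("no solvent species: pass d0 explicitly")
        d0 = solv.diameter
    z = sol.grid.z
    rho_e = charge_density(sol.fields, sol.mixture)
    sel = z <= window_diameters * d0
    signal = rho_e[sel]
    # prominence threshold keeps quadrature ripple out of the peak set
    prom = 1.0e-3 * float(np.max(np.abs(signal))) if np.any(signal != 0.0) else 0.0
    peaks, _ = find_peaks(signal, prominence=prom)
    z_peaks = z[sel][peaks]
    if len(z_peaks) < 2:
        raise ValueError(
            f"found {len(z_peaks)} charge-density maxima within {window_diameters} d0; "
            "no layering period defined"
        )
    spacing = float(np.mean(np.diff(z_peaks)))
    return spacing / d0, z_peaks


def potential_is_monotone(sol: Solution, rtol: float = 1.0e-6) -> bool:
    """True when psi(z) has no sign change and no interior extremum.

    Small numerical ripple below rtol * max|psi| is ignored.
    """
    psi = sol.fields.psi
    scale = float(np.max(np.abs(psi)))
    if scale == 0.0:
        return True
    tol = rtol * scale
    signs = np.sign(psi[np.abs(psi) > tol])
    if len(signs) and (np.any(signs > 0) and np.any(signs < 0)):
        return False
    d = np.diff(psi)
    d = d[np.abs(d) > tol * 1.0e-3]
    return bool(np.all(d >= 0.0) or np.all(d <= 0.0))
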