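"""Physical constants (CODATA 2018) and unit conversions.

Internal unit system used throughout the package:

* length      — nanometres
* energy      — k_B T (the solver is isothermal; T is fixed per Mixture)
* charge      — elementary charges e
* density     — nm^-3
* surface charge — e / nm^2
* potential   — k_B T / e ("thermal volts")

SI values enter only at configuration parsing and output writing.
"""

from __future__ import annotations

# CODATA 2018 exact values
ELEMENTARY_CHARGE = 1.602176634e-19  # C
BOLTZMANN = 1.380649e-23  # J/K
VACUUM_PERMITTIVITY = 8.8541878128e-12  # F/m
AVOGADRO = 6.02214076e23  # 1/mol

#: number density (nm^-3) of a 1 mol/L solution
MOLAR_TO_PER_NM3 = AVOGADRO / 1.0e24

#: surface charge: 1 e/nm^2 in C/m^2
E_PER_NM2_TO_C_PER_M2 = ELEMENTARY_CHARGE * 1.0e18


def molar_to_per_nm3(c_molar: float) -> float:
    """Convert a molar concentration (mol/L) to a number density in nm^-3."""
    return c_molar * MOLAR_TO_PER_NM3


def per_nm3_to_molar(rho: float) -> float:
    """Convert a number density in nm^-3 to mol/L."""
    return rho / MOLAR_TO_PER_NM3


def sigma_si_to_reduced(sigma_c_per_m2: float) -> float:
    """Convert a surface charge density from C/m^2 to e/nm^2."""
    return sigma_c_per_m2 / E_PER_NM2_TO_C_PER_M2


def sigma_reduced_to_si(sigma_e_per_nm2: float) -> float:
    """Convert a surface charge density from e/nm^2 to C/m^2."""
    return sigma_e_per_nm2 * E_PER_NM2_TO_C_PER_M2


def thermal_voltage_mV(temperature: float) -> float:
    """k_B T / e in millivolts at the given temperature (K)."""
    return BOLTZMANN * temperature / ELEMENTARY_CHARGE * 1.0e3


def bjerrum_length_nm(eps_r: float, temperature: float) -> float:
    """Bjerrum length e^2/(4 pi eps_r eps0 k_B T) in nm."""
    import math

    if eps_r <= 0.0:
        raise ValueError(f"relative permittivity must be positive, got {eps_r}")
    if temperature <= 0.0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    lam_si = ELEMENTARY_CHARGE**2 / (
        4.0 * math.pi * eps_r * VACUUM_PERMITTIVITY * BOLTZMANN * temperature
    )
    return lam_si * 1.0e9


def vacuum_bjerrum_length_nm(temperature: float) -> float:
    """Vacuum Bjerrum length e^2/(4 pi eps0 k_B T) in nm (eps_r = 1)."""
    return bjerrum_length_nm(1.0, temperature)
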