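"""Plain-text writers: profile TSV, summary JSON, iteration log."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__, constants as const
from .model import charge_density
from .solver import Solution

#: e/nm^3 -> C/m^3
_CHARGE_DENSITY_SI = const.ELEMENTARY_CHARGE * 1.0e27


def write_profile_tsv(sol: Solution, path) -> None:
    """Tab-separated profiles, one header line, one row per node."""
    mix = sol.mixture
    grid = sol.grid
    cols = [grid.z]
    header = ["z_nm"]
    for i, sp in enumerate(mix.species):
        cols.append(sol.fields.rho[i])
        header.append(f"rho_{sp.name}_per_nm3")
    kt_mv = const.thermal_voltage_mV(mix.temperature)
    rho_e = charge_density(sol.fields, mix)
    cols += [sol.fields.psi, sol.fields.psi * kt_mv, rho_e * _CHARGE_DENSITY_SI, sol.fields.eps_r]
    header += ["psi_kT_per_e", "psi_mV", "rho_e_C_per_m3", "eps_r"]
    data = np.column_stack(cols)
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        np.savetxt(fh, data, delimiter="\t", fmt="%.10g")


def write_summary_json(sol: Solution, path, config_echo: Optional[dict] = None) -> None:
    payload = {
        "schema_version": 1,
        "edldft_version": __version__,
        **sol.summary(),
        "bulk": sol.bulk.summary(),
        "config": config_echo or {},
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")


def write_iteration_log(sol: Solution, path) -> None:
    with open(path, "w") as fh:
        fh.write("# iter\tmax_residual\tsigma_e_per_nm2\tpsi0_kT_per_e\n")
        for k, r in enumerate(sol.residual_history, start=1):
            psi0 = sol.psi0_history[k - 1] if k <= len(sol.psi0_history) else sol.psi0
            fh.write(f"{k}\t{r:.6e}\t{sol.sigma:.8e}\t{psi0:.8e}\n")
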