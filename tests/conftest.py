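"""Shared fixtures: the expensive converged solutions are session-scoped."""

from __future__ import annotations

import numpy as np
import pytest

import edldft.constants as C
from edldft.bulk import BulkState
from edldft.config import primitive_setup, semiprimitive_setup
from edldft.electrostatics import solve_pb
from edldft.model import Grid, Mixture, Species
from edldft.solver import SolverConfig, charge_regulated_solve, picard_solve

WETTING_EPS = (0.0, 1.0, 2.0)


@pytest.fixture(scope="session")
def salt_001M():
    """0.01 M symmetric monovalent point-like electrolyte in water."""
    c = C.molar_to_per_nm3(0.01)
    return Mixture([Species("cat", 0.3, 1, c), Species("an", 0.3, -1, c)])


@pytest.fixture(scope="session")
def wetting_solutions():
    """Converged semi-primitive charge-regulated EDLs for the three
    solvent-wall attraction strengths (solvophobic / neutral / solvophilic)."""
    out = {}
    for eps in WETTING_EPS:
        setup = semiprimitive_setup(eps)
        grid = setup.grid()
        sol = charge_regulated_solve(setup.mixture, grid, setup.chemistry, setup.solver)
        assert sol.converged, f"wetting case eps={eps} did not converge"
        out[eps] = sol
    return out


@pytest.fixture(scope="session")
def charge_inversion_solution():
    """Primitive-model 2:1 electrolyte at 1 M, sigma = -0.1 C/m^2, with the
    MSA screening-correlation term enabled."""
    setup = primitive_setup(1.0, sc=True)
    sol = picard_solve(setup.mixture, setup.grid(), setup.sigma, setup.solver)
    assert sol.converged
    return setup, sol


@pytest.fixture(scope="session")
def charge_inversion_pb():
    """Matching Poisson-Boltzmann reference for the 1 M 2:1 case."""
    setup = primitive_setup(1.0, sc=False)
    bulk = BulkState(setup.mixture, 78.5)
    grid = setup.grid()
    psi, rho = solve_pb(bulk, setup.sigma, grid)
    return setup, grid, psi, rho
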