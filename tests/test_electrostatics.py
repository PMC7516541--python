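"""Poisson / PB solvers, dielectric models and the electroosmotic diagnostic."""

import math

import numpy as np
import pytest

import edldft.constants as C
from edldft.bulk import BulkState, debye_kappa
from edldft.electrostatics import (
    FlowSpec,
    clausius_mossotti_eps,
    eo_velocity,
    gouy_chapman_potential,
    oleksy_hansen_eps,
    solve_pb,
    solve_poisson,
    weighted_solvent_density,
)
from edldft.model import Grid, Mixture, Species


class TestWeightedSolventDensity:
    def test_uniform_preserved_exactly(self):
        grid = Grid(spacing=0.006, n_nodes=500)
        rho = np.full(500, 23.4)
        out = weighted_solvent_density(rho, 0.3, grid)
        assert np.max(np.abs(out - 23.4)) < 1e-8 * 23.4

    def test_zero_gives_zero(self):
        grid = Grid(spacing=0.006, n_nodes=500)
        assert np.max(np.abs(weighted_solvent_density(np.zeros(500), 0.3, grid))) == 0.0

    def test_unit_area_spike_gives_parabolic_bump(self):
        d0 = 0.3
        grid = Grid(spacing=0.001, n_nodes=2000)
        rho = np.zeros(2000)
        k0 = 1000
        rho[k0] = 1.0 / grid.spacing  # unit areal density
        out = weighted_solvent_density(rho, d0, grid)
        # peak value 3/(2 d0) per unit areal density
        assert out[k0] == pytest.approx(3.0 / (2.0 * d0), rel=1e-3)
        # support is exactly one diameter wide (half-width d0/2)
        half = int(round(0.5 * d0 / grid.spacing))
        assert out[k0 + half + 1] == 0.0
        # parabolic shape at the quarter point
        s = 0.25 * d0
        expect = (6.0 / d0**3) * (0.25 * d0**2 - s**2)
        assert out[k0 + int(round(s / grid.spacing))] == pytest.approx(expect, rel=1e-3)

    def test_rejects_nonpositive_diameter(self):
        grid = Grid(spacing=0.006, n_nodes=100)
        with pytest.raises(ValueError):
            weighted_solvent_density(np.ones(100), 0.0, grid)


class TestClausiusMossotti:
    def test_vacuum_and_apolar_limits(self):
        assert clausius_mossotti_eps(np.array([0.0]), 1.0)[0] == 1.0
        assert clausius_mossotti_eps(np.array([5.0]), 0.0)[0] == 1.0

    def test_polarization_catastrophe(self):
        m2 = 0.1
        rho_star = 9.0 / (4.0 * math.pi * m2)
        out = clausius_mossotti_eps(np.array([0.999 * rho_star]), m2)
        assert out[0] > 1e3
        with pytest.raises(ValueError, match="catastrophe"):
            clausius_mossotti_eps(np.array([1.001 * rho_star]), m2)


class TestOleksyHansen:
    def test_saturation_and_midpoint(self):
        d0, a, rho_mid, f = 0.3, 5.0, 0.35, 87.63
        hi = oleksy_hansen_eps(np.array([1e6]), d0, a, rho_mid, f)
        assert hi[0] == pytest.approx(1.0 + f, rel=1e-12)
        mid = oleksy_hansen_eps(np.array([rho_mid / d0**3]), d0, a, rho_mid, f)
        assert mid[0] == pytest.approx(1.0 + f / 2.0, rel=1e-12)

    def test_strictly_increasing(self):
        d0 = 0.3
        rhos = np.linspace(0.0, 1.0, 50) / d0**3
        out = oleksy_hansen_eps(rhos, d0, 5.0, 0.35, 87.63)
        assert np.all(np.diff(out) > 0.0)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError, match="f\\(T\\)"):
            oleksy_hansen_eps(np.array([1.0]), 0.3, 5.0, 0.35, 88.0 - 0.37 * 298.15)


class TestPoisson:
    def test_charge_free_neutral_wall(self):
        grid = Grid(spacing=0.01, n_nodes=300)
        psi = solve_poisson(np.zeros(300), np.full(300, 78.5), 0.0, grid)
        assert np.max(np.abs(psi)) < 1e-14

    def test_gauss_law_slope_for_bare_wall(self):
        grid = Grid(spacing=0.01, n_nodes=200)
        eps_r, sigma, T = 40.0, -0.2, 298.15
        psi = solve_poisson(np.zeros(200), np.full(200, eps_r), sigma, grid, T)
        lam0 = C.vacuum_bjerrum_length_nm(T)
        slope = np.diff(psi) / grid.spacing
        assert np.allclose(slope, 4.0 * math.pi * lam0 * abs(sigma) / eps_r, rtol=1e-10)

    @pytest.mark.parametrize("variable_eps", [False, True])
    def test_manufactured_solution_second_order(self, variable_eps):
        """psi_m = cos(kz) e^{-z}: feeding its analytic source reproduces it
        with O(h^2) error, measured by the grid-refinement slope."""
        kk, L, T = 2.0, 4.0, 298.15
        lam0 = C.vacuum_bjerrum_length_nm(T)

        def psi_m(z):
            return np.cos(kk * z) * np.exp(-z)

        def dpsi(z):
            return -np.exp(-z) * (np.cos(kk * z) + kk * np.sin(kk * z))

        def d2psi(z):
            return np.exp(-z) * ((1 - kk**2) * np.cos(kk * z) + 2 * kk * np.sin(kk * z))

        errors = []
        ns = (201, 401, 801)
        for n in ns:
            grid = Grid(spacing=L / (n - 1), n_nodes=n)
            z = grid.z
            if variable_eps:
                eps = 2.0 + np.sin(z / 2.0)
                deps = 0.5 * np.cos(z / 2.0)
                rho_e = -(deps * dpsi(z) + eps * d2psi(z)) / (4 * math.pi * lam0)
            else:
                eps = np.full(n, 10.0)
                rho_e = -eps * d2psi(z) / (4 * math.pi * lam0)
            sigma = -eps[0] * dpsi(0.0) / (4 * math.pi * lam0)
            psi = solve_poisson(rho_e, eps, sigma, grid, T, psi_far=float(psi_m(L)))
            errors.append(np.max(np.abs(psi - psi_m(z))))
        orders = [
            math.log2(errors[i] / errors[i + 1]) for i in range(len(errors) - 1)
        ]
        assert all(1.9 <= p <= 2.1 for p in orders), (errors, orders)

    def test_rejects_bad_permittivity(self):
        grid = Grid(spacing=0.01, n_nodes=50)
        with pytest.raises(ValueError, match="permittivity"):
            solve_poisson(np.zeros(50), np.zeros(50), 0.0, grid)


@pytest.fixture(scope="module")
def pb_case(salt_001M):
    bulk = BulkState(salt_001M, 78.5)
    grid = Grid.for_mixture(salt_001M, bulk.kappa, screening_lengths=16)
    return bulk, grid


class TestPB:
    def test_neutral_wall_is_flat(self, pb_case):
        bulk, grid = pb_case
        psi, rho = solve_pb(bulk, 0.0, grid)
        assert np.max(np.abs(psi)) < 1e-12
        assert np.allclose(rho, bulk.mixture.bulk_densities[:, None])

    def test_weak_charging_matches_debye_hueckel(self, pb_case):
        bulk, grid = pb_case
        sigma = -1e-4  # e/nm^2; |psi0| << 1 kT/e
        psi, _ = solve_pb(bulk, sigma, grid)
        assert abs(psi[0]) < 0.05
        ref = psi[0] * np.exp(-bulk.kappa * grid.z)
        sel = grid.z < 5.0 / bulk.kappa
        assert np.max(np.abs(psi[sel] - ref[sel])) < 0.01 * abs(psi[0])

    def test_matches_gouy_chapman_everywhere(self, pb_case):
        bulk, grid = pb_case
        sigma = C.sigma_si_to_reduced(-0.05)
        psi, _ = solve_pb(bulk, sigma, grid)
        gc = gouy_chapman_potential(float(psi[0]), bulk.kappa, grid)
        assert np.max(np.abs(psi - gc)) < 1e-3

    def test_global_electroneutrality(self, pb_case):
        bulk, grid = pb_case
        sigma = C.sigma_si_to_reduced(-0.05)
        _, rho = solve_pb(bulk, sigma, grid)
        rho_e = bulk.mixture.valences @ rho
        assert abs(grid.trapz(rho_e) + sigma) / abs(sigma) < 1e-6

    def test_contact_value_theorem_under_refinement(self, salt_001M):
        """k_B T sum_i (rho_i(0) - rho_ib) = sigma^2/(2 eps0 eps_r)."""
        bulk = BulkState(salt_001M, 78.5)
        sigma = C.sigma_si_to_reduced(-0.05)
        rhs = 2.0 * math.pi * bulk.lambda_b * sigma**2
        errs = []
        for npd in (50, 100):
            grid = Grid.for_mixture(
                salt_001M, bulk.kappa, nodes_per_diameter=npd, screening_lengths=16
            )
            _, rho = solve_pb(bulk, sigma, grid)
            lhs = float(np.sum(rho[:, 0] - salt_001M.bulk_densities))
            errs.append(abs(lhs - rhs) / rhs)
        assert errs[-1] < 1e-3
        assert errs[-1] <= errs[0]

    def test_sign_definite_and_monotone_over_sigma_sweep(self, pb_case):
        bulk, grid = pb_case
        for sigma_si in (-0.2, -0.05, -0.005, 0.01, 0.1):
            sigma = C.sigma_si_to_reduced(sigma_si)
            psi, _ = solve_pb(bulk, sigma, grid)
            s = np.sign(sigma)  # psi carries the sign of the wall charge
            assert np.all(s * psi[:-1] >= -1e-12)
            d = np.diff(psi)  # |psi| decays monotonically toward the bulk
            assert np.all(s * d <= 1e-12)


class TestGouyChapman:
    def test_zero_potential(self):
        grid = Grid(spacing=0.01, n_nodes=100)
        assert np.max(np.abs(gouy_chapman_potential(0.0, 1.0, grid))) == 0.0

    def test_linearizes_to_exponential_decay(self):
        grid = Grid(spacing=0.01, n_nodes=2000)
        psi0, kappa = 0.01, 0.5
        psi = gouy_chapman_potential(psi0, kappa, grid)
        ref = psi0 * np.exp(-kappa * grid.z)
        assert np.max(np.abs(psi / ref - 1.0)) < 1e-3

    def test_sign_definite_monotone(self):
        grid = Grid(spacing=0.01, n_nodes=1000)
        for psi0 in (-4.0, -0.3, 0.7, 3.0):
            psi = gouy_chapman_potential(psi0, 1.0, grid)
            assert np.all(np.sign(psi) == np.sign(psi0))
            assert np.all(np.sign(np.diff(psi)) == -np.sign(psi0))


class TestEoVelocity:
    def test_constant_potential_no_flow(self):
        grid = Grid(spacing=0.01, n_nodes=100)
        u = eo_velocity(np.full(100, 0.3), FlowSpec(z_slip=0.2, prefactor=2.0), grid)
        assert np.max(np.abs(u)) == 0.0

    def test_linear_in_prefactor(self):
        grid = Grid(spacing=0.01, n_nodes=100)
        psi = -np.exp(-grid.z)
        u1 = eo_velocity(psi, FlowSpec(0.2, 1.0), grid)
        u3 = eo_velocity(psi, FlowSpec(0.2, 3.0), grid)
        assert np.allclose(u3, 3.0 * u1)

    def test_charge_inversion_reverses_centerline_flow(self):
        """When the slip plane sits in a sign-reversed (inverted) region of the
        potential, the far-field fluid velocity flips direction."""
        grid = Grid(spacing=0.01, n_nodes=1000)
        z = grid.z
        normal = -np.exp(-z)  # monotone negative EDL
        inverted = -np.exp(-3 * z) + 0.4 * np.exp(-z)  # positive lobe away from wall
        slip = FlowSpec(z_slip=1.0, prefactor=1.0)
        u_n = eo_velocity(normal, slip, grid)
        u_i = eo_velocity(inverted, slip, grid)
        assert inverted[100] > 0 > normal[100]
        assert u_n[-1] * u_i[-1] < 0.0

    def test_slip_plane_outside_grid(self):
        grid = Grid(spacing=0.01, n_nodes=100)
        with pytest.raises(ValueError):
            eo_velocity(np.zeros(100), FlowSpec(z_slip=5.0), grid)
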