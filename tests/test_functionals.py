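"""FMT, mean-field LJ and screening-correlation operators, checked against
brute-force quadrature oracles and bulk sum rules."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

import edldft.constants as C
from edldft.bulk import BulkState
from edldft.functionals import (
    FunctionalWorkspace,
    fmt_mu,
    fmt_phi,
    lj_meanfield_mu,
    lj_planar_kernel,
    msa_b_coefficient,
    msa_delta_c,
    sc_mu,
    sc_planar_kernel,
    weighted_densities,
)
from edldft.model import Fields, Grid, Mixture, Species


def _one_component(rho_red=0.6, d=1.0, npd=50, n_diam=12):
    rho = rho_red / d**3
    mix = Mixture([Species("hs", d, 0, rho)])
    grid = Grid(spacing=d / npd, n_nodes=n_diam * npd)
    return mix, grid, rho


class TestWeightedDensities:
    def test_zero_density_gives_zero(self):
        mix, grid, _ = _one_component()
        f = Fields.bulk(mix, grid)
        f.rho[:] = 0.0
        n = weighted_densities(f, mix)
        for arr in (n.n0, n.n1, n.n2, n.n3, n.nv1, n.nv2):
            assert np.max(np.abs(arr)) == 0.0

    def test_uniform_closed_form(self):
        mix, grid, rho = _one_component(rho_red=0.6)
        f = Fields.bulk(mix, grid)
        n = weighted_densities(f, mix)
        assert np.max(np.abs(n.n3 - 0.1 * math.pi)) < 1e-8 * 0.1 * math.pi
        assert np.max(np.abs(n.n2 - math.pi * rho)) < 1e-8 * math.pi * rho
        assert np.max(np.abs(n.n1 - 0.5 * rho)) < 1e-8 * rho
        assert np.max(np.abs(n.n0 - rho)) < 1e-8 * rho
        assert np.max(np.abs(n.nv2)) < 1e-12
        assert np.max(np.abs(n.nv1)) < 1e-12

    def test_gaussian_spike_against_quadrature_oracle(self):
        """Independent continuous quadrature of the planar-reduced weights."""
        mix, grid, _ = _one_component(npd=250, n_diam=6)
        R = 0.5
        z0, w = 3.0, 0.15

        def rho_fun(z):
            return np.exp(-0.5 * ((z - z0) / w) ** 2)

        f = Fields.bulk(mix, grid)
        f.rho[0] = rho_fun(grid.z)
        ws = FunctionalWorkspace(mix, grid)
        n = weighted_densities(f, mix, ws)
        pad = ws.pad
        for z_eval in (2.6, 3.0, 3.3):
            k = int(round(z_eval / grid.spacing))
            n3_ref = quad(
                lambda zp: rho_fun(zp) * math.pi * (R**2 - (z_eval - zp) ** 2),
                z_eval - R, z_eval + R, limit=200,
            )[0]
            n2_ref = quad(
                lambda zp: rho_fun(zp) * 2.0 * math.pi * R,
                z_eval - R, z_eval + R, limit=200,
            )[0]
            nv2_ref = quad(
                lambda zp: rho_fun(zp) * 2.0 * math.pi * (zp - z_eval),
                z_eval - R, z_eval + R, limit=200,
            )[0]
            assert n.n3[pad + k] == pytest.approx(n3_ref, rel=1e-4)
            assert n.n2[pad + k] == pytest.approx(n2_ref, rel=1e-4)
            assert n.nv2[pad + k] == pytest.approx(nv2_ref, rel=1e-4, abs=1e-6)


class TestFmtPhi:
    def test_vanishes_with_weights(self):
        mix, grid, _ = _one_component()
        f = Fields.bulk(mix, grid)
        f.rho[:] = 0.0
        assert np.max(np.abs(fmt_phi(weighted_densities(f, mix)))) == 0.0

    def test_uniform_matches_bulk_free_energy_density(self):
        from edldft.bulk import hs_phi_bulk

        mix, grid, rho = _one_component(rho_red=6 * 0.3 / math.pi)  # eta = 0.3
        f = Fields.bulk(mix, grid)
        phi = fmt_phi(weighted_densities(f, mix))
        ref = hs_phi_bulk(mix, np.array([rho]))
        assert np.max(np.abs(phi - ref)) < 1e-8 * ref

    def test_overpacking_raises_with_location(self):
        mix, grid, _ = _one_component()
        f = Fields.bulk(mix, grid)
        f.rho[0][:] = 2.5  # eta > 1
        with pytest.raises(ValueError, match="overpacked"):
            fmt_phi(weighted_densities(f, mix))


class TestFmtMu:
    def test_flat_profiles_give_zero(self):
        for rho_red in (0.1, 0.4, 0.7):
            mix, grid, _ = _one_component(rho_red=rho_red)
            f = Fields.bulk(mix, grid)
            mu = fmt_mu(f, mix)
            assert np.max(np.abs(mu)) < 1e-8

    def test_matches_finite_difference_functional_derivative(self):
        """Perturb the density at single nodes and difference the total FMT
        free energy — an independent route to the same functional derivative."""
        mix, grid, rho = _one_component(rho_red=0.5, npd=30, n_diam=8)
        z = grid.z
        f = Fields.bulk(mix, grid)
        f.rho[0] = rho * (1.0 + 0.3 * np.exp(-((z - 3.0) ** 2)))
        f.rho[0][z < 0.5] = 0.0  # hard-wall exclusion
        ws = FunctionalWorkspace(mix, grid)
        mu = fmt_mu(f, mix, ws)
        h = grid.spacing

        def total_energy(fields):
            return h * float(np.sum(fmt_phi(weighted_densities(fields, mix, ws))))

        for k in (int(0.6 / h), int(2.0 / h), int(3.1 / h)):
            dr = 1e-5 * rho
            up, dn = f.copy(), f.copy()
            up.rho[0][k] += dr
            dn.rho[0][k] -= dr
            fd = (total_energy(up) - total_energy(dn)) / (2 * dr * h)
            expect = mu[0][k] + ws.mu_hs_bulk[0]
            assert fd == pytest.approx(expect, rel=1e-3)

    def test_equal_diameter_species_split_is_invisible(self):
        mix1, grid, rho = _one_component(rho_red=0.5)
        f1 = Fields.bulk(mix1, grid)
        f1.rho[0][grid.z < 0.5] = 0.0
        mu1 = fmt_mu(f1, mix1)

        mix2 = Mixture([Species("a", 1.0, 0, 0.3 * rho), Species("b", 1.0, 0, 0.7 * rho)])
        f2 = Fields.bulk(mix2, grid)
        for i in range(2):
            f2.rho[i][grid.z < 0.5] = 0.0
        mu2 = fmt_mu(f2, mix2)
        assert np.max(np.abs(mu2[0] - mu1[0])) < 1e-9
        assert np.max(np.abs(mu2[1] - mu1[0])) < 1e-9

    def test_reflection_equivariance(self):
        mix, grid, rho = _one_component(rho_red=0.4, npd=40, n_diam=10)
        bump = 0.2 * rho * np.exp(-((grid.z - 5.0) / 0.7) ** 2)
        f = Fields.bulk(mix, grid)
        f.rho[0] = rho + bump
        mu = fmt_mu(f, mix)
        f_m = Fields.bulk(mix, grid)
        f_m.rho[0] = (rho + bump)[::-1]
        mu_m = fmt_mu(f_m, mix)
        assert np.max(np.abs(mu_m[0] - mu[0][::-1])) < 1e-9


class TestLJKernel:
    def test_zero_epsilon(self):
        k = lj_planar_kernel(0.0, 0.3, 0.01)
        assert np.max(np.abs(k.values)) == 0.0

    def test_contact_value_against_radial_quadrature(self):
        eps, d = 1.3, 0.3

        def u_lj(r):
            return 4.0 * eps * ((d / r) ** 12 - (d / r) ** 6)

        ref = 2.0 * math.pi * quad(lambda r: r * u_lj(r), d, 50 * d, limit=400)[0]
        k = lj_planar_kernel(eps, d, 0.001)
        mid = k.half_width  # offset 0, interior sample (no endpoint halving)
        assert k.values[mid] == pytest.approx(ref, rel=1e-6)
        assert k.values[mid] == pytest.approx(-0.3 * 4.0 * math.pi * eps * d**2, rel=1e-6)

    def test_continuity_at_collision_diameter(self):
        eps, d, h = 1.0, 0.3, 1e-3
        k = lj_planar_kernel(eps, d, h)
        mid = k.half_width
        j = int(round(d / h))
        inner, outer = k.values[mid + j - 1], k.values[mid + j + 1]
        assert inner == pytest.approx(outer, rel=5e-3)
        assert k.values[mid + j] == pytest.approx(
            8.0 * math.pi * eps * d**2 * (0.1 - 0.25), rel=1e-10
        )


class TestLJMeanField:
    def _pair(self, eps=1.0):
        rho = 0.6
        mix = Mixture([Species("s", 1.0, 0, rho)], pair_epsilon=[[eps]])
        grid = Grid(spacing=1.0 / 40, n_nodes=30 * 40)
        return mix, grid, rho

    def test_flat_profiles_give_zero(self):
        mix, grid, _ = self._pair()
        f = Fields.bulk(mix, grid)
        assert np.max(np.abs(lj_meanfield_mu(f, mix))) < 1e-10

    def test_linearity_in_deviation(self):
        mix, grid, rho = self._pair()
        bump = 0.1 * rho * np.exp(-((grid.z - 10.0) / 1.5) ** 2)
        f1 = Fields.bulk(mix, grid)
        f1.rho[0] = rho + bump
        f2 = Fields.bulk(mix, grid)
        f2.rho[0] = rho + 2 * bump
        m1 = lj_meanfield_mu(f1, mix)
        m2 = lj_meanfield_mu(f2, mix)
        assert np.max(np.abs(m2 - 2 * m1)) < 1e-10

    def test_step_depletion_raises_mu_for_attractive_pair(self):
        """Losing attractive neighbours costs energy: a depleted slab near the
        wall gives Delta-mu_LJ > 0 there; cross-checked by direct trapezoid
        quadrature of the kernel on the same toy profile."""
        mix, grid, rho = self._pair(eps=1.0)
        f = Fields.bulk(mix, grid)
        f.rho[0][grid.z < 2.0] = 0.2 * rho
        mu = lj_meanfield_mu(f, mix)
        k_in = int(1.0 / grid.spacing)
        assert mu[0][k_in] > 0.0

        kern = lj_planar_kernel(1.0, 1.0, grid.spacing)
        K = kern.half_width
        dev = f.rho[0] - rho
        z_eval = grid.z[k_in]
        ref = 0.0
        for j in range(-K, K + 1):
            zp = z_eval + j * grid.spacing
            if zp < 0:
                dv = dev[0]
            elif zp > grid.length:
                dv = 0.0
            else:
                dv = float(np.interp(zp, grid.z, dev))
            ref += kern.values[j + K] * dv * grid.spacing
        assert mu[0][k_in] == pytest.approx(ref, rel=1e-6)

    def test_reflection_equivariance(self):
        mix, grid, rho = self._pair()
        bump = 0.15 * rho * np.exp(-((grid.z - 15.0) / 1.2) ** 2)
        f = Fields.bulk(mix, grid)
        f.rho[0] = rho + bump
        mu = lj_meanfield_mu(f, mix)
        f_m = Fields.bulk(mix, grid)
        f_m.rho[0] = (rho + bump)[::-1]
        mu_m = lj_meanfield_mu(f_m, mix)
        assert np.max(np.abs(mu_m[0] - mu[0][::-1])) < 1e-10


def _restricted_salt(conc_M=0.5, d=0.3):
    c = C.molar_to_per_nm3(conc_M)
    return Mixture([Species("cat", d, 1, c), Species("an", d, -1, c)])


class TestScreeningCorrelation:
    def test_b_coefficient_small_argument_series(self):
        for x in (1e-3, 1e-5, 1e-7):
            assert msa_b_coefficient(x) == pytest.approx(
                0.5 * x - 0.5 * x**2, rel=1e-3
            )

    def test_planar_kernel_against_radial_quadrature(self):
        mix = _restricted_salt(0.5)
        bulk = BulkState(mix, 78.5)
        d = bulk.ion_diameter
        h = d / 60
        kern = sc_planar_kernel(bulk, h)
        mid = kern.half_width
        for s_nodes in (5, 20, 40):
            s = s_nodes * h
            ref = (
                2.0
                * math.pi
                * quad(
                    lambda r: r
                    * msa_delta_c(np.array([r]), bulk.kappa, d, bulk.lambda_b)[0],
                    s, d, limit=400,
                )[0]
            )
            assert kern.values[mid + s_nodes] == pytest.approx(ref, rel=1e-4)

    def test_flat_profiles_and_neutral_species_give_zero(self):
        mix = _restricted_salt()
        bulk = BulkState(mix, 78.5)
        grid = Grid(spacing=0.005, n_nodes=1000)
        f = Fields.bulk(mix, grid)
        assert np.max(np.abs(sc_mu(f, bulk))) < 1e-12

        c = C.molar_to_per_nm3(0.5)
        mix3 = Mixture(
            [Species("cat", 0.3, 1, c), Species("an", 0.3, -1, c),
             Species("solv", 0.3, 0, 10.0, is_solvent=True)]
        )
        bulk3 = BulkState(mix3, 78.5)
        f3 = Fields.bulk(mix3, grid)
        f3.rho[0] *= 1.0 + 0.2 * np.exp(-grid.z)
        f3.rho[1] *= 1.0 + 0.2 * np.exp(-grid.z)
        mu3 = sc_mu(f3, bulk3)
        assert np.max(np.abs(mu3[mix3.index("solv")])) == 0.0

    def test_counterion_accumulation_lowers_sc_mu(self):
        """An excess of counterion charge near the wall makes the screening
        term negative for the accumulated species."""
        mix = _restricted_salt(0.5)
        bulk = BulkState(mix, 78.5)
        grid = Grid(spacing=0.005, n_nodes=1000)
        f = Fields.bulk(mix, grid)
        f.rho[0] *= 1.0 + 2.0 * np.exp(-grid.z / 0.3)  # cation excess at wall
        mu = sc_mu(f, bulk)
        assert mu[0][0] < 0.0  # cations
        assert mu[1][0] > 0.0  # anions, opposite charge product
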