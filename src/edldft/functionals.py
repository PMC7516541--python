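"""Excess free-energy functionals as profile-space chemical-potential operators.

Three contributions:

* Rosenfeld fundamental-measure theory (FMT) for hard-sphere packing,
* a mean-field convolution for the long-range Lennard-Jones attractions,
* a screening-correlation (SC) term for electrostatic ion-ion correlations
  beyond the mean field, via a second-order Taylor expansion about the bulk
  using the restricted-MSA direct correlation function.

All convolutions are direct banded quadrature on the uniform grid (kernel
support is a few diameters, the domain is non-periodic). Discrete scalar
kernels are renormalized so that a uniform profile reproduces the analytic
bulk weighted densities exactly; this makes every Delta-mu operator vanish
identically on flat profiles, which is what lets profiles relax to bulk.

Boundary handling: densities are extended as rho_ib beyond z = L (bulk
reservoir) and with their wall-edge value into the wall (z < 0). Any profile
subject to a hard-core mask is zero at the wall edge, so this reproduces the
physical "no fluid behind the wall" extension, while a deliberately flat
profile stays flat — the operators themselves carry no knowledge of the wall.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .bulk import BulkState, hs_mu_excess
from .model import Fields, Grid, Mixture, lorentz_diameter

__all__ = [
    "WeightedDensities",
    "PlanarKernel",
    "weighted_densities",
    "fmt_phi",
    "fmt_dphi",
    "fmt_mu",
    "lj_planar_kernel",
    "lj_meanfield_mu",
    "sc_planar_kernel",
    "sc_mu",
    "FunctionalWorkspace",
]


# ---------------------------------------------------------------------------
# discrete planar kernels


def _correlate(padded: np.ndarray, kernel: np.ndarray, h: float) -> np.ndarray:
    """Trapezoidal planar convolution: out[k] = h * sum_j padded[k+j] kernel[j].

    `padded` must already carry (len(kernel)-1)//2 pad nodes on each side.
    """
    return h * np.correlate(padded, kernel, mode="valid")


def _pad(profile: np.ndarray, half: int, left: float, right: float) -> np.ndarray:
    return np.concatenate(
        [np.full(half, left), profile, np.full(half, right)]
    )


def _jump_weighted(rho: np.ndarray) -> np.ndarray:
    """Half-weight nodes where the profile jumps from an exact zero.

    A hard-core mask puts the density discontinuity exactly on the contact
    node; trapezoidal quadrature of a function that jumps *at* a node must
    weight that node by the mean of its one-sided limits, i.e. half the
    contact value. Restores O(h^2) accuracy of the convolutions at the wall.
    """
    idx = np.where((rho[1:] > 0.0) & (rho[:-1] == 0.0))[0] + 1
    if len(idx) == 0:
        return rho
    w = rho.copy()
    w[idx] *= 0.5
    return w


def _fmt_kernels(radius: float, h: float) -> Tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Sampled planar FMT kernels (w3, wv2-base) for one species.

    Returns (w3, wv2, K) with samples at offsets j = -K..K, s = j*h. The w2
    kernel is the constant 2*pi*R with halved endpoints and is derived from w3's
    support; scalar kernels are renormalized to their exact integrals
    (4/3 pi R^3 and 4 pi R^2).
    """
    K = max(1, int(round(radius / h)))
    s = h * np.arange(-K, K + 1)
    w3 = math.pi * np.clip(radius**2 - s**2, 0.0, None)
    w3[0] *= 0.5
    w3[-1] *= 0.5
    target3 = 4.0 / 3.0 * math.pi * radius**3
    tot = h * float(np.sum(w3))
    if tot > 0.0:
        w3 *= target3 / tot
    w2 = np.full(2 * K + 1, 2.0 * math.pi * radius)
    w2[0] *= 0.5
    w2[-1] *= 0.5
    target2 = 4.0 * math.pi * radius**2
    w2 *= target2 / (h * float(np.sum(w2)))
    # vector kernel: wv2(s') with s' = z' - z; odd, endpoints halved
    wv2 = 2.0 * math.pi * s
    wv2[0] *= 0.5
    wv2[-1] *= 0.5
    return w3, w2, wv2, K


@dataclass
class WeightedDensities:
    """Planar FMT weighted densities on the (extended) grid."""

    n0: np.ndarray
    n1: np.ndarray
    n2: np.ndarray
    n3: np.ndarray
    nv1: np.ndarray
    nv2: np.ndarray


@dataclass
class PlanarKernel:
    """A tabulated even planar pair kernel on offsets [-z_cut, z_cut].

    `values[j]` is the kernel at offset (j - K)*h with K = (len-1)//2;
    trapezoid endpoint weights are already folded in.
    """

    values: np.ndarray
    spacing: float
    pair: Tuple[str, str] = ("", "")

    @property
    def half_width(self) -> int:
        return (len(self.values) - 1) // 2

    @property
    def cutoff(self) -> float:
        return self.half_width * self.spacing

    def export(self, path) -> None:
        """Write the kernel as two-column text (offset_nm, value)."""
        K = self.half_width
        s = self.spacing * np.arange(-K, K + 1)
        np.savetxt(path, np.column_stack([s, self.values]), header="dz_nm value")


# ---------------------------------------------------------------------------
# FMT


class FunctionalWorkspace:
    """Precomputed kernels and species grouping for one (mixture, grid) pair.

    Species with identical diameters share FMT kernels; identical (eps, d)
    pairs share LJ kernels. Building the workspace once and reusing it across
    Picard iterations is what keeps the solver at desk scale.
    """

    def __init__(self, mixture: Mixture, grid: Grid, bulk: Optional[BulkState] = None):
        self.mixture = mixture
        self.grid = grid
        h = grid.spacing
        # FMT kernel groups keyed by radius
        self.fmt_by_radius: Dict[float, Tuple[np.ndarray, np.ndarray, np.ndarray, int]] = {}
        for sp in mixture.species:
            r = sp.radius
            if r not in self.fmt_by_radius:
                self.fmt_by_radius[r] = _fmt_kernels(r, h)
        self.pad = max(k[3] for k in self.fmt_by_radius.values())
        # LJ kernels per unique (eps, d_ij)
        self.lj_kernels: Dict[Tuple[float, float], PlanarKernel] = {}
        m = mixture.n_species
        for i in range(m):
            for j in range(m):
                eps = mixture.pair_epsilon[i, j]
                if eps <= 0.0:
                    continue
                d_ij = lorentz_diameter(
                    mixture.species[i].diameter, mixture.species[j].diameter
                )
                key = (eps, d_ij)
                if key not in self.lj_kernels:
                    self.lj_kernels[key] = lj_planar_kernel(eps, d_ij, h)
        self.bulk = bulk
        self.sc_kernel: Optional[PlanarKernel] = None
        if bulk is not None and bulk.gamma > 0.0:
            self.sc_kernel = sc_planar_kernel(bulk, h)
        self.mu_hs_bulk = hs_mu_excess(mixture, mixture.bulk_densities)


def weighted_densities(
    fields: Fields, mixture: Mixture, ws: Optional[FunctionalWorkspace] = None
) -> WeightedDensities:
    """Planar FMT weighted densities on the extended grid [-pad, N-1+pad].

    The extension (pad = max R_i in nodes) is needed because the free-energy
    density is nonzero up to one radius behind the wall plane and one radius
    past the last node; the chemical-potential back-convolution at z in [0, L]
    reaches into both regions.
    """
    if ws is None:
        ws = FunctionalWorkspace(mixture, fields.grid)
    grid, h, pad = fields.grid, fields.grid.spacing, ws.pad
    n_ext = grid.n_nodes + 2 * pad
    out = WeightedDensities(*(np.zeros(n_ext) for _ in range(6)))
    for i, sp in enumerate(mixture.species):
        w3, w2, wv2, K = ws.fmt_by_radius[sp.radius]
        # density on extended grid, further padded by K for the convolution
        rho_w = _jump_weighted(fields.rho[i])
        edge, redge = float(rho_w[0]), float(rho_w[-1])
        rho_p = _pad(_pad(rho_w, pad, edge, redge), K, edge, redge)
        c3 = _correlate(rho_p, w3, h)
        c2 = _correlate(rho_p, w2, h)
        cv2 = _correlate(rho_p, wv2, h)
        r = sp.radius
        out.n3 += c3
        out.n2 += c2
        out.n1 += c2 / (4.0 * math.pi * r)
        out.n0 += c2 / (4.0 * math.pi * r**2)
        out.nv2 += cv2
        out.nv1 += cv2 / (4.0 * math.pi * r)
    return out


def fmt_phi(n: WeightedDensities) -> np.ndarray:
    """Rosenfeld hard-sphere free-energy density Phi_HS (k_B T / nm^3)."""
    n3 = n.n3
    if np.any(n3 >= 1.0):
        k = int(np.argmax(n3))
        raise ValueError(f"local packing n3 = {n3[k]:.4f} >= 1 at node {k}: overpacked")
    om = 1.0 - n3
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (
            -n.n0 * np.log(om)
            + (n.n1 * n.n2 - n.nv1 * n.nv2) / om
            + (n.n2**3 - 3.0 * n.n2 * n.nv2**2) / (24.0 * math.pi * om**2)
        )
    return phi


def fmt_dphi(n: WeightedDensities) -> Tuple[np.ndarray, ...]:
    """Partial derivatives (dPhi/dn0, dn1, dn2, dn3, dnv1, dnv2) of the Rosenfeld form."""
    om = 1.0 - n.n3
    d0 = -np.log(om)
    d1 = n.n2 / om
    d2 = n.n1 / om + (n.n2**2 - n.nv2**2) / (8.0 * math.pi * om**2)
    d3 = (
        n.n0 / om
        + (n.n1 * n.n2 - n.nv1 * n.nv2) / om**2
        + (n.n2**3 - 3.0 * n.n2 * n.nv2**2) / (12.0 * math.pi * om**3)
    )
    dv1 = -n.nv2 / om
    dv2 = -n.nv1 / om - n.n2 * n.nv2 / (4.0 * math.pi * om**2)
    return d0, d1, d2, d3, dv1, dv2


def fmt_mu(
    fields: Fields, mixture: Mixture, ws: Optional[FunctionalWorkspace] = None
) -> np.ndarray:
    """Per-species hard-sphere chemical-potential profiles Delta-mu_HS_i(z) in k_B T.

    The bulk value (scaled-particle form) is subtracted, so flat profiles give
    identically zero. Vector weights enter the back-convolution with reversed
    sign (they are odd under reflection).
    """
    if ws is None:
        ws = FunctionalWorkspace(mixture, fields.grid)
    grid, h, pad = fields.grid, fields.grid.spacing, ws.pad
    n = weighted_densities(fields, mixture, ws)
    if np.any(n.n3 >= 1.0):
        k = int(np.argmax(n.n3))
        raise ValueError(f"local packing n3 = {n.n3[k]:.4f} >= 1 at node {k}: overpacked")
    d0, d1, d2, d3, dv1, dv2 = fmt_dphi(n)
    out = np.zeros((mixture.n_species, grid.n_nodes))
    for i, sp in enumerate(mixture.species):
        w3, w2, wv2, K = ws.fmt_by_radius[sp.radius]
        r = sp.radius
        mu_ext = np.zeros(len(d0))

        def back(fld: np.ndarray, kern: np.ndarray) -> np.ndarray:
            return _correlate(_pad(fld, K, 0.0, float(fld[-1])), kern, h)

        mu_ext += back(d3, w3)
        mu_ext += back(d2, w2)
        mu_ext += back(d1, w2) / (4.0 * math.pi * r)
        mu_ext += back(d0, w2) / (4.0 * math.pi * r**2)
        # vector weights: reversed sign under reflection
        mu_ext -= back(dv2, wv2)
        mu_ext -= back(dv1, wv2) / (4.0 * math.pi * r)

        out[i] = mu_ext[pad : pad + grid.n_nodes] - ws.mu_hs_bulk[i]
    return out


# ---------------------------------------------------------------------------
# mean-field Lennard-Jones


def lj_planar_kernel(
    eps: float, d_ij: float, h: float, z_cut: Optional[float] = None
) -> PlanarKernel:
    """In-plane integral of the LJ pair energy over r > d_ij.

    Closed form: for |dz| >= d, Phibar = 8 pi eps d^2 [ (1/10)(d/|dz|)^10
    - (1/4)(d/|dz|)^4 ]; inside the collision core the constant
    8 pi eps d^2 (1/10 - 1/4). Continuous at |dz| = d; decays like |dz|^-4.
    """
    if eps < 0.0:
        raise ValueError("pair epsilon must be >= 0")
    if z_cut is None:
        z_cut = 10.0 * d_ij
    K = max(1, int(math.ceil(z_cut / h)))
    s = np.abs(h * np.arange(-K, K + 1))
    amp = 8.0 * math.pi * eps * d_ij**2
    vals = np.empty(2 * K + 1)
    core = s < d_ij
    vals[core] = amp * (0.1 - 0.25)
    t = d_ij / s[~core]
    vals[~core] = amp * (0.1 * t**10 - 0.25 * t**4)
    vals[0] *= 0.5
    vals[-1] *= 0.5
    return PlanarKernel(values=vals, spacing=h)


def lj_meanfield_mu(
    fields: Fields, mixture: Mixture, ws: Optional[FunctionalWorkspace] = None
) -> np.ndarray:
    """Per-species mean-field LJ chemical potentials Delta-mu_LJ_i(z) in k_B T.

    Linear operator on the density deviations: Delta-mu_i(z) =
    sum_j int Phibar_ij(|z - z'|) [rho_j(z') - rho_jb] dz'. Profiles beyond the
    grid are bulk; the wall region contributes deviation -rho_jb.
    """
    if ws is None:
        ws = FunctionalWorkspace(mixture, fields.grid)
    h = fields.grid.spacing
    m = mixture.n_species
    out = np.zeros((m, fields.grid.n_nodes))
    # group source species by shared kernel for each target species
    for i in range(m):
        acc: Dict[Tuple[float, float], np.ndarray] = {}
        wall_dev: Dict[Tuple[float, float], float] = {}
        for j in range(m):
            eps = mixture.pair_epsilon[i, j]
            if eps <= 0.0:
                continue
            d_ij = lorentz_diameter(
                mixture.species[i].diameter, mixture.species[j].diameter
            )
            key = (eps, d_ij)
            dev = _jump_weighted(fields.rho[j]) - mixture.species[j].bulk_density
            acc[key] = acc.get(key, 0.0) + dev
            # wall-side extension continues the edge deviation (=-rho_jb when masked)
            wall_dev[key] = wall_dev.get(key, 0.0) + float(dev[0])
        for key, dev_sum in acc.items():
            kern = ws.lj_kernels[key]
            K = kern.half_width
            padded = _pad(dev_sum, K, wall_dev[key], float(dev_sum[-1]))
            out[i] += _correlate(padded, kern.values, h)
    return out


# ---------------------------------------------------------------------------
# screening correlations (restricted-MSA bulk-reference Taylor expansion)


def msa_b_coefficient(kappa_d: float) -> float:
    """Waisman-Lebowitz coefficient B(kappa*d) = [x + 1 - sqrt(1 + 2x)]/x.

    Equals Gamma*d/(1 + Gamma*d); B -> kappa*d/2 as kappa*d -> 0.
    """
    x = kappa_d
    if x < 0.0:
        raise ValueError("kappa*d must be >= 0")
    if x < 1.0e-4:
        return 0.5 * x - 0.5 * x**2 + 0.625 * x**3
    return (x + 1.0 - math.sqrt(1.0 + 2.0 * x)) / x


def msa_delta_c(r: np.ndarray, kappa: float, d: float, lambda_b: float) -> np.ndarray:
    """Radial beyond-mean-field MSA direct correlation function Delta-c^SC(r)/(q_i q_j).

    Waisman-Lebowitz closed form inside the core (r < d):
    lambda_B [1/r - 2B/d + B^2 r/d^2]; zero outside (the 1/r mean-field part
    lives in the Poisson solve).
    """
    B = msa_b_coefficient(kappa * d)
    out = np.zeros_like(r)
    inside = r < d
    ri = r[inside]
    out[inside] = lambda_b * (1.0 / ri - 2.0 * B / d + B**2 * ri / d**2)
    return out


def sc_planar_kernel(bulk: BulkState, h: float) -> PlanarKernel:
    """Planar reduction of the MSA Delta-c^SC (charge factors stripped).

    G(s) = 2 pi lambda_B [ (d - s) - (B/d)(d^2 - s^2) + (B^2/(3 d^2))(d^3 - s^3) ]
    for s < d, zero beyond; multiply by q_i q_j and convolve with the density
    deviations to get the SC chemical potentials.
    """
    d = bulk.ion_diameter
    if d <= 0.0:
        raise ValueError("SC kernel requires charged species with a common diameter")
    B = msa_b_coefficient(bulk.kappa * d)
    K = max(1, int(round(d / h)))
    s = np.abs(h * np.arange(-K, K + 1))
    s = np.minimum(s, d)
    vals = (
        2.0
        * math.pi
        * bulk.lambda_b
        * ((d - s) - (B / d) * (d**2 - s**2) + (B**2 / (3.0 * d**2)) * (d**3 - s**3))
    )
    vals[0] *= 0.5
    vals[-1] *= 0.5
    return PlanarKernel(values=vals, spacing=h)


def sc_mu(
    fields: Fields, bulk: BulkState, ws: Optional[FunctionalWorkspace] = None
) -> np.ndarray:
    """Per-species screening-correlation potentials Delta-mu_SC_i(z) in k_B T.

    Second-order bulk-reference expansion: Delta-mu_i = -q_i * int G(|z-z'|)
    sum_j q_j [rho_j(z') - rho_jb] dz'. Neutral species get zero; flat profiles
    give zero. Requires the restricted (equal ion diameter) model.
    """
    mixture = bulk.mixture
    if ws is None or ws.sc_kernel is None:
        kern = sc_planar_kernel(bulk, fields.grid.spacing)
    else:
        kern = ws.sc_kernel
    h = fields.grid.spacing
    q = mixture.valences
    rho_w = np.stack([_jump_weighted(fields.rho[i]) for i in range(mixture.n_species)])
    dev_q = q @ (rho_w - mixture.bulk_densities[:, None])
    K = kern.half_width
    # wall-side extension continues the edge value of the charge deviation
    # (zero both for flat profiles and for fully masked walls, by electroneutrality)
    conv = _correlate(_pad(dev_q, K, float(dev_q[0]), float(dev_q[-1])), kern.values, h)
    return -np.outer(q, np.ones(fields.grid.n_nodes)) * conv
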