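"""Domain types for the planar electric-double-layer problem.

Species, Mixture, the uniform planar Grid, per-profile Fields, and the
elementary wall (external) potentials. The wall plane sits at z = 0 and
species centres are restricted to z >= d_i/2 (closed at contact); the grid
is node-centred with z_k = k*h, 0-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import constants as const

__all__ = [
    "Species",
    "Mixture",
    "Grid",
    "Fields",
    "ExternalPotential",
    "lorentz_diameter",
    "hard_wall_potential",
    "lj93_wall_potential",
    "wall_field_energy",
    "charge_density",
]


@dataclass(frozen=True)
class Species:
    """One fluid component.

    Parameters
    ----------
    name : str
        Label used in configuration and output columns.
    diameter : float
        Hard-sphere diameter d_i in nm.
    valence : int
        Signed charge in units of e.
    bulk_density : float
        Bulk number density in nm^-3 (see :func:`edldft.constants.molar_to_per_nm3`).
    wall_kind : {"hard", "lj93"}
        Non-electrostatic species-wall interaction.
    wall_epsilon : float
        LJ 9-3 well-depth parameter eps_{i-w} in k_B T (only for wall_kind="lj93";
        by convention the ion value is held at 1 k_B T).
    is_solvent : bool
        Flags the explicit neutral solvent component.
    """

    name: str
    diameter: float
    valence: int
    bulk_density: float
    wall_kind: str = "hard"
    wall_epsilon: float = 0.0
    is_solvent: bool = False

    def __post_init__(self) -> None:
        if self.diameter <= 0.0:
            raise ValueError(f"species {self.name!r}: diameter must be > 0")
        if self.bulk_density < 0.0:
            raise ValueError(f"species {self.name!r}: bulk density must be >= 0")
        if self.wall_kind not in ("hard", "lj93"):
            raise ValueError(f"species {self.name!r}: unknown wall_kind {self.wall_kind!r}")
        if self.is_solvent and self.valence != 0:
            raise ValueError(f"species {self.name!r}: only an uncharged species may be solvent")

    @property
    def radius(self) -> float:
        return 0.5 * self.diameter


def lorentz_diameter(d_i: float, d_j: float) -> float:
    """Lorentz combining rule d_ij = (d_i + d_j)/2 for the pair collision diameter."""
    if d_i <= 0.0 or d_j <= 0.0:
        raise ValueError("diameters must be positive")
    return 0.5 * (d_i + d_j)


_ELECTRONEUTRALITY_RTOL = 1.0e-12


class Mixture:
    """An electrolyte mixture: ordered species, pair LJ energies and temperature.

    Parameters
    ----------
    species : sequence of Species
    pair_epsilon : (M, M) array_like, optional
        Symmetric LJ well depths eps_ij in k_B T. Defaults to zeros (no
        attractions — the primitive model).
    temperature : float
        Absolute temperature in K. Enters only through SI conversions and the
        Coulomb coupling; LJ energies are specified directly in k_B T.
    bulk_pH : float, optional
        Bulk pH when a proton species participates in surface chemistry.
    """

    def __init__(
        self,
        species: Sequence[Species],
        pair_epsilon=None,
        temperature: float = 298.15,
        bulk_pH: Optional[float] = None,
    ) -> None:
        if temperature <= 0.0:
            raise ValueError("temperature must be positive")
        self.species = list(species)
        if len({s.name for s in self.species}) != len(self.species):
            raise ValueError("species names must be unique")
        m = len(self.species)
        if pair_epsilon is None:
            pair_epsilon = np.zeros((m, m))
        eps = np.asarray(pair_epsilon, dtype=float)
        if eps.shape != (m, m):
            raise ValueError(f"pair_epsilon must be ({m}, {m})")
        if not np.allclose(eps, eps.T):
            raise ValueError("pair_epsilon must be symmetric")
        if np.any(eps < 0.0):
            raise ValueError("pair_epsilon must be >= 0")
        self.pair_epsilon = eps
        self.temperature = float(temperature)
        self.bulk_pH = bulk_pH

        net = sum(s.valence * s.bulk_density for s in self.species)
        scale = sum(abs(s.valence) * s.bulk_density for s in self.species)
        if scale > 0.0 and abs(net) > _ELECTRONEUTRALITY_RTOL * scale:
            raise ValueError(
                f"bulk composition is not electroneutral: sum q_i rho_i = {net:g} nm^-3"
            )

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def bulk_densities(self) -> np.ndarray:
        return np.array([s.bulk_density for s in self.species])

    @property
    def diameters(self) -> np.ndarray:
        return np.array([s.diameter for s in self.species])

    @property
    def valences(self) -> np.ndarray:
        return np.array([s.valence for s in self.species], dtype=float)

    def index(self, name: str) -> int:
        for i, s in enumerate(self.species):
            if s.name == name:
                return i
        raise KeyError(name)

    @property
    def solvent(self) -> Optional[Species]:
        for s in self.species:
            if s.is_solvent:
                return s
        return None

    @property
    def packing_fraction(self) -> float:
        return float(sum(math.pi / 6.0 * s.diameter**3 * s.bulk_density for s in self.species))


@dataclass(frozen=True)
class Grid:
    """Uniform node-centred planar grid: z_k = k*h, k = 0..n_nodes-1."""

    spacing: float
    n_nodes: int

    def __post_init__(self) -> None:
        if self.spacing <= 0.0:
            raise ValueError("grid spacing must be positive")
        if self.n_nodes < 4:
            raise ValueError("grid needs at least 4 nodes")

    @property
    def length(self) -> float:
        return self.spacing * (self.n_nodes - 1)

    @property
    def z(self) -> np.ndarray:
        return self.spacing * np.arange(self.n_nodes)

    @classmethod
    def for_mixture(
        cls,
        mixture: "Mixture",
        kappa: float,
        *,
        nodes_per_diameter: int = 50,
        screening_lengths: float = 10.0,
        min_diameters: float = 20.0,
    ) -> "Grid":
        """Default grid: h = d_ref/nodes_per_diameter with d_ref the solvent
        (else largest) diameter; L = max(screening_lengths/kappa, min_diameters*d_max)."""
        solv = mixture.solvent
        d_ref = solv.diameter if solv is not None else float(np.max(mixture.diameters))
        h = d_ref / nodes_per_diameter
        d_max = float(np.max(mixture.diameters))
        length = min_diameters * d_max
        if kappa > 0.0:
            length = max(length, screening_lengths / kappa)
        n = int(math.ceil(length / h)) + 1
        return cls(spacing=h, n_nodes=n)

    def trapz(self, f: np.ndarray) -> float:
        return float(np.trapezoid(f, dx=self.spacing))


@dataclass
class Fields:
    """Per-species density profiles plus potential / permittivity / charge profiles.

    Densities are in nm^-3, psi in k_B T/e, eps_r dimensionless.
    """

    grid: Grid
    rho: np.ndarray  # (M, N)
    psi: np.ndarray  # (N,)
    eps_r: np.ndarray  # (N,)

    @classmethod
    def bulk(cls, mixture: Mixture, grid: Grid, eps_r: float = 78.5) -> "Fields":
        n = grid.n_nodes
        rho = np.repeat(mixture.bulk_densities[:, None], n, axis=1).astype(float)
        return cls(grid=grid, rho=rho, psi=np.zeros(n), eps_r=np.full(n, float(eps_r)))

    def copy(self) -> "Fields":
        return Fields(self.grid, self.rho.copy(), self.psi.copy(), self.eps_r.copy())


@dataclass
class ExternalPotential:
    """A wall potential: finite values plus an explicit excluded-region mask.

    The mask is a boolean array, True where the species centre is excluded;
    `values` is zero inside the mask (never a large finite surrogate, to keep
    exponentials overflow-free).
    """

    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask must have the same shape")


def hard_wall_potential(species: Species, grid: Grid) -> ExternalPotential:
    """Hard wall: centres excluded for z < d_i/2, V = 0 at and beyond contact."""
    z = grid.z
    mask = z < species.radius
    return ExternalPotential(values=np.zeros(grid.n_nodes), mask=mask)


def lj93_wall_potential(species: Species, grid: Grid, diameter: Optional[float] = None) -> ExternalPotential:
    """LJ 9-3 wall: V(z) = eps*[(2/15)(d/z)^9 - (d/z)^3] for z > d/2.

    The length scale defaults to the species' own diameter; centres at
    z <= d/2 are hard-core masked.
    """
    if species.wall_epsilon < 0.0:
        raise ValueError("wall_epsilon must be >= 0")
    d = species.diameter if diameter is None else diameter
    if d <= 0.0:
        raise ValueError("LJ 9-3 length scale must be positive")
    z = grid.z
    mask = z <= 0.5 * d
    values = np.zeros(grid.n_nodes)
    zz = z[~mask]
    r = d / zz
    values[~mask] = species.wall_epsilon * ((2.0 / 15.0) * r**9 - r**3)
    return ExternalPotential(values=values, mask=mask)


def wall_field_energy(
    species: Species, sigma: float, eps_r: float, grid: Grid, temperature: float = 298.15
) -> ExternalPotential:
    """Bare wall-field interaction energy q_i*(Psi_bare(z) - Psi_bare(0)) in k_B T.

    Psi_bare is the potential of the charged wall alone (charge-free fluid),
    i.e. the solution of the Poisson equation with Neumann wall condition
    eps0*eps_r*Psi'(0+) = -sigma, giving V(z) = -q_i*sigma*z/(eps0*eps_r*k_B T).

    Validation-only route in uniform-eps mode: the production solver carries
    the wall charge in the Poisson boundary condition instead, so this term
    must never be added on top of a Poisson solve that already sees sigma.

    Parameters use reduced units: sigma in e/nm^2; the returned values are in k_B T.
    """
    lam0 = const.vacuum_bjerrum_length_nm(temperature)
    z = grid.z
    mask = z < species.radius
    values = np.zeros(grid.n_nodes)
    # -q sigma z/(eps eps0 kT) = -4 pi lambda_B0 q sigma z / eps_r
    values[~mask] = -4.0 * math.pi * lam0 * species.valence * sigma * z[~mask] / eps_r
    return ExternalPotential(values=values, mask=mask)


def charge_density(fields: Fields, mixture: Mixture) -> np.ndarray:
    """Charge-density profile rho_e(z) = sum_i q_i rho_i(z), in e/nm^3."""
    if fields.rho.shape != (mixture.n_species, fields.grid.n_nodes):
        raise ValueError(
            f"density array shape {fields.rho.shape} does not match "
            f"({mixture.n_species}, {fields.grid.n_nodes})"
        )
    return mixture.valences @ fields.rho
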