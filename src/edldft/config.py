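"""Declarative run configuration (TOML) and preset builders.

Schema (all keys optional unless noted):

    [mixture]
    temperature_K = 298.15
    bulk_pH = 4.0                  # enables the explicit proton species

    [species.solvent]              # one table per species; the table name is the label
    diameter_nm = 0.3              # required
    valence = 0
    reduced_density = 0.7          # rho * d^3; or concentration_M, or density_per_nm3
    wall = "lj93"                  # "hard" (default) or "lj93"
    wall_epsilon_kT = 2.0
    solvent = true

    [lj]
    default_kT = 1.0               # LJ well depth for every pair
    "cation:anion" = 0.5           # per-pair override (labels sorted either way)

    [wall]
    sigma_C_per_m2 = -0.1          # fixed-charge mode (exclusive with CR)
    charge_regulation = true       # 2-pK mode; needs [surface_chemistry] + bulk_pH

    [surface_chemistry]
    site_density_per_nm2 = 1.0     # required in CR mode
    pK_plus = -2.0
    pK_minus = 6.0
    proton_species = "H"           # auto-added (with a spectator counter-ion) if absent
    sampling = "window"            # "window" | "contact" | "yfunction"
    window_width_nm = 0.15

    [dielectric]
    model = "uniform"              # "uniform" | "clausius_mossotti" | "oleksy_hansen"
    eps_r = 78.5
    # CM: m2_over_kT_nm3; OH: a, rho_mid_reduced, f_coeff0, f_coeff1, t_model

    [solver]
    mixing = 0.1
    tolerance = 1e-8
    max_iter = 20000
    cr_damping = 0.5
    cr_tolerance = 1e-8
    hs = true
    lj = true
    sc = false
    initial_guess = "pb_seed"
    electrostatics = "implicit"
    nodes_per_diameter = 50
    screening_lengths = 10.0
    min_diameters = 20.0

    [output]
    prefix = "run"
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np

from . import constants as const
from .bulk import BulkState, debye_kappa
from .chemistry import SurfaceChemistry
from .electrostatics import DielectricModel
from .model import Grid, Mixture, Species
from .solver import SolverConfig

__all__ = [
    "RunSetup",
    "ConfigError",
    "load_config",
    "setup_from_dict",
    "semiprimitive_setup",
    "primitive_setup",
]


class ConfigError(ValueError):
    """A configuration problem, reporting the offending key path."""


@dataclass
class RunSetup:
    """Everything needed to launch a solve, as parsed from configuration."""

    mixture: Mixture
    solver: SolverConfig
    sigma: Optional[float] = None  # e/nm^2; None in charge-regulation mode
    chemistry: Optional[SurfaceChemistry] = None
    nodes_per_diameter: int = 50
    screening_lengths: float = 10.0
    min_diameters: float = 20.0
    output_prefix: str = "run"
    echo: dict = field(default_factory=dict)

    def grid(self, resolution: float = 1.0) -> Grid:
        eps_b = self.solver.dielectric.eps_r if self.solver.dielectric.kind == "uniform" else None
        if eps_b is None:
            from .solver import bulk_eps_r

            eps_b = bulk_eps_r(self.mixture, self.solver.dielectric)
        kappa = debye_kappa(self.mixture, eps_b)
        return Grid.for_mixture(
            self.mixture,
            kappa,
            nodes_per_diameter=max(4, int(round(self.nodes_per_diameter * resolution))),
            screening_lengths=self.screening_lengths,
            min_diameters=self.min_diameters,
        )


def _density_from_table(name: str, tab: dict, diameter: float) -> float:
    keys = [k for k in ("concentration_M", "density_per_nm3", "reduced_density") if k in tab]
    if len(keys) > 1:
        raise ConfigError(f"species.{name}: give only one of {keys}")
    if not keys:
        raise ConfigError(
            f"species.{name}: missing density (concentration_M, density_per_nm3 "
            "or reduced_density)"
        )
    k = keys[0]
    v = float(tab[k])
    if k == "concentration_M":
        return const.molar_to_per_nm3(v)
    if k == "reduced_density":
        return v / diameter**3
    return v


def _parse_species(name: str, tab: dict) -> Species:
    if "diameter_nm" not in tab:
        raise ConfigError(f"species.{name}: missing required key diameter_nm")
    d = float(tab["diameter_nm"])
    return Species(
        name=name,
        diameter=d,
        valence=int(tab.get("valence", 0)),
        bulk_density=_density_from_table(name, tab, d),
        wall_kind=tab.get("wall", "hard"),
        wall_epsilon=float(tab.get("wall_epsilon_kT", 0.0)),
        is_solvent=bool(tab.get("solvent", False)),
    )


def _pair_epsilon(species: List[Species], lj_tab: dict) -> np.ndarray:
    m = len(species)
    eps = np.full((m, m), float(lj_tab.get("default_kT", 0.0)))
    idx = {s.name: i for i, s in enumerate(species)}
    for key, val in lj_tab.items():
        if key == "default_kT":
            continue
        try:
            a, b = key.split(":")
        except ValueError:
            raise ConfigError(f"lj: pair key {key!r} must look like 'name1:name2'")
        for nm in (a, b):
            if nm not in idx:
                raise ConfigError(f"lj: unknown species {nm!r} in pair {key!r}")
        eps[idx[a], idx[b]] = eps[idx[b], idx[a]] = float(val)
    return eps


def _ensure_cr_species(
    species: List[Species], proton_name: str, pH: float
) -> List[Species]:
    """Add the explicit proton (10^-pH M) and a spectator counter-ion when the
    configuration does not declare them. Their diameter defaults to the ion
    diameter (smallest charged species, else solvent)."""
    names = {s.name for s in species}
    if proton_name in names:
        return species
    ions = [s for s in species if s.valence != 0]
    ref = min(ions, key=lambda s: s.diameter) if ions else species[0]
    rho_h = const.molar_to_per_nm3(10.0 ** (-pH))
    extra = [
        Species(proton_name, ref.diameter, +1, rho_h, ref.wall_kind, ref.wall_epsilon),
        Species(proton_name + "_counter", ref.diameter, -1, rho_h, ref.wall_kind, ref.wall_epsilon),
    ]
    return species + extra


def setup_from_dict(cfg: dict) -> RunSetup:
    mix_tab = cfg.get("mixture", {})
    temperature = float(mix_tab.get("temperature_K", 298.15))
    pH = mix_tab.get("bulk_pH")

    sp_tab = cfg.get("species", {})
    if not sp_tab:
        raise ConfigError("no [species.*] tables found")
    species = [_parse_species(name, tab) for name, tab in sp_tab.items()]

    wall_tab = cfg.get("wall", {})
    cr_mode = bool(wall_tab.get("charge_regulation", False))
    sigma = None
    chem = None
    if cr_mode and "sigma_C_per_m2" in wall_tab:
        raise ConfigError("wall: sigma_C_per_m2 and charge_regulation are exclusive")
    if cr_mode:
        sc_tab = cfg.get("surface_chemistry")
        if sc_tab is None:
            raise ConfigError("charge_regulation = true requires [surface_chemistry]")
        if pH is None:
            raise ConfigError("charge_regulation = true requires mixture.bulk_pH")
        for key in ("site_density_per_nm2", "pK_plus", "pK_minus"):
            if key not in sc_tab:
                raise ConfigError(f"surface_chemistry: missing required key {key}")
        proton = sc_tab.get("proton_species", "H")
        species = _ensure_cr_species(species, proton, float(pH))
        chem = SurfaceChemistry(
            n_sites=float(sc_tab["site_density_per_nm2"]),
            pk_plus=float(sc_tab["pK_plus"]),
            pk_minus=float(sc_tab["pK_minus"]),
            proton=proton,
            sampling=sc_tab.get("sampling", "window"),
            window_width=sc_tab.get("window_width_nm"),
            y_wall_position=sc_tab.get("y_wall_position_nm"),
        )
    else:
        if "sigma_C_per_m2" in wall_tab:
            sigma = const.sigma_si_to_reduced(float(wall_tab["sigma_C_per_m2"]))
        elif "sigma_e_per_nm2" in wall_tab:
            sigma = float(wall_tab["sigma_e_per_nm2"])
        else:
            sigma = 0.0

    eps = _pair_epsilon(species, cfg.get("lj", {}))
    mixture = Mixture(species, eps, temperature=temperature, bulk_pH=pH)

    di_tab = cfg.get("dielectric", {})
    dielectric = DielectricModel(
        kind=di_tab.get("model", "uniform"),
        eps_r=float(di_tab.get("eps_r", 78.5)),
        m2_over_kT=float(di_tab.get("m2_over_kT_nm3", 0.0)),
        a=float(di_tab.get("a", 4.0)),
        rho_mid=float(di_tab.get("rho_mid_reduced", 0.35)),
        f_coeff0=float(di_tab.get("f_coeff0", 88.0)),
        f_coeff1=float(di_tab.get("f_coeff1", 0.37)),
        t_model=float(di_tab.get("t_model", 1.0)),
    )

    so_tab = cfg.get("solver", {})
    solver = SolverConfig(
        mixing=float(so_tab.get("mixing", 0.1)),
        tolerance=float(so_tab.get("tolerance", 1.0e-8)),
        max_iter=int(so_tab.get("max_iter", 20000)),
        cr_damping=float(so_tab.get("cr_damping", 0.5)),
        cr_tolerance=float(so_tab.get("cr_tolerance", 1.0e-8)),
        hs_on=bool(so_tab.get("hs", True)),
        lj_on=bool(so_tab.get("lj", True)),
        sc_on=bool(so_tab.get("sc", False)),
        dielectric=dielectric,
        initial_guess=so_tab.get("initial_guess", "pb_seed"),
        electrostatics=so_tab.get("electrostatics", "implicit"),
    )

    out_tab = cfg.get("output", {})
    return RunSetup(
        mixture=mixture,
        solver=solver,
        sigma=sigma,
        chemistry=chem,
        nodes_per_diameter=int(so_tab.get("nodes_per_diameter", 50)),
        screening_lengths=float(so_tab.get("screening_lengths", 10.0)),
        min_diameters=float(so_tab.get("min_diameters", 20.0)),
        output_prefix=out_tab.get("prefix", "run"),
        echo=cfg,
    )


def load_config(path) -> RunSetup:
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    return setup_from_dict(cfg)


# ---------------------------------------------------------------------------
# presets for the two canonical study conditions


def semiprimitive_setup(
    wall_epsilon_solvent: float,
    salt_molar: float = 0.01,
    bulk_pH: float = 4.0,
    pk_plus: float = -2.0,
    pk_minus: float = 6.0,
    n_sites: float = 1.0,
    d0: float = 0.3,
    reduced_solvent_density: float = 0.7,
    eps_r: float = 78.5,
    **solver_overrides,
) -> RunSetup:
    """Explicit-solvent (semi-primitive) charge-regulated EDL.

    A 1:1 electrolyte in a neutral LJ solvent at a 2-pK amphoteric wall. The
    solvent-wall LJ 9-3 strength sets the wettability (0 solvophobic, 1
    neutral, 2 solvophilic); the ion-wall strength is held at 1 k_B T. All
    fluid-fluid pairs share eps = 1 k_B T (reduced temperature 1) and the
    common diameter d0; the solvent sits at rho d0^3 = 0.7.
    """
    cfg = {
        "mixture": {"temperature_K": 298.15, "bulk_pH": bulk_pH},
        "species": {
            "solvent": {
                "diameter_nm": d0,
                "valence": 0,
                "reduced_density": reduced_solvent_density,
                "wall": "lj93",
                "wall_epsilon_kT": wall_epsilon_solvent,
                "solvent": True,
            },
            "cation": {
                "diameter_nm": d0,
                "valence": 1,
                "concentration_M": salt_molar,
                "wall": "lj93",
                "wall_epsilon_kT": 1.0,
            },
            "anion": {
                "diameter_nm": d0,
                "valence": -1,
                "concentration_M": salt_molar,
                "wall": "lj93",
                "wall_epsilon_kT": 1.0,
            },
        },
        "lj": {"default_kT": 1.0},
        "wall": {"charge_regulation": True},
        "surface_chemistry": {
            "site_density_per_nm2": n_sites,
            "pK_plus": pk_plus,
            "pK_minus": pk_minus,
        },
        "dielectric": {"model": "uniform", "eps_r": eps_r},
        # 16 Debye lengths keep the far-field truncation error in the global
        # electroneutrality balance below 1e-6
        "solver": {"hs": True, "lj": True, "sc": False, "screening_lengths": 16.0,
                   **solver_overrides},
    }
    return setup_from_dict(cfg)


def primitive_setup(
    cation_molar: float,
    sigma_C_per_m2: float = -0.1,
    cation_valence: int = 2,
    d_ion: float = 0.3,
    eps_r: float = 78.5,
    sc: bool = True,
    **solver_overrides,
) -> RunSetup:
    """Primitive-model asymmetric electrolyte at a fixed-charge hard wall.

    Charged hard spheres in a dielectric continuum: +z cations and -1 anions
    of common diameter, no solvent, no LJ attractions. With sc=True the MSA
    screening-correlation term is enabled (the charge-inversion study)."""
    cfg = {
        "mixture": {"temperature_K": 298.15},
        "species": {
            "cation": {
                "diameter_nm": d_ion,
                "valence": cation_valence,
                "concentration_M": cation_molar,
            },
            "anion": {
                "diameter_nm": d_ion,
                "valence": -1,
                "concentration_M": cation_molar * cation_valence,
            },
        },
        "wall": {"sigma_C_per_m2": sigma_C_per_m2},
        "dielectric": {"model": "uniform", "eps_r": eps_r},
        "solver": {"hs": True, "lj": False, "sc": sc, **solver_overrides},
    }
    return setup_from_dict(cfg)
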