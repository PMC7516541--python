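# edldft

A one-dimensional classical density functional theory (cDFT) solver for the
equilibrium structure of **electric double layers** (EDLs): electrolyte
solutions — optionally with an explicit neutral solvent — against a planar
charged wall whose charge can be **regulated by 2-pK surface chemistry**
instead of being prescribed.

The package is aimed at researchers in colloid and interface science,
electrochemistry and nanofluidics who want a desk-scale, fully deterministic
reference solver for double-layer structure beyond Poisson-Boltzmann: ion and
solvent packing, ion-ion screening correlations, density-dependent
permittivity, and chemically self-consistent surface charge.

## The model

Equilibrium density profiles ρᵢ(z) minimize the grand potential

    Ω[ρ] = F_id + F_HS + F_LJ + F_SC + Σᵢ ∫ ρᵢ(z) (Vᵢᵉˣᵗ(z) − μᵢ) dz

whose Euler-Lagrange equations take the Boltzmann-factor form

    ρᵢ(z) = ρᵢᵇ exp(−[Δμ_HS,i(z) + qᵢ e Ψ(z) + Δμ_LJ,i(z) + Δμ_SC,i(z)
                     + Vᵢᵉˣᵗ(z)] / k_B T).

* **F_HS** — Rosenfeld fundamental-measure theory (FMT) for hard-sphere
  packing, via planar weighted densities n₀…n₃, nv₁, nv₂.
* **F_LJ** — mean-field convolution of the Lennard-Jones attractions
  (r > d_ij domain), the "semi-primitive" route to solvation and wetting.
* **F_SC** — screening correlations beyond the mean field: a second-order
  Taylor expansion about the bulk using the restricted-MSA direct correlation
  function (Waisman-Lebowitz form, screening parameter
  Γ = (√(1+2κd) − 1)/2d). This is the term responsible for charge inversion.
* **Ψ(z)** — from the Poisson equation ∂z(ε₀ε_r(z) ∂zΨ) = −ρ_e(z) with the
  wall charge σ as Neumann condition; ε_r(z) may be uniform or follow the
  Clausius-Mossotti or Oleksy-Hansen density-dependent models evaluated on the
  volume-averaged solvent density ρ̃₀(z).
* **Charge regulation** — amphoteric sites AH₂⁺ ⇌ AH + H⁺ (pK₊),
  AH ⇌ A⁻ + H⁺ (pK₋); σ = e·N_s(f₊ − f₋) is determined by the proton activity
  sampled at the surface from an explicit proton species, so σ and Ψ₀ are
  *outputs* of the solve.

The coupled equations are solved by damped Picard iteration with a
semi-implicit electrostatic step (an inner Newton solve of the
Boltzmann-closed Poisson equation), plus an outer damped fixed-point loop on
σ in charge-regulation mode. Everything is deterministic; repeated runs are
bit-identical.

## Worked example: charge inversion

`examples/charge_inversion.toml` describes a primitive-model electrolyte with
+2 cations and −1 anions (both 0.3 nm) at 1 M against a hard wall carrying
−0.1 C/m², with the screening-correlation term enabled:

```sh
$ edldft bulk-info --config examples/charge_inversion.toml
Debye length       : 0.175633 nm
Bjerrum length     : 0.713961 nm
MSA Gamma          : 1.8358 1/nm
packing fraction   : 0.0255408
pressure           : 1.34715 kT/nm^3
mu_ex[    cation]   : HS +0.21455  SC -3.3808  LJ +0  total -3.1663 kT
mu_ex[     anion]   : HS +0.21455  SC -0.8452  LJ +0  total -0.63065 kT

$ edldft run --config examples/charge_inversion.toml --out out/
sigma = -0.1 C/m^2, psi0 = -32.3885 mV, 258 iterations
```

The surface potential is −32.4 mV, but the profile written to
`out/inversion_profiles.tsv` crosses zero and reaches *positive* values about
one ion diameter from the wall — the divalent counterions overcompensate the
wall charge and a second layer of anions accumulates above its bulk
concentration. Re-running with `sc = false` (pure mean field) gives a
potential that is negative everywhere: charge inversion is entirely a
correlation effect.

## Worked example: charge-regulated wetting

`examples/wetting_cr.toml` is the explicit-solvent case: 0.01 M 1:1 salt in a
neutral LJ solvent (ρ₀d₀³ = 0.7, d₀ = 0.3 nm), bulk pH 4, pK₊ = −2, pK₋ = 6,
and a solvophilic wall (solvent-wall LJ 9-3 strength 2 k_BT):

```sh
$ edldft run --config examples/wetting_cr.toml --out out/
sigma = -0.00197073 C/m^2, psi0 = -9.51327 mV, 28 iterations
```

The deprotonated surface regulates itself to σ = −0.012 e/nm² (the summary
JSON also reports the sampled surface pH, 4.10, slightly above bulk because
the negative wall attracts protons). The charge-density column in the profile
TSV oscillates with a period of one solvent diameter — solvent packing, not
electrostatics, sets the local EDL structure — while the potential itself
stays monotonic. Lowering `wall_epsilon_kT` of the solvent to 1 (neutral
wetting) or 0 (solvophobic) weakens the layering and shrinks |Ψ₀|.

Other subcommands: `edldft pb` (point-ion Poisson-Boltzmann reference, by
σ or by target Ψ₀) and `edldft titrate` (σ and Ψ₀ across a bulk-pH sweep).

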