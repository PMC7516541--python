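# Methods

This note records the model assumptions, numerical scheme, parameter defaults
and design choices behind `edldft`, at the level a maintainer or careful user
needs. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Units and constants

Internal computation uses reduced units: lengths in nanometres, energies in
k_BT at the fixed working temperature, charges in elementary charges e,
densities in nm⁻³, surface charge in e/nm², potential in k_BT/e. SI values
(mol/L, C/m², mV) appear only at configuration parsing and output writing.
Physical constants are CODATA 2018 (`constants.py`). The electrostatic
coupling enters through the vacuum Bjerrum length
λ_B0 = e²/(4πε₀k_BT) ≈ 56.1 nm at 298.15 K, so the reduced Poisson equation
is ∂z(ε_r ∂zψ) = −4πλ_B0 ρ_q.

## Geometry and grid

The wall plane is z = 0; species centres are restricted to z ≥ d_i/2, closed
at contact (the node at exactly d_i/2 is fluid). The grid is uniform and
node-centred, z_k = k·h. Defaults: h = d_ref/50 with d_ref the solvent (else
largest) diameter, and L = max(S·κ⁻¹, 20·d_max) with S = 10 for generic runs.
The explicit-solvent charge-regulated preset uses S = 16: the integrated
fluid charge misses the wall charge by O(e^{−κL}), and 16 screening lengths
keep that global electroneutrality defect below 10⁻⁶ relative. All
quadrature is trapezoidal on nodes.

Hard cores are represented as explicit boolean masks, never as large finite
energies, so the Boltzmann exponentials cannot overflow from the wall term;
remaining exponents are clipped at ±700 with a counter in the Solution.

## Discrete convolutions

All functional convolutions are direct banded quadrature (`np.correlate`)
with tabulated kernels; kernels are shared between species with equal
diameters and between LJ pairs with equal (ε, d_ij), which is what keeps a
five-species charge-regulated run at seconds per Picard pass.

Three numerical conventions matter for accuracy:

1. **Kernel renormalization.** Discrete scalar FMT kernels (and the solvent
   volume-average kernel) are rescaled so that a uniform profile reproduces
   the analytic bulk weighted densities *exactly*. Combined with bulk
   chemical potentials computed from the same analytic uniform limit, every
   Δμ operator vanishes identically on flat profiles (machine precision, not
   just O(h²)) — the sum rule that lets profiles relax to bulk.
2. **Edge-value extension.** Profiles are extended beyond both grid ends with
   their edge values. A masked profile is zero at the wall edge, so this
   reproduces "no fluid behind the wall"; a converged profile equals bulk at
   z = L, so the right extension is the reservoir. The operators themselves
   carry no knowledge of the wall.
3. **Jump-node half weighting.** A hard-core mask puts the density
   discontinuity exactly on the contact node. Trapezoidal quadrature of a
   function that jumps *at* a node must weight that node by the mean of its
   one-sided limits, i.e. half the contact value. This restores O(h²)
   behaviour at the wall; without it the hard-wall contact theorem converges
   only first-order (≈4% error at h = d/50 instead of ≈0.07%).

The LJ planar kernel uses the closed form of the in-plane integral over
r > d_ij, tabulated to a cutoff of 10 d_ij (the |Δz|⁻⁴ tail beyond that is
negligible against the bulk-subtracted deviations it multiplies). The
mean-field LJ and SC operators act on density *deviations* from bulk, so
their bulk values are identically zero by construction.

## Screening correlations

The SC term is the second-order bulk-reference Taylor expansion of the
correlation free energy, with the beyond-mean-field part of the restricted
MSA direct correlation function as kernel:

    Δc_ij(r) = λ_B q_i q_j [1/r − 2B/d + B²r/d²],  r < d;  0 otherwise,

with B(κd) = (κd + 1 − √(1+2κd))/κd = Γd/(1+Γd), evaluated by a series below
κd = 10⁻⁴ to avoid cancellation (B → κd/2 in the Debye-Hückel limit, verified
against the series in the tests). The 1/r mean-field part is excluded — it
lives in the Poisson solve. The corresponding bulk excess chemical potential
is μ_i^SC = −k_BT λ_B q_i² Γ/(1+Γd) and the SC pressure contribution
−Γ³/(3π), making the bulk state thermodynamically consistent with the
profile operators (checked by a Gibbs-Duhem path integral in the tests).

The restricted model (all ions share one diameter) is assumed; mixtures with
unequal ion diameters must run with `sc = false` and otherwise raise an
error naming the restriction. Because Δc_ij ∝ q_i q_j, the SC operator
reduces to a single convolution of the charge-density deviation — and is
therefore insensitive to the wall-extension convention, as the bulk charge
density is zero.

This expansion reproduces the *sign structure* of ion correlations — the SC
component of the potential of mean force is negative where counterions
accumulate, and it drives charge inversion at 1 M for 2:1 electrolytes at
−0.1 C/m² — but it is a bulk-state expansion: quantitative agreement with
reference-fluid-based correlation functionals degrades at strong
inhomogeneity, so charge-inversion results should be read qualitatively
(onset and sign, not curve shape). The operator sits behind the same
interface as the other Δμ terms so a more elaborate SC functional can be
swapped in.

## Electrostatics

`solve_poisson` is a second-order finite-volume scheme with harmonic-mean
interface permittivities, a Neumann wall condition ε₀ε_r(0)Ψ′(0⁺) = −σ and a
Dirichlet far anchor Ψ(L) = 0 (manufactured-solution tests verify the
observed order is 2.0 ± 0.1, also with spatially varying ε_r). The wall
charge enters *only* through the Neumann condition; the closed-form bare
wall-field energy q_i(Ψ_bare(z) − Ψ_bare(0)) = −q_iσz/(ε₀ε_r) is retained as
a uniform-ε cross-check against the Poisson route and is never added to a
solve that already carries σ in its boundary condition.

`solve_pb` and the semi-implicit inner step share one damped-Newton kernel
for the Boltzmann-closed Poisson equation with arbitrary spatial prefactors
w_i(z). Newton convergence is quadratic; steps are halved (up to 40 times)
whenever the residual norm grows.

### Dielectric models

The permittivity profile is computed from the *volume-averaged* solvent
density ρ̃₀(z) (spherical average over the solvent diameter, planar-reduced,
normalization fixed so a uniform profile is preserved — the raw geometric
prefactor would not preserve it). Models:

* **uniform** (default): ε_r = 78.5.
* **clausius_mossotti**: ε_r = (1 + 2y)/(1 − y), y = (4π/9)(m²/k_BT)ρ̃₀. The
  standard CM form is used; note it equals 1 at zero density and diverges at
  the polarization catastrophe, where the solver raises. (Printed variants of
  this equation with the denominator written as y − 1 give ε_r = −1 in vacuum
  and are not implemented.)
* **oleksy_hansen**: ε_r = 1 + f(T)/(1 + exp[−a(ρ̃₀d₀³ − ρ_mid d₀³)]) with
  f(T) = 88 − 0.37T. **Temperature convention:** T here is the *reduced*
  temperature of the underlying solvent model (default t_model = 1, giving
  f = 87.63 ≈ water's static permittivity amplitude); interpreting T as
  kelvin at ambient conditions would make f negative, so the coefficients and
  t_model are explicit configuration values and a non-positive f raises.

During a cDFT solve the dielectric profile is frozen per Picard iteration
(computed from the previous solvent profile) to avoid a nested nonlinear
solve.

## The Picard solver

Mixing update ρ ← (1−α)ρ + α·ρ_trial with α = 0.1 by default, automatically
halved (down to 10⁻⁴) after three consecutive residual increases. The
convergence metric is the pre-mixing fixed-point residual
max_i max_z |ρ_trial − ρ|/ρ_ib < tolerance (default 10⁻⁸), which is
independent of α — the tests verify the fixed point is invariant under
halving α.

**Semi-implicit electrostatics.** The literal explicit update (Ψ from the
previous densities, then exponentiate) is stiff: a density perturbation of
wavenumber k feeds back through the Coulomb kernel with gain κ²/k², so
stability forces α ≲ (π/2κL)², thousands of iterations at realistic domain
sizes. Instead, each iteration freezes the short-range fields
w_i = ρ_ib exp(−[Δμ_HS + Δμ_LJ + Δμ_SC + V_ext]/k_BT) and solves the Poisson
equation with the Boltzmann closure ρ_i = w_i exp(−q_iψ) by the damped
Newton kernel (a tridiagonal solve per Newton step, warm-started from the
previous ψ). The trial densities are then w_i exp(−q_iψ_new). The fixed point
is *identical* to the explicit scheme's — at convergence ψ is the Poisson
potential of the converged densities — but the electrostatic stiffness is
gone and the iteration count is set by the packing physics (tens to a few
hundred iterations at solvent packing 0.37). `electrostatics = "explicit"`
restores the literal update for verification.

Initial guess: `pb_seed` (default) seeds ψ and Boltzmann-factor densities
from the point-ion PB solution at the same σ; `bulk` starts flat.

The grand potential per area (relative to the reservoir, with second-order
forms for the deviation-based LJ/SC terms and ½(∫ρ_eψ + σψ₀) for the
electrostatic energy) can be tracked per iteration as a diagnostic; the
convergence criterion itself is the density residual, not Ω.

## Charge regulation

The proton is an explicit +1 species at 10^(−pH) mol/L; a spectator −1
counter-species of equal concentration keeps the bulk electroneutral. The
solvent-carrier bookkeeping of the surface reactions is absorbed into the
effective K± (standard 2-pK practice). Site fractions are evaluated in
log₁₀ space so extreme pK values stay finite.

The outer loop alternates: Picard solve at the current σ (warm-started, with
an inner tolerance that tightens proportionally to the remaining σ residual),
sample the surface proton activity h_s, damped update
σ ← (1−α_σ)σ + α_σ·σ_mass-action(h_s) with α_σ = 0.5. A period-2 oscillation
in the σ updates halves α_σ, up to six times. Convergence: |Δσ|/N_s < 10⁻⁸,
followed by one final full-tolerance Picard pass.

Surface sampling modes for h_s: `window` (default; mean proton density over
[d_H/2, d_H/2 + w], with w defaulting to half the proton diameter),
`contact` (density at the contact plane), `yfunction` (cavity function
ρ·e^{V_ext/k_BT} at an effective wall position). Interpolation uses only
nodes at or beyond contact — the masked wall nodes are not data. In the
dilute point-ion limit the three modes agree within 2% (tested); with strong
packing the window mode is the robust default because the contact node
carries the largest discretization error.

The site density N_s has no principled default; example configurations use
1 site/nm², which is merely illustrative (real oxide surfaces are several
per nm²). σ scales near-linearly with N_s at fixed pH while |σ| ≪ e·N_s.

## Study conditions used by the tests and the acceptance script

* **Wetting / charge regulation (explicit solvent):** d₀ = 0.3 nm for all
  five species (solvent, cation, anion, proton, spectator); solvent reduced
  density ρ₀d₀³ = 0.7; all fluid-fluid LJ pairs at ε = 1 k_BT (reduced
  temperature 1); salt 0.01 M; pH 4; pK₊ = −2, pK₋ = 6; N_s = 1 nm⁻²;
  solvent-wall LJ 9-3 strength 0, 1 or 2 k_BT with ion-wall fixed at 1 k_BT;
  uniform ε_r = 78.5 at 298.15 K; h = d₀/50, L = 16κ⁻¹ ≈ 48 nm. The solvent
  state point (ρ₀d₀³, reduced temperature) and N_s are configuration values
  chosen as a generic dense LJ liquid; they are flagged as choices, not
  literature constants.
* **Charge inversion (primitive model):** ±0.3 nm ions with +2/−1 valences,
  1 M cation concentration, σ = −0.1 C/m², hard wall, ε_r = 78.5, SC on,
  h = d/50, L = max(10κ⁻¹, 20d) ≈ 6 nm.

At these sizes the full acceptance script (three charge-regulated solves plus
peak detection) runs in about a minute on one CPU, and the complete test
suite in a few minutes.

The layering diagnostic reports the mean spacing of successive local maxima
of ρ_e(z) within 5 d₀ of the wall (SciPy peak finding with a relative
prominence floor of 10⁻³ to exclude quadrature ripple). On a grid of d₀/50
the spacing is quantized in steps of 0.02 d₀.

## What the tests do and do not show

The oracle suite checks exact limits (scaled-particle/PY-compressibility
uniform limits to 10⁻⁶, flat-profile sum rules to machine precision,
finite-difference functional derivatives, PB against the Gouy-Chapman closed
form, manufactured-solution convergence order, contact-value and
electroneutrality sum rules) and qualitative structure (layering period,
potential monotonicity and ordering across wetting states, charge-inversion
dichotomy, titration monotonicity, PZC recovery). Passing them shows the
functional machinery and solvers are internally consistent and reproduce the
known physics of these model systems. It does not validate the models
against real electrolytes: the semi-primitive solvent has no dipoles (the
permittivity is supplied ad hoc), the SC expansion is approximate away from
bulk, ion-specific (non-size) effects are absent, and the 2-pK constants are
taken as given rather than fitted.

## Known limitations

* Restricted MSA only: unequal ion diameters cannot use the SC term.
* Rosenfeld FMT (no White Bear variant); mean-field LJ without a
  WCA-style split.
* One flat wall; no image charges, curved geometries, constant-potential
  electrodes, or liquid-vapour coexistence calculations.
* The electroosmotic velocity is a post-processing diagnostic
  (u ∝ Ψ(z) − Ψ(z_slip)); no coupled hydrodynamics.
* Fixed-point iteration without DIIS/Anderson acceleration; the interface
  leaves room to add it.
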