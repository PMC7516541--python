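# Explicit-solvent (semi-primitive) charge-regulated EDL: 0.01 M 1:1 salt in
# a neutral LJ solvent at a 2-pK amphoteric wall, solvophilic wetting.

[mixture]
temperature_K = 298.15
bulk_pH = 4.0

[species.solvent]
diameter_nm = 0.3
valence = 0
reduced_density = 0.7
wall = "lj93"
wall_epsilon_kT = 2.0
solvent = true

[species.cation]
diameter_nm = 0.3
valence = 1
concentration_M = 0.01
wall = "lj93"
wall_epsilon_kT = 1.0

[species.anion]
diameter_nm = 0.3
valence = -1
concentration_M = 0.01
wall = "lj93"
wall_epsilon_kT = 1.0

[lj]
default_kT = 1.0

[wall]
charge_regulation = true

[surface_chemistry]
site_density_per_nm2 = 1.0
pK_plus = -2.0
pK_minus = 6.0

[solver]
screening_lengths = 16.0

[output]
prefix = "wetting"
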