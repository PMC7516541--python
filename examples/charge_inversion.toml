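# Primitive-model 2:1 electrolyte at a fixed-charge hard wall (1 M).
# With sc = true the MSA screening-correlation term drives charge inversion.

[mixture]
temperature_K = 298.15

[species.cation]
diameter_nm = 0.3
valence = 2
concentration_M = 1.0

[species.anion]
diameter_nm = 0.3
valence = -1
concentration_M = 2.0

[wall]
sigma_C_per_m2 = -0.1

[dielectric]
model = "uniform"
eps_r = 78.5

[solver]
hs = true
lj = false
sc = true

[output]
prefix = "inversion"
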