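# Composite preset: neutral matrix + weak-polyacid microgel filler,
# 0.1 mol/L 1:1 salt, bath pH 7.  Calibrated so that at pH 7 the
# osmotic-modulus ratio composite/matrix at the composite equilibrium
# is 2 and the filler alone at pH 4 free-swells to hydration 11.
label: composite_ph7
matrix:
  chi: 0.45
  crosslink_density: 4.7806425434794597e-04
  phi_ref: 0.1
  solvent_molar_volume: 18.0
  label: matrix
filler:
  chi: 0.65
  crosslink_density: 6.0841403619461990e-04
  phi_ref: 0.07
  solvent_molar_volume: 18.0
  pKa: 3.5
  monomer_molar_volume: 48.0
  ionizable_fraction: 1.0
  effective_charge_fraction: 0.15577222508407867
  label: filler
filler_polymer_fraction: 0.5
bath:
  salt_concentration: 0.1
  pH: 7.0
  temperature: 298.15
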