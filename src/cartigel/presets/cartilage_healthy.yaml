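# Healthy-cartilage analog: collagen-like matrix (10% stiffer than the
# composite-gel matrix) inflated by a proteoglycan-like charged filler.
label: cartilage_healthy
matrix:
  chi: 0.45
  crosslink_density: 5.2587067978274057e-04
  phi_ref: 0.1
  solvent_molar_volume: 18.0
  label: collagen
filler:
  chi: 0.65
  crosslink_density: 6.0841403619461990e-04
  phi_ref: 0.07
  solvent_molar_volume: 18.0
  pKa: 3.5
  monomer_molar_volume: 48.0
  ionizable_fraction: 1.0
  effective_charge_fraction: 0.15577222508407867
  label: proteoglycan
filler_polymer_fraction: 0.5
bath:
  salt_concentration: 0.1
  pH: 7.0
  temperature: 298.15
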