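# Loosely cross-linked neutral matrix gel (free-swelling hydration 14).
label: pva2
matrix:
  chi: 0.45
  crosslink_density: 2.3833192953227336e-04
  phi_ref: 0.1
  solvent_molar_volume: 18.0
  label: pva2
bath:
  salt_concentration: 0.1
  pH: 7.0
  temperature: 298.15
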