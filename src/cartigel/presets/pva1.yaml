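# Densely cross-linked neutral matrix gel (free-swelling hydration 10).
label: pva1
matrix:
  chi: 0.45
  crosslink_density: 4.7806425434794597e-04
  phi_ref: 0.1
  solvent_molar_volume: 18.0
  label: pva1
bath:
  salt_concentration: 0.1
  pH: 7.0
  temperature: 298.15
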