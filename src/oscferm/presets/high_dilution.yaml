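# Higher dilution rate (0.096 1/h, feed 88 g/L): no oscillation despite
# near-complete glycerol consumption.  All channels constant.
name: high_dilution
D: 0.096
D_G: 0.5
S_f: 88.0
t_start_h: 0.0
t_end_h: 200.0
dt_h: 3.0
noise_cv: 0.02
seed: 13
channels:
  X:        {role: biomass,   unit: g/L,    kind: constant, level: 2.8}
  glycerol: {role: substrate, unit: g/L,    kind: constant, level: 1.0}
  PDO:      {role: product,   unit: g/L,    kind: constant, level: 38.0}
  butyrate: {role: product,   unit: g/L,    kind: constant, level: 9.0}
  acetate:  {role: product,   unit: g/L,    kind: constant, level: 1.8}
  lactate:  {role: product,   unit: g/L,    kind: constant, level: 2.0}
  formate:  {role: product,   unit: g/L,    kind: constant, level: 1.0}
  H2:       {role: gas,       unit: mmol/L, kind: constant, level: 1.2}
  CO2:      {role: gas,       unit: mmol/L, kind: constant, level: 12.0}
  ORP:      {role: direct,    unit: mV,     kind: constant, level: -380.0}
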