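# Stable pre-oscillation phase at the same operating point (feed 88 g/L,
# D = 0.048 1/h): near-complete glycerol consumption, 1,3-PDO 40.66 g/L,
# butyrate 10.02 g/L, minor acids low.  All channels constant.
name: steady
D: 0.048
D_G: 0.5
S_f: 88.0
t_start_h: 0.0
t_end_h: 90.0
dt_h: 3.0
noise_cv: 0.02
seed: 7
channels:
  X:        {role: biomass,   unit: g/L,    kind: constant, level: 3.0}
  glycerol: {role: substrate, unit: g/L,    kind: constant, level: 0.5}
  PDO:      {role: product,   unit: g/L,    kind: constant, level: 40.66}
  butyrate: {role: product,   unit: g/L,    kind: constant, level: 10.02}
  acetate:  {role: product,   unit: g/L,    kind: constant, level: 1.5}
  lactate:  {role: product,   unit: g/L,    kind: constant, level: 4.26}
  formate:  {role: product,   unit: g/L,    kind: constant, level: 2.60}
  H2:       {role: gas,       unit: mmol/L, kind: constant, level: 1.0}
  CO2:      {role: gas,       unit: mmol/L, kind: constant, level: 10.0}
  ORP:      {role: direct,    unit: mV,     kind: constant, level: -400.0}
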