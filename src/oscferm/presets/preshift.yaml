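# Pre-oscillation metabolic shift (119-146 h): lactate more than doubles
# (4.26 -> 9.07 g/L), formate rises 2.60 -> 3.34 g/L, while biomass,
# 1,3-PDO, butyrate and acetate decline somewhat.  Half-cosine ramps.
name: preshift
D: 0.048
D_G: 0.5
S_f: 88.0
t_start_h: 110.0
t_end_h: 150.0
dt_h: 3.0
noise_cv: 0.02
seed: 7
channels:
  X:        {role: biomass,   unit: g/L,  kind: ramp, from: 3.0,   to: 2.6,  ramp_start_h: 119.0, ramp_end_h: 146.0}
  glycerol: {role: substrate, unit: g/L,  kind: constant, level: 0.5}
  PDO:      {role: product,   unit: g/L,  kind: ramp, from: 40.66, to: 36.5, ramp_start_h: 119.0, ramp_end_h: 146.0}
  butyrate: {role: product,   unit: g/L,  kind: ramp, from: 10.02, to: 9.0,  ramp_start_h: 119.0, ramp_end_h: 146.0}
  acetate:  {role: product,   unit: g/L,  kind: ramp, from: 1.5,   to: 1.2,  ramp_start_h: 119.0, ramp_end_h: 146.0}
  lactate:  {role: product,   unit: g/L,  kind: ramp, from: 4.26,  to: 9.07, ramp_start_h: 119.0, ramp_end_h: 146.0}
  formate:  {role: product,   unit: g/L,  kind: ramp, from: 2.60,  to: 3.34, ramp_start_h: 119.0, ramp_end_h: 146.0}
  H2:       {role: gas,       unit: mmol/L, kind: constant, level: 1.0}
  CO2:      {role: gas,       unit: mmol/L, kind: constant, level: 10.0}
  ORP:      {role: direct,    unit: mV,   kind: constant, level: -400.0}
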