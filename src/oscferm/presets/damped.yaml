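# Damped regime at reduced glycerol feed (44 g/L, D = 0.048 1/h):
# oscillations start but decay and vanish.  damping_rate = ln2 / (1.5 * T):
# the amplitude halves every 1.5 cycles.
name: damped
D: 0.048
D_G: 0.5
S_f: 44.0
period_h: 53.0
damping_rate: 0.00872
t_start_h: 0.0
t_end_h: 265.0
dt_h: 3.0
noise_cv: 0.02
seed: 11
channels:
  X:        {role: biomass,   unit: g/L,    level_min: 0.9,  level_max: 2.8,  rise_h: 21.0}
  glycerol: {role: substrate, unit: g/L,    level_min: 2.0,  level_max: 26.0, rise_h: 32.0, peak_offset_h: -21.0}
  PDO:      {role: product,   unit: g/L,    level_min: 10.0, level_max: 22.0, rise_h: 21.0, peak_offset_h: 0.0}
  butyrate: {role: product,   unit: g/L,    level_min: 2.5,  level_max: 6.0,  rise_h: 21.0, peak_offset_h: 0.0}
  acetate:  {role: product,   unit: g/L,    level_min: 0.6,  level_max: 1.6,  rise_h: 21.0, peak_offset_h: 0.0}
  lactate:  {role: product,   unit: g/L,    level_min: 0.8,  level_max: 3.5,  rise_h: 29.0, peak_offset_h: 16.0}
  formate:  {role: product,   unit: g/L,    level_min: 0.5,  level_max: 2.0,  rise_h: 29.0, peak_offset_h: 16.0}
  H2:       {role: gas,       unit: mmol/L, level_min: 0.05, level_max: 1.4,  rise_h: 26.5, peak_offset_h: 16.0}
  CO2:      {role: gas,       unit: mmol/L, level_min: 1.5,  level_max: 12.0, rise_h: 10.5, peak_offset_h: -10.5}
  ORP:      {role: direct,    unit: mV,     level_min: -540.0, level_max: -300.0, rise_h: 39.5, peak_offset_h: -10.5}
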