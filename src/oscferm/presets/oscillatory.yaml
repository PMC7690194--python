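# Sustained limit-cycle operating point: glycerol feed 88 g/L, D = 0.048 1/h.
# Cycle geometry: 53.4-h period, 21-h rising stage (stage I), 32.4-h
# falling stage (stage II); t = 0 is a biomass trough.  Channel extrema
# and peak offsets (hours relative to the biomass peak) encode the
# observed oscillation geometry: lactate/formate/H2 peak mid stage II
# (+16.2 h), CO2 and ORP peak mid stage I (-10.5 h), gases span
# 0.07-2.47 (H2) and 2.0-21.98 (CO2) mmol/L, ORP swings between -568
# and -271 mV.
# D_G (gas-phase dilution rate) is an assumption; see docs/methods.md.
name: oscillatory
D: 0.048
D_G: 0.5
S_f: 88.0
period_h: 53.4
t_start_h: 0.0
t_end_h: 246.0
dt_h: 3.0
noise_cv: 0.02
seed: 42
channels:
  X:        {role: biomass,   unit: g/L,    level_min: 1.0,  level_max: 4.2,   rise_h: 21.0}
  glycerol: {role: substrate, unit: g/L,    level_min: 3.0,  level_max: 55.0,  rise_h: 32.4, peak_offset_h: -21.0}
  PDO:      {role: product,   unit: g/L,    level_min: 20.0, level_max: 44.0,  rise_h: 21.0, peak_offset_h: 0.0}
  butyrate: {role: product,   unit: g/L,    level_min: 5.0,  level_max: 12.0,  rise_h: 21.0, peak_offset_h: 0.0}
  acetate:  {role: product,   unit: g/L,    level_min: 1.0,  level_max: 3.0,   rise_h: 21.0, peak_offset_h: 0.0}
  lactate:  {role: product,   unit: g/L,    level_min: 1.0,  level_max: 6.0,   rise_h: 29.2, peak_offset_h: 16.2}
  formate:  {role: product,   unit: g/L,    level_min: 0.8,  level_max: 3.4,   rise_h: 29.2, peak_offset_h: 16.2}
  H2:       {role: gas,       unit: mmol/L, level_min: 0.07, level_max: 2.47,  rise_h: 26.7, peak_offset_h: 16.2}
  CO2:      {role: gas,       unit: mmol/L, level_min: 2.0,  level_max: 21.98, rise_h: 10.5, peak_offset_h: -10.5}
  ORP:      {role: direct,    unit: mV,     level_min: -568.0, level_max: -271.0, rise_h: 39.9, peak_offset_h: -10.5}
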