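# oscferm

Analysis toolkit for spontaneous metabolic oscillations in long-term
continuous (chemostat) fermentation of glycerol to 1,3-propanediol
(1,3-PDO) by *Clostridium butyricum*.  It is written for fermentation
scientists who need to turn bioreactor concentration time series into
quantitative statements about the oscillation: specific rates from the
chemostat mass balances, cycle geometry (period, rising/falling stages,
per-cycle extrema, phase lags), oscillation-regime classification,
redox-assay quantification, oscillation-phase gene-expression patterns,
and genome-assembly summary statistics.

Because the underlying bioreactor campaign data are not public, the
package ships a first-class synthetic-data generator whose presets
encode the reported oscillation geometry; every analysis is validated by
recovering those encoded quantities from noisy simulated observations.

## The model

A chemostat with dilution rate `D` (h⁻¹), glycerol feed `S_f` (g/L) and
gas-phase dilution rate `D_G` (h⁻¹) obeys, per channel,

```
mu     = (1/X) dX/dt + D                       # specific growth rate, 1/h
q_s    = (1/X) (D·S_f − D·C_S − dC_S/dt)       # glycerol uptake, g/(g·h)
q_P    = (1/X) (dC_P/dt + D·C_P)               # liquid product, g/(g·h)
q_gas  = (1/X) (dC_gas/dt + D_G·C_gas)         # H2 / CO2, mmol/(g·h)
```

with `X` biomass (g/L), `C_S` residual glycerol, `C_P` a product (g/L)
and `C_gas` a dissolved gas (mmol/L).  Derivatives are estimated by
local quadratic smoothing, so the rates are usable on noisy 3-h-sampled
data.  One oscillation cycle is segmented on the biomass channel into
the growth rising stage (stage I, trough→peak) and the falling stage
(stage II, peak→trough); all other channels are read out per cycle
(extremum values, phase positions, lags).  Regimes are classified as
`sustained`, `damped` (amplitude half-life ≤ 3 periods) or `none`.

## Worked example

Simulate the sustained-oscillation operating point (feed 88 g/L,
D = 0.048 h⁻¹) and read the cycle geometry back from the noisy data:

```python
import numpy as np
from oscferm import synthgen, oscillation

t, ch, ds = synthgen.oscillation_recovery_run(n_cycles=3, seed=42,
                                              noise_cv=0.02)
est = oscillation.detect_period(ch["X"], t)
cycles = oscillation.segment_cycles(ch["X"], t)
_, h2 = oscillation.cycle_statistics(ch["H2"], t, cycles, "H2")
print(f"period {est.mean_period:.1f} h over {len(cycles)} cycles")
print(f"stage I {np.mean([c.stage1_duration for c in cycles]):.1f} h, "
      f"stage II {np.mean([c.stage2_duration for c in cycles]):.1f} h")
print(f"H2 per-cycle max {h2['max_mean']:.2f} mmol/L "
      f"(phase {h2['max_phase_mean']:.2f}), min {h2['min_mean']:.2f} mmol/L")
```

prints

```
period 53.3 h over 3 cycles
stage I 20.3 h, stage II 32.8 h
H2 per-cycle max 2.47 mmol/L (phase 0.68), min 0.07 mmol/L
```

i.e. the growth rising stage is markedly shorter than the falling
stage, and dissolved H₂ cycles between 0.07 and ~2.5 mmol/L with its
maximum in mid stage II (phase 0.68, past the stage boundary at ~0.39)
— H₂ production lags growth.

The numbered drivers under `analysis/` run the full campaign: simulate
all presets (`01`), compute rates (`02`; the specific growth rate dips
below zero at the stage-II trough), characterize the oscillation and
classify regimes (`03`), summarize redox (`04`), call expression
patterns (`05`), and compute assembly statistics (`06`).  Tables land in
`results/`.

A CLI mirrors the library: `oscferm simulate|rates|oscillate|redox|expr|genomestats|report`.

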