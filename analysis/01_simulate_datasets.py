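#!/usr/bin/env python
"""Simulate the five bioreactor operating conditions and write them out.

Produces, under results/datasets/: one noisy observed time series per
preset (delimited text) plus the exact specific-rate truth used by the
generator.  These files feed the downstream analysis scripts.
"""

import sys
from pathlib import Path

import pandas as pd

from oscferm import synthgen
from oscferm.kinetics import GAS_CHANNELS
from oscferm.timeseries import write_timeseries

OUT = Path(__file__).resolve().parents[1] / "results" / "datasets"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for name in synthgen.PRESET_NAMES:
        ds = synthgen.simulate_preset(name)
        write_timeseries(ds.observed, OUT / f"{name}.csv")
        truth = ds.truth_rates
        df = pd.DataFrame({"time_h": truth.t, "mu:1/h": truth.mu})
        for ch, q in truth.q.items():
            unit = "mmol/(g.h)" if ch in GAS_CHANNELS else "g/(g.h)"
            df[f"q_{ch}:{unit}"] = q
        df.to_csv(OUT / f"{name}.truth_rates.csv", index=False)
        print(
            f"{name}: {ds.observed.t.size} samples, "
            f"{len(ds.observed.channel_names)} channels, "
            f"noise_cv={ds.config.noise_cv}, seed={ds.config.seed}"
        )
    print(f"wrote datasets to {OUT}")


if __name__ == "__main__":
    sys.exit(main())
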