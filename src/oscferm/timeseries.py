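"""Time-series container and delimited-text I/O.

The common currency of the kinetic and oscillation analyses: a strictly
increasing time grid (hours) plus named concentration channels, each tagged
with a unit, and the chemostat operating parameters (dilution rate D, gas
dilution rate D_G, glycerol feed concentration S_f).

On disk a dataset is a plain CSV with a ``time_h`` column followed by one
``channel:unit`` column per channel, e.g. ``PDO:g/L`` or ``ORP:mV``; the
operating parameters travel in ``# key = value`` comment lines at the top.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: channels allowed to go negative (electrode potentials, not concentrations)
SIGNED_CHANNELS = frozenset({"ORP"})


@dataclass
class TimeSeriesSet:
    """Aligned time grid with named, unit-tagged channels.

    Parameters
    ----------
    t : ndarray
        Sampling times in hours, strictly increasing.
    channels : dict of str -> ndarray
        One value series per channel, same length as ``t``.
    units : dict of str -> str
        Unit string per channel (``g/L``, ``mmol/L``, ``mV`` ...).
    meta : dict
        Operating parameters; keys ``D`` (h^-1), ``D_G`` (h^-1),
        ``S_f`` (g/L) where known.
    """

    t: np.ndarray
    channels: dict[str, np.ndarray]
    units: dict[str, str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if self.t.ndim != 1 or self.t.size < 1:
            raise ValueError("time grid must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.t)):
            raise ValueError("time grid contains non-finite values")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        for name, vals in self.channels.items():
            vals = np.asarray(vals, dtype=float)
            self.channels[name] = vals
            if vals.shape != self.t.shape:
                raise ValueError(
                    f"channel {name!r} has length {vals.size}, expected {self.t.size}"
                )
            if name not in self.units:
                raise ValueError(f"channel {name!r} has no unit tag")
            if name not in SIGNED_CHANNELS and np.nanmin(vals) < 0:
                raise ValueError(f"channel {name!r} has negative concentrations")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    def __contains__(self, name: str) -> bool:
        return name in self.channels

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def copy(self) -> "TimeSeriesSet":
        return TimeSeriesSet(
            t=self.t.copy(),
            channels={k: v.copy() for k, v in self.channels.items()},
            units=dict(self.units),
            meta=dict(self.meta),
        )

    def to_frame(self) -> pd.DataFrame:
        data = {"time_h": self.t}
        for name, vals in self.channels.items():
            data[f"{name}:{self.units[name]}"] = vals
        return pd.DataFrame(data)


def write_timeseries(ts: TimeSeriesSet, path: str | Path) -> None:
    """Write a :class:`TimeSeriesSet` as delimited text (CSV + metadata header)."""
    path = Path(path)
    with path.open("w") as fh:
        for key, val in sorted(ts.meta.items()):
            fh.write(f"# {key} = {val}\n")
        ts.to_frame().to_csv(fh, index=False)


def read_timeseries(path: str | Path) -> TimeSeriesSet:
    """Read a dataset written by :func:`write_timeseries`.

    Raises
    ------
    ValueError
        On non-monotonic time, missing ``time_h`` column, or a channel
        column without a ``name:unit`` header.
    """
    path = Path(path)
    meta: dict = {}
    with path.open() as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            body_start = i + 1
            key, _, val = line.lstrip("#").partition("=")
            key = key.strip()
            val = val.strip()
            if key:
                try:
                    meta[key] = float(val)
                except ValueError:
                    meta[key] = val
        else:
            break
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])))
    if "time_h" not in df.columns:
        raise ValueError(f"{path}: missing 'time_h' column")
    t = df["time_h"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        bad = int(np.argmax(np.diff(t) <= 0)) + 1
        raise ValueError(f"{path}: time not strictly increasing at row {bad}")
    channels: dict[str, np.ndarray] = {}
    units: dict[str, str] = {}
    for col in df.columns:
        if col == "time_h":
            continue
        if ":" not in col:
            raise ValueError(f"{path}: column {col!r} lacks a ':unit' suffix")
        name, _, unit = col.partition(":")
        channels[name] = df[col].to_numpy(dtype=float)
        units[name] = unit
    return TimeSeriesSet(t=t, channels=channels, units=units, meta=meta)
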