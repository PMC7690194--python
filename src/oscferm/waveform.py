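"""Piecewise raised-cosine waveforms and analytic channel specifications.

The waveform family used throughout the synthetic generator is a
piecewise raised cosine: within one period ``T`` the value rises from
``level_min`` to ``level_max`` as a cosine half-wave over ``rise_fraction*T``
hours and falls back over the remainder.  It is periodic, C1-smooth, and
analytically differentiable, which lets the generator derive exact rate
waveforms from the chemostat balances.

An exponential envelope ``exp(-damping_rate * t)`` applied to the
oscillatory component (the deviation from the mid-level) models damped
oscillations; ``damping_rate = 0`` gives a sustained limit cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["WaveformParams", "make_rate_waveform", "ChannelSpec"]


@dataclass(frozen=True)
class WaveformParams:
    """Shape parameters of one raised-cosine waveform.

    ``phase_offset_h`` places this channel's peak relative to the biomass
    peak (positive = later).  ``level_min``/``level_max`` are in the
    channel's own units (rate units for rate waveforms, concentration or
    mV for channel waveforms).
    """

    period_h: float
    rise_fraction: float
    phase_offset_h: float
    level_min: float
    level_max: float

    def __post_init__(self) -> None:
        if not (self.period_h > 0):
            raise ValueError("period_h must be > 0")
        if not (0.0 < self.rise_fraction < 1.0):
            raise ValueError("rise_fraction must lie in (0, 1)")
        if self.level_max < self.level_min:
            raise ValueError("level_max must be >= level_min")


def _shape(s: np.ndarray, r: float) -> np.ndarray:
    """Unit raised cosine on cycle phase s in [0,1): 0 at trough, 1 at peak."""
    s = np.mod(s, 1.0)
    rising = s < r
    out = np.empty_like(s)
    out[rising] = 0.5 * (1.0 - np.cos(np.pi * s[rising] / r))
    out[~rising] = 0.5 * (1.0 + np.cos(np.pi * (s[~rising] - r) / (1.0 - r)))
    return out


def _shape_deriv(s: np.ndarray, r: float) -> np.ndarray:
    """d(shape)/ds on cycle phase s."""
    s = np.mod(s, 1.0)
    rising = s < r
    out = np.empty_like(s)
    out[rising] = 0.5 * (np.pi / r) * np.sin(np.pi * s[rising] / r)
    out[~rising] = -0.5 * (np.pi / (1.0 - r)) * np.sin(
        np.pi * (s[~rising] - r) / (1.0 - r)
    )
    return out


def make_rate_waveform(
    params: WaveformParams, damping_rate: float, t: np.ndarray | float
) -> np.ndarray:
    """Evaluate the raised-cosine waveform at times ``t`` (hours).

    The peak of the undamped waveform occurs at
    ``t = phase_offset_h (mod period_h)``.  The oscillatory component
    (deviation from the mid-level) is multiplied by
    ``exp(-damping_rate * t)``.
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("t contains non-finite values")
    T = params.period_h
    r = params.rise_fraction
    trough_t = params.phase_offset_h - r * T
    s = (t - trough_t) / T
    center = 0.5 * (params.level_min + params.level_max)
    half_amp = 0.5 * (params.level_max - params.level_min)
    osc = 2.0 * _shape(s, r) - 1.0  # in [-1, 1]
    env = np.exp(-damping_rate * t) if damping_rate else 1.0
    return center + half_amp * osc * env


class ChannelSpec:
    """Analytic specification of one simulated channel.

    A channel is either ``periodic`` (raised cosine), a ``ramp``
    (half-cosine transition from ``ramp_from`` to ``ramp_to`` over
    ``[ramp_start_h, ramp_end_h]``) or ``constant``.  ``role`` determines
    which chemostat balance derives the channel's specific rate:

    ===========  =====================================================
    role         balance
    ===========  =====================================================
    biomass      dX/dt = (mu - D) X       (waveform applies to ln X)
    substrate    dC/dt = D (S_f - C) - q_s X
    product      dC/dt = q_P X - D C
    gas          dC/dt = q_gas X - D_G C
    direct       no balance (e.g. ORP electrode signal)
    ===========  =====================================================
    """

    def __init__(
        self,
        name: str,
        unit: str,
        role: str,
        kind: str = "periodic",
        params: WaveformParams | None = None,
        level: float | None = None,
        ramp_from: float | None = None,
        ramp_to: float | None = None,
        ramp_start_h: float = 0.0,
        ramp_end_h: float = 1.0,
        damping_rate: float = 0.0,
        space: str = "conc",
        init: float | None = None,
    ) -> None:
        if role not in ("biomass", "substrate", "product", "gas", "direct"):
            raise ValueError(f"unknown channel role {role!r}")
        if kind not in ("periodic", "ramp", "constant"):
            raise ValueError(f"unknown waveform kind {kind!r}")
        if space not in ("conc", "rate"):
            raise ValueError(f"unknown waveform space {space!r}")
        if kind == "periodic" and params is None:
            raise ValueError("periodic channel needs WaveformParams")
        if kind == "constant" and level is None:
            raise ValueError("constant channel needs a level")
        if kind == "ramp" and (
            ramp_from is None or ramp_to is None or ramp_end_h <= ramp_start_h
        ):
            raise ValueError(
                "ramp channel needs ramp_from, ramp_to and ramp_end_h > ramp_start_h"
            )
        if damping_rate < 0:
            raise ValueError("damping_rate must be >= 0")
        if space == "rate" and role != "direct" and init is None:
            raise ValueError("rate-space channel needs an initial concentration")
        self.name = name
        self.unit = unit
        self.role = role
        self.kind = kind
        self.params = params
        self.level = level
        self.ramp_from = ramp_from
        self.ramp_to = ramp_to
        self.ramp_start_h = ramp_start_h
        self.ramp_end_h = ramp_end_h
        self.damping_rate = damping_rate
        self.space = space
        self.init = init

    # -- analytic value and time derivative (of the waveform variable; for
    #    biomass the variable is ln X) ---------------------------------

    def _wave(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.kind == "constant":
            return np.full_like(t, float(self.level))
        if self.kind == "ramp":
            u = np.clip(
                (t - self.ramp_start_h) / (self.ramp_end_h - self.ramp_start_h), 0, 1
            )
            frac = 0.5 * (1.0 - np.cos(np.pi * u))
            return self.ramp_from + (self.ramp_to - self.ramp_from) * frac
        return make_rate_waveform(self.params, self.damping_rate, t)

    def _wave_deriv(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.kind == "constant":
            return np.zeros_like(t)
        if self.kind == "ramp":
            span = self.ramp_end_h - self.ramp_start_h
            u = (t - self.ramp_start_h) / span
            inside = (u > 0) & (u < 1)
            out = np.zeros_like(t)
            out[inside] = (
                (self.ramp_to - self.ramp_from)
                * 0.5
                * np.pi
                / span
                * np.sin(np.pi * u[inside])
            )
            return out
        p = self.params
        T, r = p.period_h, p.rise_fraction
        trough_t = p.phase_offset_h - r * T
        s = (t - trough_t) / T
        half_amp = 0.5 * (p.level_max - p.level_min)
        osc = 2.0 * _shape(s, r) - 1.0
        dosc = 2.0 * _shape_deriv(s, r) / T
        lam = self.damping_rate
        env = np.exp(-lam * t) if lam else 1.0
        return half_amp * env * (dosc - lam * osc)

    def value(self, t: np.ndarray) -> np.ndarray:
        """Channel value at times ``t`` (concentration / mV; X in g/L).

        Only available for concentration-space channels; a rate-space
        channel's concentration exists only as the ODE solution.
        """
        if self.space == "rate":
            raise ValueError(
                f"channel {self.name!r} is rate-space; its concentration "
                "is defined by the ODE solution, not analytically"
            )
        if self.role == "biomass":
            return np.exp(self._wave(t))
        return self._wave(t)

    def deriv(self, t: np.ndarray) -> np.ndarray:
        """Time derivative of the channel value (concentration space only)."""
        if self.space == "rate":
            raise ValueError(f"channel {self.name!r} is rate-space")
        if self.role == "biomass":
            return np.exp(self._wave(t)) * self._wave_deriv(t)
        return self._wave_deriv(t)

    # -- exact specific rate implied by the chemostat balance -----------

    def rate(self, t: np.ndarray, X: np.ndarray, D: float, D_G: float, S_f: float):
        """Specific rate waveform of this channel.

        For concentration-space channels the rate is derived exactly from
        the channel's chemostat balance, with ``X`` the biomass
        concentration at ``t``; for rate-space channels the waveform *is*
        the rate.  Returns ``None`` for ``direct`` channels (no balance).
        """
        t = np.asarray(t, dtype=float)
        if self.role == "direct":
            return None
        if self.space == "rate":
            return self._wave(t)
        if self.role == "biomass":
            # mu = dlnX/dt + D
            return self._wave_deriv(t) + D
        C = self._wave(t)
        dC = self._wave_deriv(t)
        if self.role == "substrate":
            return (D * (S_f - C) - dC) / X
        if self.role == "product":
            return (dC + D * C) / X
        # gas
        return (dC + D_G * C) / X
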