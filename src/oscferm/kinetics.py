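"""Specific-rate kinetics from chemostat mass balances.

A chemostat fed at dilution rate ``D`` (h^-1) with glycerol feed ``S_f``
(g/L) obeys, per channel,

.. math::

    \\mu   = \\frac{1}{X}\\frac{dX}{dt} + D

    q_s   = \\frac{1}{X}\\Bigl(D S_f - D C_S - \\frac{dC_S}{dt}\\Bigr)

    q_P   = \\frac{1}{X}\\Bigl(\\frac{dC_P}{dt} + D C_P\\Bigr)

    q_{gas} = \\frac{1}{X}\\Bigl(\\frac{dC_{gas}}{dt} + D_G C_{gas}\\Bigr)

with ``X`` the biomass (g/L), ``C_S`` the residual substrate, ``C_P`` a
liquid product (both g/L), ``C_gas`` a dissolved gas (mmol/L) washed out
at the gas-phase dilution rate ``D_G``.  The substrate equation is the
standard mass balance written with the dilution term ``D*C_S``; variant
forms circulating in the literature that multiply ``C_S`` by ``dX/dt``
are dimensionally inconsistent and are not used here.

Derivatives are estimated by local polynomial smoothing (degree 2) so the
rates stay usable on noisy, possibly irregular sampling grids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .timeseries import TimeSeriesSet

#: biomass below this (g/L) makes 1/X division meaningless -> masked
X_MIN_DEFAULT = 1e-3

GAS_CHANNELS = ("H2", "CO2")
SUBSTRATE_CHANNEL = "glycerol"
BIOMASS_CHANNEL = "X"
NON_RATE_CHANNELS = ("ORP",)


@dataclass
class RateProfile:
    """Per-channel specific rates on a common time grid.

    ``mu`` is in h^-1; entries of ``q`` are g/(g*h) for the substrate and
    liquid products and mmol/(g*h) for gases.  Masked (unreliable) points
    are NaN.
    """

    t: np.ndarray
    mu: np.ndarray
    q: dict[str, np.ndarray] = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.q[name]


def estimate_derivative(
    values: np.ndarray,
    t_grid: np.ndarray,
    method: str = "local_poly",
    window: int = 5,
) -> np.ndarray:
    """Estimate d(values)/dt on ``t_grid`` (hours).

    Default is a degree-2 local polynomial fit over ``window`` samples,
    centred where possible and one-sided at the ends; at ``window=3`` on a
    uniform grid this reduces to central differences.  Fits are done in
    time, not index, so irregular grids are handled correctly.
    """
    values = np.asarray(values, dtype=float)
    t = np.asarray(t_grid, dtype=float)
    n = t.size
    if n < 3:
        raise ValueError("need at least 3 points to estimate a derivative")
    if values.shape != t.shape:
        raise ValueError("values and t_grid must have the same length")
    if method != "local_poly":
        raise ValueError(f"unknown method {method!r}")
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    window = min(window, n if n % 2 == 1 else n - 1)
    half = window // 2
    deriv = np.empty(n)
    for i in range(n):
        lo = max(0, min(i - half, n - window))
        sl = slice(lo, lo + window)
        ti = t[sl] - t[i]
        # quadratic least squares; derivative at t[i] is the linear coef
        coeffs = np.polynomial.polynomial.polyfit(ti, values[sl], deg=2)
        deriv[i] = coeffs[1]
    return deriv


def _masked_inverse_biomass(X: np.ndarray, x_min: float) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    bad = ~(X > x_min)
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} points with biomass <= {x_min} g/L masked",
            stacklevel=3,
        )
    inv = np.where(bad, np.nan, 1.0 / np.where(bad, 1.0, X))
    return inv


def specific_growth_rate(
    X: np.ndarray,
    t_grid: np.ndarray,
    D: float,
    x_min: float = X_MIN_DEFAULT,
    window: int = 5,
) -> np.ndarray:
    """mu = (1/X) dX/dt + D, in h^-1."""
    dX = estimate_derivative(X, t_grid, window=window)
    return _masked_inverse_biomass(X, x_min) * dX + D


def specific_substrate_uptake(
    C_S: np.ndarray,
    X: np.ndarray,
    t_grid: np.ndarray,
    D: float,
    S_f: float,
    x_min: float = X_MIN_DEFAULT,
    window: int = 5,
) -> np.ndarray:
    """q_s = (1/X)(D*S_f - D*C_S - dC_S/dt), in g/(g*h)."""
    dC = estimate_derivative(C_S, t_grid, window=window)
    return _masked_inverse_biomass(X, x_min) * (D * S_f - D * np.asarray(C_S) - dC)


def specific_product_rate(
    C_P: np.ndarray,
    X: np.ndarray,
    t_grid: np.ndarray,
    D: float,
    x_min: float = X_MIN_DEFAULT,
    window: int = 5,
) -> np.ndarray:
    """q_P = (1/X)(dC_P/dt + D*C_P), in g/(g*h)."""
    dC = estimate_derivative(C_P, t_grid, window=window)
    return _masked_inverse_biomass(X, x_min) * (dC + D * np.asarray(C_P))


def specific_gas_rate(
    C_gas: np.ndarray,
    X: np.ndarray,
    t_grid: np.ndarray,
    D_G: float,
    x_min: float = X_MIN_DEFAULT,
    window: int = 5,
) -> np.ndarray:
    """q_gas = (1/X)(dC_gas/dt + D_G*C_gas), in mmol/(g*h)."""
    dC = estimate_derivative(C_gas, t_grid, window=window)
    return _masked_inverse_biomass(X, x_min) * (dC + D_G * np.asarray(C_gas))


def rate_profile(
    ts: TimeSeriesSet,
    D: float | None = None,
    D_G: float | None = None,
    S_f: float | None = None,
    x_min: float = X_MIN_DEFAULT,
    window: int = 5,
) -> RateProfile:
    """Compute mu and every channel's specific rate from a dataset.

    Operating parameters default to the dataset's metadata; ``D_G`` has no
    universal default and must be available whenever a gas channel is
    present.
    """
    D = float(ts.meta["D"]) if D is None else D
    S_f = float(ts.meta["S_f"]) if S_f is None else S_f
    if D_G is None:
        D_G = ts.meta.get("D_G")
    X = ts[BIOMASS_CHANNEL]
    mu = specific_growth_rate(X, ts.t, D, x_min=x_min, window=window)
    q: dict[str, np.ndarray] = {}
    for name in ts.channel_names:
        if name == BIOMASS_CHANNEL or name in NON_RATE_CHANNELS:
            continue
        if name == SUBSTRATE_CHANNEL:
            q[name] = specific_substrate_uptake(
                ts[name], X, ts.t, D, S_f, x_min=x_min, window=window
            )
        elif name in GAS_CHANNELS:
            if D_G is None:
                raise ValueError(
                    "gas channels present but D_G not given (it is never "
                    "derivable from the liquid-phase parameters)"
                )
            q[name] = specific_gas_rate(
                ts[name], X, ts.t, float(D_G), x_min=x_min, window=window
            )
        else:
            q[name] = specific_product_rate(
                ts[name], X, ts.t, D, x_min=x_min, window=window
            )
    return RateProfile(t=ts.t.copy(), mu=mu, q=q)


def balance_residual(
    ts: TimeSeriesSet, rates: RateProfile, window: int = 5
) -> dict[str, np.ndarray]:
    """Re-insert rates into the balances and return per-channel residuals.

    For self-consistent data every residual series is ~0 (up to the
    finite-difference error of the derivative estimate).  Units follow the
    channel (g/(L*h) or mmol/(L*h)).
    """
    if rates.t.shape != ts.t.shape or np.any(rates.t != ts.t):
        raise ValueError("time grids of dataset and rates do not match")
    D = float(ts.meta["D"])
    S_f = float(ts.meta.get("S_f", np.nan))
    D_G = ts.meta.get("D_G")
    X = ts[BIOMASS_CHANNEL]
    res: dict[str, np.ndarray] = {}
    dX = estimate_derivative(X, ts.t, window=window)
    res[BIOMASS_CHANNEL] = dX - (rates.mu - D) * X
    for name, qv in rates.q.items():
        C = ts[name]
        dC = estimate_derivative(C, ts.t, window=window)
        if name == SUBSTRATE_CHANNEL:
            res[name] = dC - (D * (S_f - C) - qv * X)
        elif name in GAS_CHANNELS:
            res[name] = dC - (qv * X - float(D_G) * C)
        else:
            res[name] = dC - (qv * X - D * C)
    return res
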