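"""Oscillation detection, cycle segmentation and phase analysis.

One oscillation cycle is defined on the biomass channel: stage I is the
growth rising stage (trough to peak) and stage II the falling stage (peak
back to trough).  All other channels are then read out per biomass cycle:
extremum values, phase positions within the cycle (0 at the stage-I
trough, the stage boundary at ``stage1_duration/period``), inter-channel
phase lags, and the number of prominent peaks per cycle (to detect
bimodal "M-shaped" rate patterns).

Regimes: ``sustained`` (stable limit cycle), ``damped`` (amplitude decays
with a half-life of at most three periods) and ``none``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, savgol_filter

__all__ = [
    "CycleSegment",
    "ExtremumRecord",
    "PeriodEstimate",
    "OscillationSummary",
    "detect_extrema",
    "detect_period",
    "segment_cycles",
    "cycle_statistics",
    "phase_lag",
    "peaks_per_cycle",
    "classify_regime",
    "summarize",
]

PROMINENCE_FRAC_DEFAULT = 0.2
#: per-cycle periods deviating more than this from the running median are
#: flagged irregular and excluded from the mean
IRREGULAR_PERIOD_FRAC = 0.3
#: amplitude half-life threshold (in periods) separating damped from
#: sustained oscillation
DAMPED_HALFLIFE_PERIODS = 3.0
#: oscillation amplitude must exceed this multiple of the estimated noise
#: level to count as oscillatory at all
MIN_SNR = 4.0


@dataclass(frozen=True)
class CycleSegment:
    """One trough-peak-trough biomass cycle."""

    trough_start_t: float
    peak_t: float
    trough_end_t: float
    cycle_index: int

    def __post_init__(self) -> None:
        if not (self.trough_start_t < self.peak_t < self.trough_end_t):
            raise ValueError("cycle must satisfy trough < peak < trough")

    @property
    def period(self) -> float:
        return self.trough_end_t - self.trough_start_t

    @property
    def stage1_duration(self) -> float:
        """Rising stage (stage I), hours."""
        return self.peak_t - self.trough_start_t

    @property
    def stage2_duration(self) -> float:
        """Falling stage (stage II), hours."""
        return self.trough_end_t - self.peak_t

    def phase_of(self, t: float) -> float:
        """Phase position of time ``t`` within this cycle, in [0, 1)."""
        return ((t - self.trough_start_t) / self.period) % 1.0

    @property
    def stage_boundary_phase(self) -> float:
        return self.stage1_duration / self.period


@dataclass(frozen=True)
class ExtremumRecord:
    """A per-cycle channel extremum with its phase position."""

    channel: str
    cycle_index: int
    kind: str  # "max" | "min"
    value: float
    t: float
    phase_position: float
    stage: str  # "I" | "II"


@dataclass
class PeriodEstimate:
    """Mean and per-cycle peak-to-peak periods of one channel."""

    mean_period: float | None
    periods: np.ndarray
    all_periods: np.ndarray
    peak_times: np.ndarray
    autocorr_period: float | None = None
    irregular: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))


@dataclass
class OscillationSummary:
    reference_channel: str
    regime: str
    mean_period: float | None
    periods: np.ndarray
    cycles: list[CycleSegment]
    extrema: dict[str, list[ExtremumRecord]]
    peaks_per_cycle: dict[str, list[int]]


def _smooth(series: np.ndarray, window: int = 5) -> np.ndarray:
    """Mild quadratic smoothing for extremum localization on noisy data."""
    n = series.size
    if n < window:
        return np.asarray(series, dtype=float)
    return savgol_filter(np.asarray(series, dtype=float), window, polyorder=2)


def _refine(t: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-grid extremum location by a parabola through three samples."""
    if i == 0 or i == t.size - 1:
        return float(t[i]), float(y[i])
    ts = t[i - 1 : i + 2] - t[i]
    ys = y[i - 1 : i + 2]
    c = np.polynomial.polynomial.polyfit(ts, ys, deg=2)
    if c[2] == 0:
        return float(t[i]), float(y[i])
    dt = -c[1] / (2.0 * c[2])
    dt = float(np.clip(dt, ts[0], ts[2]))
    val = c[0] + c[1] * dt + c[2] * dt * dt
    return float(t[i] + dt), float(val)


def _refine_breakpoint(
    t: np.ndarray, y: np.ndarray, i: int, half: int = 5, n_grid: int = 121
) -> float:
    """Extremum time by a two-sided polynomial fit with a free breakpoint.

    An asymmetric cycle has different curvature on its rising and falling
    flanks, so the waveform has a curvature break at each extremum and a
    symmetric parabola fit locates it with a systematic shift.  Fitting
    a separate quadratic+cubic on each side of a breakpoint ``tau``
    (``v + a_l d^2 + b_l d^3`` for d < 0, ``v + a_r d^2 + b_r d^3`` for
    d > 0, continuous and flat at ``tau``) over ``2*half+1`` samples
    removes that bias; ``tau`` is grid-searched, the rest is linear least
    squares.  For symmetric extrema this reduces to the parabola answer.
    """
    n = t.size
    lo = max(0, i - half)
    hi = min(n, i + half + 1)
    ts, ys = t[lo:hi], y[lo:hi]
    if ts.size < 6:
        return _refine(t, y, i)[0]
    left = t[i] - ts[0] if i > lo else 0.5 * (t[min(i + 1, n - 1)] - t[i])
    right = ts[-1] - t[i] if hi - 1 > i else 0.5 * (t[i] - t[max(i - 1, 0)])
    best_tau, best_rss = float(t[i]), np.inf
    for tau in np.linspace(t[i] - 0.999 * left, t[i] + 0.999 * right, n_grid):
        d = ts - tau
        dn, dp = np.minimum(d, 0.0), np.maximum(d, 0.0)
        design = np.column_stack(
            [np.ones_like(d), dn**2, dn**3, dp**2, dp**3]
        )
        coef, *_ = np.linalg.lstsq(design, ys, rcond=None)
        rss = float(np.sum((design @ coef - ys) ** 2))
        if rss < best_rss:
            best_rss, best_tau = rss, float(tau)
    return best_tau


def detect_extrema(
    series: np.ndarray,
    t_grid: np.ndarray,
    prominence_frac: float = PROMINENCE_FRAC_DEFAULT,
    refine: bool = True,
):
    """Find alternating peaks and troughs with relative prominence.

    Prominence threshold is ``prominence_frac`` times the channel range;
    peaks and troughs are forced to interleave (between two peaks only the
    deepest trough survives, and vice versa).  Returns a dict with arrays
    ``peak_t``, ``peak_value``, ``trough_t``, ``trough_value`` and the raw
    indices ``peak_idx``, ``trough_idx``.
    """
    y = np.asarray(series, dtype=float)
    t = np.asarray(t_grid, dtype=float)
    if y.size == 0:
        raise ValueError("empty series")
    rng = float(np.nanmax(y) - np.nanmin(y))
    if rng <= 1e-12 * max(1.0, float(np.nanmax(np.abs(y)))):
        empty = np.array([])
        return {
            "peak_t": empty, "peak_value": empty, "peak_idx": empty.astype(int),
            "trough_t": empty, "trough_value": empty, "trough_idx": empty.astype(int),
        }
    prom = prominence_frac * rng
    pk, _ = find_peaks(y, prominence=prom)
    tr, _ = find_peaks(-y, prominence=prom)

    events = sorted(
        [(i, "peak") for i in pk] + [(i, "trough") for i in tr]
    )
    kept: list[tuple[int, str]] = []
    for idx, kind in events:
        if kept and kept[-1][1] == kind:
            prev_idx, _ = kept[-1]
            better = y[idx] > y[prev_idx] if kind == "peak" else y[idx] < y[prev_idx]
            # equal heights: keep the earliest
            if better:
                kept[-1] = (idx, kind)
        else:
            kept.append((idx, kind))
    pk = np.array([i for i, k in kept if k == "peak"], dtype=int)
    tr = np.array([i for i, k in kept if k == "trough"], dtype=int)

    def extract(indices, sign):
        tt, vv = [], []
        for i in indices:
            if refine:
                ti, vi = _refine(t, y, int(i))
            else:
                ti, vi = float(t[i]), float(y[i])
            tt.append(ti)
            vv.append(vi)
        return np.array(tt), np.array(vv)

    peak_t, peak_v = extract(pk, +1)
    trough_t, trough_v = extract(tr, -1)
    return {
        "peak_t": peak_t, "peak_value": peak_v, "peak_idx": pk,
        "trough_t": trough_t, "trough_value": trough_v, "trough_idx": tr,
    }


def _autocorr_period(y: np.ndarray, t: np.ndarray) -> float | None:
    dt = float(np.median(np.diff(t)))
    x = y - np.nanmean(y)
    x = np.nan_to_num(x)
    ac = np.correlate(x, x, mode="full")[x.size - 1 :]
    if ac.size < 3 or ac[0] <= 0:
        return None
    pk, _ = find_peaks(ac)
    if pk.size == 0:
        return None
    return float(pk[0] * dt)


def detect_period(
    series: np.ndarray,
    t_grid: np.ndarray,
    prominence_frac: float = PROMINENCE_FRAC_DEFAULT,
    smooth: bool = True,
) -> PeriodEstimate:
    """Mean and per-cycle peak-to-peak periods of one channel.

    Per-cycle periods are consecutive peak-to-peak intervals; cycles whose
    period deviates more than 30% from the running median are flagged
    irregular and excluded from the mean.  The mean is cross-checked
    against the first autocorrelation maximum (a warning is issued if the
    two disagree by more than 20%).  With fewer than two detected peaks no
    period is defined and ``mean_period`` is None.
    """
    y = np.asarray(series, dtype=float)
    t = np.asarray(t_grid, dtype=float)
    work = _smooth(y) if smooth else y
    ext = detect_extrema(work, t, prominence_frac=prominence_frac)
    peak_t = ext["peak_t"]
    if peak_t.size < 2:
        return PeriodEstimate(
            mean_period=None,
            periods=np.array([]),
            all_periods=np.array([]),
            peak_times=peak_t,
        )
    all_periods = np.diff(peak_t)
    med = np.median(all_periods)
    irregular = np.abs(all_periods - med) > IRREGULAR_PERIOD_FRAC * med
    periods = all_periods[~irregular]
    mean_period = float(np.mean(periods)) if periods.size else None
    ac = _autocorr_period(work, t)
    if ac is not None and mean_period is not None:
        if abs(ac - mean_period) > 0.2 * mean_period:
            warnings.warn(
                f"peak-to-peak period {mean_period:.1f} h and autocorrelation "
                f"period {ac:.1f} h disagree by more than 20%",
                stacklevel=2,
            )
    return PeriodEstimate(
        mean_period=mean_period,
        periods=periods,
        all_periods=all_periods,
        peak_times=peak_t,
        autocorr_period=ac,
        irregular=irregular,
    )


def segment_cycles(
    biomass: np.ndarray,
    t_grid: np.ndarray,
    prominence_frac: float = PROMINENCE_FRAC_DEFAULT,
    smooth: bool = True,
) -> list[CycleSegment]:
    """Segment the biomass channel into trough-peak-trough cycles.

    Stage I runs trough to peak, stage II peak to trough; stage durations
    sum to the trough-to-trough cycle length by construction.  Candidate
    extrema are detected on a mildly smoothed copy; boundary times are
    then refined on the raw series with the breakpoint fit (see
    :func:`_refine_breakpoint`), which stays unbiased when the two stages
    have different curvature at the shared extremum.  Strictly positive
    biomass is log-transformed first — growth is multiplicative, and the
    monotone transform leaves extremum times unchanged while making the
    cycle shape polynomial-friendly.
    """
    y = np.asarray(biomass, dtype=float)
    t = np.asarray(t_grid, dtype=float)
    if np.nanmin(y) > 0:
        y = np.log(y)
    work = _smooth(y) if smooth else y
    ext = detect_extrema(work, t, prominence_frac=prominence_frac, refine=False)
    peak_t = [_refine_breakpoint(t, y, int(i)) for i in ext["peak_idx"]]
    trough_t = [_refine_breakpoint(t, y, int(i)) for i in ext["trough_idx"]]
    events = sorted(
        [(tt, "peak") for tt in peak_t]
        + [(tt, "trough") for tt in trough_t]
    )
    cycles: list[CycleSegment] = []
    for i in range(len(events) - 2):
        (t0, k0), (t1, k1), (t2, k2) = events[i : i + 3]
        if (k0, k1, k2) == ("trough", "peak", "trough"):
            cycles.append(
                CycleSegment(
                    trough_start_t=t0,
                    peak_t=t1,
                    trough_end_t=t2,
                    cycle_index=len(cycles),
                )
            )
    if not cycles:
        warnings.warn("no complete trough-peak-trough cycle found", stacklevel=2)
    return cycles


def cycle_statistics(
    series: np.ndarray,
    t_grid: np.ndarray,
    cycles: list[CycleSegment],
    channel: str = "",
) -> tuple[list[ExtremumRecord], dict]:
    """Per-cycle max/min of a channel within biomass-defined cycles.

    Extrema are taken over the grid samples inside each cycle window, so a
    record's value is exactly the channel value at its time.  The summary
    aggregates mean and standard deviation of the per-cycle maxima and
    minima and their mean phase positions.
    """
    if not cycles:
        raise ValueError("cycles must be nonempty")
    y = np.asarray(series, dtype=float)
    t = np.asarray(t_grid, dtype=float)
    if y.shape != t.shape:
        raise ValueError("series and t_grid must have equal length")
    records: list[ExtremumRecord] = []
    for cyc in cycles:
        mask = (t >= cyc.trough_start_t) & (t < cyc.trough_end_t)
        if not np.any(mask):
            continue
        ts, ys = t[mask], y[mask]
        for kind, idx in (("max", int(np.nanargmax(ys))), ("min", int(np.nanargmin(ys)))):
            phase = cyc.phase_of(float(ts[idx]))
            records.append(
                ExtremumRecord(
                    channel=channel,
                    cycle_index=cyc.cycle_index,
                    kind=kind,
                    value=float(ys[idx]),
                    t=float(ts[idx]),
                    phase_position=phase,
                    stage="I" if phase < cyc.stage_boundary_phase else "II",
                )
            )
    maxima = [r for r in records if r.kind == "max"]
    minima = [r for r in records if r.kind == "min"]
    summary = {
        "max_mean": float(np.mean([r.value for r in maxima])) if maxima else np.nan,
        "max_sd": float(np.std([r.value for r in maxima], ddof=1))
        if len(maxima) > 1 else np.nan,
        "min_mean": float(np.mean([r.value for r in minima])) if minima else np.nan,
        "min_sd": float(np.std([r.value for r in minima], ddof=1))
        if len(minima) > 1 else np.nan,
        "max_phase_mean": float(np.mean([r.phase_position for r in maxima]))
        if maxima else np.nan,
        "min_phase_mean": float(np.mean([r.phase_position for r in minima]))
        if minima else np.nan,
        "n_cycles": len(cycles),
    }
    return records, summary


def phase_lag(
    series_a: np.ndarray,
    series_b: np.ndarray,
    t_grid: np.ndarray,
    cycles: list[CycleSegment],
) -> float:
    """Circular mean lag of channel b's peak behind channel a's, in hours.

    Per cycle, the lag is the difference of (parabola-refined) peak times;
    the circular mean over cycles is mapped to (-T/2, T/2].  Antisymmetric
    by construction: lag(a, b) = -lag(b, a) (mod T).
    """
    if not cycles:
        raise ValueError("cycles must be nonempty")
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    t = np.asarray(t_grid, dtype=float)
    for name, y in (("a", a), ("b", b)):
        if float(np.nanmax(y) - np.nanmin(y)) <= 0:
            raise ValueError(f"channel {name} is not oscillatory (zero range)")
    T = float(np.mean([c.period for c in cycles]))
    angles = []
    for cyc in cycles:
        lags_ab = []
        for y in (a, b):
            mask = (t >= cyc.trough_start_t) & (t < cyc.trough_end_t)
            idx_local = int(np.nanargmax(y[mask]))
            idx = np.flatnonzero(mask)[idx_local]
            t_pk, _ = _refine(t, y, idx)
            lags_ab.append(t_pk)
        delta = lags_ab[1] - lags_ab[0]
        angles.append(2.0 * np.pi * delta / T)
    mean_sin = float(np.mean(np.sin(angles)))
    mean_cos = float(np.mean(np.cos(angles)))
    lag = T * np.arctan2(mean_sin, mean_cos) / (2.0 * np.pi)
    if lag <= -T / 2:
        lag += T
    return float(lag)


def peaks_per_cycle(
    series: np.ndarray,
    t_grid: np.ndarray,
    cycles: list[CycleSegment],
    prominence_frac: float = PROMINENCE_FRAC_DEFAULT,
) -> list[int]:
    """Count prominent maxima of a series inside each biomass cycle.

    A bimodal ("M-shaped") rate waveform yields 2 per cycle; a simple
    oscillation aligned with the cycles yields 1.
    """
    if not cycles:
        raise ValueError("cycles must be nonempty")
    y = np.asarray(series, dtype=float)
    t = np.asarray(t_grid, dtype=float)
    rng = float(np.nanmax(y) - np.nanmin(y))
    if rng == 0:
        return [0 for _ in cycles]
    pk, _ = find_peaks(y, prominence=prominence_frac * rng)
    pk_t = t[pk]
    return [
        int(np.sum((pk_t >= c.trough_start_t) & (pk_t < c.trough_end_t)))
        for c in cycles
    ]


def _noise_sd(y: np.ndarray) -> float:
    """Robust noise scale from first differences (MAD-based)."""
    d = np.diff(y)
    if d.size == 0:
        return 0.0
    return 1.4826 * float(np.median(np.abs(d - np.median(d)))) / np.sqrt(2.0)


def classify_regime(
    series: np.ndarray,
    t_grid: np.ndarray,
    prominence_frac: float = PROMINENCE_FRAC_DEFAULT,
    smooth: bool = True,
) -> str:
    """Label a channel ``sustained``, ``damped`` or ``none``.

    A channel is non-oscillatory ("none") if fewer than two prominent
    peaks are found or the oscillation amplitude does not clearly exceed
    the measurement noise.  Otherwise the log peak amplitude (peak minus
    series median) is regressed on time; if the fitted amplitude half-life
    is at most three periods the oscillation is "damped", else
    "sustained".
    """
    y = np.asarray(series, dtype=float)
    t = np.asarray(t_grid, dtype=float)
    work = _smooth(y) if smooth else y
    ext = detect_extrema(work, t, prominence_frac=prominence_frac)
    peak_t, peak_v = ext["peak_t"], ext["peak_value"]
    if peak_t.size < 2:
        return "none"
    baseline = float(np.median(work))
    amps = peak_v - baseline
    noise = _noise_sd(y)
    if np.median(amps) < MIN_SNR * noise or np.any(amps <= 0):
        return "none"
    T = float(np.mean(np.diff(peak_t)))
    slope = np.polyfit(peak_t, np.log(amps), 1)[0]
    decay = -slope  # 1/h; positive = shrinking amplitude
    if decay <= 0:
        return "sustained"
    half_life = np.log(2.0) / decay
    return "damped" if half_life <= DAMPED_HALFLIFE_PERIODS * T else "sustained"


def summarize(
    ts,
    ref_channel: str = "X",
    prominence_frac: float = PROMINENCE_FRAC_DEFAULT,
) -> OscillationSummary:
    """Full oscillation readout of a dataset against a reference channel."""
    t = ts.t
    ref = ts[ref_channel]
    regime = classify_regime(ref, t, prominence_frac=prominence_frac)
    est = detect_period(ref, t, prominence_frac=prominence_frac)
    cycles = (
        segment_cycles(ref, t, prominence_frac=prominence_frac)
        if regime != "none"
        else []
    )
    extrema: dict[str, list[ExtremumRecord]] = {}
    ppc: dict[str, list[int]] = {}
    if cycles:
        for name in ts.channel_names:
            recs, _ = cycle_statistics(ts[name], t, cycles, channel=name)
            extrema[name] = recs
            ppc[name] = peaks_per_cycle(ts[name], t, cycles)
    return OscillationSummary(
        reference_channel=ref_channel,
        regime=regime,
        mean_period=est.mean_period,
        periods=est.periods,
        cycles=cycles,
        extrema=extrema,
        peaks_per_cycle=ppc,
    )
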