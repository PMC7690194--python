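"""Extremum detection, period recovery, cycle segmentation, phase lags."""

import numpy as np
import pytest

from oscferm import oscillation as osc
from oscferm import synthgen
from oscferm.oscillation import (
    CycleSegment,
    classify_regime,
    cycle_statistics,
    detect_extrema,
    detect_period,
    peaks_per_cycle,
    phase_lag,
    segment_cycles,
)


def brute_force_peaks(series, t, n_cycles, period):
    """Oracle: windowed argmax per cycle on the raw grid."""
    out = []
    for k in range(n_cycles):
        win = (t >= t[0] + k * period) & (t < t[0] + (k + 1) * period)
        out.append(t[win][np.argmax(series[win])])
    return np.array(out)


class TestDetectExtrema:
    def test_sine_positions(self):
        t = np.arange(0, 212.0, 1.0)
        y = np.sin(2 * np.pi * t / 53.0)
        ext = detect_extrema(y, t)
        # one peak per period, at T/4 + k T
        want = 53.0 / 4 + 53.0 * np.arange(4)
        assert ext["peak_t"] == pytest.approx(want, abs=1.0)
        assert ext["trough_t"].size in (3, 4)

    def test_constant_series_no_extrema(self):
        t = np.arange(0, 10.0)
        ext = detect_extrema(np.ones_like(t), t)
        assert ext["peak_t"].size == 0 and ext["trough_t"].size == 0

    def test_empty_series_errors(self):
        with pytest.raises(ValueError):
            detect_extrema(np.array([]), np.array([]))

    def test_alternation_enforced(self):
        t = np.arange(0, 212.0, 1.0)
        rng = np.random.default_rng(0)
        y = np.sin(2 * np.pi * t / 53.0) + 0.05 * rng.standard_normal(t.size)
        ext = detect_extrema(y, t)
        events = sorted(
            [(x, "p") for x in ext["peak_t"]] + [(x, "t") for x in ext["trough_t"]]
        )
        kinds = [k for _, k in events]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))

    def test_noisy_peak_count_matches_windowed_argmax_oracle(self):
        t, ch, ds = synthgen.oscillation_recovery_run(
            n_cycles=3, seed=1, noise_cv=0.02
        )
        X = ch["X"]
        ext = detect_extrema(osc._smooth(X), t)
        n_win = int((t[-1] - t[0]) // 53.4)
        oracle = brute_force_peaks(X, t, n_win, 53.4)
        # same count, and each detected peak within one sample of the
        # windowed argmax
        hi = t[0] + n_win * 53.4
        interior = [p for p in ext["peak_t"] if t[0] + 10 < p < hi]
        assert len(interior) == oracle.size
        assert np.max(np.abs(np.sort(interior) - np.sort(oracle))) <= 3.0


class TestDetectPeriod:
    def test_sine_51h(self):
        t = np.arange(0, 51.0 * 4, 1.0)
        est = detect_period(np.sin(2 * np.pi * t / 51.0), t)
        assert est.mean_period == pytest.approx(51.0, abs=1.0)

    def test_fewer_than_two_peaks(self):
        t = np.arange(0, 30.0)
        est = detect_period(np.ones_like(t), t)
        assert est.mean_period is None

    def test_noiseless_waveform_matches_dense_grid_oracle(self):
        ds = synthgen.simulate_preset("oscillatory", noise_cv=0.0, t_end=594.0,
                                      dt_h=0.25)
        t, X = ds.clean.t, ds.clean["X"]
        m = t >= 47
        est = detect_period(X[m], t[m])
        # dense-grid argmax peak-to-peak intervals equal the configured
        # period exactly
        oracle = np.diff(brute_force_peaks(X[m], t[m], 10, 53.4))
        assert oracle == pytest.approx(np.full(9, 53.4), abs=0.5)
        assert est.mean_period == pytest.approx(53.4, abs=0.5)

    def test_affine_invariance(self):
        t, ch, _ = synthgen.oscillation_recovery_run(n_cycles=3, seed=2)
        a = detect_period(ch["X"], t).mean_period
        b = detect_period(3.7 * ch["X"] + 11.0, t).mean_period
        assert a == pytest.approx(b, rel=1e-9)

    def test_preset_period_recovered_within_5pct(self):
        t, ch, ds = synthgen.oscillation_recovery_run(
            n_cycles=3, seed=42, noise_cv=0.03
        )
        est = detect_period(ch["X"], t)
        T = ds.config.channels["X"].params.period_h
        assert est.mean_period == pytest.approx(T, rel=0.05)


class TestSegmentCycles:
    def test_symmetric_sinusoid_equal_stages(self):
        t = np.arange(0, 212.0, 1.0)
        y = np.sin(2 * np.pi * t / 53.0)
        cycles = segment_cycles(y, t)
        assert len(cycles) >= 2
        for c in cycles:
            assert c.stage1_duration == pytest.approx(53.0 / 2, abs=1.5)
            assert c.stage2_duration == pytest.approx(53.0 / 2, abs=1.5)

    def test_durations_sum_to_cycle_length(self):
        t, ch, _ = synthgen.oscillation_recovery_run(n_cycles=3, seed=3)
        for c in segment_cycles(ch["X"], t):
            assert c.stage1_duration + c.stage2_duration == pytest.approx(
                c.period, abs=1e-12
            )

    def test_no_cycle_warns_empty(self):
        t = np.arange(0, 30.0)
        with pytest.warns(UserWarning):
            cycles = segment_cycles(np.ones_like(t), t)
        assert cycles == []

    def test_invalid_segment_rejected(self):
        with pytest.raises(ValueError):
            CycleSegment(10.0, 5.0, 20.0, 0)

    def test_preset_stage_asymmetry(self):
        t, ch, _ = synthgen.oscillation_recovery_run(
            n_cycles=10, seed=42, noise_cv=0.02
        )
        cycles = segment_cycles(ch["X"], t)
        s1 = np.mean([c.stage1_duration for c in cycles])
        s2 = np.mean([c.stage2_duration for c in cycles])
        assert s1 < s2
        # configured rising span 21 h of a 53.4-h cycle
        assert s1 == pytest.approx(21.0, abs=1.5)


class TestCycleStatistics:
    def test_constant_channel(self):
        t = np.arange(0, 100.0, 1.0)
        cycles = [CycleSegment(0.0, 20.0, 53.0, 0)]
        recs, summ = cycle_statistics(np.full_like(t, 7.0), t, cycles, "c")
        assert summ["max_mean"] == 7.0 and summ["min_mean"] == 7.0

    def test_biomass_peak_phase_equals_stage_boundary(self):
        t, ch, _ = synthgen.oscillation_recovery_run(n_cycles=3, seed=4)
        cycles = segment_cycles(ch["X"], t)
        for c in cycles:
            assert c.phase_of(c.peak_t) == pytest.approx(
                c.stage_boundary_phase, abs=1e-12
            )

    def test_empty_cycles_error(self):
        with pytest.raises(ValueError):
            cycle_statistics(np.ones(5), np.arange(5.0), [], "c")

    def test_h2_extrema_against_configured_truth(self):
        t, ch, ds = synthgen.oscillation_recovery_run(
            n_cycles=3, seed=42, noise_cv=0.02
        )
        cycles = segment_cycles(ch["X"], t)
        _, s = cycle_statistics(ch["H2"], t, cycles, "H2")
        p = ds.config.channels["H2"].params
        assert s["max_mean"] == pytest.approx(p.level_max, rel=0.15)
        # maximum sits in stage II
        bound = np.mean([c.stage_boundary_phase for c in cycles])
        assert s["max_phase_mean"] > bound


class TestPhaseLag:
    def _cycles(self, t):
        return [
            CycleSegment(k * 53.0, k * 53.0 + 21.0, (k + 1) * 53.0, k)
            for k in range(1, 3)
        ]

    def test_identical_series_zero_lag(self):
        t = np.arange(0, 212.0, 1.0)
        y = np.sin(2 * np.pi * t / 53.0)
        assert phase_lag(y, y, t, self._cycles(t)) == pytest.approx(0.0, abs=1e-9)

    def test_quarter_period_shift(self):
        t = np.arange(0, 212.0, 1.0)
        a = np.sin(2 * np.pi * t / 53.0)
        b = np.sin(2 * np.pi * (t - 53.0 / 4) / 53.0)
        lag = phase_lag(a, b, t, self._cycles(t))
        assert lag == pytest.approx(53.0 / 4, abs=1.5)

    def test_antisymmetry_and_additivity(self):
        t = np.arange(0, 212.0, 1.0)
        T = 53.0
        a = np.sin(2 * np.pi * t / T)
        b = np.sin(2 * np.pi * (t - 8.0) / T)
        c = np.sin(2 * np.pi * (t - 20.0) / T)
        cycles = self._cycles(t)
        ab = phase_lag(a, b, t, cycles)
        ba = phase_lag(b, a, t, cycles)
        ac = phase_lag(a, c, t, cycles)
        bc = phase_lag(b, c, t, cycles)
        assert (ab + ba) % T == pytest.approx(0.0, abs=2.0)
        assert (ab + bc - ac) % T == pytest.approx(0.0, abs=2.0)

    def test_lactate_lags_pdo_by_configured_offset(self):
        # generator-truth check, run noise-free: measurement noise adds
        # ~1 sample of timing jitter on the flat-topped lactate peak
        t, ch, ds = synthgen.oscillation_recovery_run(
            n_cycles=3, seed=5, noise_cv=0.0
        )
        cycles = segment_cycles(ch["X"], t)
        lag = phase_lag(ch["PDO"], ch["lactate"], t, cycles)
        want = ds.config.channels["lactate"].params.phase_offset_h - \
            ds.config.channels["PDO"].params.phase_offset_h
        assert lag > 0
        assert lag == pytest.approx(want, rel=0.10, abs=1.7)

    def test_non_oscillatory_channel_errors(self):
        t = np.arange(0, 212.0, 1.0)
        y = np.sin(2 * np.pi * t / 53.0)
        with pytest.raises(ValueError):
            phase_lag(y, np.zeros_like(t), t, self._cycles(t))


class TestPeaksPerCycle:
    def test_aligned_sinusoid_one_per_cycle(self):
        t = np.arange(0, 212.0, 1.0)
        y = np.sin(2 * np.pi * (t - 13.0) / 53.0)
        cycles = [
            CycleSegment(k * 53.0, k * 53.0 + 26.0, (k + 1) * 53.0, k)
            for k in range(4)
        ]
        assert peaks_per_cycle(y, t, cycles) == [1, 1, 1, 1]

    def test_bimodal_m_shape_two_per_cycle(self):
        """A lactate-rate-like waveform with peaks mid stage I and mid
        stage II yields two prominent maxima per cycle."""
        t = np.arange(0, 212.0, 1.0)
        T = 53.0
        y = 1.0 + 0.5 * np.sin(2 * np.pi * t / T) + 1.5 * np.maximum(
            np.sin(4 * np.pi * t / T), 0.0
        )
        cycles = [
            CycleSegment(k * T, k * T + 21.0, (k + 1) * T, k) for k in range(1, 4)
        ]
        counts = peaks_per_cycle(y, t, cycles)
        brute = []
        for c in cycles:
            win = (t >= c.trough_start_t) & (t < c.trough_end_t)
            yy = y[win]
            local = np.flatnonzero(
                (yy[1:-1] > yy[:-2]) & (yy[1:-1] >= yy[2:])
            )
            # brute-force local maxima with the same prominence rule
            rng_y = y.max() - y.min()
            keep = [
                i for i in local
                if yy[i + 1] - yy.min() >= 0.2 * rng_y
            ]
            brute.append(len(keep))
        assert counts == [2, 2, 2]
        assert brute == [2, 2, 2]


class TestClassifyRegime:
    def test_constant_none(self):
        t = np.arange(0, 212.0, 3.0)
        assert classify_regime(np.full_like(t, 2.0), t) == "none"

    def test_noise_only_none(self):
        rng = np.random.default_rng(6)
        t = np.arange(0, 212.0, 3.0)
        y = 3.0 * (1 + 0.02 * rng.standard_normal(t.size))
        assert classify_regime(y, t) == "none"

    @pytest.mark.parametrize(
        "preset,expected",
        [("oscillatory", "sustained"), ("damped", "damped"),
         ("steady", "none"), ("high_dilution", "none")],
    )
    def test_presets(self, preset, expected, request):
        fixture = {
            "oscillatory": "osc_clean", "damped": "damped_clean",
            "steady": "steady_clean", "high_dilution": None,
        }[preset]
        if fixture is None:
            ds = synthgen.simulate_preset(preset)
        else:
            clean = request.getfixturevalue(fixture)
            ds = clean
            ds = synthgen.SimulatedDataset(
                observed=synthgen.add_noise(clean.clean, 0.02, seed=20),
                truth_rates=clean.truth_rates, config=clean.config,
                clean=clean.clean,
            )
        got = classify_regime(ds.observed["X"], ds.observed.t)
        assert got == expected

    def test_decay_threshold_boundary(self):
        """An exponentially decaying sinusoid flips damped/sustained at
        the half-life = 3 periods threshold."""
        t = np.arange(0, 53.0 * 6, 1.0)
        T = 53.0
        for factor, want in ((2.0, "damped"), (9.0, "sustained")):
            lam = np.log(2) / (factor * T)
            y = 2.0 + np.exp(-lam * t) * np.sin(2 * np.pi * t / T)
            assert classify_regime(y, t, smooth=False) == want


class TestSummarize:
    def test_full_summary_on_preset(self):
        t, ch, ds = synthgen.oscillation_recovery_run(n_cycles=3, seed=7)
        from oscferm.timeseries import TimeSeriesSet

        ts = TimeSeriesSet(
            t=t, channels=ch, units=dict(ds.observed.units),
            meta=dict(ds.observed.meta),
        )
        summ = osc.summarize(ts)
        assert summ.regime == "sustained"
        assert summ.mean_period == pytest.approx(53.4, rel=0.05)
        assert len(summ.cycles) == 3
        assert "H2" in summ.extrema
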