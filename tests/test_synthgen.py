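"""Generator: waveforms, ODE consistency, noise, presets."""

import numpy as np
import pytest

from oscferm import synthgen
from oscferm.kinetics import estimate_derivative
from oscferm.synthgen import (
    add_noise,
    config_from_preset,
    load_preset,
    simulate_assay_plate,
    simulate_chemostat,
    simulate_preset,
)
from oscferm.waveform import ChannelSpec, WaveformParams, make_rate_waveform


class TestRateWaveform:
    def test_periodicity(self):
        p = WaveformParams(
            period_h=53.0, rise_fraction=0.5, phase_offset_h=7.0,
            level_min=0.1, level_max=2.0,
        )
        t = np.linspace(0, 53, 40)
        assert make_rate_waveform(p, 0.0, t) == pytest.approx(
            make_rate_waveform(p, 0.0, t + 53.0)
        )

    def test_degenerate_amplitude_constant(self):
        p = WaveformParams(53.0, 0.4, 0.0, 1.5, 1.5)
        t = np.linspace(0, 200, 100)
        assert make_rate_waveform(p, 0.0, t) == pytest.approx(np.full(100, 1.5))

    def test_damping_shrinks_cycle_peaks(self):
        # dense-grid oracle: per-cycle maxima strictly decrease
        p = WaveformParams(50.0, 0.4, 0.0, 0.0, 2.0)
        t = np.linspace(0, 250, 25_000)
        y = make_rate_waveform(p, 0.01, t)
        peaks = [
            y[(t >= k * 50) & (t < (k + 1) * 50)].max() for k in range(5)
        ]
        assert np.all(np.diff(peaks) < 0)

    def test_nonfinite_time_rejected(self):
        p = WaveformParams(53.0, 0.4, 0.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            make_rate_waveform(p, 0.0, np.array([np.nan]))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            WaveformParams(-1.0, 0.4, 0.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            WaveformParams(53.0, 1.2, 0.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            WaveformParams(53.0, 0.4, 0.0, 1.0, 0.0)


def _rate_space_config(t_grid, mu_params=None, q_params=None, X0=0.5):
    channels = {
        "X": ChannelSpec(
            "X", "g/L", "biomass", kind="constant", level=0.048,
            space="rate", init=X0,
        )
        if mu_params is None
        else ChannelSpec(
            "X", "g/L", "biomass", params=mu_params, space="rate", init=X0
        ),
    }
    if q_params is not None:
        channels["P"] = ChannelSpec(
            "P", "g/L", "product", kind="constant", level=q_params,
            space="rate", init=0.0,
        )
    return synthgen.GeneratorConfig(
        D=0.048, D_G=0.5, S_f=88.0, t_grid=t_grid, channels=channels,
        noise_cv=0.0, seed=0,
    )


class TestSimulateChemostat:
    def test_constant_rates_reach_steady_product(self):
        # mu = D keeps X constant; q_P constant -> C_P -> q_P*X/D
        t = np.arange(0.0, 400.0, 4.0)
        cfg = _rate_space_config(t, q_params=0.3, X0=2.0)
        ds = simulate_chemostat(cfg)
        assert ds.clean["X"][-1] == pytest.approx(2.0, rel=1e-6)
        assert ds.clean["P"][-1] == pytest.approx(0.3 * 2.0 / 0.048, rel=1e-3)

    def test_washout_closed_form(self):
        # all rates zero, C_S(0)=0: C_S(t) = S_f (1 - exp(-D t))
        t = np.arange(0.0, 100.0, 2.0)
        channels = {
            "X": ChannelSpec("X", "g/L", "biomass", kind="constant",
                             level=0.048, space="rate", init=1.0),
            "S": ChannelSpec("S", "g/L", "substrate", kind="constant",
                             level=0.0, space="rate", init=0.0),
        }
        cfg = synthgen.GeneratorConfig(
            D=0.048, D_G=0.5, S_f=88.0, t_grid=t, channels=channels,
        )
        ds = simulate_chemostat(cfg)
        want = 88.0 * (1 - np.exp(-0.048 * t))
        assert ds.clean["S"] == pytest.approx(want, rel=1e-5, abs=1e-6)

    def test_ode_matches_analytic_channels(self, osc_clean):
        ds = osc_clean
        for name, spec in ds.config.channels.items():
            if spec.role == "direct":
                continue
            want = spec.value(ds.clean.t)
            assert ds.clean[name] == pytest.approx(want, rel=1e-5, abs=1e-5), name

    def test_phase_structure_of_oscillatory_preset(self, osc_clean):
        """Biomass and 1,3-PDO peak together; H2 peaks later in the cycle
        (generator's own configured offsets)."""
        ds = osc_clean
        t = ds.clean.t
        win = (t >= 53.4) & (t < 2 * 53.4)
        tX = t[win][np.argmax(ds.clean["X"][win])]
        tP = t[win][np.argmax(ds.clean["PDO"][win])]
        tH = t[win][np.argmax(ds.clean["H2"][win])]
        assert abs(tX - tP) <= 3.0
        assert 10.0 <= tH - tX <= 22.0  # configured +16.2 h offset

    def test_mass_balance_residual_small(self, osc_clean):
        """Finite-difference residual of every balance stays below
        1e-3 x channel scale on a 1-h grid."""
        ds = synthgen.simulate_preset(
            "oscillatory", noise_cv=0.0, t_end=160.0, dt_h=1.0
        )
        ts, truth = ds.clean, ds.truth_rates
        D, DG, Sf = ts.meta["D"], ts.meta["D_G"], ts.meta["S_f"]
        X = ts["X"]
        for name in ("glycerol", "PDO", "H2"):
            p = ds.config.channels[name].params
            T = p.period_h
            phase = ts.t % T
            keep = (ts.t > 5) & (ts.t < 155)
            # the raised cosine is C1: keep clear of its two curvature
            # breaks per cycle, where finite differences degrade
            for kink in (p.phase_offset_h % T,
                         (p.phase_offset_h - p.rise_fraction * T) % T):
                d = np.abs(phase - kink)
                keep &= np.minimum(d, T - d) > 3.0
            dC = estimate_derivative(ts[name], ts.t, window=3)
            if name == "glycerol":
                rhs = D * (Sf - ts[name]) - truth.q[name] * X
            elif name == "H2":
                rhs = truth.q[name] * X - DG * ts[name]
            else:
                rhs = truth.q[name] * X - D * ts[name]
            scale = np.ptp(ts[name])
            assert np.max(np.abs((dC - rhs)[keep])) < 1e-3 * scale, name

    def test_per_cycle_peaks_stable_without_damping(self, osc_clean_long):
        # dense evaluation of the undamped waveform: per-cycle peak
        # values agree to well under 1% after the first cycle
        ds = osc_clean_long
        spec = ds.config.channels["X"]
        t = np.arange(53.4, 53.4 * 10, 0.05)
        X = spec.value(t)
        peaks = []
        for k in range(1, 10):
            win = (t >= k * 53.4) & (t < (k + 1) * 53.4)
            peaks.append(X[win].max())
        peaks = np.array(peaks)
        assert np.ptp(peaks) / peaks.mean() < 0.01

    def test_seed_determinism(self):
        a = simulate_preset("oscillatory", seed=5, t_end=100.0)
        b = simulate_preset("oscillatory", seed=5, t_end=100.0)
        for name in a.observed.channel_names:
            assert np.array_equal(a.observed[name], b.observed[name])


class TestAddNoise:
    def test_zero_noise_identity(self, steady_clean):
        out = add_noise(steady_clean.clean, 0.0, seed=1)
        for name in out.channel_names:
            assert np.array_equal(out[name], steady_clean.clean[name])

    def test_same_seed_identical(self, steady_clean):
        a = add_noise(steady_clean.clean, 0.02, seed=9)
        b = add_noise(steady_clean.clean, 0.02, seed=9)
        for name in a.channel_names:
            assert np.array_equal(a[name], b[name])

    def test_monte_carlo_cv(self):
        """1e4 replicate draws of one point: sample CV within 10% of the
        requested 0.02."""
        from oscferm.timeseries import TimeSeriesSet

        base = TimeSeriesSet(
            t=np.array([0.0]), channels={"X": np.array([5.0])},
            units={"X": "g/L"},
        )
        draws = np.array(
            [add_noise(base, 0.02, seed=s)["X"][0] for s in range(10_000)]
        )
        cv = draws.std() / draws.mean()
        assert abs(cv - 0.02) / 0.02 < 0.10


class TestPresets:
    @pytest.mark.parametrize("name", synthgen.PRESET_NAMES)
    def test_presets_load_and_validate(self, name):
        cfg = config_from_preset(name)
        assert cfg.D > 0 and cfg.S_f > 0

    def test_unknown_preset(self):
        with pytest.raises(ValueError):
            load_preset("nope")

    def test_damped_preset_amplitude_decays(self, damped_clean):
        t, X = damped_clean.clean.t, damped_clean.clean["X"]
        first = X[(t >= 0) & (t < 53.4)].max()
        last = X[(t >= 3 * 53.4) & (t < 4 * 53.4)].max()
        mid = 0.5 * (np.log(0.9) + np.log(2.8))
        assert last - np.exp(mid) < 0.55 * (first - np.exp(mid))


class TestAssayPlate:
    def test_noise_free_linear(self):
        plate = simulate_assay_plate([0.02, 0.04], 2.5, 0.0, seed=0)
        for conc, slope in plate["standards"]:
            assert slope == pytest.approx(2.5 * conc)
        assert plate["sample_slopes"] == pytest.approx([0.05, 0.10])

    def test_standards_span_calibration_range(self):
        plate = simulate_assay_plate([0.02], 2.0, 0.0, seed=0)
        concs = [c for c, _ in plate["standards"]]
        assert min(concs) == pytest.approx(0.01)
        assert max(concs) == pytest.approx(0.05)

    def test_seed_reproducible(self):
        a = simulate_assay_plate([0.02], 2.0, 0.01, seed=4)
        b = simulate_assay_plate([0.02], 2.0, 0.01, seed=4)
        assert a["sample_slopes"] == pytest.approx(b["sample_slopes"])
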