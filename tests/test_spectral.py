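import numpy as np
import pytest
from scipy import stats

from deltatrack.spectral import (band_power_at_zero, band_power_contrast,
                                 coherence_with_null, default_freq_grid,
                                 delta_cycle_split_power, plv_from_phases,
                                 spike_phase_locking, triggered_spectrogram,
                                 wavelet_spectrogram)
from deltatrack.traces import SpikeTrain

FS = 1000.0


class TestPlvClosedForms:
    def test_identical_phases_give_unity(self):
        for n in (2, 5, 50):
            plv, plvu2, pref = plv_from_phases(np.full(n, 0.7))
            assert plv == pytest.approx(1.0)
            assert plvu2 == pytest.approx(1.0)
            assert pref == pytest.approx(0.7)

    def test_quadrant_phases_cancel(self):
        plv, plvu2, _ = plv_from_phases(np.array([0, np.pi / 2, np.pi,
                                                  3 * np.pi / 2]))
        assert plv == pytest.approx(0.0, abs=1e-12)
        assert plvu2 == pytest.approx(-1.0 / 3.0)

    def test_bias_correction_arithmetic(self):
        # engineered sample with PLV = 0.5 at N = 10
        n, target = 10, 0.5
        phi = np.arccos(target)
        phases = np.array([phi, -phi] * 5)
        plv, plvu2, _ = plv_from_phases(phases)
        assert plv == pytest.approx(0.5)
        assert plvu2 == pytest.approx((0.25 * n - 1) / (n - 1))

    @pytest.mark.parametrize("n", [10, 100])
    def test_uniform_phase_bias_vanishes(self, n, rng):
        phi = rng.uniform(-np.pi, np.pi, (10_000, n))
        _, plvu2, _ = plv_from_phases(phi)
        assert abs(plvu2.mean()) < 0.01

    def test_converges_to_plv_squared(self, rng):
        phi = rng.vonmises(0.0, 2.0, (100, 1000))
        plv, plvu2, _ = plv_from_phases(phi)
        assert np.abs(plvu2 - plv**2).max() < 0.01

    def test_plvu2_lower_bound(self, rng):
        for n in (3, 7, 20):
            phi = rng.uniform(-np.pi, np.pi, (200, n))
            _, plvu2, _ = plv_from_phases(phi)
            assert plvu2.min() >= -1.0 / (n - 1) - 1e-12


class TestWavelet:
    def test_single_tone_ridge(self):
        t = np.arange(12_000) / FS
        sp = wavelet_spectrogram(np.sin(2 * np.pi * 10 * t), FS)
        mean_pow = sp.power[:, sp.valid.all(axis=0)].mean(axis=1)
        ridge = sp.freqs_hz[np.argmax(mean_pow)]
        assert ridge == pytest.approx(10.0, rel=0.1)  # log-grid resolution

    def test_two_tone_ridges(self):
        t = np.arange(12_000) / FS
        x = np.sin(2 * np.pi * 2 * t) + 0.8 * np.sin(2 * np.pi * 30 * t)
        sp = wavelet_spectrogram(x, FS)
        mean_pow = sp.power[:, 3000:9000].mean(axis=1)
        lo = sp.freqs_hz[np.argmax(np.where(sp.freqs_hz < 10, mean_pow, 0))]
        hi = sp.freqs_hz[np.argmax(np.where(sp.freqs_hz > 10, mean_pow, 0))]
        assert lo == pytest.approx(2.0, rel=0.1)
        assert hi == pytest.approx(30.0, rel=0.1)

    def test_am_envelope_recovered(self, rng):
        t = np.arange(12_000) / FS
        env = 1 + 0.9 * np.cos(2 * np.pi * 2 * t)
        x = env * np.sin(2 * np.pi * 30 * t) + 0.1 * rng.standard_normal(t.size)
        sp = wavelet_spectrogram(x, FS, np.linspace(25, 35, 5))
        amp = np.sqrt(sp.power.mean(axis=0))
        mid = slice(2000, 10_000)
        r = np.corrcoef(amp[mid], env[mid])[0, 1]
        assert r > 0.9

    def test_band_power_tracks_bandpassed_variance(self, rng):
        """Parseval-style sanity: mean wavelet beta power scales with the
        variance of the beta-band component."""
        from scipy import signal as sig
        t = np.arange(20_000) / FS
        x = rng.standard_normal(t.size)
        sos = sig.butter(4, (20, 40), btype="bandpass", fs=FS, output="sos")
        xb = sig.sosfiltfilt(sos, x)
        sp1 = wavelet_spectrogram(x, FS, np.linspace(20, 40, 10))
        sp2 = wavelet_spectrogram(2 * x, FS, np.linspace(20, 40, 10))
        ratio = sp2.power.mean() / sp1.power.mean()
        assert ratio == pytest.approx(4.0, rel=0.15)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError, match="3 cycles"):
            wavelet_spectrogram(np.zeros(100), FS, np.array([1.0]))


class TestSpikePhaseLocking:
    def test_min_spike_gate(self, caplog):
        t = np.arange(6000) / FS
        sp = wavelet_spectrogram(np.sin(2 * np.pi * 3 * t), FS,
                                 np.array([2.0, 3.0, 4.0]))
        st = SpikeTrain(np.array([3000.0, 3100.0]), np.array([3000, 3100]),
                        np.ones(2), FS)
        with caplog.at_level("WARNING", logger="deltatrack"):
            assert spike_phase_locking([st], [sp], min_spikes=10) is None
        assert "minimum" in caplog.text

    def test_spikes_at_oscillation_peak_lock_at_phase_zero(self):
        t = np.arange(12_000) / FS
        x = np.sin(2 * np.pi * 2.5 * t)
        peaks = (np.arange(30) + 0.0625) * 400.0 + 100.0  # sin peaks at t=0.1+k*0.4
        peaks = 100.0 + np.arange(28) * 400.0
        st = SpikeTrain(peaks, np.round(peaks).astype(int),
                        np.ones(peaks.size), FS)
        sp = wavelet_spectrogram(x, FS, np.array([2.5]))
        res = spike_phase_locking([st], [sp], min_spikes=10)
        assert res.plv[0] > 0.95
        assert res.plvu2[0] > 0.9


class TestTriggeredSpectrogram:
    def test_stationary_noise_ratio_near_one(self, rng):
        spectra, events = [], []
        for _ in range(3):
            x = rng.standard_normal(12_000)
            spectra.append(wavelet_spectrogram(x, FS, np.linspace(15, 45, 8)))
            events.append(np.sort(rng.uniform(1000, 11_000, 200)))
        trig = triggered_spectrogram(spectra, events, min_events=20)
        band = band_power_at_zero(trig, (20, 40))
        assert band == pytest.approx(1.0, abs=0.1)

    def test_events_at_am_peaks_raise_band_ratio(self, rng):
        t = np.arange(12_000) / FS
        env = 1 + 0.8 * np.cos(2 * np.pi * 2 * t)
        x = env * np.sin(2 * np.pi * 30 * t) + 0.3 * rng.standard_normal(t.size)
        sp = wavelet_spectrogram(x, FS, np.linspace(20, 40, 8))
        events = np.arange(500, 11_500, 500.0)  # env peaks every 500 ms
        trig = triggered_spectrogram([sp], [events])
        assert band_power_at_zero(trig, (20, 40)) > 1.1

    def test_minimum_event_rule(self, caplog):
        sp = wavelet_spectrogram(np.random.default_rng(0).standard_normal(6000),
                                 FS, np.linspace(20, 40, 4))
        events = np.linspace(500, 5500, 19)
        with caplog.at_level("WARNING", logger="deltatrack"):
            assert triggered_spectrogram([sp], [events], min_events=20) is None
        assert "19 events" in caplog.text

    def test_identical_conditions_zero_contrast(self, rng):
        x = rng.standard_normal(12_000)
        sp = wavelet_spectrogram(x, FS, np.linspace(20, 40, 6))
        ev = np.sort(rng.uniform(1000, 11_000, 100))
        a = triggered_spectrogram([sp], [ev])
        b = triggered_spectrogram([sp], [ev])
        assert band_power_contrast(a, b, (20, 40)) == pytest.approx(0.0, abs=1e-12)


class TestDeltaCycleSplit:
    def test_nested_beta_visible_in_spikeless_cycles(self):
        from deltatrack.synthetic import SyntheticConfig, gen_delta_neuron
        from deltatrack.traces import process_trial
        cfg = SyntheticConfig(seed=70, n_trials=2, vm_beta_amp=1.5,
                              burst_skip_prob=0.5)
        traces, _ = gen_delta_neuron(cfg)
        vals = []
        for tr in traces:
            st, vm, _ = process_trial(tr)
            out = delta_cycle_split_power(vm.values, st.spike_times_ms,
                                          rate_hz=tr.rate_hz)
            if out is not None:
                vals.append(out["beta_peak_power_without_spikes"])
        assert np.mean(vals) > 1.1

    def test_no_nesting_both_partitions_near_one(self, rng):
        t = np.arange(20_000) / FS
        vm = 2 * np.cos(2 * np.pi * 2.3 * t) + 0.3 * rng.standard_normal(t.size)
        spikes = np.arange(500, 19_000, 870.0)
        out = delta_cycle_split_power(vm, spikes, rate_hz=FS)
        assert out["beta_peak_power_with_spikes"] == pytest.approx(1.0, abs=0.35)
        assert out["beta_peak_power_without_spikes"] == pytest.approx(1.0, abs=0.35)

    def test_all_cycles_spiked_returns_none(self, caplog):
        t = np.arange(10_000) / FS
        vm = np.cos(2 * np.pi * 2.0 * t)
        spikes = np.arange(10, 10_000, 100.0)  # every cycle occupied
        with caplog.at_level("WARNING", logger="deltatrack"):
            assert delta_cycle_split_power(vm, spikes, rate_hz=FS) is None


class TestCoherence:
    def test_delayed_copy_significant(self, rng):
        x = rng.standard_normal(12_000)
        from scipy import signal as sig
        sos = sig.butter(4, (2, 3), btype="bandpass", fs=FS, output="sos")
        xb = sig.sosfiltfilt(sos, x)
        y = np.roll(xb, 40) + 0.1 * rng.standard_normal(x.size)
        res = coherence_with_null(xb, y, FS, n_shuffles=100, seed=1)
        band = (res["freqs_hz"] >= 2) & (res["freqs_hz"] <= 3)
        assert res["coherence"][band].max() > 0.9
        assert res["significant"][band].any()

    def test_independent_noise_inside_null(self, rng):
        res = coherence_with_null(rng.standard_normal(20_000),
                                  rng.standard_normal(20_000),
                                  FS, n_shuffles=100, seed=2)
        assert (~res["significant"]).mean() >= 0.9

    def test_shared_stepping_band_only(self):
        from deltatrack.io_core import align_and_resample
        from deltatrack.synthetic import SyntheticConfig, gen_treadmill_and_limbs
        cfg = SyntheticConfig(seed=71, trial_len_ms=12_000,
                              bout_schedule=((0.0, 12_000.0),))
        speed, lhl, _, _ = gen_treadmill_and_limbs(cfg)
        trial = align_and_resample({"treadmill_speed": speed, "limb_LHL": lhl},
                                   [0.0], trial_len_ms=12_000)
        res = coherence_with_null(trial["treadmill_speed"].values,
                                  trial["limb_LHL"].values, FS,
                                  n_shuffles=100, seed=3)
        f = res["freqs_hz"]
        step_band = (f >= 2.0) & (f <= 3.0)
        away = (f >= 8.0) & (f <= 40.0)
        assert res["significant"][step_band].any()
        assert res["significant"][away].mean() < 0.2
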