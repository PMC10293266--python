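import numpy as np
import pytest

from deltatrack.behavior import (circular_mean, limb_locomotion_periods,
                                 movement_rate_test, omnibus_test,
                                 segment_movement, stepping_locked_rate,
                                 transition_triggered_rate,
                                 treadmill_delta_phase)
from deltatrack.io_core import TimeSeries, align_and_resample
from deltatrack.synthetic import (SyntheticConfig, gen_rate_modulated_spikes,
                                  gen_treadmill_and_limbs)
from deltatrack.traces import SpikeTrain

FS = 1000.0


def _train(times_ms):
    times_ms = np.asarray(times_ms, dtype=float)
    return SpikeTrain(times_ms, np.round(times_ms).astype(int),
                      np.ones(times_ms.size), FS)


@pytest.fixture(scope="module")
def bout_trial():
    cfg = SyntheticConfig(seed=80)
    speed, lhl, rhl, truth = gen_treadmill_and_limbs(cfg)
    trial = align_and_resample({"treadmill_speed": speed, "limb_LHL": lhl},
                               [0.0], trial_len_ms=12_000)
    return cfg, trial, truth


class TestSegmentation:
    def test_boundaries_near_truth(self, bout_trial):
        _, trial, truth = bout_trial
        seg = segment_movement(trial["treadmill_speed"])
        for est, true in zip(seg.onsets_ms, truth.onsets_ms[0]):
            assert abs(est - true) <= 50.0
        for est, true in zip(seg.offsets_ms, truth.offsets_ms[0]):
            assert abs(est - true) <= 50.0

    def test_constant_low_speed_single_rest(self):
        speed = TimeSeries(np.full(8000, 2.0), FS, label="treadmill_speed")
        seg = segment_movement(speed)
        assert seg.move_intervals_ms == [] and seg.onsets_ms.size == 0
        assert seg.rest_intervals_ms == [(0.0, 8000.0)]

    def test_constant_high_speed_single_move(self):
        speed = TimeSeries(np.full(8000, 10.0), FS, label="treadmill_speed")
        seg = segment_movement(speed)
        assert seg.rest_intervals_ms == [] and seg.offsets_ms.size == 0
        assert seg.move_intervals_ms == [(0.0, 8000.0)]

    def test_intervals_tile_trial(self, bout_trial):
        _, trial, _ = bout_trial
        seg = segment_movement(trial["treadmill_speed"])
        total = sum(b - a for a, b in seg.rest_intervals_ms + seg.move_intervals_ms)
        assert total == pytest.approx(trial.n_samples, abs=1e-9)


class TestMovementRateTest:
    def test_zero_spikes_is_ns(self, bout_trial):
        _, trial, _ = bout_trial
        seg = segment_movement(trial["treadmill_speed"])
        res = movement_rate_test([_train([])], [seg], 200, seed=0)
        assert res.observed == 0.0 and res.verdict == "ns"

    def test_verdict_stable_across_seeds(self, bout_trial):
        _, trial, _ = bout_trial
        seg = segment_movement(trial["treadmill_speed"])
        rng = np.random.default_rng(7)
        rate = np.where(seg.move_mask, 10.0, 2.0)
        sts = [_train(gen_rate_modulated_spikes(rate, FS, rng))
               for _ in range(3)]
        verdicts = {movement_rate_test(sts, [seg] * 3, 1000, seed=s).verdict
                    for s in range(10)}
        assert verdicts == {"increased"}

    def test_no_usable_trial_returns_none(self, caplog):
        speed = TimeSeries(np.full(6000, 1.0), FS, label="treadmill_speed")
        seg = segment_movement(speed)  # no movement frames
        with caplog.at_level("WARNING", logger="deltatrack"):
            assert movement_rate_test([_train([100.0])], [seg], 100, 0) is None


class TestTransitionTriggeredRate:
    def test_no_events_returns_none(self, caplog):
        with caplog.at_level("WARNING", logger="deltatrack"):
            out = transition_triggered_rate([_train([100.0])],
                                            [np.empty(0)], 6000.0, seed=0)
        assert out is None

    def test_step_neuron_positive_scalar(self, bout_trial):
        _, trial, _ = bout_trial
        seg = segment_movement(trial["treadmill_speed"])
        rng = np.random.default_rng(8)
        rate = np.where(seg.move_mask, 12.0, 4.0)
        sts = [_train(gen_rate_modulated_spikes(rate, FS, rng))
               for _ in range(10)]
        out = transition_triggered_rate(sts, [seg.onsets_ms] * 10, 12_000.0,
                                        seed=9)
        assert out.post_minus_pre_hz > 0
        assert out.scalar_p < 0.05

    def test_homogeneous_neuron_flat_inside_band(self, bout_trial):
        _, trial, _ = bout_trial
        seg = segment_movement(trial["treadmill_speed"])
        rng = np.random.default_rng(10)
        sts = [_train(gen_rate_modulated_spikes(np.full(12_000, 6.0), FS, rng))
               for _ in range(5)]
        out = transition_triggered_rate(sts, [seg.onsets_ms] * 5, 12_000.0,
                                        seed=11)
        assert out.significant.mean() < 0.3


class TestTreadmillDeltaPhase:
    def test_pure_sinusoid_peaks_at_maxima(self):
        t = np.arange(12_000) / FS
        speed = TimeSeries(8 + 3 * np.cos(2 * np.pi * 2.5 * t), FS,
                           label="treadmill_speed")
        _, peaks, _ = treadmill_delta_phase(speed)
        true_peaks = np.arange(0, 12_000, 400.0)
        inner = peaks[(peaks > 1000) & (peaks < 11_000)]
        for p in inner:
            assert np.min(np.abs(true_peaks - p)) <= 2.0

    def test_generator_peak_rate_matches_stepping(self, bout_trial):
        cfg, trial, truth = bout_trial
        seg = segment_movement(trial["treadmill_speed"])
        _, peaks, _ = treadmill_delta_phase(trial["treadmill_speed"],
                                            move_intervals_ms=seg.move_intervals_ms)
        move_ms = sum(b - a for a, b in seg.move_intervals_ms)
        in_move = [p for p in peaks
                   if any(a <= p < b for a, b in seg.move_intervals_ms)]
        rate = len(in_move) / (move_ms / 1000.0)
        assert rate == pytest.approx(cfg.step_delta_hz, rel=0.15)

    def test_rest_only_trace_suppresses_peaks(self, rng):
        x = 1.0 + 0.05 * rng.standard_normal(12_000)
        burst = 3 * np.sin(2 * np.pi * 2.5 * np.arange(2000) / FS)
        x[2000:4000] += burst  # one strong epoch defines the envelope reference
        speed = TimeSeries(x, FS, label="treadmill_speed")
        _, peaks, valid = treadmill_delta_phase(
            speed, move_intervals_ms=[(2000.0, 4000.0)])
        outside = peaks[(peaks > 5000)]
        assert outside.size < 5  # noise-floor peaks suppressed
        assert valid[2500:3500].all()


class TestSteppingLockedRate:
    def test_preferred_phase_recovered(self, bout_trial):
        _, trial, _ = bout_trial
        seg = segment_movement(trial["treadmill_speed"])
        phase, peaks, valid = treadmill_delta_phase(
            trial["treadmill_speed"], move_intervals_ms=seg.move_intervals_ms)
        rng = np.random.default_rng(12)
        pref = -np.pi / 2
        rate = np.where(seg.move_mask & valid,
                        6.0 * np.exp(2.5 * np.cos(phase - pref)) / np.i0(2.5),
                        0.5)
        sts = [_train(gen_rate_modulated_spikes(rate, FS, rng))
               for _ in range(3)]
        out = stepping_locked_rate(sts, [peaks] * 3, [phase] * 3, 12_000.0,
                                   valid_masks=[seg.move_mask & valid] * 3)
        err = np.angle(np.exp(1j * (out["circular"].preferred_phase - pref)))
        assert abs(err) < 0.2
        assert out["normalized_rate"].max() > 1.0

    def test_minimum_window_rule(self, caplog):
        st = _train(np.arange(100, 5000, 200.0))
        peaks = np.linspace(600, 5000, 9)
        phase = np.zeros(6000)
        with caplog.at_level("WARNING", logger="deltatrack"):
            out = stepping_locked_rate([st], [peaks], [phase], 6000.0,
                                       min_windows=10)
        assert out is None


class TestLimbLocomotion:
    def test_stationary_limb_no_periods(self):
        limb = TimeSeries(np.full(6000, 3.0), FS, label="limb_LHL")
        assert limb_locomotion_periods(limb) == []

    def test_threshold_is_strict(self):
        # derivative envelope exactly at threshold must not trigger
        t = np.arange(8000) / FS
        f = 2.0
        amp = 0.1 / (2 * np.pi * f / FS * FS / 1000.0) / FS * 1000.0
        amp = 0.1 * 1000.0 / (2 * np.pi * f)  # peak derivative exactly 0.1/ms
        limb = TimeSeries(amp * np.sin(2 * np.pi * f * t), FS)
        assert limb_locomotion_periods(limb, thresh=0.1) == []
        limb2 = TimeSeries(1.05 * amp * np.sin(2 * np.pi * f * t), FS)
        assert limb_locomotion_periods(limb2, thresh=0.1) != []

    def test_generator_periods_overlap_bouts(self, bout_trial):
        _, trial, truth = bout_trial
        periods = limb_locomotion_periods(trial["limb_LHL"], thresh=0.1)
        covered = np.zeros(trial.n_samples, bool)
        for a, b in periods:
            covered[int(a):int(b)] = True
        true_cov = np.zeros(trial.n_samples, bool)
        for a, b in truth.bout_intervals_ms[0]:
            true_cov[int(a):int(b)] = True
        jaccard = (covered & true_cov).sum() / (covered | true_cov).sum()
        assert jaccard > 0.8


class TestCircularStats:
    def test_identical_phases_highly_significant(self):
        assert omnibus_test(np.zeros(20)) < 0.001

    def test_quadrant_symmetry_not_significant(self):
        p = omnibus_test(np.array([0, np.pi / 2, np.pi, 3 * np.pi / 2]))
        assert p == pytest.approx(1.0)

    def test_calibrated_under_uniformity(self, rng):
        m = 1000
        rej = sum(omnibus_test(rng.uniform(-np.pi, np.pi, 59)) < 0.05
                  for _ in range(m))
        assert rej / m <= 0.06

    def test_circular_mean_wraps(self):
        mu, r = circular_mean(np.array([np.pi - 0.1, -np.pi + 0.1]))
        assert abs(abs(mu) - np.pi) < 1e-9
        assert r == pytest.approx(np.cos(0.1))
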