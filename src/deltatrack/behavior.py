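"""Locomotion analyses: bout segmentation, shuffle-null firing-rate tests,
transition-triggered rates, treadmill delta phase, limb locomotion, and
circular statistics.

Movement bouts are defined on the 1.5 Hz low-passed treadmill speed with a
5 cm/s criterion; rest and movement intervals tile each trial.  Firing-rate
modulation by movement is tested against a null built by drawing random
frame subsets of the same size as the rest (and movement) frames — a neuron
is "increased" when its observed movement-minus-rest rate difference exceeds
the 97.5th percentile of 1000 such draws, "decreased" below the 2.5th.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb

import numpy as np
from scipy import signal as sig

from .config import BehaviorConfig
from .io_core import TimeSeries
from .traces import SpikeTrain

logger = logging.getLogger("deltatrack")


# ---------------------------------------------------------------------------
# circular statistics
# ---------------------------------------------------------------------------

@dataclass
class CircularSummary:
    preferred_phase: float   # radians, (-pi, pi]
    resultant: float         # mean resultant length in [0, 1]
    omnibus_p: float
    n: int


def circular_mean(phases: np.ndarray) -> tuple[float, float]:
    """(mean direction, resultant length) of a sample of angles."""
    vec = np.exp(1j * np.asarray(phases)).mean()
    return float(np.angle(vec)), float(np.abs(vec))


def omnibus_test(phases: np.ndarray, step_deg: float = 1.0) -> float:
    """Hodges-Ajne omnibus test for non-uniformity of circular data.

    The statistic m is the smallest number of observations within any
    half circle.  The exact tail probability (n - 2m) C(n, m) 2^(1-n) is
    used for n <= 50; Ajne's large-sample approximation above.  A sample
    whose every half circle holds exactly half the points (m = n/2) carries
    no evidence against uniformity and returns p = 1.
    """
    phases = np.asarray(phases, dtype=float)
    n = phases.size
    if n < 2:
        return 1.0
    dirs = np.deg2rad(np.arange(0.0, 180.0, step_deg))
    # count of points in the half-plane [d, d + pi) for each direction
    diffs = (phases[None, :] - dirs[:, None]) % (2.0 * np.pi)
    counts = np.count_nonzero(diffs < np.pi, axis=1)
    m = int(np.min(np.minimum(counts, n - counts)))
    if n - 2 * m <= 0:
        return 1.0
    if n <= 50:
        p = (n - 2 * m) * comb(n, m) * 2.0 ** (1 - n)
    else:
        a = np.pi * np.sqrt(n) / (2.0 * (n - 2 * m))
        p = np.sqrt(2.0 * np.pi) / a * np.exp(-np.pi**2 / (8.0 * a**2))
    return float(min(1.0, p))


def circular_summary(phases: np.ndarray) -> CircularSummary:
    mu, r = circular_mean(phases)
    return CircularSummary(mu, r, omnibus_test(phases), np.asarray(phases).size)


# ---------------------------------------------------------------------------
# movement segmentation
# ---------------------------------------------------------------------------

@dataclass
class MovementSegmentation:
    rest_intervals_ms: list      # half-open [a, b)
    move_intervals_ms: list
    onsets_ms: np.ndarray        # rest -> move boundaries
    offsets_ms: np.ndarray
    move_mask: np.ndarray        # per-sample boolean
    rate_hz: float


def _enforce_min_runs(state: np.ndarray, min_len: int) -> np.ndarray:
    """Absorb runs shorter than ``min_len`` into the neighboring state."""
    if min_len <= 1:
        return state
    state = state.copy()
    changed = True
    while changed:
        changed = False
        bounds = np.flatnonzero(np.diff(state.astype(int))) + 1
        edges = np.concatenate([[0], bounds, [state.size]])
        runs = [(edges[i], edges[i + 1]) for i in range(edges.size - 1)]
        if len(runs) <= 1:
            break
        lengths = [b - a for a, b in runs]
        i = int(np.argmin(lengths))
        if lengths[i] < min_len:
            a, b = runs[i]
            state[a:b] = ~state[a]
            changed = True
    return state


def segment_movement(speed: TimeSeries, cfg: BehaviorConfig | None = None
                     ) -> MovementSegmentation:
    """Threshold the low-passed speed into rest / movement intervals.

    Intervals shorter than ``min_bout_ms`` are absorbed into their neighbor
    (threshold flicker suppression); rest and movement intervals tile the
    trial exactly.
    """
    cfg = cfg or BehaviorConfig()
    sos = sig.butter(4, cfg.speed_lowpass_hz, btype="lowpass",
                     fs=speed.rate_hz, output="sos")
    smooth = sig.sosfiltfilt(sos, speed.values)
    move = smooth >= cfg.speed_threshold_cm_s
    min_len = int(round(cfg.min_bout_ms / 1000.0 * speed.rate_hz))
    move = _enforce_min_runs(move, min_len)
    dt = 1000.0 / speed.rate_hz
    bounds = np.flatnonzero(np.diff(move.astype(int))) + 1
    edges = np.concatenate([[0], bounds, [move.size]])
    rest_iv, move_iv, onsets, offsets = [], [], [], []
    for a, b in zip(edges[:-1], edges[1:]):
        iv = (a * dt, b * dt)
        (move_iv if move[a] else rest_iv).append(iv)
    for b in bounds:
        if move[b]:
            onsets.append(b * dt)
        else:
            offsets.append(b * dt)
    return MovementSegmentation(rest_iv, move_iv, np.asarray(onsets),
                                np.asarray(offsets), move, speed.rate_hz)


# ---------------------------------------------------------------------------
# shuffle-null firing-rate tests
# ---------------------------------------------------------------------------

@dataclass
class ShuffleTestResult:
    observed: float
    null_lo: float               # 2.5th percentile
    null_hi: float               # 97.5th percentile
    verdict: str                 # 'increased' | 'decreased' | 'ns'
    p_two_sided: float
    n_shuffles: int
    seed: int | None = None


def _rank_p(observed: float, null: np.ndarray) -> float:
    hi = (np.count_nonzero(null >= observed) + 1) / (null.size + 1)
    lo = (np.count_nonzero(null <= observed) + 1) / (null.size + 1)
    return min(1.0, 2.0 * min(hi, lo))


def movement_rate_test(spike_trains: list[SpikeTrain],
                       segmentations: list[MovementSegmentation],
                       n_shuffles: int = 1000,
                       seed: int | np.random.Generator = 0) -> ShuffleTestResult | None:
    """Movement-minus-rest firing-rate difference against a random-frame null.

    Observed: per-trial movement and rest rates (spikes/s) averaged across
    trials, differenced.  Null: per trial, a random frame subset the size of
    the rest frame count plays the role of rest, and its complement (the
    size of the movement frames) the role of movement.  Frames are drawn
    without replacement and carry at most one spike each, so the selected
    spike count is exactly hypergeometric and is sampled as such; the
    complementary construction makes the null statistic exchangeable with
    the observed one under a homogeneous train.  Verdict follows the
    2.5/97.5 percentile rule.
    """
    rng = np.random.default_rng(seed)
    obs_diffs, trials = [], []
    for st, seg in zip(spike_trains, segmentations, strict=True):
        n_total = seg.move_mask.size
        n_move = int(seg.move_mask.sum())
        n_rest = n_total - n_move
        if n_move == 0 or n_rest == 0:
            continue
        idx = np.clip(np.round(st.spike_times_ms / 1000.0 * seg.rate_hz).astype(int),
                      0, n_total - 1)
        k_move = int(np.count_nonzero(seg.move_mask[idx]))
        n_spk = st.n
        obs_diffs.append(k_move / n_move * seg.rate_hz
                         - (n_spk - k_move) / n_rest * seg.rate_hz)
        trials.append((n_total, n_spk, n_rest, n_move))
    if not trials:
        logger.warning("movement rate test skipped: no trial with both states")
        return None
    observed = float(np.mean(obs_diffs))
    null = np.zeros(n_shuffles)
    for n_total, n_spk, n_rest, n_move in trials:
        k_rest = rng.hypergeometric(n_spk, n_total - n_spk, n_rest, size=n_shuffles)
        k_move = n_spk - k_rest
        null += (k_move / n_move - k_rest / n_rest) * 1000.0
    null /= len(trials)
    lo, hi = np.percentile(null, [2.5, 97.5])
    verdict = "increased" if observed > hi else \
              "decreased" if observed < lo else "ns"
    return ShuffleTestResult(observed, float(lo), float(hi), verdict,
                             _rank_p(observed, null), n_shuffles)


@dataclass
class TriggeredRate:
    lags_ms: np.ndarray          # bin centers
    rate_hz: np.ndarray
    null_lo: np.ndarray
    null_hi: np.ndarray
    significant: np.ndarray
    post_minus_pre_hz: float     # (0..120 ms) minus (-120..0 ms) rate
    scalar_p: float              # rank p of the scalar against its null
    n_events: int


def _event_bin_counts(spike_times: np.ndarray, events: np.ndarray,
                      edges_ms: np.ndarray) -> np.ndarray:
    """Summed spike counts per lag bin over events (vectorized searchsorted)."""
    abs_edges = events[:, None] + edges_ms[None, :]
    pos = np.searchsorted(spike_times, abs_edges)
    return np.diff(pos, axis=1).sum(axis=0)


def transition_triggered_rate(spike_trains: list[SpikeTrain],
                              events_by_trial: list[np.ndarray],
                              trial_len_ms: float,
                              window_ms: float = 500.0, bin_ms: float = 100.0,
                              n_shuffles: int = 1000,
                              scalar_ms: float = 120.0,
                              seed: int | np.random.Generator = 0
                              ) -> TriggeredRate | None:
    """Event-aligned firing rate in 100 ms bins with a shuffled-event null.

    The null redraws the same number of event times uniformly inside each
    trial (1000 repetitions); bins outside the null's 2.5-97.5 percentile
    band are flagged significant.  Also reports the onset-response scalar:
    post-event (0..``scalar_ms``) minus pre-event (-``scalar_ms``..0) rate.
    """
    rng = np.random.default_rng(seed)
    edges = np.arange(-window_ms, window_ms + bin_ms, bin_ms)
    n_bins = edges.size - 1
    obs_counts = np.zeros(n_bins)
    null_counts = np.zeros((n_shuffles, n_bins))
    obs_pre = obs_post = 0.0
    null_pre = np.zeros(n_shuffles)
    null_post = np.zeros(n_shuffles)
    n_events = 0
    for st, events in zip(spike_trains, events_by_trial, strict=True):
        events = np.asarray(events, dtype=float)
        events = events[(events >= window_ms) & (events <= trial_len_ms - window_ms)]
        if events.size == 0:
            continue
        n_events += events.size
        t = st.spike_times_ms
        obs_counts += _event_bin_counts(t, events, edges)
        sc = np.array([-scalar_ms, 0.0, scalar_ms])
        c = _event_bin_counts(t, events, sc)
        obs_pre += c[0]
        obs_post += c[1]
        rand = rng.uniform(window_ms, trial_len_ms - window_ms,
                           size=(n_shuffles, events.size))
        for s in range(n_shuffles):
            null_counts[s] += _event_bin_counts(t, rand[s], edges)
            cc = _event_bin_counts(t, rand[s], sc)
            null_pre[s] += cc[0]
            null_post[s] += cc[1]
    if n_events == 0:
        logger.warning("transition-triggered rate skipped: no usable events")
        return None
    to_hz = 1000.0 / (bin_ms * n_events)
    rate = obs_counts * to_hz
    null_rate = null_counts * to_hz
    lo, hi = np.percentile(null_rate, [2.5, 97.5], axis=0)
    to_hz_sc = 1000.0 / (scalar_ms * n_events)
    scalar = (obs_post - obs_pre) * to_hz_sc
    null_scalar = (null_post - null_pre) * to_hz_sc
    centers = 0.5 * (edges[:-1] + edges[1:])
    return TriggeredRate(centers, rate, lo, hi, (rate > hi) | (rate < lo),
                         float(scalar), _rank_p(scalar, null_scalar), n_events)


# ---------------------------------------------------------------------------
# treadmill delta phase & stepping coupling
# ---------------------------------------------------------------------------

def treadmill_delta_phase(speed: TimeSeries, band_hz: tuple = (1.0, 4.0),
                          move_intervals_ms: list | None = None,
                          env_floor_frac: float = 0.25
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Instantaneous phase of the delta-filtered treadmill speed.

    Returns (phase trace wrapped to (-pi, pi], delta-peak times in ms,
    per-sample validity).  Peaks are phase-zero crossings (cosine
    convention: phase 0 at local maxima); peaks where the band envelope is
    below ``env_floor_frac`` of its movement-period median are suppressed,
    and samples below the floor are marked invalid.
    """
    sos = sig.butter(2, band_hz, btype="bandpass", fs=speed.rate_hz, output="sos")
    x = sig.sosfiltfilt(sos, speed.values)
    analytic = sig.hilbert(x)
    phase_u = np.unwrap(np.angle(analytic))
    env = np.abs(analytic)
    dt = 1000.0 / speed.rate_hz
    if move_intervals_ms:
        sel = np.zeros(env.size, dtype=bool)
        for a, b in move_intervals_ms:
            sel[int(a / dt):int(b / dt)] = True
        ref = np.median(env[sel]) if sel.any() else np.median(env)
    else:
        ref = np.median(env)
    floor = env_floor_frac * ref
    valid = env > floor
    cross = np.flatnonzero(np.diff(np.floor(phase_u / (2 * np.pi))) > 0) + 1
    cross = cross[valid[cross]]
    # sub-sample crossing time by linear interpolation of the phase
    k = np.floor(phase_u[cross] / (2 * np.pi))
    frac = (2 * np.pi * k - phase_u[cross - 1]) \
        / (phase_u[cross] - phase_u[cross - 1])
    peak_times = (cross - 1 + frac) * dt
    phase = np.mod(phase_u + np.pi, 2 * np.pi) - np.pi
    return phase, peak_times, valid


def stepping_locked_rate(spike_trains: list[SpikeTrain],
                         peak_times_by_trial: list[np.ndarray],
                         phase_by_trial: list[np.ndarray],
                         trial_len_ms: float,
                         rate_hz: float = 1000.0,
                         window_ms: float = 500.0, bin_ms: float = 100.0,
                         min_windows: int = 10,
                         valid_masks: list[np.ndarray] | None = None) -> dict | None:
    """Firing rate around treadmill delta peaks, normalized by the mean rate,
    plus the circular summary of spike phases relative to the stepping cycle.

    ``valid_masks`` (e.g. the envelope-validity output of
    :func:`treadmill_delta_phase`) restricts which spikes contribute phases.
    Neurons with fewer than ``min_windows`` delta-peak-triggered windows are
    omitted (returns ``None`` with a logged reason).
    """
    edges = np.arange(-window_ms, window_ms + bin_ms, bin_ms)
    counts = np.zeros(edges.size - 1)
    n_windows = 0
    total_spikes = 0
    total_ms = 0.0
    phis = []
    for st, peaks, phase in zip(spike_trains, peak_times_by_trial,
                                phase_by_trial, strict=True):
        peaks = np.asarray(peaks, dtype=float)
        peaks = peaks[(peaks >= window_ms) & (peaks <= trial_len_ms - window_ms)]
        total_spikes += st.n
        total_ms += trial_len_ms
        if peaks.size:
            counts += _event_bin_counts(st.spike_times_ms, peaks, edges)
            n_windows += peaks.size
        idx = np.round(st.spike_times_ms / 1000.0 * rate_hz).astype(int)
        idx = idx[(idx >= 0) & (idx < phase.size)]
        if valid_masks is not None and valid_masks[len(phis)] is not None:
            idx = idx[np.asarray(valid_masks[len(phis)], dtype=bool)[idx]]
        phis.append(phase[idx])
    if n_windows < min_windows:
        logger.warning("stepping-locked rate skipped: %d windows < minimum %d",
                       n_windows, min_windows)
        return None
    mean_rate = total_spikes / (total_ms / 1000.0)
    rate = counts * 1000.0 / (bin_ms * n_windows)
    norm = rate / mean_rate if mean_rate > 0 else rate
    summary = circular_summary(np.concatenate(phis)) if phis else None
    centers = 0.5 * (edges[:-1] + edges[1:])
    return {"lags_ms": centers, "normalized_rate": norm,
            "circular": summary, "n_windows": n_windows}


def limb_locomotion_periods(limb: TimeSeries, thresh: float = 0.1,
                            min_duration_ms: float = 100.0) -> list:
    """Intervals where the limb-signal derivative's amplitude envelope
    exceeds ``thresh`` (strictly).  Units: signal units per ms at 1 kHz.
    """
    deriv = np.gradient(limb.values) * limb.rate_hz / 1000.0
    env = np.abs(sig.hilbert(deriv))
    # the envelope of a stepping cycle is slow; smoothing removes ripple
    # from interpolation harmonics before the (strict) threshold
    sos = sig.butter(2, min(3.0, 0.4 * limb.rate_hz / 2),
                     btype="lowpass", fs=limb.rate_hz, output="sos")
    env = sig.sosfiltfilt(sos, env)
    active = env > thresh
    min_len = int(round(min_duration_ms / 1000.0 * limb.rate_hz))
    active = _enforce_min_runs(active, min_len)
    bounds = np.flatnonzero(np.diff(active.astype(int))) + 1
    edges = np.concatenate([[0], bounds, [active.size]])
    dt = 1000.0 / limb.rate_hz
    return [(a * dt, b * dt) for a, b in zip(edges[:-1], edges[1:])
            if active[a] and b - a >= min_len]
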