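"""ISI statistics, delta/non-delta classification, bursts, IF distribution.

A neuron is classified *delta-rhythmic* from its inter-spike-interval (ISI)
profile: with A the number of ISIs in the delta band (300-700 ms, i.e.
1.3-3.3 Hz) and B the number in the faster band (80-200 ms, 5-12.5 Hz), the
ISI ratio is (A - B) / (A + B) and a neuron is labelled delta when the ratio
is at least 0.  ISIs never cross trial boundaries.

The instantaneous delta frequency of the subthreshold Vm is obtained by
band-passing (1-6 Hz), taking the Hilbert analytic phase, unwrapping, and
Savitzky-Golay differentiating (polyorder 2, 201 ms frame).  The frequency
distribution's mode and its full width at half maximum (outermost half-
maximum crossings) summarize delta-cycle variability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sig

from .config import RhythmConfig
from .traces import SpikeTrain, VmTrace


@dataclass
class IsiProfile:
    isis_ms: np.ndarray
    return_pairs: np.ndarray     # (n-1, 2): (ISI_n, ISI_{n+1})
    a_count: int
    b_count: int
    ratio: float
    label: str                   # 'delta' | 'non_delta' | 'undefined'


@dataclass
class BurstDecomposition:
    bursts: list                 # list of spike-index arrays (per concatenated train)
    interburst_rate_hz: float
    intraburst_rate_hz: float    # nan when no multi-spike burst exists


@dataclass
class FreqDistribution:
    if_samples_hz: np.ndarray
    bin_centers_hz: np.ndarray
    density: np.ndarray
    peak_hz: float
    fwhm_hz: float


def _trial_isis(spike_trains: list[SpikeTrain]) -> list[np.ndarray]:
    return [np.diff(st.spike_times_ms) for st in spike_trains if st.n >= 2]


def isi_profile(spike_trains: list[SpikeTrain] | SpikeTrain,
                cfg: RhythmConfig | None = None) -> IsiProfile:
    """ISI return map and delta/non-delta label for one neuron.

    Accepts one train or a per-trial list; intervals are formed within trials
    only.  Fewer than ``cfg.min_spikes`` total spikes gives label
    ``'undefined'``.
    """
    cfg = cfg or RhythmConfig()
    if isinstance(spike_trains, SpikeTrain):
        spike_trains = [spike_trains]
    per_trial = _trial_isis(spike_trains)
    isis = np.concatenate(per_trial) if per_trial else np.empty(0)
    pairs = (np.concatenate([np.column_stack([x[:-1], x[1:]]) for x in per_trial
                             if x.size >= 2])
             if any(x.size >= 2 for x in per_trial) else np.empty((0, 2)))
    n_spikes = sum(st.n for st in spike_trains)
    a_lo, a_hi = cfg.isi_a_band_ms
    b_lo, b_hi = cfg.isi_b_band_ms
    a = int(np.count_nonzero((isis >= a_lo) & (isis <= a_hi)))
    b = int(np.count_nonzero((isis >= b_lo) & (isis <= b_hi)))
    if n_spikes < cfg.min_spikes or a + b == 0:
        return IsiProfile(isis, pairs, a, b, float("nan"), "undefined")
    ratio = (a - b) / (a + b)
    label = "delta" if ratio >= 0 else "non_delta"
    return IsiProfile(isis, pairs, a, b, ratio, label)


def burst_decompose(spike_train: SpikeTrain,
                    intraburst_isi_max_ms: float = 80.0) -> BurstDecomposition:
    """Group consecutive spikes with ISI below threshold into bursts.

    Interburst rate = 1 / mean interval between consecutive burst starts;
    intraburst rate = 1 / mean within-burst ISI (NaN if every burst has one
    spike).
    """
    t = spike_train.spike_times_ms
    if t.size == 0:
        return BurstDecomposition([], float("nan"), float("nan"))
    isis = np.diff(t)
    breaks = np.flatnonzero(isis >= intraburst_isi_max_ms) + 1
    bursts = [idx for idx in np.split(np.arange(t.size), breaks)]
    starts = np.array([t[b[0]] for b in bursts])
    inter = (1000.0 / np.mean(np.diff(starts))) if starts.size >= 2 else float("nan")
    within = np.concatenate([np.diff(t[b]) for b in bursts if b.size >= 2]) \
        if any(b.size >= 2 for b in bursts) else np.empty(0)
    intra = 1000.0 / within.mean() if within.size else float("nan")
    return BurstDecomposition(bursts, inter, intra)


def pooled_burst_rates(spike_trains: list[SpikeTrain],
                       intraburst_isi_max_ms: float = 80.0) -> tuple[float, float]:
    """Inter-/intraburst rates pooled over trials (burst intervals never span trials)."""
    inter_iv, intra_iv = [], []
    for st in spike_trains:
        d = burst_decompose(st, intraburst_isi_max_ms)
        t = st.spike_times_ms
        starts = np.array([t[b[0]] for b in d.bursts])
        if starts.size >= 2:
            inter_iv.append(np.diff(starts))
        for b in d.bursts:
            if b.size >= 2:
                intra_iv.append(np.diff(t[b]))
    inter = 1000.0 / np.concatenate(inter_iv).mean() if inter_iv else float("nan")
    intra = 1000.0 / np.concatenate(intra_iv).mean() if intra_iv else float("nan")
    return inter, intra


def spike_autocorrelogram(spike_trains: list[SpikeTrain] | SpikeTrain,
                          lag_min_ms: float = 3.0, lag_max_ms: float = 2500.0,
                          bin_ms: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Spike-train autocorrelation histogram at positive lags.

    Returns (lag bin centers, counts per spike).  The zero-lag peak (a spike's
    perfect correlation with itself) is excluded by starting at ``lag_min_ms``.
    """
    if isinstance(spike_trains, SpikeTrain):
        spike_trains = [spike_trains]
    edges = np.arange(lag_min_ms, lag_max_ms + bin_ms, bin_ms)
    counts = np.zeros(edges.size - 1)
    n_spikes = 0
    for st in spike_trains:
        t = st.spike_times_ms
        n_spikes += t.size
        for i in range(t.size):
            lags = t[i + 1:] - t[i]
            lags = lags[(lags >= lag_min_ms) & (lags < lag_max_ms)]
            if lags.size:
                counts += np.histogram(lags, bins=edges)[0]
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts / max(n_spikes, 1)


def vm_autocorrelogram(vm: VmTrace, lag_min_ms: float = 3.0,
                       lag_max_ms: float = 2500.0) -> tuple[np.ndarray, np.ndarray]:
    """Normalized Vm autocorrelation at lags ``lag_min_ms``..``lag_max_ms``."""
    x = vm.values - vm.values.mean()
    n = x.size
    max_lag = min(int(lag_max_ms / 1000.0 * vm.rate_hz), n - 1)
    full = sig.correlate(x, x, mode="full")[n - 1:]
    # unbiased: divide out the overlap taper, normalize to unit zero lag
    unbiased = full[:max_lag + 1] / (n - np.arange(max_lag + 1))
    unbiased /= full[0] / n
    lags_ms = np.arange(max_lag + 1) / vm.rate_hz * 1000.0
    keep = lags_ms >= lag_min_ms
    return lags_ms[keep], unbiased[keep]


def _segment_runs(mask_good: np.ndarray, min_len: int) -> list[slice]:
    """Contiguous True runs of at least ``min_len`` samples."""
    padded = np.diff(np.concatenate([[0], mask_good.astype(int), [0]]))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    return [slice(a, b) for a, b in zip(starts, ends) if b - a >= min_len]


def instantaneous_frequency(vm: VmTrace, cfg: RhythmConfig | None = None,
                            exclusion_mask: np.ndarray | None = None
                            ) -> FreqDistribution:
    """Instantaneous delta-frequency distribution of the Vm.

    Band-pass -> analytic signal -> unwrapped phase -> Savitzky-Golay first
    derivative.  Excluded-sample gaps split the trace; segments shorter than
    1 s are dropped.  The histogram (0.1 Hz bins over the band) is smoothed
    with a 3-bin mean before taking the mode; FWHM spans the outermost bins
    still at or above half the maximum.
    """
    cfg = cfg or RhythmConfig()
    lo, hi = cfg.if_band_hz
    if hi >= vm.rate_hz / 2:
        raise ValueError("band upper edge at or above Nyquist")
    good = np.ones(vm.values.size, dtype=bool) if exclusion_mask is None \
        else ~np.asarray(exclusion_mask, dtype=bool)
    min_len = int(1.0 * vm.rate_hz)
    win = int(round(cfg.if_savgol_window_ms / 1000.0 * vm.rate_hz))
    win += 1 - win % 2  # odd
    sos = sig.butter(3, (lo, hi), btype="bandpass", fs=vm.rate_hz, output="sos")
    if_all = []
    for seg in _segment_runs(good, max(min_len, 2 * win)):
        x = sig.sosfiltfilt(sos, vm.values[seg])
        phase = np.unwrap(np.angle(sig.hilbert(x)))
        inst = sig.savgol_filter(phase, win, cfg.if_savgol_polyorder,
                                 deriv=1, delta=1.0 / vm.rate_hz) / (2.0 * np.pi)
        if_all.append(inst[win // 2: -win // 2 or None])  # drop filter edges
    if not if_all:
        raise ValueError("no unmasked Vm segment of at least 1 s")
    samples = np.concatenate(if_all)
    return if_distribution(samples, (lo, hi), cfg.if_hist_bin_hz)


def if_distribution(samples: np.ndarray, band: tuple,
                    bin_hz: float = 0.1) -> FreqDistribution:
    """Histogram, mode, and FWHM of instantaneous-frequency samples.

    The mode is taken on a 3-bin-mean smoothed histogram (stabilizes the
    peak); the FWHM spans the outermost raw-histogram bins at or above half
    the raw maximum.
    """
    lo, hi = band
    samples = samples[(samples >= lo) & (samples <= hi)]
    edges = np.arange(lo, hi + bin_hz, bin_hz)
    hist, _ = np.histogram(samples, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    smooth = np.convolve(hist, np.ones(3) / 3.0, mode="same")
    peak_idx = int(np.argmax(smooth))
    half = hist.max() / 2.0
    above = np.flatnonzero(hist >= half)
    fwhm = float(centers[above[-1]] - centers[above[0]]) if above.size \
        else float("nan")
    return FreqDistribution(samples, centers, hist, float(centers[peak_idx]), fwhm)
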