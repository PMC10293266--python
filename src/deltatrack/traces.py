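"""Fluorescence trace processing: detrend, baseline, spikes, SBR, Vm.

The processing chain for each trial:

1. photobleach correction — subtract a moving-average smoothed copy;
2. baseline estimation — ±100-frame moving mean, clip values above it,
   re-smooth (a spike-free subthreshold baseline);
3. spike detection — zero-phase >120 Hz high-pass, threshold at 4 SD of the
   subthreshold fluctuation (SD re-estimated once with supra-threshold
   samples masked), 3 ms refractory;
4. spike-to-baseline ratio (SBR) — mean spike amplitude (peak minus the
   lowest value within the three preceding samples) over the SD of the Vm
   trace; trials with SBR < 5 are excluded;
5. subthreshold Vm — ±3 samples around each spike peak replaced by linear
   interpolation from the surrounding samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sig
from scipy.ndimage import uniform_filter1d

from .config import SpikeDetectionConfig
from .io_core import TimeSeries


@dataclass
class SpikeTrain:
    """Detected spikes of one neuron, one trial."""

    spike_times_ms: np.ndarray
    peak_indices: np.ndarray
    amplitudes: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        if self.spike_times_ms.size and np.any(np.diff(self.spike_times_ms) <= 0):
            raise ValueError("spike times must be strictly increasing")

    @property
    def n(self) -> int:
        return self.spike_times_ms.size


@dataclass
class VmTrace:
    """Spike-removed subthreshold trace on the trial grid."""

    values: np.ndarray
    rate_hz: float
    interpolated_mask: np.ndarray = field(default=None)

    def as_timeseries(self, label: str = "vm") -> TimeSeries:
        return TimeSeries(self.values, self.rate_hz, label=label)


@dataclass
class SbrReport:
    sbr: float
    excluded: bool
    n_spikes: int


def detrend(trace: TimeSeries, window_ms: float = 1000.0) -> TimeSeries:
    """Subtract the moving-average smoothed trace (photobleach correction)."""
    w = int(round(window_ms / 1000.0 * trace.rate_hz))
    if trace.n <= w:
        raise ValueError(f"trace ({trace.n} samples) shorter than detrend window ({w})")
    smooth = uniform_filter1d(trace.values, size=w, mode="nearest")
    return TimeSeries(trace.values - smooth, trace.rate_hz,
                      t0_ms=trace.t0_ms, label=trace.label)


def estimate_baseline(trace: TimeSeries, halfwin_frames: int = 100) -> TimeSeries:
    """Spike-free subthreshold baseline.

    Two passes: a ±``halfwin_frames`` moving mean ("smoothed trace", ST),
    then values above the ST are replaced by the ST (removing spike
    contributions) and the result re-smoothed.
    """
    w = 2 * halfwin_frames + 1
    if trace.n <= w:
        raise ValueError("trace shorter than the baseline window")
    st = uniform_filter1d(trace.values, size=w, mode="nearest")
    clipped = np.minimum(trace.values, st)
    baseline = uniform_filter1d(clipped, size=w, mode="nearest")
    return TimeSeries(baseline, trace.rate_hz, t0_ms=trace.t0_ms, label="baseline")


def _highpass(x: np.ndarray, rate_hz: float, corner_hz: float, order: int) -> np.ndarray:
    sos = sig.butter(order, corner_hz, btype="highpass", fs=rate_hz, output="sos")
    return sig.sosfiltfilt(sos, x)


def detect_spikes(trace: TimeSeries, cfg: SpikeDetectionConfig | None = None) -> SpikeTrain:
    """Threshold-crossing spike detection on the high-passed trace.

    The threshold is ``threshold_sd`` times the SD of the subthreshold
    fluctuation: the SD of the high-passed trace is estimated, samples beyond
    that preliminary threshold are masked, and the SD re-estimated once.
    Spike times are local maxima separated by at least the refractory period.
    """
    cfg = cfg or SpikeDetectionConfig()
    if trace.rate_hz < 500:
        raise ValueError("spike detection needs >= 500 Hz sampling")
    hp = _highpass(trace.values, trace.rate_hz, cfg.highpass_hz, cfg.highpass_order)
    sd0 = hp.std()
    if sd0 == 0:
        return SpikeTrain(np.empty(0), np.empty(0, int), np.empty(0), trace.rate_hz)
    sub = hp[np.abs(hp) < cfg.threshold_sd * sd0]
    sd = sub.std() if sub.size > 10 else sd0
    thr = cfg.threshold_sd * sd
    distance = max(1, int(round(cfg.refractory_ms / 1000.0 * trace.rate_hz)))
    peaks, props = sig.find_peaks(hp, height=thr, distance=distance)
    times = trace.t0_ms + peaks / trace.rate_hz * 1000.0
    return SpikeTrain(times, peaks, props["peak_heights"], trace.rate_hz)


def extract_vm(trace: TimeSeries, spikes: SpikeTrain,
               halfwin: int = 3) -> VmTrace:
    """Remove ±``halfwin`` samples around each spike peak, interpolate linearly.

    Overlapping removal windows (doublets) merge into one gap; interpolation
    anchors on the surviving samples, so a spike on a linear ramp is replaced
    by the ramp exactly.
    """
    removed = np.zeros(trace.n, dtype=bool)
    for p in spikes.peak_indices:
        removed[max(0, p - halfwin):min(trace.n, p + halfwin + 1)] = True
    vals = trace.values.copy()
    if removed.any() and not removed.all():
        good = np.flatnonzero(~removed)
        bad = np.flatnonzero(removed)
        vals[bad] = np.interp(bad, good, vals[good])
    return VmTrace(vals, trace.rate_hz, interpolated_mask=removed)


def compute_sbr(trace: TimeSeries, spikes: SpikeTrain, vm: VmTrace,
                sbr_min: float = 5.0) -> SbrReport:
    """Spike-to-baseline ratio of one trial.

    Per-spike amplitude: peak fluorescence minus the lowest value within the
    three samples before the peak.  SBR = mean amplitude / SD of the Vm over
    the whole trial.  Trials without spikes or with SBR below ``sbr_min`` are
    flagged excluded.
    """
    if spikes.n == 0:
        return SbrReport(sbr=float("nan"), excluded=True, n_spikes=0)
    amps = []
    for p in spikes.peak_indices:
        lo = max(0, p - 3)
        prior = trace.values[lo:p]
        if prior.size == 0:
            continue
        amps.append(trace.values[p] - prior.min())
    if not amps:
        return SbrReport(sbr=float("nan"), excluded=True, n_spikes=spikes.n)
    sd_vm = vm.values.std()
    sbr = float(np.mean(amps) / sd_vm) if sd_vm > 0 else float("inf")
    return SbrReport(sbr=sbr, excluded=bool(sbr < sbr_min), n_spikes=spikes.n)


def process_trial(trace: TimeSeries, cfg: SpikeDetectionConfig | None = None
                  ) -> tuple[SpikeTrain, VmTrace, SbrReport]:
    """Full per-trial chain: detrend -> detect -> Vm -> SBR."""
    cfg = cfg or SpikeDetectionConfig()
    flat = detrend(trace, cfg.detrend_window_ms)
    spikes = detect_spikes(flat, cfg)
    vm = extract_vm(flat, spikes, cfg.spike_removal_halfwin)
    sbr = compute_sbr(flat, spikes, vm, cfg.sbr_min)
    return spikes, vm, sbr
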