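"""Morlet spectrograms, spike phase locking (PLV / PLVu2), event-triggered
power, and coherence with a randomization null.

Phase locking of spikes to an oscillation is quantified by the phase-locking
value

    PLV(f) = | (1/N) sum_n exp(i * phi(f, n)) |

over the N spike phases phi(f, n) taken from the complex Morlet spectrum.
Because PLV inflates at low spike counts (E[PLV^2] = 1/N under uniform
phases), the bias-corrected squared PLV

    PLVu2(f) = (PLV(f)^2 * N - 1) / (N - 1)

is used for comparisons across neurons; it has expectation 0 for uniform
phases at any N and converges to PLV^2 as N grows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal as sig

from .config import SpectralConfig
from .io_core import TimeSeries
from .traces import SpikeTrain

logger = logging.getLogger("deltatrack")


def default_freq_grid(cfg: SpectralConfig | None = None) -> np.ndarray:
    cfg = cfg or SpectralConfig()
    return np.geomspace(cfg.freq_min_hz, cfg.freq_max_hz, cfg.n_freqs)


def _morlet_name(cycles: float) -> str:
    # 'cmorB-C' with C = 1: sigma_t(f) = sqrt(B/2)/f  ->  B = cycles^2/(2 pi^2)
    bandwidth = cycles**2 / (2.0 * np.pi**2)
    return f"cmor{bandwidth:.6f}-1.0"


@dataclass
class WaveletSpectrogram:
    freqs_hz: np.ndarray
    power: np.ndarray        # (n_freq, n_time)
    phase: np.ndarray        # radians in (-pi, pi]
    valid: np.ndarray        # False within one wavelet SD of the edges
    rate_hz: float


def wavelet_spectrogram(values: np.ndarray | TimeSeries, rate_hz: float | None = None,
                        freqs_hz: np.ndarray | None = None,
                        cycles: float = 7.0) -> WaveletSpectrogram:
    """Complex Morlet transform: power, phase, and edge-validity flags."""
    if isinstance(values, TimeSeries):
        rate_hz = values.rate_hz
        values = values.values
    if rate_hz is None:
        raise ValueError("rate_hz required for array input")
    freqs_hz = default_freq_grid() if freqs_hz is None else np.asarray(freqs_hz, float)
    n = values.size
    if n < 3 * rate_hz / freqs_hz.min():
        raise ValueError("signal shorter than 3 cycles of the lowest frequency")
    scales = rate_hz / freqs_hz  # C = 1
    coef, _ = pywt.cwt(values.astype(float), scales, _morlet_name(cycles),
                       sampling_period=1.0 / rate_hz, method="fft")
    power = np.abs(coef) ** 2
    phase = np.angle(coef)
    valid = np.ones((freqs_hz.size, n), dtype=bool)
    for i, f in enumerate(freqs_hz):
        edge = int(np.ceil(cycles / (2.0 * np.pi * f) * rate_hz))  # one SD
        if edge > 0:
            valid[i, :edge] = False
            valid[i, n - edge:] = False
    return WaveletSpectrogram(freqs_hz, power, phase, valid, rate_hz)


# ---------------------------------------------------------------------------
# phase locking
# ---------------------------------------------------------------------------

@dataclass
class SpikePhaseSet:
    freqs_hz: np.ndarray
    phi: np.ndarray          # (n_freq, N) spike phases
    n_spikes: int


@dataclass
class PhaseLockingResult:
    freqs_hz: np.ndarray
    plv: np.ndarray
    plvu2: np.ndarray
    preferred_phase: np.ndarray
    n_spikes: int


def plv_from_phases(phi: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(plv, plvu2, preferred phase) from a (..., N) phase array."""
    phi = np.asarray(phi)
    n = phi.shape[-1]
    if n < 2:
        raise ValueError("need at least 2 phases")
    mean_vec = np.exp(1j * phi).mean(axis=-1)
    plv = np.abs(mean_vec)
    plvu2 = (plv**2 * n - 1.0) / (n - 1.0)
    return plv, plvu2, np.angle(mean_vec)


def spike_phases(spike_trains: list[SpikeTrain], spectra: list[WaveletSpectrogram],
                 exclusion_masks: list[np.ndarray] | None = None) -> SpikePhaseSet:
    """Gather per-frequency phases at spike samples across trials.

    Spikes on edge-invalid or excluded samples are dropped for all
    frequencies jointly (using the lowest frequency's validity span, the
    widest) so every frequency sees the same spike set and N.
    """
    cols = []
    freqs = spectra[0].freqs_hz
    widest = int(np.argmin(freqs))
    for k, (st, sp) in enumerate(zip(spike_trains, spectra, strict=True)):
        idx = np.round(st.spike_times_ms / 1000.0 * sp.rate_hz).astype(int)
        idx = idx[(idx >= 0) & (idx < sp.power.shape[1])]
        ok = sp.valid[widest, idx]
        if exclusion_masks is not None and exclusion_masks[k] is not None:
            ok &= ~np.asarray(exclusion_masks[k], dtype=bool)[idx]
        cols.append(sp.phase[:, idx[ok]])
    phi = np.concatenate(cols, axis=1) if cols else np.empty((freqs.size, 0))
    return SpikePhaseSet(freqs, phi, phi.shape[1])


def spike_phase_locking(spike_trains: list[SpikeTrain],
                        spectra: list[WaveletSpectrogram],
                        min_spikes: int = 10,
                        exclusion_masks: list[np.ndarray] | None = None
                        ) -> PhaseLockingResult | None:
    """Spike PLV and PLVu2 across the wavelet frequency grid.

    Returns ``None`` (with a logged reason) when fewer than ``min_spikes``
    usable spikes remain, mirroring the analysis inclusion rule.
    """
    ps = spike_phases(spike_trains, spectra, exclusion_masks)
    if ps.n_spikes < min_spikes:
        logger.warning("phase locking skipped: %d spikes < minimum %d",
                       ps.n_spikes, min_spikes)
        return None
    plv, plvu2, pref = plv_from_phases(ps.phi)
    return PhaseLockingResult(ps.freqs_hz, plv, plvu2, pref, ps.n_spikes)


def phase_locking_to_phase_trace(spike_trains: list[SpikeTrain],
                                 phase_traces: list[np.ndarray],
                                 rate_hz: float = 1000.0,
                                 min_spikes: int = 10,
                                 valid_masks: list[np.ndarray] | None = None
                                 ) -> tuple[float, float, float, int] | None:
    """PLV/PLVu2 of spikes against a single instantaneous-phase trace
    (e.g. the Hilbert phase of delta-filtered treadmill speed).

    Returns (plv, plvu2, preferred phase, N) or None below ``min_spikes``.
    """
    phis = []
    for k, st in enumerate(spike_trains):
        idx = np.round(st.spike_times_ms / 1000.0 * rate_hz).astype(int)
        idx = idx[(idx >= 0) & (idx < phase_traces[k].size)]
        if valid_masks is not None and valid_masks[k] is not None:
            idx = idx[np.asarray(valid_masks[k], dtype=bool)[idx]]
        phis.append(phase_traces[k][idx])
    phi = np.concatenate(phis) if phis else np.empty(0)
    if phi.size < min_spikes:
        logger.warning("phase locking skipped: %d spikes < minimum %d",
                       phi.size, min_spikes)
        return None
    plv, plvu2, pref = plv_from_phases(phi[None, :])
    return float(plv[0]), float(plvu2[0]), float(pref[0]), phi.size


# ---------------------------------------------------------------------------
# event-triggered spectrograms
# ---------------------------------------------------------------------------

@dataclass
class TriggeredSpectrogram:
    lags_ms: np.ndarray
    freqs_hz: np.ndarray
    power: np.ndarray            # (n_freq, n_lag), normalized
    normalization: str           # 'pre_event' | 'window_mean'
    n_events: int


def triggered_spectrogram(spectra: list[WaveletSpectrogram],
                          event_times_ms: list[np.ndarray],
                          window_ms: float = 250.0,
                          normalization: str = "pre_event",
                          pre_window_ms: tuple = (-200.0, -100.0),
                          min_events: int = 20) -> TriggeredSpectrogram | None:
    """Average wavelet power in ±``window_ms`` around events, normalized.

    Events closer than the window to trial edges are dropped.  Normalization
    divides each frequency row either by its mean pre-event power
    (``pre_window_ms`` before the trigger) or by its mean over the whole
    window.  Fewer than ``min_events`` usable events returns ``None`` with a
    logged reason.
    """
    rate = spectra[0].rate_hz
    half = int(round(window_ms / 1000.0 * rate))
    windows = []
    for sp, events in zip(spectra, event_times_ms, strict=True):
        n = sp.power.shape[1]
        idx = np.round(np.asarray(events) / 1000.0 * rate).astype(int)
        idx = idx[(idx - half >= 0) & (idx + half < n)]
        for i in idx:
            windows.append(sp.power[:, i - half:i + half + 1])
    if len(windows) < min_events:
        logger.warning("triggered spectrogram skipped: %d events < minimum %d",
                       len(windows), min_events)
        return None
    mean_pow = np.mean(windows, axis=0)
    lags_ms = (np.arange(2 * half + 1) - half) / rate * 1000.0
    if normalization == "pre_event":
        sel = (lags_ms >= pre_window_ms[0]) & (lags_ms <= pre_window_ms[1])
        ref = mean_pow[:, sel].mean(axis=1, keepdims=True)
    elif normalization == "window_mean":
        ref = mean_pow.mean(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown normalization '{normalization}'")
    return TriggeredSpectrogram(lags_ms, spectra[0].freqs_hz, mean_pow / ref,
                                normalization, len(windows))


def band_power_at_zero(ts: TriggeredSpectrogram, band_hz: tuple) -> float:
    """Mean normalized power in ``band_hz`` at lag 0 (e.g. spike-peak beta ratio)."""
    fsel = (ts.freqs_hz >= band_hz[0]) & (ts.freqs_hz <= band_hz[1])
    i0 = int(np.argmin(np.abs(ts.lags_ms)))
    return float(ts.power[fsel, i0].mean())


def band_power_contrast(ts_a: TriggeredSpectrogram, ts_b: TriggeredSpectrogram,
                        band_hz: tuple) -> float:
    """Difference of band power at lag 0 between two conditions (a minus b)."""
    return band_power_at_zero(ts_a, band_hz) - band_power_at_zero(ts_b, band_hz)


# ---------------------------------------------------------------------------
# delta-cycle split
# ---------------------------------------------------------------------------

def delta_cycle_split_power(vm_values: np.ndarray, spike_times_ms: np.ndarray,
                            rate_hz: float = 1000.0,
                            delta_band_hz: tuple = (1.0, 4.0),
                            beta_band_hz: tuple = (20.0, 40.0),
                            cycles: float = 7.0) -> dict | None:
    """Beta power at Vm delta-cycle peaks, split by spike occupancy.

    Delta cycles are trough-to-trough intervals of the delta-filtered Vm;
    the normalized beta power (relative to its recording mean) is read at
    each cycle's peak, and cycles are partitioned into those containing at
    least one spike versus none.  Returns ``None`` if either partition is
    empty.
    """
    sos = sig.butter(3, delta_band_hz, btype="bandpass", fs=rate_hz, output="sos")
    delta = sig.sosfiltfilt(sos, vm_values)
    phase = np.unwrap(np.angle(sig.hilbert(delta)))
    peaks = np.flatnonzero(np.diff(np.floor(phase / (2 * np.pi))) > 0) + 1
    troughs = np.flatnonzero(np.diff(np.floor((phase - np.pi) / (2 * np.pi))) > 0) + 1
    if peaks.size < 3 or troughs.size < 3:
        return None
    freqs = np.linspace(beta_band_hz[0], beta_band_hz[1], 8)
    sp = wavelet_spectrogram(vm_values, rate_hz, freqs, cycles)
    beta = sp.power.mean(axis=0)
    beta_norm = beta / beta[sp.valid[0]].mean()
    spike_idx = np.round(np.asarray(spike_times_ms) / 1000.0 * rate_hz).astype(int)
    with_spk, without_spk = [], []
    for a, b in zip(troughs[:-1], troughs[1:]):
        pk = peaks[(peaks >= a) & (peaks < b)]
        if pk.size == 0 or not sp.valid[0, pk[0]]:
            continue
        occupied = np.any((spike_idx >= a) & (spike_idx < b))
        (with_spk if occupied else without_spk).append(beta_norm[pk[0]])
    if not with_spk or not without_spk:
        logger.warning("delta-cycle split: one partition empty "
                       "(%d with, %d without spikes)", len(with_spk), len(without_spk))
        return None
    return {"beta_peak_power_with_spikes": float(np.mean(with_spk)),
            "beta_peak_power_without_spikes": float(np.mean(without_spk)),
            "n_cycles_with": len(with_spk), "n_cycles_without": len(without_spk)}


# ---------------------------------------------------------------------------
# coherence with a time-flip randomization null
# ---------------------------------------------------------------------------

def _welch_segments(x: np.ndarray, nperseg: int) -> np.ndarray:
    """Hann-windowed, 50%-overlap segment spectra (n_seg, n_freq)."""
    step = nperseg // 2
    n_seg = max(1, (x.size - nperseg) // step + 1)
    win = sig.windows.hann(nperseg)
    segs = np.stack([x[i * step:i * step + nperseg] for i in range(n_seg)])
    segs = (segs - segs.mean(axis=1, keepdims=True)) * win
    return np.fft.rfft(segs, axis=1)


def coherence_with_null(x: list[np.ndarray] | np.ndarray,
                        y: list[np.ndarray] | np.ndarray,
                        rate_hz: float = 1000.0,
                        segment_ms: float = 2000.0,
                        n_shuffles: int = 200,
                        seed: int | np.random.Generator = 0) -> dict:
    """Magnitude-squared coherence with a time-reversal shuffle null.

    Welch cross-spectra (Hann segments, 50% overlap) pooled over trials.
    The null destroys the temporal correspondence by time-flipping the
    second signal and randomly permuting segment pairings; ``n_shuffles``
    null curves give a per-frequency 95th-percentile band and significance.
    """
    rng = np.random.default_rng(seed)
    xs = [x] if isinstance(x, np.ndarray) else list(x)
    ys = [y] if isinstance(y, np.ndarray) else list(y)
    nperseg = int(round(segment_ms / 1000.0 * rate_hz))
    fx = np.concatenate([_welch_segments(np.asarray(a, float), nperseg) for a in xs])
    fy = np.concatenate([_welch_segments(np.asarray(b, float), nperseg) for b in ys])
    fy_flip = np.concatenate([_welch_segments(np.asarray(b, float)[::-1], nperseg)
                              for b in ys])
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / rate_hz)

    def coh(a, b):
        sxy = (a * np.conj(b)).mean(axis=0)
        sxx = (np.abs(a) ** 2).mean(axis=0)
        syy = (np.abs(b) ** 2).mean(axis=0)
        return np.abs(sxy) ** 2 / (sxx * syy + 1e-300)

    observed = coh(fx, fy)
    n_seg = fx.shape[0]
    null = np.empty((n_shuffles, freqs.size))
    for s in range(n_shuffles):
        perm = rng.permutation(n_seg)
        null[s] = coh(fx, fy_flip[perm])
    upper = np.percentile(null, 95, axis=0)
    return {"freqs_hz": freqs, "coherence": observed, "null_95": upper,
            "significant": observed > upper, "n_segments": n_seg}
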