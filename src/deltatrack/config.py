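"""Pipeline configuration: every tunable threshold in one serializable object."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml


def _from_mapping(cls, data: dict):
    """Build a dataclass from a mapping, rejecting unknown keys."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {name: data[name] for name in names if name in data}
    return cls(**kwargs)


@dataclass
class SpikeDetectionConfig:
    highpass_hz: float = 120.0        # spike-band high-pass corner
    highpass_order: int = 4           # Butterworth, zero-phase
    threshold_sd: float = 4.0         # multiples of subthreshold SD
    refractory_ms: float = 3.0
    detrend_window_ms: float = 1000.0
    baseline_halfwin_frames: int = 100  # ±100-frame smoothed-trace window
    spike_removal_halfwin: int = 3      # ±3 samples replaced around each peak
    sbr_min: float = 5.0                # trials below this SBR are excluded


@dataclass
class RhythmConfig:
    isi_a_band_ms: tuple = (300.0, 700.0)   # delta-scale ISIs (1.3-3.3 Hz)
    isi_b_band_ms: tuple = (80.0, 200.0)    # faster ISIs (5-12.5 Hz)
    min_spikes: int = 3
    burst_isi_max_ms: float = 80.0
    if_band_hz: tuple = (1.0, 6.0)
    if_savgol_window_ms: int = 201
    if_savgol_polyorder: int = 2
    if_hist_bin_hz: float = 0.1
    acg_lag_min_ms: float = 3.0
    acg_lag_max_ms: float = 2500.0


@dataclass
class SpectralConfig:
    morlet_cycles: float = 7.0
    freq_min_hz: float = 1.0
    freq_max_hz: float = 140.0
    n_freqs: int = 60                 # log-spaced grid
    min_spikes_plv: int = 10
    min_triggered_events: int = 20
    trigger_window_ms: float = 250.0
    pre_event_norm_ms: tuple = (-200.0, -100.0)
    beta_band_hz: tuple = (20.0, 40.0)
    gamma_band_hz: tuple = (70.0, 100.0)
    coherence_segment_ms: float = 2000.0
    coherence_n_shuffles: int = 200


@dataclass
class BehaviorConfig:
    speed_lowpass_hz: float = 1.5
    speed_threshold_cm_s: float = 5.0
    min_bout_ms: float = 200.0        # 0 disables minimum interval length
    n_shuffles: int = 1000
    transition_window_ms: float = 500.0
    transition_bin_ms: float = 100.0
    onset_scalar_ms: float = 120.0    # post-onset minus pre-onset rate window
    tread_delta_band_hz: tuple = (1.0, 4.0)
    delta_peak_env_frac: float = 0.25  # envelope floor rel. to movement median
    min_delta_peak_windows: int = 10
    limb_envelope_thresh: float = 0.1


@dataclass
class ImagingConfig:
    px_size_um: float = 0.325         # 6.5 um sensor px, 2x2 binning, 40x objective
    motion_thresh_um_per_ms: float = 0.065
    subpixel: bool = False            # Fourier-upsampled (x10) shifts if True
    upsample_factor: int = 10
    max_shift_px: int = 10


@dataclass
class PipelineConfig:
    """Top-level configuration; defaults are the analysis defaults."""

    seed: int = 0
    spike: SpikeDetectionConfig = field(default_factory=SpikeDetectionConfig)
    rhythm: RhythmConfig = field(default_factory=RhythmConfig)
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    behavior: BehaviorConfig = field(default_factory=BehaviorConfig)
    imaging: ImagingConfig = field(default_factory=ImagingConfig)

    _nested = {
        "spike": SpikeDetectionConfig,
        "rhythm": RhythmConfig,
        "spectral": SpectralConfig,
        "behavior": BehaviorConfig,
        "imaging": ImagingConfig,
    }

    def to_dict(self) -> dict:
        def conv(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: conv(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return conv(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in data:
                continue
            val = data.pop(f.name)
            sub = cls._nested.get(f.name)
            if sub is not None:
                subval = _from_mapping(sub, val)
                # YAML has no tuple type; restore tuples for band fields
                for sf in dataclasses.fields(sub):
                    v = getattr(subval, sf.name)
                    if isinstance(v, list):
                        setattr(subval, sf.name, tuple(v))
                val = subval
            kwargs[f.name] = val
        if data:
            raise ValueError(f"unknown config keys: {sorted(data)}")
        return cls(**kwargs)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
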