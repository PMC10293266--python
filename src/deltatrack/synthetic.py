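"""Ground-truthed synthetic recordings.

Emulates the statistical structure of somatic voltage-imaging sessions from
head-fixed mice on a spherical treadmill: delta-rhythmic (1-4 Hz) subthreshold
membrane-voltage (Vm) oscillations with drifting instantaneous frequency,
beta-rate spike bursts riding delta peaks, tonically regular control neurons,
delta-phase-nested beta/gamma LFP, movement bouts with delta-rhythmic speed
fluctuations, anti-phase hindlimb cycles, photobleaching, sensor noise, and
rigid frame jitter.  Every generator returns the hidden truth (spike times,
delta phase, bout boundaries, frame shifts) so each analysis stage can be
scored against it.

Quasi-periodicity model: the instantaneous delta frequency follows an
Ornstein-Uhlenbeck process with stationary mean ``delta_center_hz`` and
stationary SD ``delta_fwhm_hz / 2.3548``, so the frequency distribution has
the configured full width at half maximum.  Spike bursts are triggered near
delta peaks with a Bernoulli skip probability, giving occasional skipped
cycles.  Fluorescence noise is white Gaussian (configurable SD); spike
transients are short positive deflections whose amplitude is expressed in
units of the noise SD, making the spike-to-baseline ratio directly
controllable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sig

from .io_core import TimeSeries, Trial, AlignedRecording, align_and_resample

MASTER_RATE_HZ = 1000.0
_FWHM_PER_SD = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548


@dataclass
class SyntheticConfig:
    """Knobs of the generator; defaults are the emulated study conditions."""

    seed: int = 0
    n_trials: int = 5
    trial_len_ms: float = 12_000.0        # 12 s trials

    # Vm delta rhythm
    delta_center_hz: float = 2.3
    delta_fwhm_hz: float = 1.5
    ou_tau_s: float = 1.0                 # correlation time of the frequency drift
    vm_delta_amp: float = 2.0             # in noise-SD units
    vm_beta_amp: float = 0.0              # delta-nested Vm beta (off by default)
    drift_amp: float = 0.5

    # spiking
    intraburst_rate_hz: float = 25.0
    spikes_per_burst: tuple = (2, 4)
    burst_skip_prob: float = 0.2
    intraburst_jitter_cv: float = 0.08
    burst_time_jitter_ms: float = 25.0
    tonic_rate_hz: float = 8.0
    tonic_jitter_cv: float = 0.1

    # fluorescence
    fluor_rate_hz: float = 833.0
    # transient amplitude in noise-SD units; 14 renders sessions at a
    # spike-to-baseline ratio ~8, i.e. >= 7 even at end-of-trial bleach
    spike_amp_sd_units: float = 14.0
    noise_sd: float = 1.0
    bleach_tau_s: float = 30.0
    f0: float = 100.0                     # baseline fluorescence level

    # LFP
    lfp_pink_sd: float = 1.0
    lfp_delta_amp: float = 1.5
    lfp_beta_amp: float = 0.8
    lfp_gamma_amp: float = 0.5
    lfp_beta_depth: float = 0.8           # delta-phase modulation of 20-40 Hz amp
    lfp_gamma_depth: float = 0.5

    # locomotion
    bout_schedule: tuple = ((3000.0, 3000.0),)  # (rest_ms, move_ms) pairs, tiled
    rest_speed_cm_s: float = 1.0
    move_speed_cm_s: float = 12.0
    step_delta_hz: float = 2.5
    step_amp_cm_s: float = 3.0
    speed_criterion_cm_s: float = 5.0    # rest/movement boundary criterion
    speed_noise_sd: float = 0.3
    speed_rate_hz: float = 20.0
    ramp_ms: float = 250.0
    limb_rate_hz: float = 120.0
    limb_amp: float = 10.0
    limb_noise_sd: float = 0.2
    limb_phase_lag_rad: float = np.pi     # hindlimbs alternate

    # imaging
    frame_shape: tuple = (48, 64)
    blob_sigma_px: float = 6.0
    max_shift_px: int = 3
    sensor_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("delta_center_hz", "intraburst_rate_hz", "tonic_rate_hz",
                     "step_delta_hz", "fluor_rate_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("lfp_beta_depth", "lfp_gamma_depth"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class SyntheticGroundTruth:
    """Hidden state emitted alongside generated signals (per trial lists)."""

    spike_times_ms: list = field(default_factory=list)
    delta_phase: list = field(default_factory=list)     # 1 kHz, wrapped (-pi, pi]
    vm_master: list = field(default_factory=list)       # true spike-free Vm, 1 kHz
    burst_start_times_ms: list = field(default_factory=list)
    bout_intervals_ms: list = field(default_factory=list)  # movement [a, b) per trial
    onsets_ms: list = field(default_factory=list)
    offsets_ms: list = field(default_factory=list)
    frame_shifts_px: list = field(default_factory=list)
    step_peak_times_ms: list = field(default_factory=list)
    step_phase: list = field(default_factory=list)      # 1 kHz, wrapped


def _wrap(phi: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    out = np.mod(phi + np.pi, 2.0 * np.pi) - np.pi
    out[out == -np.pi] = np.pi
    return out


def _ou_frequency(n: int, dt_s: float, mu: float, sd: float, tau_s: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Exact-discretization OU path, clipped away from zero."""
    a = np.exp(-dt_s / tau_s)
    innov = rng.standard_normal(n) * sd * np.sqrt(1.0 - a * a)
    f = np.empty(n)
    f[0] = mu + sd * rng.standard_normal()
    for k in range(1, n):
        f[k] = mu + a * (f[k - 1] - mu) + innov[k]
    return np.clip(f, 0.3, 8.0)


def _bandpassed_noise(n: int, rate_hz: float, band: tuple, rng) -> np.ndarray:
    """Unit-SD Gaussian noise band-limited to ``band`` (Hz)."""
    sos = sig.butter(4, band, btype="bandpass", fs=rate_hz, output="sos")
    x = sig.sosfiltfilt(sos, rng.standard_normal(n + 2000))[1000:-1000]
    sd = x.std()
    return x / sd if sd > 0 else x


def _pink_noise(n: int, rate_hz: float, rng) -> np.ndarray:
    """Unit-SD 1/f-power noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / rate_hz)
    scale = np.ones_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n)
    return x / x.std()


def _slow_drift(n: int, rate_hz: float, amp: float, rng) -> np.ndarray:
    if amp == 0:
        return np.zeros(n)
    sos = sig.butter(2, 0.3, btype="lowpass", fs=rate_hz, output="sos")
    x = sig.sosfiltfilt(sos, rng.standard_normal(n + 4000))[2000:-2000]
    return amp * x / max(x.std(), 1e-12)


def _delta_phase_trial(cfg: SyntheticConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    """Return (unwrapped phase, instantaneous frequency) on the 1 kHz grid."""
    n = int(round(cfg.trial_len_ms / 1000.0 * MASTER_RATE_HZ))
    dt = 1.0 / MASTER_RATE_HZ
    freq = _ou_frequency(n, dt, cfg.delta_center_hz,
                         cfg.delta_fwhm_hz / _FWHM_PER_SD, cfg.ou_tau_s, rng)
    phi0 = rng.uniform(-np.pi, np.pi)
    phase = phi0 + 2.0 * np.pi * np.cumsum(freq) * dt
    return phase, freq


def _burst_spikes(cfg: SyntheticConfig, phase_unwrapped: np.ndarray,
                  rng) -> tuple[np.ndarray, np.ndarray]:
    """Spike and burst-start times (ms) from delta-peak-triggered bursts."""
    dt_ms = 1000.0 / MASTER_RATE_HZ
    # delta peaks: unwrapped phase crosses multiples of 2*pi
    k = np.floor(phase_unwrapped / (2.0 * np.pi))
    cross = np.flatnonzero(np.diff(k) > 0) + 1
    peak_times = cross * dt_ms
    spikes: list[float] = []
    burst_starts: list[float] = []
    mean_isi = 1000.0 / cfg.intraburst_rate_hz
    lo, hi = int(cfg.spikes_per_burst[0]), int(cfg.spikes_per_burst[1])
    t_max = len(phase_unwrapped) * dt_ms
    for pt in peak_times:
        if rng.uniform() < cfg.burst_skip_prob:
            continue
        n_sp = int(rng.integers(lo, hi + 1))
        isis = mean_isi * (1.0 + cfg.intraburst_jitter_cv * rng.standard_normal(n_sp - 1))
        isis = np.clip(isis, 4.0, None) if n_sp > 1 else np.empty(0)
        start = pt - isis.sum() / 2.0 + rng.uniform(-1, 1) * cfg.burst_time_jitter_ms
        times = start + np.concatenate([[0.0], np.cumsum(isis)])
        times = times[(times > 5.0) & (times < t_max - 5.0)]
        if times.size:
            burst_starts.append(times[0])
            spikes.extend(times)
    spikes = np.sort(np.asarray(spikes))
    keep = np.ones(spikes.size, dtype=bool)
    last = -np.inf
    for i, t in enumerate(spikes):  # enforce a 4 ms minimum separation
        if t - last < 4.0:
            keep[i] = False
        else:
            last = t
    return spikes[keep], np.asarray(burst_starts)


def _tonic_spikes(cfg: SyntheticConfig, rng) -> np.ndarray:
    isi = 1000.0 / cfg.tonic_rate_hz
    n_max = int(cfg.trial_len_ms / isi) + 3
    isis = isi * (1.0 + cfg.tonic_jitter_cv * rng.standard_normal(n_max))
    isis = np.clip(isis, 4.0, None)
    times = rng.uniform(0, isi) + np.cumsum(isis)
    return times[(times > 5.0) & (times < cfg.trial_len_ms - 5.0)]


def _render_fluorescence(cfg: SyntheticConfig, vm_master: np.ndarray,
                         spike_times_ms: np.ndarray, rng) -> tuple[TimeSeries, np.ndarray]:
    """Render Vm + spike transients + bleach + noise at the native frame rate.

    Returns the trace and the spike times snapped to native frame peaks
    (the detection oracle).
    """
    t_master = np.arange(vm_master.size) / MASTER_RATE_HZ * 1000.0
    n_native = int(np.floor(t_master[-1] / 1000.0 * cfg.fluor_rate_hz)) + 1
    t_native = np.arange(n_native) / cfg.fluor_rate_hz * 1000.0
    # amplitudes are expressed in noise-SD units; a noiseless trace keeps
    # unit scale so the deterministic structure survives
    unit = cfg.noise_sd if cfg.noise_sd > 0 else 1.0
    vm = np.interp(t_native, t_master, vm_master) * unit

    spikes = np.zeros(n_native)
    amp = cfg.spike_amp_sd_units * unit
    idx = np.round(spike_times_ms / 1000.0 * cfg.fluor_rate_hz).astype(int)
    idx = idx[(idx >= 1) & (idx < n_native - 1)]
    # 2-sample triangular transient (~1-2 ms at the native rate)
    np.add.at(spikes, idx, amp)
    np.add.at(spikes, idx + 1, 0.5 * amp)
    true_times = t_native[idx]

    bleach = np.exp(-t_native / (cfg.bleach_tau_s * 1000.0))
    values = (cfg.f0 * unit + vm + spikes) * bleach
    values = values + cfg.noise_sd * rng.standard_normal(n_native)
    ts = TimeSeries(values, cfg.fluor_rate_hz, t0_ms=0.0, label="fluorescence")
    return ts, true_times


def gen_delta_neuron(cfg: SyntheticConfig,
                     rng: np.random.Generator | int | None = None,
                     ) -> tuple[list[TimeSeries], SyntheticGroundTruth]:
    """Delta-rhythmic neuron: bursty spiking riding Vm delta peaks.

    Returns one fluorescence trace per trial (native frame rate) and the
    ground truth (true spike times, 1 kHz delta phase, burst starts).
    """
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    if cfg.spike_amp_sd_units < 5:
        import warnings
        warnings.warn("spike amplitude below 5 noise SDs; spikes may be undetectable")
    traces: list[TimeSeries] = []
    truth = SyntheticGroundTruth()
    for _ in range(cfg.n_trials):
        phase, _freq = _delta_phase_trial(cfg, rng)
        n = phase.size
        vm = cfg.vm_delta_amp * np.cos(phase)
        vm += _slow_drift(n, MASTER_RATE_HZ, cfg.drift_amp, rng)
        if cfg.vm_beta_amp > 0:
            carrier = _bandpassed_noise(n, MASTER_RATE_HZ, (20.0, 40.0), rng)
            vm += cfg.vm_beta_amp * 0.5 * (1.0 + np.cos(phase)) * carrier
        spikes, burst_starts = _burst_spikes(cfg, phase, rng)
        trace, true_times = _render_fluorescence(cfg, vm, spikes, rng)
        traces.append(trace)
        truth.spike_times_ms.append(true_times)
        truth.delta_phase.append(_wrap(phase))
        truth.vm_master.append(vm)
        truth.burst_start_times_ms.append(burst_starts)
    return traces, truth


def gen_tonic_neuron(cfg: SyntheticConfig,
                     rng: np.random.Generator | int | None = None,
                     ) -> tuple[list[TimeSeries], SyntheticGroundTruth]:
    """Regular-spiking control neuron: jittered-periodic spikes, no Vm delta."""
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    traces: list[TimeSeries] = []
    truth = SyntheticGroundTruth()
    for _ in range(cfg.n_trials):
        n = int(round(cfg.trial_len_ms / 1000.0 * MASTER_RATE_HZ))
        vm = _slow_drift(n, MASTER_RATE_HZ, cfg.drift_amp, rng)
        spikes = _tonic_spikes(cfg, rng)
        trace, true_times = _render_fluorescence(cfg, vm, spikes, rng)
        traces.append(trace)
        truth.spike_times_ms.append(true_times)
        truth.delta_phase.append(np.full(n, np.nan))
        truth.vm_master.append(vm)
    return traces, truth


def gen_lfp(cfg: SyntheticConfig, delta_phase: np.ndarray,
            rng: np.random.Generator | int | None = None) -> TimeSeries:
    """LFP for one trial: 1/f background + coherent delta + phase-nested beta/gamma.

    ``delta_phase`` is the (wrapped or unwrapped) 1 kHz delta phase the beta
    and gamma envelopes are nested in; carriers are band-limited noise whose
    amplitude is modulated by ``(1 + depth * cos(phase))``.
    """
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    n = np.asarray(delta_phase).size
    cosphi = np.cos(delta_phase)
    lfp = cfg.lfp_pink_sd * _pink_noise(n, MASTER_RATE_HZ, rng)
    lfp = lfp + cfg.lfp_delta_amp * cosphi
    beta = _bandpassed_noise(n, MASTER_RATE_HZ, (20.0, 40.0), rng)
    lfp = lfp + cfg.lfp_beta_amp * (1.0 + cfg.lfp_beta_depth * cosphi) * beta
    gamma = _bandpassed_noise(n, MASTER_RATE_HZ, (70.0, 100.0), rng)
    lfp = lfp + cfg.lfp_gamma_amp * (1.0 + cfg.lfp_gamma_depth * cosphi) * gamma
    return TimeSeries(lfp, MASTER_RATE_HZ, t0_ms=0.0, label="lfp")


def _bout_envelope(cfg: SyntheticConfig, t_ms: np.ndarray
                   ) -> tuple[np.ndarray, list, list, list]:
    """Smooth 0-1 movement envelope from the tiled bout schedule.

    Returns (envelope, move_intervals, onsets, offsets).  True onset/offset
    times are where the noise-free envelope speed crosses the rest/movement
    speed criterion (the quantity the segmentation stage recovers), which
    sits part-way up the transition ramp rather than at the nominal schedule
    boundary.
    """
    env = np.zeros_like(t_ms)
    move_iv, onsets, offsets = [], [], []
    t_end = t_ms[-1]
    # where along the ramp the mean speed crosses the criterion
    cross = np.clip((cfg.speed_criterion_cm_s - cfg.rest_speed_cm_s)
                    / max(cfg.move_speed_cm_s - cfg.rest_speed_cm_s, 1e-9),
                    0.0, 1.0)
    lead = cfg.ramp_ms * (cross - 0.5)
    t = 0.0
    i = 0
    while t < t_end:
        rest_ms, move_ms = cfg.bout_schedule[i % len(cfg.bout_schedule)]
        a, b = t + rest_ms, t + rest_ms + move_ms
        if move_ms > 0 and a < t_end:
            move_iv.append((a, min(b, t_end)))
            onsets.append(a + lead)
            if b < t_end:
                offsets.append(b - lead)
            ramp = cfg.ramp_ms
            up = np.clip((t_ms - (a - ramp / 2)) / ramp, 0.0, 1.0)
            down = np.clip(((b + ramp / 2) - t_ms) / ramp, 0.0, 1.0)
            env = np.maximum(env, np.minimum(up, down))
        t = b
        i += 1
        if move_ms <= 0 and rest_ms <= 0:
            break
    return env, move_iv, onsets, offsets


def gen_treadmill_and_limbs(cfg: SyntheticConfig,
                            rng: np.random.Generator | int | None = None,
                            ) -> tuple[TimeSeries, TimeSeries, TimeSeries, SyntheticGroundTruth]:
    """One trial of treadmill speed plus two hindlimb position traces.

    Speed = bout envelope (rest below, movement above the 5 cm/s criterion)
    plus a sinusoidal stepping fluctuation at ``step_delta_hz`` during
    movement.  Hindlimbs are anti-phase (lag ``limb_phase_lag_rad``) copies of
    the stepping cycle with independent noise, at their native video rate.
    """
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    n = int(round(cfg.trial_len_ms / 1000.0 * MASTER_RATE_HZ))
    t_ms = np.arange(n) / MASTER_RATE_HZ * 1000.0
    env, move_iv, onsets, offsets = _bout_envelope(cfg, t_ms)

    step_phi0 = rng.uniform(-np.pi, np.pi)
    step_phase = 2.0 * np.pi * cfg.step_delta_hz * t_ms / 1000.0 + step_phi0
    stepping = np.sin(step_phase)
    speed_master = (cfg.rest_speed_cm_s
                    + env * (cfg.move_speed_cm_s - cfg.rest_speed_cm_s)
                    + env * cfg.step_amp_cm_s * stepping)

    # stepping-cycle peaks inside movement bouts
    k = np.floor((step_phase - np.pi / 2) / (2 * np.pi))
    cross = np.flatnonzero(np.diff(k) > 0) + 1
    peaks = t_ms[cross]
    peaks = peaks[[any(a <= p < b for a, b in move_iv) for p in peaks]]

    t_speed = np.arange(int(cfg.trial_len_ms / 1000.0 * cfg.speed_rate_hz)) \
        / cfg.speed_rate_hz * 1000.0
    speed = np.interp(t_speed, t_ms, speed_master) \
        + cfg.speed_noise_sd * rng.standard_normal(t_speed.size)
    speed_ts = TimeSeries(speed, cfg.speed_rate_hz, t0_ms=0.0, label="treadmill_speed")

    t_limb = np.arange(int(cfg.trial_len_ms / 1000.0 * cfg.limb_rate_hz)) \
        / cfg.limb_rate_hz * 1000.0
    env_l = np.interp(t_limb, t_ms, env)
    phase_l = 2.0 * np.pi * cfg.step_delta_hz * t_limb / 1000.0 + step_phi0
    lhl = cfg.limb_amp * env_l * np.sin(phase_l) \
        + cfg.limb_noise_sd * rng.standard_normal(t_limb.size)
    rhl = cfg.limb_amp * env_l * np.sin(phase_l + cfg.limb_phase_lag_rad) \
        + cfg.limb_noise_sd * rng.standard_normal(t_limb.size)
    lhl_ts = TimeSeries(lhl, cfg.limb_rate_hz, t0_ms=0.0, label="limb_LHL")
    rhl_ts = TimeSeries(rhl, cfg.limb_rate_hz, t0_ms=0.0, label="limb_RHL")

    truth = SyntheticGroundTruth(
        bout_intervals_ms=[move_iv], onsets_ms=[np.asarray(onsets)],
        offsets_ms=[np.asarray(offsets)], step_peak_times_ms=[peaks],
        step_phase=[_wrap(step_phase)],
    )
    return speed_ts, lhl_ts, rhl_ts, truth


def gen_image_stack(cfg: SyntheticConfig, fluorescence: TimeSeries,
                    rng: np.random.Generator | int | None = None,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Render a jittering Gaussian-blob soma whose brightness follows the trace.

    Returns ``(stack, shifts)`` with ``stack`` of shape (n_frames, H, W) and
    ``shifts`` the true per-frame integer (dy, dx) displacements (a bounded
    random walk starting at zero).
    """
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    h, w = cfg.frame_shape
    yy, xx = np.mgrid[0:h, 0:w]
    blob = np.exp(-(((yy - h / 2) ** 2 + (xx - w / 2) ** 2)
                    / (2.0 * cfg.blob_sigma_px ** 2)))
    blob /= blob.sum()
    n_frames = fluorescence.n
    shifts = np.zeros((n_frames, 2), dtype=int)
    for k in range(1, n_frames):
        step = rng.integers(-1, 2, size=2)
        shifts[k] = np.clip(shifts[k - 1] + step, -cfg.max_shift_px, cfg.max_shift_px)
    stack = np.empty((n_frames, h, w))
    base = np.clip(fluorescence.values, 0.0, None)
    for k in range(n_frames):
        frame = base[k] * blob
        frame = np.roll(frame, tuple(shifts[k]), axis=(0, 1))
        if cfg.sensor_noise_sd > 0:
            frame = frame + cfg.sensor_noise_sd * rng.standard_normal((h, w))
        stack[k] = frame
    return stack, shifts


def gen_rate_modulated_spikes(rate_hz: np.ndarray, rate_grid_hz: float,
                              rng: np.random.Generator | int,
                              refractory_ms: float = 4.0) -> np.ndarray:
    """Inhomogeneous-Poisson spike times (ms) from a rate profile (Hz).

    Bernoulli thinning per sample; used for behavior-test neurons whose rate
    is gated by movement or by stepping phase.
    """
    rng = np.random.default_rng(rng)
    dt_s = 1.0 / rate_grid_hz
    p = np.clip(np.asarray(rate_hz) * dt_s, 0.0, 1.0)
    hits = np.flatnonzero(rng.uniform(size=p.size) < p)
    times = hits * dt_s * 1000.0
    if times.size == 0:
        return times
    keep = [0]
    for i in range(1, times.size):
        if times[i] - times[keep[-1]] >= refractory_ms:
            keep.append(i)
    return times[keep]


def simulate_session(cfg: SyntheticConfig, kind: str = "delta",
                     rng: np.random.Generator | int | None = None,
                     ) -> tuple[AlignedRecording, SyntheticGroundTruth]:
    """Full single-neuron session: fluorescence + LFP + treadmill + limbs.

    All signals are generated at their native rates and aligned to the shared
    1 kHz grid, exactly as acquired sessions would be.
    """
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    gen = gen_delta_neuron if kind == "delta" else gen_tonic_neuron
    traces, truth = gen(cfg, rng)
    trials = []
    for k, fluor in enumerate(traces):
        phase = truth.delta_phase[k]
        lfp_phase = phase if np.all(np.isfinite(phase)) else np.zeros(phase.size)
        lfp = gen_lfp(cfg, lfp_phase, rng)
        speed, lhl, rhl, btruth = gen_treadmill_and_limbs(cfg, rng)
        raw = {"fluorescence": fluor, "lfp": lfp, "treadmill_speed": speed,
               "limb_LHL": lhl, "limb_RHL": rhl}
        trials.append(align_and_resample(raw, np.array([0.0]),
                                         trial_len_ms=cfg.trial_len_ms))
        truth.bout_intervals_ms.append(btruth.bout_intervals_ms[0])
        truth.onsets_ms.append(btruth.onsets_ms[0])
        truth.offsets_ms.append(btruth.offsets_ms[0])
        truth.step_peak_times_ms.append(btruth.step_peak_times_ms[0])
        truth.step_phase.append(btruth.step_phase[0])
    meta = {"neuron_id": f"sim_{kind}_{cfg.seed}",
            "cell_class_label": "ChI" if kind == "delta" else "SYN"}
    return AlignedRecording(trials=trials, neuron_meta=meta), truth
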