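"""Core containers, timebase alignment, and session I/O.

All downstream analyses run on a common 1 kHz grid: every signal in a trial
(fluorescence, LFP, treadmill speed, limb positions) is aligned to the trial
start marker and linearly interpolated to 1000 Hz.  Times are milliseconds,
trial-relative, with half-open ``[start, end)`` intervals and 0-based sample
indexing throughout the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger("deltatrack")

#: common analysis rate after alignment (Hz)
ALIGNED_RATE_HZ = 1000.0


class AlignmentError(ValueError):
    """A signal cannot be placed on the requested trial grid."""


@dataclass
class TimeSeries:
    """A uniformly sampled signal.

    Parameters
    ----------
    values : ndarray
        Sample values; must be finite after load validation.
    rate_hz : float
        Sampling rate, > 0.
    t0_ms : float
        Time of the first sample, relative to the trial start marker.
    label : str
        Signal name, e.g. ``"fluorescence"``, ``"lfp"``, ``"treadmill_speed"``.
    """

    values: np.ndarray
    rate_hz: float
    t0_ms: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.rate_hz <= 0:
            raise ValueError(f"rate_hz must be > 0, got {self.rate_hz}")
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("TimeSeries needs a 1-D array of length >= 2")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.rate_hz

    @property
    def duration_ms(self) -> float:
        return self.n * self.dt_ms

    def times_ms(self) -> np.ndarray:
        """Sample times in ms relative to the trial start."""
        return self.t0_ms + np.arange(self.n) * self.dt_ms

    def validate_finite(self) -> "TimeSeries":
        if not np.all(np.isfinite(self.values)):
            bad = int(np.flatnonzero(~np.isfinite(self.values))[0])
            raise ValueError(f"non-finite value in '{self.label}' at sample {bad}")
        return self


@dataclass
class Trial:
    """Named signals of one trial, all on the shared 1 kHz grid after alignment."""

    signals: dict[str, TimeSeries]
    exclusion_mask: np.ndarray | None = None  # True = sample excluded from Vm analyses

    def __post_init__(self) -> None:
        if self.exclusion_mask is None and self.signals:
            self.exclusion_mask = np.zeros(self.n_samples, dtype=bool)

    @property
    def n_samples(self) -> int:
        return next(iter(self.signals.values())).n

    def __getitem__(self, name: str) -> TimeSeries:
        return self.signals[name]

    def __contains__(self, name: str) -> bool:
        return name in self.signals


@dataclass
class AlignedRecording:
    """Per-session, multi-trial container of aligned signals.

    ``neuron_meta`` holds at least ``neuron_id`` and ``cell_class_label``
    (``"ChI"``, ``"SYN"`` or ``"unknown"``).
    """

    trials: list[Trial]
    neuron_meta: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def signal_names(self) -> list[str]:
        names: list[str] = []
        for trial in self.trials:
            for name in trial.signals:
                if name not in names:
                    names.append(name)
        return names


def align_and_resample(
    raw: dict[str, TimeSeries],
    trial_markers: np.ndarray,
    trial_len_ms: float | None = None,
    rate_hz: float = ALIGNED_RATE_HZ,
) -> Trial:
    """Align native-rate signals of one trial onto a shared grid.

    Each signal is linearly interpolated onto a grid at ``rate_hz`` starting at
    the trial marker.  No extrapolation is performed: the grid is trimmed to
    the overlap of all signals (and to ``trial_len_ms`` if given).

    Parameters
    ----------
    raw : dict of TimeSeries
        Signals at their native rates; ``t0_ms`` is relative to session time.
    trial_markers : array
        Strictly increasing event times (ms); the first is the trial start.
    """
    trial_markers = np.atleast_1d(np.asarray(trial_markers, dtype=float))
    if trial_markers.size == 0:
        raise ValueError("at least one trial marker is required")
    if np.any(np.diff(trial_markers) <= 0):
        raise ValueError("trial markers must be strictly increasing")
    start = trial_markers[0]

    t_end = np.inf if trial_len_ms is None else start + trial_len_ms
    for name, ts in raw.items():
        ts.validate_finite()
        t = ts.times_ms()
        if t[-1] <= start or (trial_len_ms is not None and t[0] >= t_end):
            raise AlignmentError(f"signal '{name}' does not overlap the trial window")
        t_end = min(t_end, t[-1])
    t_begin = max(start, max(ts.times_ms()[0] for ts in raw.values()))

    dt = 1000.0 / rate_hz
    n = int(np.floor((t_end - t_begin) / dt)) + 1
    if n < 2:
        raise AlignmentError("common overlap shorter than two samples")
    grid = t_begin + np.arange(n) * dt

    signals = {}
    for name, ts in raw.items():
        vals = np.interp(grid, ts.times_ms(), ts.values)
        signals[name] = TimeSeries(vals, rate_hz, t0_ms=t_begin - start, label=name)
    return Trial(signals=signals)


def align_trials(
    raw_trials: list[dict[str, TimeSeries]],
    trial_markers: np.ndarray,
    neuron_meta: dict | None = None,
    trial_len_ms: float | None = None,
) -> AlignedRecording:
    """Align a list of per-trial raw signal dicts into an AlignedRecording."""
    trial_markers = np.asarray(trial_markers, dtype=float)
    if np.any(np.diff(trial_markers) <= 0):
        raise ValueError("trial markers must be strictly increasing")
    trials = [
        align_and_resample(raw, np.atleast_1d(marker), trial_len_ms=trial_len_ms)
        for raw, marker in zip(raw_trials, trial_markers, strict=True)
    ]
    return AlignedRecording(trials=trials, neuron_meta=dict(neuron_meta or {}))


# ---------------------------------------------------------------------------
# HDF5 session container: /trial_k/<signal_name>, /trial_k/exclusion_mask
# ---------------------------------------------------------------------------

KNOWN_SIGNALS = (
    "fluorescence",
    "lfp",
    "treadmill_speed",
    "limb_RHL",
    "limb_LHL",
    "limb_RFL",
    "limb_LFL",
)


def write_recording(path, rec: AlignedRecording) -> None:
    """Write an AlignedRecording as a hierarchical HDF5 session file."""
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "deltatrack-session-v1"
        f.attrs["n_trials"] = rec.n_trials
        for key, val in rec.neuron_meta.items():
            f.attrs[f"meta_{key}"] = val
        for k, trial in enumerate(rec.trials):
            g = f.create_group(f"trial_{k}")
            g.create_dataset("exclusion_mask", data=trial.exclusion_mask)
            for name, ts in trial.signals.items():
                d = g.create_dataset(name, data=ts.values)
                d.attrs["rate_hz"] = ts.rate_hz
                d.attrs["t0_ms"] = ts.t0_ms


def read_recording(path, required: tuple[str, ...] = ()) -> AlignedRecording:
    """Read a session file; optional signals may be absent (logged).

    Raises a ``ValueError`` naming the field if the file is malformed or a
    ``required`` signal is missing.
    """
    with h5py.File(path, "r") as f:
        if f.attrs.get("format") != "deltatrack-session-v1":
            raise ValueError("not a deltatrack session file (missing format attr)")
        n_trials = int(f.attrs["n_trials"])
        meta = {
            key[5:]: (val.item() if hasattr(val, "item") else val)
            for key, val in f.attrs.items()
            if key.startswith("meta_")
        }
        trials = []
        for k in range(n_trials):
            gname = f"trial_{k}"
            if gname not in f:
                raise ValueError(f"corrupt session file: missing group '{gname}'")
            g = f[gname]
            signals = {}
            for name in g:
                if name == "exclusion_mask":
                    continue
                d = g[name]
                signals[name] = TimeSeries(
                    d[...],
                    rate_hz=float(d.attrs["rate_hz"]),
                    t0_ms=float(d.attrs["t0_ms"]),
                    label=name,
                )
            for name in required:
                if name not in signals:
                    raise ValueError(f"required signal '{name}' missing in {gname}")
            for name in KNOWN_SIGNALS:
                if name not in signals:
                    logger.warning("trial %d: optional signal '%s' absent", k, name)
            mask = g["exclusion_mask"][...].astype(bool)
            trials.append(Trial(signals=signals, exclusion_mask=mask))
    return AlignedRecording(trials=trials, neuron_meta=meta)


def spikes_to_frame(spike_times_by_trial: list[np.ndarray], neuron_id: str = "") -> pd.DataFrame:
    """Flat spike table: one row per spike with trial id and time (ms)."""
    rows = [
        {"neuron_id": neuron_id, "trial": k, "time_ms": float(t)}
        for k, times in enumerate(spike_times_by_trial)
        for t in np.asarray(times)
    ]
    return pd.DataFrame(rows, columns=["neuron_id", "trial", "time_ms"])


def export_spikes_csv(path, spike_times_by_trial, neuron_id: str = "") -> None:
    spikes_to_frame(spike_times_by_trial, neuron_id).to_csv(path, index=False)


def merge_exclusion(trial: Trial, extra_mask: np.ndarray) -> Trial:
    """Return the trial with ``extra_mask`` OR-ed into its exclusion mask."""
    mask = np.asarray(extra_mask, dtype=bool)
    if mask.size != trial.n_samples:
        raise ValueError("exclusion mask length must match trial length")
    return replace(trial, exclusion_mask=trial.exclusion_mask | mask)
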