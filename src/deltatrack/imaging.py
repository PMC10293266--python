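"""Rigid motion correction, ROI trace extraction, motion-based exclusion.

Correction is pairwise rigid: each frame's displacement is the location of
the maximum cross-correlation coefficient against a reference image (the
trial's temporal mean), computed inside a user-selected rectangular window.
Trials are corrected individually and then referenced to the first trial.
Shifts are re-referenced to each trial's first frame so that frame 0 defines
the trial's coordinate frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .io_core import TimeSeries


@dataclass
class MotionTrace:
    """Per-frame rigid shifts and the derived motion-speed trace."""

    shifts_px: np.ndarray        # (n_frames, 2) as (dy, dx)
    motion_speed: np.ndarray     # |d(dy)| + |d(dx)| in um per frame interval -> um/ms
    px_size_um: float
    rate_hz: float


@dataclass
class RoiMask:
    mask: np.ndarray             # boolean, frame-shaped
    provenance: str = "manual-polygon"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("ROI mask is empty")


def _xcorr_shift(frame: np.ndarray, ref: np.ndarray, max_shift: int) -> tuple[int, int]:
    """Integer shift maximizing the cross-correlation coefficient.

    Both images are mean-subtracted; the search is restricted to
    ``|shift| <= max_shift`` and ties go to the smallest-magnitude shift.
    The returned (dy, dx) is the displacement of ``frame`` relative to
    ``ref`` (apply the negative to undo it).
    """
    f = frame - frame.mean()
    r = ref - ref.mean()
    if not np.any(r):
        raise ValueError("flat reference window: cannot motion correct")
    # circular cross-correlation: constant overlap at every lag, so the
    # mean subtraction adds only a lag-independent constant
    nrow, ncol = f.shape
    corr = np.fft.irfft2(np.fft.rfft2(f) * np.conj(np.fft.rfft2(r)),
                         (nrow, ncol))
    # lag (dy, dx) lives at index (dy mod nrow, dx mod ncol)
    dys = np.arange(-max_shift, max_shift + 1)
    dxs = np.arange(-max_shift, max_shift + 1)
    sub = corr[np.ix_(dys % nrow, dxs % ncol)]
    best = None
    best_val = -np.inf
    for i, dy in enumerate(dys):
        for j, dx in enumerate(dxs):
            v = sub[i, j]
            if v > best_val + 1e-12:
                best_val, best = v, (dy, dx)
            elif abs(v - best_val) <= 1e-12 and best is not None:
                if abs(dy) + abs(dx) < abs(best[0]) + abs(best[1]):
                    best = (dy, dx)
    return best


def _apply_shift(frame: np.ndarray, shift: np.ndarray) -> np.ndarray:
    dy, dx = shift
    if float(dy).is_integer() and float(dx).is_integer():
        return np.roll(frame, (-int(dy), -int(dx)), axis=(0, 1))
    return ndimage.shift(frame, (-dy, -dx), order=1, mode="nearest")


def _correct_single_trial(stack: np.ndarray, window: tuple[slice, slice],
                          max_shift: int, subpixel: bool,
                          upsample: int) -> np.ndarray:
    """Two-pass shifts vs the trial's temporal mean.

    The raw temporal mean is motion-blurred, so a second pass against the
    mean of the provisionally aligned frames sharpens the reference and
    settles near-tied correlation maxima.
    """
    ref = stack[:, window[0], window[1]].mean(axis=0)
    if np.allclose(ref, ref.flat[0]):
        raise ValueError("flat (zero-variance) correction window")
    shifts = np.zeros((stack.shape[0], 2))
    for _ in range(2):
        wins = [_apply_shift(stack[k], shifts[k])[window[0], window[1]]
                for k in range(stack.shape[0])]
        ref = np.mean(wins, axis=0)
        for k, win in enumerate(wins):
            if subpixel:
                sh, _err, _ph = phase_cross_correlation(ref, win,
                                                        upsample_factor=upsample)
                shifts[k] += -sh  # displacement of the frame relative to ref
            else:
                shifts[k] += _xcorr_shift(win, ref, max_shift)
    return shifts - shifts[0]  # frame 0 defines the trial coordinate frame


def motion_correct(stacks, window: tuple[slice, slice] | None = None,
                   max_shift: int = 10, px_size_um: float = 0.325,
                   rate_hz: float = 833.0, subpixel: bool = False,
                   upsample_factor: int = 10) -> tuple[list[np.ndarray], MotionTrace]:
    """Rigid-correct one or more trial stacks.

    Parameters
    ----------
    stacks : ndarray or list of ndarray
        (n_frames, H, W) per trial; a single array is treated as one trial.
    window : (slice, slice), optional
        Rectangular correction window; defaults to the full frame.

    Returns
    -------
    corrected : list of ndarray
        Shift-compensated stacks.
    motion : MotionTrace
        Concatenated per-frame shifts and the combined rectified X-Y
        derivative of the shift converted to um/ms.
    """
    if isinstance(stacks, np.ndarray) and stacks.ndim == 3:
        stacks = [stacks]
    if any(s.shape[0] < 2 for s in stacks):
        raise ValueError("motion correction needs at least 2 frames per trial")
    if window is None:
        window = (slice(None), slice(None))

    all_shifts = []
    trial_offset = np.zeros(2)
    ref_mean = None
    corrected = []
    for stack in stacks:
        shifts = _correct_single_trial(stack, window, max_shift, subpixel,
                                       upsample_factor)
        fixed = np.stack([_apply_shift(fr, sh) for fr, sh in zip(stack, shifts)])
        mean_win = fixed[:, window[0], window[1]].mean(axis=0)
        if ref_mean is None:
            ref_mean = mean_win          # all later trials reference trial 1
            trial_offset = np.zeros(2)
        else:
            trial_offset = np.asarray(
                _xcorr_shift(mean_win, ref_mean, max_shift), dtype=float)
            fixed = np.stack([_apply_shift(fr, trial_offset) for fr in fixed])
        corrected.append(fixed)
        all_shifts.append(shifts + trial_offset)

    shifts_px = np.vstack(all_shifts)
    dshift = np.abs(np.diff(shifts_px, axis=0, prepend=shifts_px[:1]))
    speed_um_per_ms = dshift.sum(axis=1) * px_size_um * rate_hz / 1000.0
    motion = MotionTrace(shifts_px=shifts_px, motion_speed=speed_um_per_ms,
                         px_size_um=px_size_um, rate_hz=rate_hz)
    return corrected, motion


def extract_trace(corrected, roi: RoiMask, rate_hz: float = 833.0) -> TimeSeries:
    """Per-frame mean fluorescence over the ROI pixels."""
    stacks = [corrected] if isinstance(corrected, np.ndarray) and corrected.ndim == 3 \
        else list(corrected)
    h, w = stacks[0].shape[1:]
    if roi.mask.shape != (h, w):
        raise ValueError("ROI mask shape does not match frame shape")
    vals = np.concatenate([s[:, roi.mask].mean(axis=1) for s in stacks])
    return TimeSeries(vals, rate_hz, t0_ms=0.0, label="fluorescence")


def motion_exclusion_mask(motion: MotionTrace,
                          threshold_um_per_ms: float = 0.065) -> np.ndarray:
    """True where the combined rectified X-Y shift derivative exceeds threshold.

    Samples flagged here are excluded from subthreshold-Vm analyses.
    """
    return motion.motion_speed > threshold_um_per_ms


def write_tiff_stack(path, stack: np.ndarray) -> None:
    """Write a (n_frames, H, W) stack as a multi-page grayscale TIFF."""
    import tifffile

    tifffile.imwrite(path, stack.astype(np.float32))


def read_tiff_stack(path) -> np.ndarray:
    """Read a multi-page grayscale TIFF into a (n_frames, H, W) array."""
    import tifffile

    stack = np.asarray(tifffile.imread(path), dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise ValueError(f"expected a grayscale stack, got shape {stack.shape}")
    return stack


def frames_mask_to_1khz(mask_frames: np.ndarray, rate_hz: float,
                        n_samples_1khz: int) -> np.ndarray:
    """Resample a per-frame boolean mask onto the 1 kHz analysis grid."""
    t_ms = np.arange(n_samples_1khz)  # 1 kHz: sample index == ms
    idx = np.clip(np.round(t_ms / 1000.0 * rate_hz).astype(int),
                  0, mask_frames.size - 1)
    return mask_frames[idx]
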