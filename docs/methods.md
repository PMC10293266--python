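# Methods

This note documents the models, estimators, and numerical choices behind
`deltatrack`, what the synthetic-data generator does and does not emulate,
and the limitations a user should keep in mind.

## Signal model and timebase

All per-trial signals — somatic fluorescence (native ~833 Hz), LFP (1 kHz),
treadmill speed (~20 Hz), limb positions (~120 Hz) — are aligned to the trial
start marker and linearly interpolated onto a shared 1 kHz grid before
analysis. Linear interpolation is used because it is monotone, passes through
the native samples, and introduces no ringing; the choice is exposed in the
configuration. Times are milliseconds, trial-relative; intervals are
half-open `[start, end)`; sample indexing is 0-based. Trials are independent
epochs: no statistic (ISIs, burst intervals, autocorrelations) ever spans a
trial boundary.

## Motion correction

Rigid per-frame displacement is the argmax of the circular FFT
cross-correlation between each (mean-subtracted) frame window and a
reference, restricted to `|shift| ≤ max_shift` with ties broken toward the
smallest shift magnitude. Circular rather than zero-padded correlation is
used because the mean subtraction otherwise acquires an overlap-dependent
bias near the window edges. The reference is the trial's temporal mean,
applied in two passes: the raw mean of a jittering stack is motion-blurred
and its correlation peak nearly flat, so a second pass against the mean of
the provisionally aligned frames sharpens the reference and settles
near-tied maxima; on noiseless integer-shifted stacks recovery is then
exact. Shifts are re-referenced so the trial's first frame defines its
coordinate frame, and trials after the first are registered to the first
trial's aligned mean. Sub-pixel estimation (Fourier upsampling ×10 via
`skimage.registration.phase_cross_correlation`) is available but off by
default.

Motion speed is the combined rectified X-Y derivative of the shift trace in
µm/ms, using a default pixel size of 0.325 µm (6.5 µm sensor pixels, 2×2
binning, 40× objective). Samples above 0.065 µm/ms are excluded from Vm
analyses. (The source describes this threshold inconsistently as µm/s in one
place and µm/ms in another; the µm/ms reading is implemented and the value
is configurable.)

## Trace processing

Photobleaching is corrected by subtracting a 1000 ms moving-average smoothed
copy of the trace — the window is much longer than a spike (1–2 ms) and much
shorter than the bleaching time constant (tens of seconds), so spikes and
oscillations survive while the exponential trend is removed to well under 2%
of its initial drop.

The spike-free baseline is estimated in two passes: a ±100-frame moving mean
("smoothed trace"), then clipping the trace above that mean and re-smoothing.
Note the moving mean attenuates genuine oscillations by the rectangular
window factor `sin(πfw)/(πfw)` (≈0.75 at 2 Hz for a 201 ms window); the
baseline is a slow envelope, not a reconstruction of the oscillation.

Spike detection: zero-phase 4th-order Butterworth high-pass above 120 Hz;
the detection threshold is 4 × the SD of the *subthreshold* fluctuation,
estimated by computing the SD of the high-passed trace, masking samples
beyond 4 SD, and re-estimating once. Spike times are local maxima with a
3 ms refractory (matching the ±3-sample spike footprint). The SD is computed
per trial; whether the original procedure pooled across trials is unstated.

SBR: per-spike amplitude is the peak minus the lowest value within the three
preceding samples; the trial's SBR is the mean amplitude divided by the SD of
the Vm over the trial; trials with SBR < 5 (or no spikes) are excluded.

Vm extraction replaces ±3 samples around each spike peak by linear
interpolation anchored on the surviving neighbors; overlapping windows from
doublets merge into one gap. The Vm estimate equals the true subthreshold
trace plus the white shot-noise floor; agreement within the subthreshold
band (≤30 Hz) is r > 0.95 under the generator's default noise.

## Rhythm classification

ISI ratio (A − B)/(A + B) with A = count of ISIs in 300–700 ms and
B = count in 80–200 ms (counts of intervals, not of spikes; the wording of
the original rule is ambiguous by one spike). Ratio ≥ 0 ⇒ delta-rhythmic.
Neurons with fewer than 3 spikes are labelled undefined and excluded from
population summaries.

Burst decomposition groups consecutive spikes with ISI < 80 ms — the lower
edge of the B band, cleanly separating the 10–40 ms intraburst mode from the
300–700 ms interburst mode; this criterion is a package choice (the original
procedure is not described) and is configurable. Interburst rate is the
reciprocal of the mean burst-start-to-burst-start interval; intraburst rate
the reciprocal of the mean within-burst ISI.

Instantaneous frequency: Vm band-passed 1–6 Hz (3rd-order Butterworth,
zero-phase), Hilbert analytic phase, unwrapped, differentiated with a
Savitzky-Golay filter (polyorder 2, 201 ms frame, first derivative).
Excluded-sample gaps split the trace; segments shorter than 1 s (or twice
the filter frame) are dropped, and half a filter frame is trimmed at each
segment edge. The distribution is histogrammed at 0.1 Hz; the peak is the
mode of a 3-bin smoothed histogram (stabilizes the mode), while the FWHM
spans the outermost *raw* bins at or above half the raw maximum. Under
additive noise the mode estimate biases low by a few tenths of a Hz (phase
slips at low-envelope moments); the FWHM is robust to this and is the
recovered quantity in validation (within 25% of the generator's setting).

## Spectral coupling

Morlet spectrograms use PyWavelets' complex Morlet; the bandwidth parameter
is derived from the requested number of cycles m via `B = m²/(2π²)` with
center frequency 1, giving `σ_t = m/(2πf)`. Default m = 7, log-spaced grid
of 60 frequencies over 1–140 Hz (width, spacing, and grid are not stated in
the source and are configuration-exposed). Samples within one wavelet SD of
a trace edge are flagged invalid; spikes on invalid samples are dropped from
phase-locking (using the lowest frequency's span, so every frequency sees
the same N).

PLV and PLVu² are as in the README; PLVu² is exactly unbiased under uniform
phases (E[PLV²] = 1/N) and bounded below by −1/(N−1). Neurons with fewer
than 10 spikes are omitted.

Event-triggered spectrograms average ±250 ms power windows around events
(≥250 ms from trial edges), normalized per frequency either to the mean
pre-event power (−200…−100 ms) or to the window mean; a minimum of 20
windows is enforced. Rest/movement contrasts subtract the two conditioned
spectrograms' band power at lag 0.

Delta-cycle-resolved beta: cycles are trough-to-trough intervals of the
delta-filtered Vm; normalized beta (20–40 Hz) power is read at each cycle
peak and compared between cycles with and without spikes.

Coherence: Welch magnitude-squared coherence from Hann-windowed 2 s segments
with 50% overlap pooled over trials. The null time-flips the second signal
and permutes segment pairings (destroying temporal correspondence while
preserving spectra); 200 shuffles give a per-frequency 95th-percentile band.

## Behavior

Movement bouts: treadmill speed low-passed at 1.5 Hz (4th-order Butterworth,
zero-phase) and thresholded at 5 cm/s; runs shorter than 200 ms are absorbed
into their neighbor to suppress threshold flicker (configurable, 0 disables).
Rest and movement intervals tile each trial; onsets/offsets are the
boundaries.

Movement-rate test: observed statistic is the across-trial mean of
(movement rate − rest rate). The null draws, per trial, a random frame
subset the size of the rest frames and uses its complement as surrogate
movement frames. Because frames are drawn without replacement and carry at
most one spike each (1 kHz grid, 3 ms refractory), the selected spike count
is exactly hypergeometric and is sampled as such — distributionally
identical to enumerating frame subsets and orders of magnitude faster. The
complementary construction makes the null exchangeable with the observed
statistic under a homogeneous train; measured type-I error is ~5% at the
2.5/97.5 percentile rule (independent rest/movement draws would halve the
null variance and triple the false-positive rate). Verdicts: increased /
decreased / ns; a two-sided rank p-value is reported alongside.

Transition-triggered rates: spike counts in 100 ms bins over ±500 ms around
onsets (or offsets), averaged across events; the null redraws the same
number of event times uniformly within each trial, 1000 times; per-bin
significance uses the null's 2.5/97.5 percentiles, and the onset-response
scalar (post 0–120 ms minus pre −120–0 ms rate) gets its own rank p-value.

Treadmill delta phase: speed band-passed 1–4 Hz (2nd-order Butterworth —
the low order keeps passband phase distortion small enough that detected
peaks fall within 2 ms of true sinusoid maxima), Hilbert phase with
sub-sample peak interpolation. Peaks (and spike phases) are only accepted
where the band envelope exceeds 25% of its movement-period median — an
amplitude guard against spurious phase during rest, which the original
procedure leaves implicit. Band splits (1–2.6 / 2.8–6 Hz) are parameters.
Stepping-locked rates are normalized by the neuron's mean rate and require
10 delta-peak windows.

Limb locomotion: the limb signal's derivative, Hilbert amplitude envelope,
smoothed below 3 Hz (the stepping envelope is slow; smoothing removes
interpolation-harmonic ripple), thresholded strictly above 0.1.

Hodges–Ajne omnibus test: the statistic m is the smallest count in any half
circle (360 directions at 1°); exact tail probability
`(n − 2m)·C(n, m)·2^(1−n)` for n ≤ 50, Ajne's approximation above; p = 1
when n = 2m (the exact formula degenerates there, and a perfectly balanced
sample carries no evidence). Measured rejection at α = 0.05 under uniformity
is ≈0.02 (the test is conservative, as known).

## Synthetic data generator

The generator emulates the study conditions: up to 12 s trials (default 5
per session), fluorescence at 833 Hz, LFP at 1 kHz, treadmill speed at
20 Hz, limbs at 120 Hz.

- **Delta neurons.** The instantaneous delta frequency is an
  Ornstein-Uhlenbeck process (exact discretization) with stationary mean
  2.3 Hz, stationary SD = FWHM/2.3548 with FWHM 1.5 Hz, and a 1 s
  correlation time — a stationary, tunable-width model of the observed
  cycle-to-cycle drift; no mechanistic claim is intended. Vm is the cosine
  of the accumulated phase (amplitude 2 noise-SD units) plus a slow drift;
  optionally a 20–40 Hz carrier amplitude-modulated by the delta phase
  (off by default) for nesting experiments. Bursts of 2–4 spikes at 25 Hz
  (8% ISI jitter) trigger near delta peaks with a 20% skip probability, so
  the effective interburst rate is the delta rate times 0.8.
- **Spikes** are 2-sample triangular transients; amplitude is parameterized
  in units of the white shot-noise SD, making SBR directly controllable.
  The default (14) renders sessions at SBR ≈ 8 — comfortably inside the
  "well above the SBR-5 exclusion line" regime the validation targets, even
  after end-of-trial photobleaching (τ = 30 s) has shrunk spikes by ~30%.
- **Tonic neurons** spike at 8 Hz with CV 0.1 (ISIs ≈125 ms, inside the
  B band), no delta Vm component.
- **LFP** is 1/f-power background plus a delta component coherent with the
  neuron's Vm phase plus band-limited 20–40 Hz and 70–100 Hz carriers whose
  amplitudes are modulated as `1 + depth·cos(delta phase)`.
- **Locomotion**: a rest/movement schedule (default 3 s / 3 s) with 250 ms
  ramps; rest speed 1 cm/s, movement 12 cm/s plus a 3 cm/s sinusoidal
  stepping fluctuation at 2.5 Hz. True onset/offset times are where the
  noise-free envelope crosses the 5 cm/s criterion (part-way up the ramp),
  since that is the quantity segmentation recovers. Hindlimbs are anti-phase
  (lag π) copies of the stepping cycle with independent noise; no gait
  dynamics are modelled.
- **Image stacks**: a Gaussian-blob soma whose brightness follows the
  fluorescence trace, translated by a bounded integer random walk, plus
  optional Gaussian sensor noise.

What passing tests on these data do **not** show: robustness to non-rigid
or sub-frame motion, correlated or signal-dependent (photon) noise,
non-sinusoidal stepping, gait asymmetries, electrode drift, or any neuron
class beyond the two stereotypes generated. The generator's white-Gaussian
noise model is an assumption (none is specified for the indicator).

## Validation problem sizes

The test suite and the acceptance script use populations of 20 neurons
(2 × 12 s trials each) for detection/classification/coupling recovery,
100 null neurons for shuffle-test calibration, 10,000 replicates for the
PLVu² bias check, and 5000 draws for omnibus calibration — sizes chosen so
each check carries clear statistical resolution while the whole suite runs
in well under a minute of compute per module.

## Command-line interface

`deltatrack simulate` writes a ground-truthed HDF5 session (+ JSON truth
sidecar); `deltatrack run` simulates a population and executes the full
chain, writing `neurons.csv`, `manifest.json` (every consumed threshold),
and a classification figure; `deltatrack report` pretty-prints an existing
report. The per-stage operations (align, detect, classify, couple, behave)
are library functions orchestrated by `run`; a one-verb-per-stage CLI would
duplicate that orchestration without adding capability at this scale.
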