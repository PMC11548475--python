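# Methods

## Study design being modeled

The package analyzes sessions in which two acquisition devices — a
commercial reference system and a laboratory prototype — digitize the same
bipolar electrode site simultaneously at 2 kHz, with a third analog channel
carrying trigger pulses that mark and label trials. A session consists of
6 movement types × 10 repetitions presented in random order; each trial is
a 2 s contraction followed by 5 s of rest, with a leading rest period
before the first trial. Device agreement is then quantified per feature and
per subject on matched analysis windows.

## Synthetic session generator

Surface EMG during a steady contraction is well approximated by colored
Gaussian noise whose amplitude tracks muscle activation. The simulator
therefore models one shared muscle source as white Gaussian noise
band-passed to 20–300 Hz (4th-order Butterworth) and rescaled to unit
standard deviation, multiplied by a trapezoidal activation envelope:

* baseline (rest) level 0.03 of the contraction plateau — small enough that
  contraction RMS exceeds rest RMS by well over an order of magnitude, while
  keeping a realistic non-zero resting tone;
* each trial ramps up over 200 ms starting a reaction delay of 150 ± 50 ms
  (Gaussian, clipped at 0) after the cue onset, holds for the 2 s
  contraction, and ramps down over 200 ms. The delay emulates participant
  response latency, which is why analysis windows are 3 s rather than 2 s.

The two channels are derived from this common source:

* **reference** = source + white noise (sd 0.02 in source units);
* **prototype** = source passed through a digital model of the prototype's
  analog chain — first-order high-pass at 20.7 Hz, second-order Butterworth
  low-pass at 330 Hz, and two cascaded biquad notches (Q = 30) at 60 Hz
  standing in for the board's 4th-order notch — scaled by a gain, plus
  white noise of sd 0.08. Only the spectral shaping of the chain matters
  for validation, so bilinear-transform IIR approximations at the measured
  corner frequencies are used, applied causally (the analog chain is
  causal). The low-pass order is not documented for the hardware; second
  order is the mildest realistic active-filter choice and the 330 Hz corner
  is far above the 200 Hz analysis band, so the choice is inconsequential.
  The prototype's noise sd is deliberately higher than the reference's:
  prototype front ends are noisier than commercial systems.

The trigger channel is zero except for a rectangular 5 ms pulse at each
trial onset with amplitude 15, 20, …, 40 mV for movements 1–6. Movement
identity affects only this label, not the source statistics: the pipeline
validates devices, not movement classes.

All randomness (trial order, reaction jitter, both noise realizations)
comes from one seeded generator recorded in the session metadata, so a
session is a pure function of its config. What the generator does **not**
emulate: motor-unit firing structure, electrode–skin impedance and motion
artifacts, movement-specific spatial patterns, ADC quantization, and
channel-to-channel sampling skew. Consequently, passing tests demonstrate
that the statistics pipeline behaves correctly on signals with the assumed
structure — not that any particular hardware meets a concordance level on
real recordings.

## Preprocessing

Order of operations: decimate → band-pass → normalize.

* **Decimation** 2 kHz → 500 Hz by integer factor, preceded by a zero-phase
  FIR low-pass (81 taps at factor 4) cutting at 0.8× the target Nyquist
  (200 Hz) to prevent aliasing. A non-integer rate ratio is a configuration
  error.
* **Band-pass** 20–200 Hz, 4th-order Butterworth, applied
  forward–backward. Zero-phase filtering preserves trigger-relative timing,
  which matters because windows are cut at trigger onsets.
* **Normalization** y = x / max|x| per channel over the whole recording, so
  max|y| = 1 exactly and both devices land on a common −1..1 scale. An
  all-zero channel is a reported degenerate-input error, never a silent
  division by zero. A per-window normalization scope is available but the
  default follows the convention of normalizing each device's full
  recording.

The trigger channel is never filtered or normalized.

## Epoching

Trigger detection runs on the **original 2 kHz grid**, where a 5 ms pulse
spans ~10 samples (it would be 2–3 after decimation). The onset is the
first sample exceeding half the smallest configured level (7.5 mV, which
cleanly separates pulses from a quiet channel); the pulse amplitude is the
median of above-threshold samples in the nominal pulse span, which is
robust to an edge sample caught mid-transition. A 1 s refractory period
suppresses duplicate crossings. Onsets map to the 500 Hz analysis grid by
integer division of the sample index.

Amplitude decoding assigns the nearest configured level within a closed
±2 mV tolerance (half the 5 mV spacing minus margin; a 10⁻¹² absolute slack
keeps the closed boundary stable under binary floating point). An
out-of-tolerance pulse is logged and excluded — never silently given a
default id. Windows are 3 s per device per decoded event, starting at the
onset (configurable offset); windows truncated by the end of the recording
are dropped with a warning.

## Feature indices

The 22 time-domain indices are defined once, in `features.py`, with these
conventions: 1-based sample indices in all piecewise weight boundaries
(closed comparisons against fractional multiples of N); fractional powers
of negative samples in ASM/ASS evaluated as principal complex roots with
the modulus of the complex sum returned; logarithms guarded by ε = 1e-10;
thresholds (FZC/WA/CARD 0.01, MYOP 0.016) expressed in normalized −1..1
units. KURT is the non-excess population kurtosis and is NaN (with a
warning) on a zero-variance window. Every formula is checked against an
independent loop-based implementation to 1e-9 relative tolerance in the
test suite.

COV divides the window standard deviation by the window mean. Band-passed
EMG windows have means near zero, so COV is numerically explosive; any
window whose |mean| < √ε = 10⁻⁵ gets a flag carried through the feature
table.

## Concordance

MAPE is stored as a **fraction** (0 = identical), converted to percent only
for display; this is what makes 1 − MAPE a 0-to-1 similarity. The
denominator is |yᵢ|, since several features (LDAMV, LDASDV, COV) are
legitimately negative and a signed denominator would flip error signs
meaninglessly. Pairs with |yᵢ| < 10⁻⁸ are excluded and counted — MAPE is
undefined at zero, and reported exclusion beats silent inflation. A cell
with every pair excluded is an explicit undefined-concordance error.
Negative cells (MAPE > 1) are kept by default; a clip option floors them at
0 for display. The overall mean is the mean over non-missing cells and, on
a complete grid, coincides with the mean of either marginal to 10⁻¹².

**COV aggregation.** In the end-to-end pipeline, a subject's COV cell is
dropped from the aggregate (recorded as missing, listed in the summary)
when more than half of that subject's windows carry the near-zero-mean
flag. The measured COV of such windows is the ratio of two quantities whose
signs are noise, so the cell quantifies nothing about device agreement and
its inclusion injects unbounded variance into the overall mean. The raw COV
values remain in the feature table, and the low-level
`concordance_matrix` includes everything unless told otherwise.

## Spectral comparison

* `fft_spectrum`: one-sided DFT magnitude.
* `cross_correlation`: Pearson correlation at each lag, normalized over the
  overlapping samples only, computed exactly via cumulative sums plus one
  full cross-correlation; the zero-lag value therefore equals the ordinary
  Pearson coefficient (cross-checked to 10⁻¹² in tests). Positive lag means
  the second signal is delayed. Default maximum lag is half the signal
  length, keeping overlaps long enough for the coefficient to be
  meaningful.
* `spectrogram`: Hann window, 256 samples (~2 Hz resolution at 500 Hz),
  50% overlap, magnitude mode.
* `spectrogram_xcorr2d`: per-shift Pearson coefficient over the overlapping
  region of the two grids (each overlap mean-subtracted and unit-scaled);
  shifts covering less than half the grid are ignored, coefficients are
  clipped to [−1, 1] against floating-point overshoot, and ties within
  10⁻⁹ of the peak resolve to the smallest |shift| so identical grids
  report exactly (0, 0). The squared peak is the explained variance.
* The pipeline's diagnostic segment spans from 2 s before the first
  decoded onset through 6 s total — rest, contraction, and aftermath.

## Problem sizes

The test suite runs most properties on short sessions (2 movements × 2
repetitions) and uses the full 60-trial protocol where trial counts are the
point; the noise-sweep check averages ten 60-trial single-subject sessions
per noise level. The acceptance script simulates one full session
(425 s, 850 000 samples per channel) per run. These sizes were chosen to
exercise every code path at full protocol scale while keeping a complete
run in the tens of seconds.

## Known limitations

* The simulator's simplifications listed above mean absolute concordance
  values from synthetic sessions should not be read as predictions for any
  real device pair; the pipeline's *relative* behavior (perfect agreement
  in the identity limit, monotone degradation with noise) is what the tests
  establish.
* MAPE-based agreement is scale-invariant only under *joint* rescaling of
  both devices; calibration differences appear as disagreement, by design.
* The 2-D spectrogram correlation is reported at its peak shift; sub-bin
  time-frequency misalignment is not interpolated.
* Trigger decoding assumes a quiet trigger channel (pulses ≫ noise); it is
  not designed for triggers embedded in signal-level interference.
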