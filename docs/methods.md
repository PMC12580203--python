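# Methods

## The oddball frequency-tagging model

A stimulation sequence presents items at the base rate f_base (default
10 Hz) with every Nth item (default N = 5) drawn from a deviant category,
so the deviant appears at f_odd = f_base / N = 2 Hz in the fixed pattern
BBBBO.  A 60-s sequence therefore holds 600 items, 120 of them deviants.
Sequences are flanked by 2-s contrast fades (items generated but flagged
and excluded from analysis) and carry 15 orthogonal-task color-change
events placed uniformly at random with ≥1 s separation.  Sequences start
at pattern position 1 after the fade; token draws are uniform over the
category pool with rejection of the immediately preceding token, so no
item repeats back-to-back (this requires ≥2 base tokens).

Steady-state responses are modeled as phase-locked cosines at the base and
oddball frequencies and their harmonics.  Because all analysis frequencies
are integer Hz and epochs are integer seconds, every component falls
exactly on a DFT bin: a cosine of peak amplitude A contributes A/2 to the
one-sided |FFT|/N spectrum, with no spectral leakage.  This bin-exactness
is what makes zero-noise parameter recovery a machine-precision test.

## Spectral statistics

The normalized amplitude spectrum is |FFT|/N of the time-domain-averaged
epoch.  No one-sided ×2 factor is applied; every downstream quantity is a
ratio or difference of such values, so the convention cancels everywhere
it could matter.

Local statistics reference each bin to its surrounding noise bins
(`NoiseWindow`, default 10 per side, no adjacent-bin or extreme-value
exclusion; both exclusions exist as options because usage in the wider
frequency-tagging literature varies).  Baseline correction subtracts the
window mean; SNR divides by it (flat spectrum → SNR = 1, the chance
level); the Z-score divides the mean-subtracted value by the window SD.
The SD uses the n−1 denominator (a choice; configurable via the brute
force in tests, not exposed as an option since the difference at n = 20 is
≈2.6% of the SD).  Bins whose window would run off the grid edge — the DC
bin and everything within 10 bins of either end — are NaN, never silently
computed, as are bins with a degenerate (zero-SD or zero-mean)
denominator.

Harmonic bookkeeping: `enumerate_harmonics(2, 10, 14)` yields the seven
harmonics 2–14 Hz and flags 10 Hz as a base-rate collision.  Collisions
stay in the set (they are real harmonics) but are excluded from the
summed baseline-corrected amplitude (SBL, six terms by default) and are
skipped — without breaking the run — when counting consecutive
significant harmonics from the fundamental.  The distinction "seven
enumerated, six summed" is deliberate and exposed through
`HarmonicSet.harmonics` vs `HarmonicSet.summable`.

Z-scores are meant for group-level spectra: average the participants'
amplitude spectra (`average_spectra`) and apply `zscore` to the average.
Per-spectrum Z works identically when needed.  Electrode ranking orders
channels by their maximum SBL over all condition × session cells, with
ties broken by label order; the top k (default 5) defines the ROI, and
ROI aggregation is an unweighted mean.

## Preprocessing

Order: zero-phase Butterworth band-pass (order 4, 0.1–100 Hz, applied
forward-backward with `sosfiltfilt` — the paradigm depends on phase-locked
averaging, so phase distortion is unacceptable) on the continuous
recording → segmentation into padded epochs (2 s + 60 s + 2 s = 64 s;
epochs that would cross the recording edge are rejected with a warning) →
FIR anti-aliased decimation to 512 Hz (integer ratios only) → optional
artifact hook (an ICA ocular-correction pass can be plugged in here;
component selection is out of scope) → bad-channel interpolation
(unweighted mean of the 3 nearest good channels; distances are 3-D
Euclidean between standard montage positions, because a flat top-down
projection folds the inferior posterior row onto the superior parietal
ring and corrupts neighborhoods) → common-average re-reference (reference
computed over scalp channels only, excluded labels configurable) → crop to
the 60-s stimulation window starting at the event onset (half-open sample
interval, 0-based) → pointwise trial mean.

Common-average referencing is linear, so it re-expresses an injected
topography w as w − mean(w); ground-truth comparisons after the full chain
use this referenced topography (`GroundTruth.expected_bin_amplitude(...,
referenced=True)`).

## Synthetic EEG

The generator lays each trial out as [1-s gap | 2-s fade-in | 60-s
stimulation | 2-s fade-out] with an event marker at stimulation onset, at
64 channels / 1024 Hz / 4 trials per condition by default.  Signal
components are cosines with phase 0 at stimulation onset (identical across
trials) when `phase_locked`, or fresh uniform phases per trial otherwise;
the contrast fades apply a linear amplitude ramp.

Noise is synthesized in the frequency domain: each positive-frequency
coefficient is an independent complex Gaussian scaled by
`noise_scale · f^(−exponent/2)` plus a Gaussian alpha bump (default 10 Hz,
SD 1.5 Hz).  This gives Rayleigh-distributed bin amplitudes with uniform
phases — a literal deterministic-amplitude/random-phase construction would
produce amplitude spectra with zero variance across bins, making Z-scores
degenerate, so the stochastic-amplitude form is required for the noise
statistics to behave like EEG.  The scale convention is anchored to a 60-s
epoch: `noise_scale` is approximately the expected single-trial
amplitude-spectrum floor at 1 Hz in μV, and other segment lengths follow
the same spectral density (floor ∝ 1/√duration).  Noise is independent
across channels and across trials (synthesized per trial chunk).

Defaults are chosen so the study-like contrast is comfortably measurable:
oddball harmonic amplitudes (0.55, 0.45, 0.35, 0.25, —, 0.20, 0.14) μV at
harmonics 1–7 of 2 Hz (harmonic 5 = 10 Hz is left at zero because it would
be indistinguishable from the base response), summing to 0.97 μV of
injected A/2 amplitude over the six summable harmonics — the magnitude of
a clear post-learning word-selective response; `noise_scale` 0.05 and
alpha 0.10 μV put the averaged 4-trial floor near 0.018 μV around 2 Hz, so
the group fundamental reaches Z ≫ 2.33 while a zero-amplitude (pre-
learning) run stays at the floor.  The oddball topography is a Gaussian
falloff (spread 0.03 m in 3-D scalp distance) around the five left
occipito-temporal channels {P9, PO9, PO7, P7, I1}; the base-rate
topography is a broad medial-occipital falloff around Oz.  The montage is
the standard Biosemi 64 10-20 set with four anterior sites (Fpz, AFz, F1,
F2) repositioned to PO9, PO10, I1, I2, forming the extra posterior row and
making the ROI labels exist verbatim.

What the generator does **not** emulate: volume-conducted correlated noise
across channels, ocular/muscle artifacts, electrode drift, inter-subject
topography variability, or any nonlinearity relating stimulus to response.
Passing recovery tests therefore validates the *analysis arithmetic* and
its statistical calibration, not robustness to real-world artifacts.

## Behavioral generator and analysis

Trial tables emulate a pre/post lexical-decision design: categories are
novel words, their real-word neighbors (ON1L), pseudoword neighbors
(PW1L), unlearned words, and word/pseudoword fillers; learned categories
split their items between the two training methods (OP, OPS).  Reaction
times are lognormal with constant log-scale σ = 0.4 (giving SD ≈ 0.42 ×
mean, matching the ratio of the printed group SDs to means); for a target
arithmetic mean m, μ = ln m − σ²/2.  Post-session means add the
calibrated competition shifts: +48.47 ms for ON1L (both methods),
+239.33 / +160.96 ms for PW1L under OP / OPS.  Word-endorsement
probabilities shift for novel words from 0.072 to 0.908.  Categories
without published anchors (novel-word RT, fillers, unlearned) use round
plausible values and are documented as such.

The analysis trims RTs above mean + 3 SD within category × method ×
session (one pass, n−1 SD; a single extreme value in a group of 4 can
never exceed the cutoff since max z = (n−1)/√n = 1.5 — the rule only bites
in larger groups), adds a natural-log RT column, and summarizes each
category × method cell by per-participant means, the group pre/post means
and delta, accuracy per session, and a paired two-sided t on participant
means.  RT summaries use correct trials only by default (standard
lexical-decision practice; configurable).  Mixed-effects modeling is
deliberately not reimplemented; the tidy trial table is the hand-off
point.

## Problem sizes and numerical choices

End-to-end tests run the full 64-channel geometry with 4 × 60-s trials;
calibration tests that do not depend on channel count (averaging law,
null Z rate) use 2–8 channels at 512 Hz, and the null Z calibration uses
16 simulated participants' averaged spectra (≈24,000 scored bins).  The
behavioral type-I check uses 1,000 replicates of a 16-participant,
8-item null generator.  All randomness flows through
`numpy.random.default_rng` seeds; two runs with the same seed are
byte-identical, including pipeline output files.

Known limitations: EDF/BDF files are read (via MNE) but not written (no
maintained pure-Python EDF writer is depended upon; FIF and HDF5 writers
are provided); the ICA hook is pass-through by design; the electrode
ranking uses the max over cells (the field also uses means — trivially
swappable on the SBL table); baseline correction at strong signal bins
carries the method's intrinsic small negative bias (it subtracts the
local noise floor, which the magnitude at a high-SNR bin does not
contain).
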