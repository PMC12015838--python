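# Processing model and methods

This note documents how `gazelab` turns a wearable eye-tracking export
into per-epoch features: the model assumptions, the parameters that
matter (with units and defaults), the numerical choices, what the
synthetic generator does and does not emulate, and the package's known
limitations.

## Time base and units

All streams share one session clock. Timestamps are 64-bit integer
nanoseconds and every interval comparison is integer arithmetic, so
epoch membership never depends on float rounding. Durations are carried
in milliseconds as exported; where a duration is recomputed from
timestamps the two must agree within 1 ms. Pupil diameters are
millimetres, gaze positions scene-camera pixels, surface coordinates
normalised to [0, 1].

When the eye-state table exports separate left/right diameters, the
resolved diameter is their mean; when only one eye is present, that
one. The mean is the symmetric default for a binocular headset; it is
isolated in one resolver function for easy substitution.

## Epochs

Events chain into half-open epochs: event *i* opens `[t_i, t_{i+1})`
and the final event is a pure terminator, so *n* events yield *n − 1*
epochs that tile the analysed span exactly (no gap, no overlap). A
recording with only a start and an end event is analysed as one epoch.
Point samples (gaze, pupil, surface) belong to an epoch iff
`start ≤ t < end`; a sample sitting exactly on a boundary therefore
belongs to the *next* epoch. Interval events (blinks, fixations,
saccades) are assigned whole to the epoch containing their integer
midpoint — they are never split, so per-epoch counts and duration
totals are conserved over any partition. A user-supplied event table
replaces the cloud events wholesale (no merging); it is fatal only when
every replacement event falls outside the recording span, which
indicates unaligned clocks.

## ROI gating

ROI membership is consumed from the surface-enrichment stream, not
recomputed geometrically (the marker/reference-image mapping is the
acquisition platform's job). Policies per stream:

* **Gaze, pupil** — flag of the temporally nearest surface sample,
  within a 25 ms tolerance (≥ 5 nominal sample periods at 200 Hz:
  absorbs jitter without bridging real gaps). Outside tolerance the
  sample defaults to off-ROI and the gap is logged. Gaze flags are
  0/1 integers; pupil flags are booleans.
* **Saccades** — majority vote of the surface samples overlapping
  `[start, end)`; ties (including the no-overlap case) resolve to the
  status at onset. Gaze is valid throughout a saccade, so the interior
  samples are trustworthy.
* **Blinks** — status of the last surface sample at or before onset
  (lookback ≤ 200 ms), else the first sample at or after offset
  (lookahead ≤ 200 ms), else off-ROI with a warning. Gaze is absent or
  unreliable while the lid is closed, so the flag must come from the
  blink's shoulders; the pre-onset shoulder is preferred because it is
  uncontaminated by the re-opening transient.

Unknowns always default to off-ROI (never missing) so downstream sums
stay well-defined; every default is logged. Annotation adds flags only
— it never changes counts, timestamps, or durations.

## Movements

Fixation and blink detection are trusted from the device; `gazelab`
only segments. The ordered run of gaze samples carrying neither a
fixation id nor a blink id, strictly between the last sample of
fixation *k* and the first sample of fixation *k + 1*, is movement *k*.
Samples before the first or after the last fixation belong to no
movement; samples inside a blink are excluded as lid-closed noise. Each
movement reports its duration, path length (sum of consecutive
Euclidean steps), and displacement (first-to-last distance); path
length ≥ displacement always, with equality only for monotone collinear
runs. "Absolute" metrics are computed in scene pixels, "relative"
metrics in surface-normalised coordinates obtained by nearest-timestamp
matching (25 ms) against the enrichment stream — both are reported, as
either reading of absolute/relative is serviced by exposing both
coordinate frames.

## Feature battery and statistics

Each epoch × category cell reports the index set described in the
README. Conventions:

* Descriptive statistics use the **population** standard deviation
  (divisor = count). That is the summary-equation contract this
  pipeline implements, even though the sample form is more common.
* Empty categories yield explicit empty markers (NaN in memory, empty
  fields in the CSV), not zeros — "no saccades" is distinct from
  "saccades of zero amplitude". Counts are genuinely 0.
* The mean fixation position is unweighted; a duration-weighted mean
  was considered and rejected as the less predictable default (the
  longest-fixation position is reported separately).
* The epoch blink filter excludes epochs with **strictly more than 5**
  blinks (configurable). The rationale: with typical blink rates of
  roughly 15–20 per minute, more than five blinks inside a few-second
  window signals acquisition error rather than behaviour.
* `two_sample_ttest` is Student's pooled-variance independent-samples
  test by default, with a Welch unequal-variance switch; two identical
  zero-variance groups report t = 0, p = 1 rather than NaN. The
  implementation delegates to `scipy.stats.ttest_ind`; the test suite
  checks it against a direct evaluation of the pooled formula.

## Pupillometry spectra

The pupil series is linearly interpolated onto a uniform grid (default
200 Hz, the nominal device rate) before any FFT; input gaps longer than
1 s are interpolated through like any other interval but flagged, and
the flagged-gap fraction is returned, so the caller can judge how much
spectrum rests on interpolation. Blink dropouts are thus bridged by
linear interpolation rather than detrended out — interpolation avoids
the spectral leakage of hard gaps while remaining transparent through
the gap report. Welch periodograms and spectrograms use Hann-tapered
256-sample segments with 50 % overlap and per-segment mean removal
(all configurable); frequencies span 0 to half the resampling rate.

## Plot preparation

Every figure is prepared as plain numeric arrays plus annotations
before anything is drawn; rendering applies no numeric transformation.
Colour semantics live in the annotations (green = on-ROI, red =
off-ROI) and are therefore testable as labels. The fixation cloud's
Gaussian KDE uses Scott's rule per axis (scalar override available) on
a 256 × 256 grid padded by three kernel bandwidths per axis, so grid
quadrature of the density recovers ≈ 1. Saccade series are indexed by
saccade order (not interpolated time) and velocities are displayed in
px/ms. Histograms default to 30 bins, fixed for determinism.

## Synthetic recordings

The generator emulates the statistical structure of a screen-watching
session, not oculomotor physiology:

* alternating fixations (duration lognormal, mean 250 ms, sd 100 ms)
  and inter-fixation movements (normal, mean 50 ms, sd 15 ms, floor
  10 ms), with centroids drawn uniformly over a 1600 × 1200 px scene
  and 2 px isotropic gaze jitter;
* blinks as a Poisson count at 17.5 per minute — the midpoint of the
  15–20/min range typical of adults — with lognormal durations
  (mean 150 ms, sd 40 ms), placed uniformly without overlap; the count
  is drawn first and placement retried, so the planted rate is unbiased
  by the non-overlap constraint;
* gaze and eye-state samples on a 200 Hz grid, **omitted during
  blinks** to mirror device dropouts (this exercises the blink
  shoulder policy and the spectral gap handling);
* pupil diameter 3.5 mm baseline + slow sinusoidal drift (0.2 mm over
  the recording) + optional planted oscillation + 0.05 mm white noise,
  exported as left/right diameters sharing the signal with small
  anisocoria noise, so the mean-resolution rule is exercised;
* a surface stream aligned to the emitted gaze grid whose on/off flag
  follows a configurable schedule (uncovered time is off-ROI), with
  normalised coordinates `x/1600, y/1200` clipped to [0, 1];
* the amplitude–velocity link is a fixed factor (peak = 1.8 × mean),
  a monotone placeholder, **not** a saccadic main sequence.

Passing tests on these fixtures therefore demonstrates bookkeeping
correctness (counts, durations, conservation, gating policies,
statistical recovery), not fidelity to real oculomotor dynamics, real
enrichment noise, or real pupil light responses.

The scripted mode builds the same file set from explicit interval lists
with zero noise, for exact-equality oracles; internal inconsistencies
(overlapping or out-of-range intervals) are fatal before anything is
written. Both modes emit a JSON manifest of the planted inventory,
cross-checked against the written streams at generation time.

### The MDMT preset

The packaged worked example encodes a moral-decision-task session of
56 audio-visual dilemmas (one non-moral block plus six condition ×
variation blocks of eight): per dilemma a 1 s inter-stimulus interval,
an audio stimulus drawn from N(27.8 s, 3.00 s²), another 1 s ISI, and
a choice window drawn from N(4.34 s, 2.01 s²) truncated below at
0.5 s (a shorter choice is not a plausible response), with a 30 s
pause after every 7th dilemma. Truncation is by exact truncated-normal
sampling, and the manifest records the analytic truncated mean
(≈ 4.47 s) as the planted value for the choice windows.

## Problem sizes used by the test suite

The statistical checks run at sizes chosen to make sampling error small
against the assertion bands: parameter recovery pools 200 seeds of 60 s
sessions at the generator defaults (≈ 700 k blink-trial seconds,
≈ 38 k fixations, ≈ 2.3 M gaze samples); conservation uses 200 random
partitions of one 30 s session; the MDMT timing check draws 500
dilemmas. All bands are 3 standard errors of the planted models.
`scripts/acceptance.py` reports the MDMT epoch-duration means at the
same 500-dilemma size.

## Known limitations

* Enrichment is required; recordings without a surface stream are
  rejected (ROI gating is central to the feature set).
* No fixation/saccade detection from raw gaze — upstream labels are
  trusted, so label errors propagate.
* No cross-device clock alignment beyond what a replacement event
  table encodes.
* No multitaper/wavelet spectra, no pupil response deconvolution, no
  multiple-comparison correction (plain t-tests only).
* The video-synchronised pupillometry display needs raw video and is
  out of scope; the time-series panel is covered by the ROI-coloured
  pupil plot.
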