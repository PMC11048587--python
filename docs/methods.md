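# Methods

This note documents the models, detectors, and numerical choices behind
`kymovox`, and what its validation does and does not establish.

## Pipeline overview

A high-speed laryngoscopy recording (nominally 2000 fps) is reduced to a
**digital kymogram** (DKG): the pixel row at one fixed scanline across the
glottis, stacked over time. Tracking the left and right glottal edges per
kymogram row yields the **vibrogram** — the glottal-width waveform w(t) —
on which onset landmarks are detected and whose FFT gives the harmonic
structure of the oscillation. Synchronous phonatory-aerodynamic (PAS)
traces of [pa:pa:] tokens provide SPL, F0, airflow, and intraoral pressure,
from which glottal resistance and its change per decibel are derived.

## Synthetic glottis model

No public high-speed recordings of voice onset exist, so validation rests
on simulation with exactly known ground truth. The renderer draws two
bright fold bands (intensity 200) converging on a dark medial gap
(intensity 25) with anti-aliased (area-coverage) edges, additive Gaussian
pixel noise, and 8-bit quantization. Geometry is deliberately minimal: the
validation target is parameter recovery, not photorealism.

Each side's half-gap is

    g(t) = max(0, G(t) − A(t) · cos(2π f₀ (t − t_osc)))

with three ingredients:

* **Adduction ramp** `G(t)`: linear from the resting half-gap (default
  40 px; 60 px in the recovery study) to the final posture half-gap over
  `adduction_time_ms` (default 100 ms), after a quiet pre-roll (100 ms).
* **Amplitude growth** `A(t) = A∞(1 − exp(−(t−t_osc)/τ))` with
  `τ = growth_tau_cycles / f₀` (default 1.5 cycles).
* **Closed quotient** `cq`: the posture half-gap is coupled as
  `G_final = A∞ · cos(π·cq)` (negative for cq > 0.5 — virtual
  over-adduction). This is the unique choice for which the steady-state
  width is a cosine clipped at zero whose flat closed phase occupies
  exactly `cq` of each cycle, giving an analytically known harmonic
  structure (the Fourier coefficients of `max(0, cos(π·cq) − cos θ)`),
  used as the spectral oracle. With cq = 0 the width is a pure sinusoid
  that touches zero only instantaneously — onset does not require full
  closure, as observed clinically.

Oscillation starts a configurable **pre-phonation delay** (default 100 ms;
the study of real tokens reports no numbers, so this default is an order-
of-magnitude choice) after the ramp crosses the one-third-width criterion,
making pre-phonation time a free ground-truth parameter. Ground-truth
`steady_state_frame` is when `A(t)` reaches 90% of `A∞` (t_osc + τ·ln 10),
and `true_cycles_to_steady = floor(growth_tau_cycles · ln 10)`. Landmark
frames may lie beyond the recording when it ends early. The left/right
amplitude split follows the `asymmetry` ratio with the sum fixed at 2A.
**Whiteout** (loss of view, e.g. epiglottis retroflexion) renders whole
frames saturated at 255 over a configurable interval. In full frame
stacks the gap tapers sinusoidally along an odd-length fold extent so the
mid-membranous scanline (taper exactly 1) reproduces the direct kymogram
renderer bit-for-bit in the noiseless case.

The default pixel-noise SD of 5 intensity units (on a 175-unit fold/gap
contrast) emulates a usable-but-grainy fiberscope image. What the
simulator does **not** model: endoscope motion, uneven illumination,
mucus/specular highlights, anterior–posterior phase differences, and true
tissue texture. Passing recovery tests therefore shows the algorithms are
correct and noise-tolerant under these conditions, not that they will
track arbitrarily poor clinical recordings — the QC stage exists precisely
because some real recordings (notably deeper, squeezed male larynges) are
untrackable.

## Preprocessing and DKG extraction

The intensity transfer is fixed as gamma → contrast gain → brightness
offset → rotation → resize (the order is a package convention; sources
describing such adjustment rarely state one). Multiples of 90° rotate
losslessly; resizing uses area averaging (`resize_local_mean`) so
downsizing to the 320×240 analysis format does not alias the edges.
Scanline selection defaults to the row with maximal temporal intensity
variance (the folds oscillate where intensity varies most), overridable by
an explicit index. NPY and multipage TIFF round-trip losslessly with a
JSON sidecar carrying the frame rate; MP4/AVI support requires an
imageio ffmpeg/pyav backend and is otherwise reported as unavailable.

## Edge tracking

Commercial edge trackers for this task are proprietary; the tracker here
is the simplest design whose failure modes mirror practice:

* threshold per row at 50% of the row's min→max range (making the width
  invariant to global intensity gain), or a fixed intensity;
* the gap is the below-threshold run nearest the previous row's gap
  centre (first row: the image centre); ties go to the wider run, then
  the more medial — deterministic by construction;
* edges are refined to subpixel by linear interpolation between the two
  pixels straddling the threshold (≈0.1 px accuracy against the
  anti-aliased renderer; ≤0.25 px width error for gaps ≥4 px);
* a row is **whiteout** when ≥95% of pixels exceed 0.9×255; a row with
  min→max range below `min_contrast` (default 50, chosen above the
  ~40-unit range that pure pixel noise produces across a row) is a closed
  glottis if bright, untrackable otherwise;
* closed rows get width exactly 0 with both edges at the gap centre of
  the nearest open row.

`fill_gaps` linearly interpolates invalid runs up to a length cap and
flags them imputed; QC reports the valid fraction, mean row contrast and
whiteout intervals, with configurable pass minima standing in for the
visual verification a clinician would perform.

## Onset landmarks

* **Adduction criterion**: first frame where the 3-frame-median-smoothed
  width stays ≤ one third of the pre-gesture reference width for ≥5 ms.
  The "one-third" rule is interpreted against the pre-gesture *gap*
  width (the fold width in pixels is not observable in a kymogram); the
  reference is exposed as a parameter and echoed in the report.
* **Oscillation onset** ("just noticeable vibration", which has no
  standard quantitative definition): the first cycle whose peak-to-peak
  amplitude exceeds k·σ (k = 3) of the quiet-segment noise floor (scaled
  MAD; 0.5 px floor) anchors the search, and the onset is the first of 3
  consecutive frames before that cycle's peak whose residual about a
  one-period rolling median exceeds the threshold. The rolling median
  removes both the flat baseline and the linear ramp, and the backtrack
  matters because the first width *maximum* lags the true oscillation
  start by about half a period.
* **Steady state**: first cycle of the earliest run of M = 3 consecutive
  cycles whose periods and amplitudes each stay within 10% of the run's
  medians (both configurable, echoed in the report). Cycle amplitude is
  measured from the cycle's *starting* peak over its trough so a growing
  tail cannot inflate the current cycle; the count to steady state
  includes the partial cycle between onset and the first peak. Against
  the generator's analytic ground truth this agrees to ≤1 cycle across
  growth constants of 0.5–3 cycles.

Cycles are delimited by successive width maxima (scipy `find_peaks` with
the amplitude threshold as prominence); peak times are refined by
quadratic interpolation on a 3-frame boxcar mean (the median filter used
for landmark robustness flattens peaks and would defeat refinement).
Untrackable runs of ≥10 frames that overlap the onset region void the
landmarks they span — the report returns them as absent rather than
guessing through a whiteout.

## Spectral analysis

The steady segment (onset transient excluded, truncated to whole
estimated cycles) is mean-detrended, Hann-windowed, and zero-padded to
the next power of two; power is scaled so that without padding the bins
sum to the windowed-signal energy (Parseval). F0 comes from the mean of
inlier refined cycle periods, cross-checked against the dominant spectral
peak in the 50–600 Hz physiologic range (>10% discrepancy is flagged).
Harmonic peaks are the maxima within ±2 bins of k·f₀ (k = 1..4),
tolerating slight F0 drift; entries above Nyquist are absent. "First
three harmonics" is read as 2f₀, 3f₀, 4f₀ above the fundamental, and both
indexing conventions appear in the JSON output. Published spectra of this
kind carry no absolute axis calibration, so harmonic findings are
validated as *orderings* (higher closed quotient ⇒ larger harmonic/
fundamental ratio; louder configuration ⇒ larger fundamental power and
ratio), never as absolute numbers. Two numerical caveats the tests make
explicit: zero-padding introduces window scalloping of up to ~1.4 dB per
peak, and at 10 samples per cycle the clipped waveform's high harmonics
alias near low harmonics — the Fourier-oracle comparison therefore uses
bin-aligned, unpadded segments at 20 samples per cycle.

## Aerodynamics

Glottal resistance is `(Psub/flow)·1000` in cm H₂O per L/s. Subglottic
pressure is estimated by the standard interpolation practice: intraoral
occlusion peaks (local maxima above 0.7× the interval maximum, ≥150 ms
apart) are read as plateau medians, each vowel takes the linear
interpolation of its flanking plateaus, and the token pressure averages
the interior vowels; fewer than two peaks is an error. Token segmentation
takes maximal SPL runs above a floor (default 65 dB), merging sub-400 ms
dips (the bilabial occlusions) and dropping runs under 300 ms; labels
follow the fixed soft→modal→loud recording order, falling back to
SPL-rank labelling with a warning on a count mismatch. Repetitions of a
level are averaged.

Group summaries use n−1 SDs throughout and a paired t contrast of the
resistance-change-per-dB between the soft→modal and modal→loud
transitions, computed from the closed form t = mean(d)/(sd(d)/√n),
df = n−1 (cross-checked against `scipy.stats.ttest_rel`). Both two-sided
and one-sided p-values are reported: on the embedded six-subject table
the contrast gives t = 3.83, df = 5 (p₂ = 0.012, p₁ = 0.006), so only the
one-sided reading clears 0.01. Regenerating the published summary table
from the embedded per-token rows reproduces most cells but not all: the
modal→loud per-dB mean recomputes to 11.13 (printed 11.15), the
soft→modal mean to 1.28 (printed 1.27), the soft→modal SD to 2.52
(printed 2.49), and a few sex-stratified cells (male pressure mean 4.9 vs
printed 4; male F0 SD 12.7 vs printed 12; female flow 106.7 vs printed
106) differ under any standard rounding. These disagreements are
documented rather than patched; none involves the quantities the
acceptance checks compare.

Rounding for table regeneration is decimal round-half-up to each printed
precision (`round_half_up`), the convention of printed clinical tables.

## Validation design and problem sizes

Because published onset durations are descriptive only, the image
pipeline is validated by **parameter recovery**: 100 seeded tokens with
F0 ~ U(100, 250) Hz, steady amplitude ~ U(5, 30) px, pre-phonation delay
~ U(20, 300) ms at 2000 fps, pixel noise SD 5, other parameters at their
defaults. Each token is generated via the direct kymogram path (the
frame-rendering path is separately verified to agree bit-for-bit) at
~0.6–0.9 s duration. Medians of the absolute errors are ≈0.07 px
(width), ≤1 frame (pre-phonation time), 0 cycles (cycles to steady
state), and ≈0.13 Hz (F0); the whole study runs in a few seconds on one
CPU. Aerodynamic checks run on the embedded 18-row table and on
noiseless synthetic PAS traces built from its targets (full-chain
recovery within 1%).

## Known limitations

* The tracker follows a single gap; diplophonic or doubled-gap imagery is
  resolved by the continuity window, not modelled.
* Steady-state detection under strong clipping (high closed quotient with
  slow growth) can fire one to two cycles before the amplitude-based
  ground truth; at the default growth constant the two agree.
* The PAS simulator uses rectangular plateaus and stationary Gaussian
  noise; real traces drift and their occlusions are not ideal squares.
* No motion compensation, no multi-scanline kinematics, no voice-offset
  analysis, and no perturbation (jitter/shimmer) measures.
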