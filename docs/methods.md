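# Methods

`scratchdetect` detects mouse scratch bouts in cage audio. A scratch bout is
a run of 3–6 hindpaw swipes at a period of roughly 50 ms; each swipe is a
short (~8 ms) broadband burst whose energy stands out above 10 kHz, where
ordinary cage noise is weak. The detector has two passes: a permissive
scan-statistic pass that proposes *candidate islands*, and a random-forest
pass that accepts or rejects each island.

## First pass: scan statistic and candidate islands

Each microphone channel is transformed with a short-time Fourier transform
using ~3 ms Gaussian-tapered windows (128 samples at 44.1 kHz, 256 at
96 kHz) and 3/4 overlap. Power in bins at or above 10 kHz is summed per
frame and smoothed with a unit-sum triangular kernel of 8 ms half-width — a
crude matched filter, since a swipe's power envelope is roughly an 8 ms
triangle. On the smoothed series P_t, a time t* is a **peak** when

* P_{t*} is the maximum of P over the two-sided 25 ms window around t*, and
* P_{t*} − h exceeds the minimum of P over that window,

with strict inequality for the threshold condition and ties in the maximum
broken toward the earlier time. The local (max − min) form makes peak
picking invariant to additive drifts in background level. Peaks from the
two microphones are pooled and near-coincident pairs (< 5 ms) are merged to
their midpoint, closest pair first, iterated to a fixed point. Chains of
peaks with adjacent gaps under 120 ms and at least three members become
candidate islands; island bounds are padded by one 25 ms peak window on each
side so feature windows include burst edges.

The threshold h is the one free parameter. It is expressed in units of the
smoothed power of amplitude-normalized ([-1, 1]) audio and is set by
calibration: the largest value on a 25-point logarithmic grid (spanning
10⁻⁴–10⁰ of the observed smoothed-power range) whose islands overlap at
least 95% of labeled bouts. The first pass is deliberately permissive —
bouts lost here are unrecoverable, while false islands can still be rejected
by the classifier.

## Second pass: features and random forest

Each island receives 117 features.

* **Transform × extractor bank (108).** Six series on the detection frame
  grid: triangular-smoothed power above 10, 15 and 20 kHz; the 10 kHz series
  re-smoothed with a Gaussian kernel (σ = 8 ms); the same re-smoothed with a
  two-Gaussian mixture (σ = 8 and 25 ms, weights ½/½ — the 25 ms component
  spans half a scratch period and blurs adjacent swipes into one hump); and
  the per-frame cosine similarity between the magnitude spectrum and a
  *template spectrum* (the L2-normalized average magnitude spectrum over all
  frames inside training scratch intervals; the similarity of an all-zero
  frame is defined as 0). Transforms are computed per channel and averaged
  across microphones. Each series restricted to the island is summarized by
  eighteen statistics: peak count, mean and standard deviation of inter-peak
  gaps, and {mean, median, min, max, sd} of the series values, of the series
  at peaks, and of per-peak full widths at half maximum. Peaks here use the
  same rule as the first pass with the detection h (the template-similarity
  series lives on a cosine [0, 1] scale, so it has its own threshold,
  default 0.05). FWHM is measured from absolute half-height, walking outward
  from the peak with linear interpolation and clamping at segment edges. A
  statistic without enough support (e.g. the gap standard deviation with
  fewer than three peaks; any sd of fewer than two values) is coded exactly
  −1, letting the forest treat "undefined" as informative.
* **Spectral moments (8).** A coarser STFT of the island's raw audio (50 ms
  bins, 38.5 ms overlap; islands shorter than a bin are zero-padded) gives
  magnitudes |c(t, ω)|; c₁(ω) is their time-mean and c₂(ω) their time-max.
  The moments are m_{i,j,k} = Σ_ω ω^k c_i(ω)^j / Σ_ω c_i(ω)^j for
  (i, j, k) ∈ {1, 2}³, in Hz^k. With two microphones the channel with
  greater island energy is used (configurable). An all-zero island is coded
  −1.
* **Duration (1).**

The classifier is a bootstrap-bagged random forest (500 trees, √p features
per split, unlimited depth, bag size n; scikit-learn ensemble underneath,
with per-tree bag membership recorded). A prediction is the fraction of
trees voting "scratch". Within-recording accuracy uses **out-of-bag**
voting: an island's probability counts only trees whose bag excluded it.
Cross-recording prediction uses all trees. **Neighborhood adjustment**
multiplies an island's probability by the mean raw probability of all other
islands whose midpoints lie within 7.5 s (islands without neighbors keep
their raw value; one pass, no iteration — adjusted never exceeds raw).
Because a training island's label leaks into its neighbors' out-of-bag
votes, adjustment is only evaluated under train/test on separate recordings,
and the command-line interface refuses `--oob --adjust` without `--force`.

Training labels for islands are derived with the same overlap rule used for
scoring: positive iff the island overlaps a labeled bout by more than 50 ms.

## Evaluation

A predicted island matches a labeled bout when they overlap by strictly more
than 50 ms (≈ two swipes). Partial overlaps, islands spanning several bouts
and bouts spanning several islands are handled by one rule: one true
positive per connected component of the bipartite overlap graph containing
at least one island and one bout — the minimal rule consistent with all
enumerated cases. Islands in no such component are false positives. Then

    sensitivity = TP / #bouts,    FDR = FP / (TP + FP),

with FDR defined 0 when nothing is predicted. Tradeoff curves sweep the
distinct predicted probabilities as cutoffs (exact ROC-style sweep).
Scratch-rate curves are Gaussian kernel estimates of bout times (default
bandwidth 60 s, a free choice), reflected at the recording boundaries so the
curve integrates to the event count, reported in bouts per minute.

## Baseline: template matching

For comparison, a rule-based detector computes, over a sliding 50 ms window
of the 10–20 kHz band-passed signal, the log ratio of the energy in the
central 10 ms to the energy in the outer 40 ms (log(10/40) for stationary
noise; strongly positive for an isolated burst). Local maxima above a fixed
threshold are candidate scratches; runs of at least three candidates with
successive gaps within 50 ± 15 ms (the tolerance is our choice) are
predicted bouts. It has no learning stage, so confounder sounds cost it
false discoveries directly.

## Synthetic corpus

The generator plants known truth in white background noise: Poisson cluster
onsets (3/min), 1–4 bouts per cluster separated by 0.3–1.0 s, 3–6 swipes per
bout at 50 ± 5 ms spacing, each swipe an 8 ms 10–20 kHz noise burst with a
triangular envelope at 20 dB SNR over the noise floor, with bout- and
swipe-level gain variation (×0.6–1.3 and ×0.7–1.4). Confounders are planted
alongside and tagged in the truth track: *grooming* (0.3–3 s of broadband
noise with pseudo-periodic 45–110 ms bump envelopes plus high-band click
components) and *walking* (runs of 3–6 variable-width broadband thumps with
strong low-frequency mass, occasionally falling into a steady footfall
rhythm near the scratch period). A quarter of confounder events are
*scratch mimics* — near-periodic trains of scratch-like high-band bursts
(rhythmic paw licking, head shakes). These mimics are the deliberate hard
cases: without them the two classes were linearly separable and the second
pass had nothing to do; with them the corpus reproduces the realistic
regime where a rule-based detector pays a high false-discovery rate and the
learned pass earns its keep. Confounder onsets that would collide with a
true bout are thinned out so scratch truth stays clean. The second
microphone is an attenuated (×0.7) copy delayed by 0.1–0.5 ms plus
independent noise. Everything is a deterministic function of the seed.

Grooming and walking rates (5/min and 14/min) were chosen so the study
corpus lands near the prescribed ~28% positive island balance after
threshold calibration. The packaged study corpus is 20 minutes at 44.1 kHz,
two channels, ~150 planted bouts.

What the generator does *not* emulate: real scratch timbre (unknowable from
published material — bursts are filtered noise, band and envelope
configurable), cage reverberation, microphone frequency response, mouse
vocalizations, and non-stationary background noise. Passing tests therefore
demonstrate that the pipeline recovers planted structure under realistic
interference statistics, not that the packaged defaults transfer to any
particular lab's recordings — the intended workflow is always to label a
portion of one's own recording and train on it.

## Numerical and protocol choices

* Amplitude is normalized to [-1, 1] on read so h has one scale across bit
  depths; 16-bit round trips are exact to half a quantization step.
* Smoothing kernels are normalized to unit sum and use reflection padding,
  so constants pass through unchanged and series means are preserved up to
  boundary effects.
* The Gaussian STFT taper uses σ = window/6 (≈1% amplitude at window edges);
  the band cut "above 10 kHz" is inclusive (bin center ≥ cut).
* "Overlap of more than 50 ms" and the peak-threshold condition are strict
  inequalities.
* The 7.5 s neighborhood is defined on island midpoints and excludes the
  island itself; averaging uses raw (not adjusted) neighbor probabilities.
* Stratified subsampling keeps the class that must not shrink and subsamples
  the other without replacement; it errors when no integer split comes
  within 2 percentage points of the target balance.
* Forests are fitted single-threaded with a fixed seed; the full
  simulate → detect → featurize → train → predict path is bit-reproducible.

## Problem sizes in the test suite

The packaged checks run the full pipeline on the 20-minute study corpus
once (shared across tests) and use shorter recordings (40–600 s) for
module-level and cross-recording checks. The training-size comparison uses
subsample sizes scaled to this corpus (≈69% and ≈17% of the training pool,
the same ratios as 2000 and 500 islands out of 2880) because the corpus
yields ~400 islands in total. These sizes are the package's own choices for
a self-contained, reproducible test corpus.

## Known limitations

* Confounder acoustics are stylized; only their timing statistics and
  band-energy profiles are controlled.
* The two-microphone model assumes a shared clock (one multi-channel file);
  clock drift between independent recorders is out of scope.
* The merge rule for cross-channel peaks is deterministic (midpoint,
  closest pair first) — one of several readings of "merge pairs within
  5 ms"; alternatives differ only at pathological peak spacings.
* No probability calibration is attempted; cutoffs are chosen on the
  sensitivity/FDR curve directly.
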