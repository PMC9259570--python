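# Methods

This note documents the models, conventions and design choices behind
`calyximg`, in the spirit of a methods section: enough detail to
re-derive every number the package produces.

## Signal model

A recording segment is modelled as

    F(t) = B · e^{−t/τ_b} · (1 + s(t)/100) + ε(t)

where `B` is the baseline intensity (16-bit scale), `τ_b` a
mono-exponential bleaching constant, `s(t)` the summed transient signal
in %ΔF/F, and `ε(t)` i.i.d. Gaussian noise whose SD is a fixed
percentage of the *bleached* baseline (so signal-to-noise is
bleach-invariant).  Transients multiply the baseline rather than adding
raw counts, which keeps planted %ΔF/F amplitudes interpretable after
downstream normalization.  A transient rises linearly over
`rise_frames` frames to its amplitude and decays as `exp(−t/τ)`;
overlapping transients superpose additively, which is what produces the
"short decay with a superimposed new event" candidate shape.

## %ΔF/F processing

* **Filter.** 2nd-order Butterworth band-pass, 0.025–5 Hz, applied
  forward–backward (`sosfiltfilt`, reflective padding), so the filter is
  zero-phase and event onset/peak timing is preserved.  The filter family
  and order are this package's choice; only the band is fixed by the
  method being implemented.
* **DC restoration.** A 0.025 Hz high-pass removes the mean, which would
  drive the percentile baseline to ≈ 0 and make the ratio meaningless;
  the pre-filter segment mean is added back after filtering.
* **Baseline.** `F₀` is the 8th percentile of the filtered segment,
  using the linear-interpolation percentile convention, computed *after*
  filtering (the processing steps are applied in sequence).  By
  construction at most 8 % of frames fall below 0 %ΔF/F.
* **Edge behaviour.** The 0.025 Hz high-pass has a settling time of tens
  of seconds; on short segments the first/last few seconds carry a
  residual transient.  Filtering is applied per analyzed segment with
  reflective padding, and segments shorter than three filter startup
  lengths are processed with reduced padding and a warning.

%ΔF/F is exactly invariant under multiplicative rescaling of the raw
intensities (the whole chain is linear up to the final ratio).

## Event detection

The numeric acceptance rules for an event are: rise of ≥ 2 frames
(100 ms at 20 Hz) from onset to the peak; relative amplitude
(peak − onset, on the unsmoothed trace) ≥ max(0.02 %ΔF/F, 0.3 · SD) with
SD the *pooled* population standard deviation of all of the animal's
%ΔF/F samples across segments; peak = first strict local maximum within
2 s of the onset (plateaus take their first frame).

These rules filter *candidates*; they do not define a detector.  In the
original workflow candidates were identified visually, which implicitly
rejects fluctuations that merely clear the 0.3·SD bar — on a band-passed
trace the typical noise excursion is comparable to the trace SD itself,
an order of magnitude above that bar.  The deterministic surrogate for
visual screening is:

1. onsets at local minima of a 3-frame moving average of the trace
   (the *foot* of each rise: the last non-rising frame before it);
2. a prominence gate: the smoothed rise, measured against the higher of
   the onset value and the trailing 1-s median (21 frames), must reach
   5 × a robust noise SD estimated as `1.4826 · MAD(ΔF)/√2` — an
   estimator sparse transients barely perturb;
3. a persistence gate: after its smoothed peak the trace must stay above
   the half-rise level for ≥ 4 frames (0.2 s) — transients decay over
   many frames, noise bumps collapse within a couple.

Both gates vanish on noiseless traces (the noise estimate is 0), so the
proposal reduces to pure rise geometry there.  Smoothing and gates are
used only to *propose* candidates; amplitude and timing are always
measured on the raw trace, with the onset snapped to the raw-trace
minimum within ± 1 frame (ties resolved toward the later frame) before
the numeric criteria are applied verbatim.  Gate parameters were frozen
after a simulation study at 5× SNR (transient amplitude 1.0 %ΔF/F,
noise 0.2 %): pooled F1 against planted events is ≈ 0.97 at 0.1 Hz and
≈ 0.94 at 0.2 Hz event rate; without the gates the same conditions yield
several hundred false positives per 139-s segment.

Tie-breaks and edge rules: a candidate whose 2-s peak window crosses the
segment end is dropped with a warning; two candidates resolving to the
same raw peak are merged into the earlier onset; superimposed events are
split at interior local minima during a decay.  Lowering either
amplitude threshold can only add events (monotonicity), which the tests
verify.

## Evoked responses

The evoked response of a trial is `Σ %ΔF/F` over the stimulus window
minus the sum over the immediately preceding window of equal length —
9 s for the visual danger stimulus (starting at the first movement-cycle
onset; the second cycle, 2.2 s + 2 s later, falls inside it) and 1 s for
the mechanical pulse.  Sums are over frames (units %·frame) at the fixed
frame rate; a time integral would differ only by the constant 1/20 and
change no comparison.  Windows are half-open frame intervals; the trial
is rejected if fewer pre-stimulus frames exist than the window needs.

## Spatial activity patterns

Per analyzed segment: 2×2 pixel binning (block means; odd edges cropped
with a warning); per-pixel %ΔF/F against a centered 400-frame (20 s)
rolling mean with shrinking windows at the edges; subtraction of the
global minimum of the normalized video, so all values are ≥ 0 while
relative intensities are preserved.  The pattern of an event is the mean
of its peak frame ± 1, divided by the in-ROI maximum, Gaussian-smoothed
(σ = 1 px, skippable per animal), and thresholded at 0.5.  After
smoothing the map is re-normalized to the in-ROI maximum before
thresholding — smoothing lowers the peak, and re-normalizing keeps the
0.5 threshold meaningful relative to it and guarantees the surviving
maximum is exactly 1.

Patterns are clustered with K-means (scikit-learn, ≥ 10 restarts, fixed
seed) on the in-ROI pixels vectorized in row-major order.  When k is not
given it is chosen by maximum mean silhouette over k ∈ [2, 8] — a
deterministic, standard heuristic adopted because no per-animal rule for
k is available; it is overridable.  Stimulus-evoked patterns are
assigned post hoc to the nearest centroid (Euclidean distance over
in-ROI pixels); they are flagged as *matching* the spontaneous
repertoire when their distance is within the 95th percentile of that
cluster's member-to-own-centroid distances — a convention of this
package, stated as such.

Two interacting limitations matter here.  First, the centered rolling
mean turns a bleaching trend into end-of-segment dips, and the
subsequent global-minimum subtraction then raises the floor of *every*
frame, compressing pattern contrast; motif recovery is therefore
benchmarked under negligible-bleach, high-amplitude conditions.  Second,
an activation map taken while two transients overlap in time is a
mixture of motifs and cannot be assigned to either; the recovery
benchmark uses a low event rate and a short decay constant
(0.06 Hz, τ = 0.5 s over 180 s) so that events are temporally isolated.
Under those conditions (three motifs, centers ≥ 10 blob-σ apart, 48×48
frames) end-to-end clustering recovers the planted labels perfectly.

## Group statistics

Each measure (event rate over pre/pos; vds and mec evoked sums over
bas/stim) is analyzed with a mixed-design ANOVA: group (between) ×
period (within, 2 levels).  Sums of squares use the classical weighted
univariate decomposition; because every subject carries both
within-factor levels the five components add exactly to the total also
for unequal group sizes, and each F ratio uses the error term of its
stratum (subjects-within-group for the between factor; period × subjects
for the within factor and the interaction), giving F(1, N−2) throughout
the 2×2 design.  An effect with literally zero sum of squares is
reported as F = 0, p = 1 even when its error term is also zero.

Post hoc tests follow each omnibus: a paired t-test per group across the
within levels, plus an independent t-test on the groups' difference
scores — Welch-adjusted whenever group sizes differ.  That set of tests
is the family used for the Holm–Bonferroni step-down correction, and the
family membership is recorded in the report rather than left implicit.
Stimulus-transient tests are one-tailed (an *increase* over basal
activity is the hypothesis); all others two-tailed.  Identical paired
samples are reported as t = 0, p = 1 (a zero effect measured with zero
noise); two constant independent samples with equal means leave the
statistic undefined and raise.  The Pearson correlation relates each
animal's (pos − pre) rate change to its vds (stim − bas) delta; its
p-value comes from the exact t transform with n − 2 df.  All p-values
use exact distribution functions, never simulation.

## The synthetic cohort

The generator's defaults are the study conditions: 20 Hz frame rate;
139-s spontaneous segments (the average analyzed length, inside the
60–188 s range; hard cap 400 s); a 27-s context with the vds occupying
its last 9 s as two movement cycles 2.2 s + 2 s apart; a 1-s mechanical
pulse; 6 NAIVE and 5 TR animals (matching the rate design's F(1,9));
baseline 10 000 counts, bleaching τ = 600 s.

Event rates and amplitudes are not reported numerically in the study and
are free parameters chosen once: spontaneous rate 0.10 Hz, transient
amplitude 1.0 %ΔF/F with 2-frame rise and τ = 1 s, noise 0.2 %ΔF/F
(5× SNR — transients a human would identify without hesitation), evoked
amplitude 2.0 %ΔF/F per movement cycle.  The planted group effects are a
+0.12 Hz post-context rate increase in TR animals and a suppression of
the TR vds response to 0.2 %ΔF/F (a weak, mostly non-significant
residual trend); NAIVE and TR_CHX animals get neither effect, and the
mec response is identical across groups.  The effect sizes were fixed by
a prospective power analysis at n = 6/5: the full qualitative pattern
(significant rate interaction; NAIVE vds > basal one-tailed but not TR;
negative rate-change/evoked correlation) reproduces in ≈ 90 % of
cohorts, comfortably above the 80 % the calibration checks demand.

What the generator does *not* emulate: photon-shot (Poisson) noise,
motion artifacts, dye diffusion or non-exponential bleaching, per-animal
heterogeneity in rates or amplitudes, and spatially correlated noise.
Passing recovery tests therefore show that the analysis rules are
implemented correctly and behave as designed under their stated
assumptions — not that the pipeline is robust to every pathology of real
recordings.

## Problem sizes and determinism

The test suite and the acceptance script size their simulations to run
comfortably on one CPU: 50 segments for the detection benchmark, 100
noiseless segments for rate recovery, 500 null cohorts (pre/pos only)
for type-I calibration, 20 planted cohorts for the qualitative pattern,
200 random datasets for the ANOVA oracle, and one 180-s 48×48 movie for
motif recovery.  Every random draw descends from a single seed via
`numpy.random.SeedSequence` spawning, so any run — including each
animal's stream inside a cohort — is exactly reproducible; K-means uses
a fixed `random_state` with 10 restarts.

## Known limitations

* The candidate-proposal gates (5× robust noise SD, 0.2 s persistence)
  are calibrated for transients resolvable at 20 Hz with τ on the order
  of 0.5–1 s; much faster or slower kernels warrant re-tuning.
* Pooled-SD thresholding couples segments within an animal: a segment
  with large evoked transients raises the bar for every segment of that
  animal.  This mirrors the method's definition and is not removed.
* The silhouette rule for k and the 95th-percentile match criterion are
  conventions; both are exposed as parameters.
* Movies are analyzed as-is: motion correction, neuropil subtraction and
  image registration across animals are out of scope.
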