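# Methods

This note documents the models and numerical choices behind `gaitfall`:
what the synthetic cohort generator emulates, how gait events and the 58
descriptors are computed, how the feature engineering and random-forest
experiments are wired, and where the open design decisions were settled.

## Synthetic walk model

A walk trial is a 100 Hz record of tri-axial trunk acceleration (AP/ML/V,
m/s²; V includes gravity) plus vertical angular velocity (deg/s), with 5 s
of quiet standing before and after the walk, matching a 10-m walk protocol
with two trials per participant.

**Stride schedule.** Stride durations are drawn i.i.d. normal with the
programmed mean (default 1.1 s) and CV (default 3%), clipped at 0.4× the
mean. Contralateral heel contacts fall at fraction 0.5 + asymmetry of each
stride plus an independent step-phase jitter with SD equal to half the
stride SD; without that jitter the second foot's stride series would
average adjacent stride times and carry only ~70% of the programmed CV.
Toe-offs trail the contralateral HC by half the double-support fraction
(default 0.20 of a cycle, i.e. swing ≈ 0.40).

**Signal model.** Each axis is a sum of stride harmonics 1–10 on a
piecewise-linear stride phase anchored at the HCs: AP and V are
even-harmonic dominant (two oscillations per stride), ML odd-dominant. On
this phase every sine harmonic attains its maximum slope exactly at each
HC, which is the landmark the wavelet detector locates in real trunk data;
validating the detector against the generator is therefore a recovery
test, not a circular definition. A negative Gaussian transient (σ = 25 ms,
1 m/s² by default) marks each toe-off in AP (the push-off). Noise is a
white/pink mixture at a programmed SD (default 0.12 m/s² per axis, 30%
pink), the standard model for the broadband and 1/f components of trunk
accelerometry. The gyro is a smooth alternating-sign waveform equal to
±amplitude exactly at each HC (positive ↔ right stance by convention).

**Faller phenotype.** Fallers get stride-time CV ×1.5, pink-noise fraction
+0.2, dominant-harmonic amplitudes ×0.7 (reduced smoothness ⇒ lower
harmonic ratio and RMS), and walking speed −0.1 m/s. Between-participant
heterogeneity (speed SD 0.10 m/s, stride-time SD 0.08 s, log-normal
spreads on stride CV σ=0.4 and harmonic amplitude σ=0.25, pink-fraction SD
0.15) is calibrated so these shifts amount to ~1.0–1.5 within-class SDs
per affected descriptor: classes are separable but clearly overlapping,
as in real fall cohorts, and a neutral phenotype yields chance-level
classification.

**What the generator does not model:** turns, stops, shuffling or other
non-steady gait; sensor drift and re-orientation; spatial parameters (no
true step length per step); inter-trial learning effects. Passing tests on
this cohort demonstrate that the pipeline recovers the structures it
claims to measure, not that the specific effect sizes transfer to any
clinical population.

## Event detection

The resultant acceleration (rotation-invariant) is filtered with a
zero-phase 4th-order Butterworth low-pass at 2 Hz. Zero-phase
(forward–backward) filtering is used even though a single pass would match
the nominal order, because event timing must not be lagged; the effective
attenuation is squared. The filter runs on the whole record so the walking
window has no edge transients.

The filtered resultant is convolved with a symlet-4 waveform at one scale
in the 35–70 band. PyWavelets exposes sym4 as a discrete wavelet only, so
the single-scale transform is computed directly from the sampled waveform
(`wavefun`), with the kernel's group delay measured on a probe sinusoid at
the scale's pseudo-frequency and rolled out — making the coefficient
series phase-neutral at band center. The detection scale is chosen so the
pseudo-frequency (0.714·fs/scale for sym4) matches the dominant spectral
peak of the walk-window resultant in 0.5–3 Hz; the HC landmark recurs once
per *step* (~1.7–2 Hz at ordinary stride times, which is exactly the 35–70
scale band at 100 Hz), with the band midpoint as fallback.

Heel contacts are maxima of the time-differentiated coefficient series,
with a 0.25 s minimum separation and peaks below 20% of the 90th-percentile
height discarded; intervals above 2 s raise a warning. Because the wavelet
kernel spans ~2.5 strides, raw CWT peak timing is slightly averaged across
neighbors; each retained peak is therefore re-located at the nearby maximum
(±0.2 step) of the derivative of a 5 Hz-filtered resultant, whose impulse
response is much shorter than a stride. This refinement is what lets the
downstream gait-cycle-time CV read the programmed stride variability
within ±1 percentage point instead of ~80% of it.

Toe-offs: for each HC, a window opens at HC + 50 ms and closes at the next
zero crossing of the differentiated coefficient series, never earlier than
HC + 0.35 step and extended to HC + 0.6 step if the crossing is degenerate.
The TO is the first local minimum of the 10 Hz-filtered AP signal with
prominence ≥ 5% of the AP range; the minimum is refined by removing the
local linear trend (estimated from symmetric straddling samples, where a
symmetric transient cancels) and fitting a parabolic vertex, since the
slope of the underlying gait harmonics otherwise drags the minimum by
several milliseconds. Windows without a qualifying minimum yield a missing
TO; only TO-dependent parameters drop that cycle.

Sides: the first HC takes the sign of the vertical angular velocity
(positive → right, configurable); sides alternate thereafter. A first-HC
gyro value within a small epsilon of zero defers to the next unambiguous
HC. The first and last detected stride are excluded from every descriptor;
a trial must keep at least one stride after exclusion (and at least three
detected) or it is rejected.

## Descriptors

Temporal parameters follow the event table: gait cycle time = ipsilateral
HC→HC; step time = HC→contralateral HC; single-stance time per foot =
that foot's HC→TO; swing = TO→next ipsilateral HC; double support = sum of
the two double-support periods per cycle. Summaries are mean, sample SD
(n−1; per-trial stride counts are small), and CV = SD/mean×100. Walking
velocity is distance/duration in cm/s. The "time to velocity quartile"
descriptors are operationalized via the cumulative distance profile (each
detected step advances an equal share of the 10 m): the reported time is
when 25/50/75% of the distance is first covered, interpolated between heel
contacts. This definition is isolated in one function (`velocity_features`)
so an alternative reading can be swapped in.

RMS is computed on mean-removed walk-window signals (the V axis otherwise
just reads gravity); normalized RMS divides each axis RMS by the Euclidean
norm of the three, so the squared shares sum to 1. Harmonic ratios
resample each included stride to 1024 points (uniform harmonic indexing
across variable stride times), take rfft amplitudes, and divide Σ even by
Σ odd harmonics 1–20 for AP/V (inverted for ML); a vanishing denominator
caps the ratio (default 100) with a flag.

The 2 Hz low-pass is used **only** for event detection: a 2 Hz cutoff
would delete harmonics 3–10 (HR needs content up to ~9 Hz) and the very
noise structure the entropy and recurrence measures quantify, so all
amplitude/frequency/complexity descriptors use the raw, mean-removed
walk-window signals.

Nonlinear measures: SampEn with m = 2, r = 0.25·SD (Chebyshev distance,
self-matches excluded, both template lengths drawn from the first N−m
positions); ApEn per Pincus with self-matches included (reported as an
auxiliary column — it is not one of the 58 model inputs). MSE coarse-grains
by non-overlapping means with the tolerance held at the scale-1 SD; the
curve is summarized by trapezoidal area (complexity index) and
least-squares slope. Default scales 1–6 keep ≥150 coarse samples for a
~10 s walk; `EntropySpec.for_length` applies the same ≥150-sample rule to
longer series (scales 1–13 at n = 2000), where the white-vs-1/f area
contrast is decisive. RQA z-scores the series, embeds at dimension 5 /
delay 10, thresholds Euclidean distances at 40% of the maximum pairwise
distance, excludes a Theiler band (= delay) around the identity line, and
reports recurrence rate, determinism (points on diagonals ≥ 2), Shannon
entropy (nats) of the diagonal-length histogram, and MaxLine. A degenerate
embedding (all points identical) is flagged with recurrence = determinism
= 1.

The 58-descriptor registry reproduces the published descriptor list
verbatim, including its binning of `RMS_AP` with the nonlinear block and
the lowercase `RSwt_cv` spelling — the 33/25 linear/nonlinear split only
adds up with that binning, and Experiments I/II consume the families as
listed. Each participant's vector averages their two trials (NaN-aware).

## Feature engineering

Discrepancy screening: the training rows are randomly halved 1000 times;
each repeat runs a per-feature two-sample Welch t-test (Student's by flag)
between halves, and p-values are averaged. Labels never enter. The k
features (default 4) with the lowest averaged p — those that behave
inhomogeneously across random subsets of the same source — are removed; a
count, not a p threshold, is the knob. A feature constant within a split
contributes p = 1 for that repeat and is logged.

PCA operates on z-scored features (training mean and n−1 SD; the
descriptor list mixes seconds, cm/s and unitless quantities, so
correlation-mode is the only defensible default), keeps the smallest
component count reaching 99% cumulative explained variance, and fixes
signs so each component's largest-magnitude loading is positive. Center,
scale and loadings are fitted on training rows only and applied unchanged
to held-out rows; the pipeline hashes every matrix a fit touches so
blind-test isolation is auditable.

## Forests and experiments

The forest grows unpruned Gini CART trees (scikit-learn trees) on
bootstrap samples drawn here, not by scikit-learn, so out-of-bag
membership is explicit: the OOB prediction for a row is the majority vote
of the trees that never saw it, and the OOB error is the mean mismatch
over rows with at least one OOB vote (rows with none are excluded with a
warning). In-bag coverage per tree is ~63.2% of rows, and the OOB estimate
tracks held-out error within a few points — both are tested. `mtry`
features are considered per split; default (trees, mtry) pairs per
experiment are (365, 1) and (311, 3) for Experiment I linear/nonlinear,
(230, 1) and (490, 18) for Experiment II, (490, 20) for Experiment III,
with a grid helper (`error_surface`) for exploring alternatives.

A vote fraction at or above 0.5 predicts "faller" (ties go to the positive
class — the clinically conservative choice; configurable). Metrics are
accuracy, sensitivity, specificity, F1 (harmonic mean of precision and
sensitivity), Matthews correlation, and AUC over vote fractions, reported
as mean ± SE (SD/√n) over 10 seeded forest runs; OOB errors are averaged
the same way.

Experiment III starts from the nonlinear PCs and adds linear PCs in
explained-variance order; for each k the OOB error and OOB-vote AUC are
averaged over 5 seeded forests (a single OOB curve is too noisy to place
an elbow), and k* is the smallest k minimizing mean OOB error, ties broken
by higher AUC then fewer PCs. Selection AUC uses OOB votes on training
data only, keeping the blind test blind. Class imbalance is left
unweighted by default (a flag exists); the test split touches only
`pca_apply` and `evaluate`.

## Problem sizes and degenerate inputs

Validation runs use 12–20-stride walks for event benchmarks (50 seeds),
66 m walks for variability recovery, n = 2000 series for the noise
complexity ordering, a 400-row Gaussian cohort for OOB honesty, and the
study-shaped cohort (127 train / 44 test, two trials each) for the
end-to-end experiments — sizes at which each quantity's sampling noise is
small against the margin being tested. Degenerate inputs are never silent:
quiet standing yields zero events; constant series yield zero entropy and
flagged RQA; zero-variance features get unit scale in PCA with a warning;
single-class training splits are rejected.
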