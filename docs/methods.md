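# Methods

This note documents the models and procedures implemented in
`noxpipe`, the choices made where the design was genuinely open, and
what the synthetic cohorts can and cannot establish.

## Signals and conventions

The stimulus is at t = 0; windows are half-open `[start, end)`;
times are in seconds, postmenstrual age (PMA) in days internally
(weeks at presentation). EEG epochs span −0.5…+1.05 s for ERP work and
−2.5…+4 s for time–frequency work; ECG ±30 s; EMG −5…+15 s. The cohort
interchange format is long-format CSV (signals, demographics,
behaviour, missing-feature table, config YAML); EDF can be read
through mne. Signals below the working EEG rate (2 kHz) are upsampled
by polyphase resampling on read.

## EEG pipeline

**Filtering.** Zero-phase Hamming windowed-sinc FIR filters designed
by mne and applied as a single `same`-mode convolution; band-pass
1–30 Hz with mne's standard transition rule (min(max(0.25·f, 2 Hz), f),
so 1 Hz for the high-pass edge) and a 2 Hz-wide 50 Hz notch. Filter
kernels are cached per (rate, band). Epochs whose filtered amplitude
exceeds 250 µV, or that are flat, are treated as artifacts and their
cerebral features marked missing — an automated stand-in for visual
artifact rejection.

**Age weighting.** `w(Δ) = exp(−½·(2.5·Δ/R)²)` with R = half the
window length, zero beyond R. The constant 2.5 places the stated
landmarks: w ≈ 0.46 at a 2-week offset of the 56-day window (and at a
1-week offset of the 28-day trajectory window), w ≈ 0.04 at the window
edge. The weighting function is shared by the ERP reference averaging
and the developmental trajectories.

**Woody alignment.** Integer-sample lag maximizing the Pearson
correlation between the epoch and the reference on the first
post-stimulus second, bounded at ±50 ms; the epoch is shifted by the
negated lag with edge-value padding; no sub-sample interpolation. The
alignment is single-pass against the age-weighted reference.
Alignment maximizes the *signed* correlation: content matching the
reference is registered exactly, anti-correlated content is attenuated
rather than amplified. A consequence is that the projection
coefficient (below) is exactly linear in epoch amplitude for
positively-scaled epochs and conservative (shrunk toward zero) for
polarity-inverted ones.

**Temporal PCA.** Epochs are variables, timepoints observations; each
epoch is mean-centred over time (no centering across epochs, so the
decomposition is of second moments, not covariances); the left
singular vectors of the timepoints × epochs matrix are the principal
waveforms, unit-norm by construction. The smallest number of
components reaching 75% cumulative variance is retained, with a floor
of three per response set so the feature table always carries nine PC
features. Sign convention: the mean training-set projection
coefficient is non-negative.

**Projection.** An epoch (baseline-corrected to its prestimulus mean)
is Woody-aligned to the unit-norm waveform, and the coefficient is the
inner product of the aligned first-second segment with the waveform —
the least-squares regression weight. The template of noxious-evoked
brain activity is consumed from a user-supplied single-column file;
its documented fallback is the third noxious-set principal waveform,
whose shape it closely matches.

**ERSP.** Morlet wavelets at 59 frequencies, 1–30 Hz in 0.5 Hz steps,
with cycles(f) = 3 + 42·(f−1)/29 (3 at 1 Hz to 45 at 30 Hz — half the
cycle count of the equivalent FFT window). Single-trial power at each
frequency is divided by that frequency's mean power in the 500 ms
before the stimulus, then 10·log10-transformed (divide-then-log, in
that order). The epoch is reflection-padded beyond the longest
wavelet's half-support before the transform so that the analysis
interval is supported by data; the map is trimmed to the edge-free
interval (−1…+2.5 s for the default epoch) and linearly resampled to
200 time pixels. Window features are arithmetic means over pixels
whose centres fall in the five windows of interest (early delta
250–750 ms × 2–4 Hz; early alpha 250–750 ms × 7–15 Hz; late delta
1–2 s × 1–2 Hz; late alpha 1–2 s × 7–15 Hz; late beta 1.5–2.3 s ×
28–30 Hz).

A property of the single-trial log transform worth knowing: under
stationary noise the expected dB value is not 0 but a small negative
constant (the mean of the log of a normalized power ratio; for
exponentially distributed power the offset is ≈ −2.5 dB at a single
pixel, partially cancelled by baseline averaging). The offset is
uniform across the map and identical between conditions, so window
contrasts and condition comparisons are unaffected; the test suite
asserts uniformity rather than a literal zero.

## Physiological features

**Heart rate.** ECG band-passed 12–40 Hz; R peaks picked at 40% of the
98th absolute-amplitude percentile with a 250 ms refractory period
(deterministic replacements for manual peak correction; fewer than two
peaks marks the feature missing). Heart rate at each integer second is
60 / (mean RR interval overlapping the centred 3-s window), valid only
where the window holds ≥2 peaks. The evoked rise is the maximum over
(0, 15] s minus the mean over [−15, 0) s; both windows are
configurable (14 s mode for recordings with shorter coverage — note
the 14-s and 15-s definitions are deliberately not numerically
identical). The centred window alignment is this package's choice; the
method description does not state one.

**Limb withdrawal.** EMG is rectified first, then band-passed
10–500 Hz with 50/100/150 Hz notches; RMS per 250 ms bin; post-stimulus
bins divided by the mean RMS of the four prestimulus-second bins; the
feature is the mean of the four bins in [0, 1) s. It is exactly
invariant to amplitude scaling. A zero baseline makes the fold-change
undefined: the feature is returned missing with a degenerate-baseline
warning. Sides are processed independently; an absent contralateral
channel yields a missing feature.

## Classifier

500 CART trees on bootstrap resamples of the observations (an
infant-level bootstrap is available behind a flag; observation-level
is the default), Gini impurity with exhaustive threshold search,
minimum leaf size 3, all predictors eligible at every split (unlike a
random forest). The per-node split search is scikit-learn's; the
surrogate-split machinery is this package's own: at each internal
node, up to five surrogate splits are ranked by their agreement with
the primary split on the in-node bootstrap rows (kept only if they
beat the blind-majority rule), and a row missing the primary variable
at prediction time follows the best available surrogate, falling back
to the branch holding the training majority. Surrogates are computed
lazily and cached, since most rows never need them. Ensemble
prediction is a majority vote; ties break toward nonnoxious; the vote
fraction serves as a probability-like score.

Evaluation is leave-one-infant-out: both of an infant's events are
held out together. Reports carry accuracy with Wald binomial 95%
intervals (which reproduce the reference intervals 74/94 → 0.70–0.87
and 124/148 → 0.78–0.90), FPR/FNR, and per-bin accuracies over the
half-open PMA bins [28, 31), [31, 34), [34, 37), [37, 40) weeks with
bins under three infants flagged unreliable. Out-of-bag importance
permutes each feature's OOB values per tree and standardizes the
accuracy drop by its across-tree mean/SD (sample SD); held-out
importance permutes the held-out rows 50 times per tree per feature.
The curvature/interaction split-selection test used by some
implementations to de-bias impurity importances is not reproduced;
only permutation importances are reported, which do not need it. The
reduced model retrains on the four most important features (heart
rate, late delta, ipsilateral reflex, template by default) plus PMA.

## Developmental statistics

Trajectories are age-weighted means (or weighted medians for EMG) on a
weekly PMA grid using the Gaussian kernel with a 4-week window;
brow-bulge development uses response proportions (duration > 0) in
hard ±1.5-week windows. The weighted median is the non-interpolating
rule: the smallest value whose cumulative normalized weight exceeds
0.5.

PMA associations are ordinary least-squares slopes (per PMA week) with
two-sided permutation p-values, p = (1 + #{|t*| ≥ |t|}) / (n_perm + 1),
n_perm = 10 000 by default; with nuisance covariates (postnatal age)
the Freedman–Lane scheme permutes nuisance-model residuals. The
11-test Holm–Bonferroni family is: heart rate, the three noxious-set
PC coefficients, the five ERSP windows and the two reflexes; the
template (redundant with the third PC) and brow bulge are excluded,
and the PNA-adjusted exploratory models are reported unadjusted for
multiplicity. Paired condition comparisons use sign-flip t-tests with
exact enumeration whenever 2^n does not exceed the requested flip
count. The trajectory summary z-scores each feature across the noxious
events, computes its age-weighted curve and orders features by the
OLS slope of the z-scores on PMA; cluster labels are not assigned —
the ordering exposes the decreasing and increasing blocks.

## Synthetic cohort generator

The generator defines the study conditions for all tests. Per infant:
PMA evenly covering [28, 40) weeks with small jitter, postnatal age
< 8 weeks, one noxious and one nonnoxious event.

*EEG.* A deterministic kernel plus 1/f-and-white background noise
(5 µV RMS default). The kernel mixes (a) shared components — an
immature slow wave (80 µV peak, fading steeply around 29.6 weeks) with
a superimposed 15 Hz burst, the delta-brush-like pattern, and a small
early N–P complex — and noxious-only components scaled by the `erp`
effect scale: (b) a transitory negative deflection at 445 ms, largest
near 30–31 weeks and gone by ~36, and (c) a positive deflection at
~600 ms with a small early P–N complex, rising from ~33 weeks to a
plateau at term. The noxious response also supplants 25% of the slow
wave, leaving it larger in the control condition. Per-infant gamma
amplitude gains (mean 1, CV 0.5) model idiosyncratic response
magnitude. All component shapes are zero-mean biphasic waveforms
(Ricker / mean-corrected windowed cosines) with near-exclusive age
bands: this was calibrated — at the level of shapes and relative
amplitudes, not of any test threshold — so that uncentered temporal
PCA on a cohort decomposes them into separate components in the
canonical order (slow wave, negative 445 ms, positive ~600 ms) with
the canonical condition and age directions. With temporally or
developmentally collinear components, PCA instead returns sum and
difference modes; that regime is faithful to the method but makes
component-level assertions meaningless. Amplitudes are placeholders
chosen for realistic signal-to-noise, not literature values.

*Heart rate.* Per-infant baseline ~N(140, 7) bpm clipped to 120–160,
per-beat RR jitter (10 ms default); the noxious event adds a smooth
rate transient (peak near 3 s, gone by 15 s) of magnitude
2 + 1.6·(PMA_weeks − 28) bpm times the effect scale. The ECG trace is
synthesized as Gaussian R waves at the beat times plus noise, so the
full detection chain is exercised.

*EMG.* Stationary Gaussian baseline (4 µV) plus, for noxious events, a
noise burst starting 150 ms post-stimulus with amplitude ~5× baseline
(3.5× contralateral) independent of age, and duration
1 + 0.12·(40 − PMA_weeks) s: the burst always spans the 1-s analysis
window, so the windowed fold-change carries no age trend, while the
response visibly lasts longer in younger infants beyond it.

*Brow bulge.* Bernoulli response with probability 1/3 below ~30 weeks
rising to 2/3 at term for noxious events (0.25 for controls,
interpolated by the effect scale), with gamma-distributed durations
clipped to 30 s.

*Missingness.* Completely at random, per infant for heart rate,
reflexes and brow bulge (both conditions at once) and per event for
the ERSP family, at rates echoing the reference cohorts' exclusion
counts (10% heart rate, ~5% ERSP, 4–6% others).

All draws flow from one seed through per-infant, per-modality
substreams (`numpy` `SeedSequence.spawn`), so restricting the
generated modalities leaves the remaining traces bit-identical.
Setting every effect scale to 0 makes the two conditions exchangeable
by construction; this is the null used for classifier calibration.

**What the synthetic cohorts do not show.** Real neonatal EEG has
nonstationary artifacts, state changes and inter-site montage
differences; real missingness is not completely at random; the default
effect sizes separate the conditions essentially perfectly, so the
synthetic cross-validated accuracy (≈1.0) says nothing about clinical
accuracy — the informative checks are chance-level accuracy on null
cohorts, monotone accuracy in the effect scale, directional recovery
of the developmental trends, and the oracle equivalences of the
numerical building blocks.

## Problem sizes used in the checks

The bundled checks run the full pipeline at the scale of the study
they emulate: 47-infant default cohorts for classifier properties,
100 infants for the null-accuracy calibration, 144–150 infants (20
seeds) for developmental direction recovery, 500 trees throughout,
and reduced permutation counts (500–2000) where only calibration, not
fine p-value resolution, is at stake.
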