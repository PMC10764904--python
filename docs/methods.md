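# Methods

This note documents the models, conventions and design choices behind
`chronofp`, in the order data flows through the pipeline.

## Problem setting

A patient-specific seizure predictor watches multichannel scalp EEG and
raises alarms. An alarm at time *t* is correct if a seizure onset falls in
`(t + SPH, t + SPH + SOP]`: the Seizure Prediction Horizon (SPH, fixed at
5 min here) gives the patient time to act, and the Seizure Occurrence
Period (SOP, tuned between 10 and 55 min in 5-min steps) bounds how long
the warning remains meaningful. The preictal period is modelled not as one
homogeneous state but as a chronology of up to three brain-activity events,
and that chronology is enforced in the post-processing stage.

## Synthetic patients

Real long-term annotated scalp EEG of this kind is not publicly
distributable, so the package ships a generator whose output exercises
every pipeline stage.

* **Background**: per-channel independent AR(1)-filtered white noise
  (pole 0.95), scaled to 20 µV RMS. This gives a smooth 1/f-shaped
  spectrum with power in all analysis bands — cheap, stationary, and fully
  controllable. Channels are independent; no volume-conduction correlation
  is modelled.
* **Preictal stages**: each onset is preceded by 1–3 stages that tile the
  interval ending SPH before the onset (stage 3 ends exactly SPH before
  onset). A stage multiplies the background power of chosen bands by
  `1 + effect_size·(delta − 1)`, implemented by adding independent
  band-passed noise with the matching variance (computed from the analytic
  AR(1) spectrum). `effect_size = 0` reproduces background exactly, giving
  null patients. Defaults: three 10-min stages boosting theta, alpha and
  beta power by 4× respectively — distinct signatures that the spectral
  band-power features can see, in a fixed chronological order.
* **Geometry**: onset *i* sits at `i · interictal_gap`; the gap must exceed
  the planted preictal span. Ictal/postictal morphology is *not* modelled;
  labeling skips a configurable post-onset exclusion zone (default 10 min)
  instead.

What passing tests on this generator do **not** show: robustness to
artifacts, non-stationary background (sleep/wake), channel correlation, or
realistic seizure morphology. The generator establishes that the pipeline's
logic and statistics behave correctly, not that the method works on
clinical data.

## Features

Recordings are segmented into non-overlapping 5-s windows (1280 samples at
256 Hz; trailing remainder dropped). Per channel and window, exactly 59
features (count asserted at import time):

* **Spectral (45)** — Welch PSD (256-sample Hann segments, 50 % overlap,
  1 Hz resolution): absolute and relative power of delta (0.5–4 Hz), theta
  (4–8), alpha (8–13), beta (13–30) and four gamma sub-bands (30–47,
  53–75, 75–97, 103–128 Hz; the gaps avoid the 50 Hz line and harmonics);
  total power (0.5 Hz–Nyquist); mean frequency; alpha peak frequency;
  spectral edge frequency at 50 % and the cumulative power at that edge;
  and a fixed list of 24 pairwise band-power ratios (all 6 pairs among the
  four classical bands, each classical band over each gamma sub-band, and
  gamma1/gamma2, gamma3/gamma4). Band intervals are half-open `[lo, hi)`,
  the last band closed.
* **Temporal (8)** — mean, variance, skewness, excess kurtosis, Hjorth
  activity/mobility/complexity (derivatives as first differences × fs),
  and decorrelation time: the lag, in seconds, of the first nonpositive
  autocorrelation value (computed exactly via FFT; reported in seconds).
* **Wavelet (6)** — energies of Daubechies-4 detail levels D1–D5 and
  approximation A5, using the periodized orthogonal DWT so level energies
  sum exactly to signal energy. At 256 Hz the levels map to the dyadic
  bands 64–128, 32–64, 16–32, 8–16, 4–8 and 0–4 Hz.

Degenerate inputs: a zero-variance window defines skewness, kurtosis,
mobility and complexity as 0 and the decorrelation time as one sample; zero
total power (below 10⁻²⁰ µV², i.e. numerically zero) defines all relative
powers, ratios and spectral summary frequencies as 0. No feature is ever
NaN.

Raw-EEG artifact screening is provided as an optional zero-phase 0.5 Hz
high-pass plus 50 Hz notch (`features.bandpass_notch`); it is off by
default for synthetic data, which contains neither drift nor line noise.

## Labeling and balancing

Event windows are half-open `(start, end]` on window **start** times.
Schemes: Control — one event `(onset−SPH−SOP, onset−SPH]`; Chronological —
three contiguous SOP-length events tiling `(onset−SPH−3·SOP, onset−SPH]`,
event 3 nearest the onset; Cumulative — three nested events of lengths
3·SOP, 2·SOP and SOP (events 1, 2, 3), all ending SPH before the onset, so
event 3 ⊂ event 2 ⊂ event 1. For one event classifier, windows in the
scheme's preictal span but outside the target event are excluded rather
than labeled interictal, as are SPH and post-onset exclusion windows.
A preictal span extending before the record start is truncated with a
warning, never silently relabeled.

The first three seizures (and all data up to the end of the third one's
exclusion zone) train; the rest test. Patients with fewer than four
seizures are rejected.

Class balance: per seizure, the time-ordered interictal samples are split
into as many contiguous groups as that seizure has preictal samples and one
sample is drawn uniformly per group — systematic random undersampling that
covers the whole interictal period. Normalization is z-score with training
parameters (zero-variance columns get SD 1 with a warning); feature
selection keeps the k largest one-way ANOVA F statistics over the full
channel × feature space.

## Classifier and tuning

31 linear-kernel SVMs (libsvm, tol 10⁻³), each trained on its own seeded
undersampling draw, each with its own z-score fit and ANOVA selection
(the draws differ, so re-selecting per draw is the consistent choice).
Majority vote over the 31 members decides each test sample; 31 is odd, so
there are no ties.

Hyperparameters (k, C, SOP) are tuned by leave-one-seizure-out CV over the
three training seizures: two train (balanced), the held-out seizure
validates on its unbalanced samples, scored by √(SS_sample · SP_sample),
averaged over folds. For the multi-event approaches one shared triple is
tuned and the metric is the mean of the three event classifiers' scores.
Ties break toward smaller C, then smaller k, then smaller SOP (prefer
smoother, simpler, shorter). Grid cells infeasible for the data geometry
(e.g. a fold with no positive samples, or too little interictal data to
balance) are skipped with a warning; an empty evaluable grid is an error.

## Post-processing

Firing power: `fp[n] = Σ_{k=n−τ+1..n} O[k] / τ` with τ equal to the event
duration in windows (Control: SOP·12; Chronological: SOP·12 for all three;
Cumulative: 3·SOP·12, 2·SOP·12, SOP·12 for events 1–3). During warm-up
(n < τ−1) the mean is taken over the available history (a config-switchable
alternative emits 0). A *crossing* is strictly above the threshold at n
with a value at or below it at n−1 (implicit 0 before the record).

* **Control**: alarm at each upward 0.5-crossing; crossings inside the
  refractory period (SOP + SPH) are ignored entirely.
* **Chronological**: an event occurs at an upward 0.5-crossing of its
  curve; an alarm fires at an event-3 occurrence preceded (non-strictly in
  time: same-sample occurrences count as ordered 1→2→3) by an event-2
  occurrence, itself preceded by an event-1 occurrence, with the e1→e3 span
  at most the span limit. The most recent qualifying e1/e2 occurrences are
  retained; the pending sequence clears on alarm.
* **Cumulative**: the three curves are summed (range [0, 3]); after an
  upward 0.5-crossing the sum must exceed 1.0 and then 1.5 within the span
  limit; the alarm fires at the 1.5-crossing. The sequence resets on alarm
  and on span expiry; resetting when the sum drops below 0.5 is available
  but off by default (the smoothed sum dipping briefly should not cancel an
  unfolding cascade). Same-sample multi-threshold jumps count as
  sequential.

The span limit defaults to 3·SOP — the full chronological preictal span —
for both multi-event strategies; it is config-exposed.

## Evaluation and statistical validation

SS = predicted/all seizures; FPR/h = false alarms / (interictal hours −
false alarms × (SOP+SPH)/60). The interictal duration of a scoring interval
subtracts each onset's preictal footprint (scheme span incl. SPH) and
post-onset exclusion. A chance-level model can saturate the refractory
budget and drive the denominator to zero; the scoring function raises an
error then, and the pipeline records an infinite rate (sensitivity remains
well defined).

Surrogate test: N = 30 replicates; each relocates *every* onset uniformly
into the scoring interval, rejecting positions inside any real onset's
preictal/exclusion footprint or within SOP+SPH of another surrogate, then
re-scores sensitivity against the fixed alarms. Significance is the
exchangeability rank p-value `p = (1 + #{surrogate SS ≥ real SS})/(N+1)`,
one-sided at α = 0.05; "validated" means p < 0.05, which with N = 30
requires the real sensitivity to beat every surrogate (minimum p = 1/31 ≈
0.032). A mean-comparison test was considered and rejected: the real
sensitivity carries the full per-replicate variance while a surrogate
*mean* carries 1/N of it, so comparing against the mean is anti-conservative
under the null; the rank statistic is exact for exchangeable surrogates,
and its Type-I behavior is verified on null patients by the test suite.
Ties (surrogate SS equal to real SS) count against validation, which makes
the test conservative for the discrete sensitivities of few-seizure
patients.

## Study conditions of the simulation experiments

All desk-scale sizes are the package's own choices, fixed in
`chronofp.experiments`:

* **SOP recovery** — 10 patients, 4 channels, 4 seizures 80 min apart, one
  20-min stage with a 4× alpha boost, effect size 1; grid k ∈ {10, 20},
  C ∈ {¼, 1, 4}, SOP ∈ {10…30}. The planted stage is clean, so labeling
  with the matching SOP yields the purest classes and the CV metric peaks
  at SOP = 20.
* **Null calibration** — 50 patients, 3 channels, effect size 0, a fixed
  (k=10, C=1, SOP=10) Control model. The fraction of validated models
  estimates the surrogate test's Type-I error (nominal ≤ 0.05; the
  acceptance bound is 0.10 to absorb binomial noise at n = 50).
* **Cascade detection** — 10 patients, 4 channels, 5 seizures 80 min
  apart, three 10-min stages boosting theta/alpha/beta by 4×, fixed
  (k=20, C=1, SOP=10). Cumulative and Chronological models are trained on
  the ordered patient; the Chronological model is additionally applied to
  a patient whose stage *order* is shuffled (beta, theta, alpha), which
  destroys the 1→2→3 occurrence order and should suppress its alarms while
  the ordered patient is predicted.

## Known limitations

* The exact composition of a 59-feature univariate set is a documented
  convention (which 24 ratios; 5 wavelet levels; decorrelation time in
  seconds); other enumerations are defensible.
* The generator's stages are stationary band-power steps; real preictal
  dynamics are not quantitatively characterized here and no physiological
  claim is made.
* Chronological/Cumulative reset-and-span semantics beyond the documented
  defaults (e.g. the exact "stipulated time interval") are modelling
  choices, config-exposed.
* EDF ingestion/export is not provided; the native fixture is an
  array container plus a JSON annotation sidecar.
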