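# Methods

## Paradigm model

A run consists of blocks of four stimulus classes: standards, deviants,
and correct/incorrect novel stimuli.  Defaults follow the published
protocol: two blocks per mode in the order active → passive → breathing,
200/50/25/25 stimuli per block, 600 ms stimulus duration, each novel
welded to a preceding deviant at a fixed 1200 ms onset gap (600 ms
stimulus + 600 ms pause), all other inter-stimulus intervals uniform on
600–1000 ms, 1000 Hz sampling.  Within-block order is randomized subject
to the deviant→novel pairing constraint; the protocol's source describes
a fixed block order but not within-block ordering, so the generator
treats the (deviant, novel) pair as one presentation unit and shuffles
units.  Onsets are rounded to 1 ms.  Each block gets a 1 s lead-in and a
2 s trailing gap (stand-ins for the instruction screen and break; their
length only pads the recording).

## Synthetic EEG

The generator writes 32 channels (28 scalp on the 10/20 layout, M1/M2
mastoids, VEOG/HEOG) and is additive:

* **Background**: 1/f^β noise (β = 1 default), scaled to `noise_sd`
  (default 10 µV) per channel, mixed from a shared and a private stream
  in equal power halves (spatial correlation 0.5 — plausible EEG texture,
  a documented constant, not fitted).
* **Phase-locked components**: raised-cosine (Hann) bumps spanning
  exactly the analysis windows — P300 (250–400 ms, deviants), a novelty
  P3 (250–500 ms, both novel classes), N400 (380–420 ms) and P600
  (650–750 ms) added only to incorrect novels so the incorrect-minus-
  correct difference wave equals the injected bump; the CNV is a linear
  negative ramp from 600 ms to the epoch end (deviants).  Each component
  is spread over channels by a fixed topographic weight map (1.0 on its
  ROI, 0.5 on neighbours, 0.1 leakage, 0 on mastoids/EOG).  A Hann bump
  of peak A spanning its window has window-mean A/2, which makes
  parameter recovery analytically checkable.
* **Effect sizes**: the conscious visual profile sets peaks so the
  active-mode window means land near the grand-average values reported
  for healthy subjects under this protocol (P300 peak 9.3 µV → 4.65 µV
  window mean; CNV ramp −2.3 µV → −1.7 µV; N400 −4.8 µV and P600 6.4 µV
  peaks → −2.4/3.2 µV difference amplitudes), with passive intermediate
  and breathing strongly reduced.  The published incorrect-minus-correct
  N400 differences are not monotone across modes; the profile enforces
  |active| ≥ |passive| ≥ |breathing| as its defining invariant, so the
  passive/breathing N400 defaults are ordered rather than copied.  The
  unconscious profile injects nothing and is identical across modes.
* **Oscillatory (non-phase-locked) effects**: ongoing theta (4–7 Hz) and
  alpha (8–13 Hz) filtered-noise rhythms at FZ, with standing SDs of
  6 and 8 µV at the default noise floor (scaled proportionally with
  `noise_sd` so a silent profile yields a silent recording).  These SDs
  put the rhythms above the 1/f background inside their own bands, as
  frontal rhythms are in real EEG; smaller values leave the modelled
  ERS/ERD phenomenon below the background fluctuation and hence absent
  from the signal.  Within each event's analysis window the rhythm
  amplitude is multiplied by √(1+g) (theta, g = ERS gain) or √(1−g)
  (alpha, g = ERD gain) with 50 ms cosine ramps kept inside the window —
  a power change with random phase per trial, invisible to the evoked
  average but visible to the ERSP.
* **Artifacts**: Poisson blinks (10/min, 100 µV, 300 ms raised cosine)
  on VEOG with fixed propagation weights to the frontal leads.

What the generator does **not** emulate: real scalp mixing from cortical
sources, latency jitter and amplitude habituation, non-stationary
vigilance, muscle/line artifacts beyond the notch's reach, and
inter-subject topography differences.  Passing tests therefore show the
pipeline recovers what it is designed to recover under controlled
conditions — not that it would perform identically on clinical data.

## Preprocessing

Zero-phase (forward-backward) filtering: 4th-order Butterworth band-pass
0.1–20 Hz plus a Q = 30 notch at 50 Hz (EEG channels only; EOG channels
are band-passed but not notched).  Zero-phase doubles the magnitude
response, which costs ~6% at 10 Hz from the 20 Hz edge but protects
component latencies.  Re-referencing subtracts (M1+M2)/2 from every
non-EOG channel.  Epochs span −200..+1000 ms inclusive on the native
grid (1201 samples at 1000 Hz), time 0 at the stimulus-onset sample;
baseline is the mean over −200..0 ms, subtracted per trial and channel
(a projection — idempotent).  Ocular artifacts are removed by regressing
each EEG channel on VEOG and HEOG (coefficients from demeaned data
pooled over all trials; the subtracted contribution uses the raw EOG so
an exactly proportional channel is zeroed).  The interface is pluggable
for component-based alternatives.  Rejection drops trials whose scalp
channels *strictly exceed* ±75 µV (exactly ±75 is retained) and runs
last, after artifact removal, which maximizes retained trials; the
rejection log keeps one entry per dropped trial.

## ERSP

Per trial, frames of 200 ms Hann-windowed signal hopped every 50 ms are
zero-padded to one second (1 Hz bins) and squared: P(t,f) = |F(t,f)|².
Only fully supported frames are formed; the per-trial baseline R̄(f) is
the mean over frames with centres in (−200, 0] ms, subtracted per
frequency (raw µV² subtraction, not the dB convention), then maps are
averaged across trials.  The band-window summaries are plain means over
bins in 4–7 Hz × 200–400 ms (theta) and 8–13 Hz × 400–1000 ms (alpha) at
FZ; sign positive = ERS, negative = ERD.  A 200 ms window cannot resolve
structure below ~5 Hz; bins from 1 Hz are retained as axis coverage
only.

## Classification

Features: post-stimulus 0–1000 ms of the 28 scalp channels, anti-alias
resampled to 100 Hz (polyphase) and concatenated (2800 values).  Labels:
deviant/correct-novel/active = +1, standard/incorrect-novel/other mode =
−1.  Evaluation: stratified random half-split from a single shared
permutation (making the partition exactly symmetric under label swap),
SMOTE applied to the training half only when classes are imbalanced
(bespoke implementation: x_i + u·(x_nn − x_i), u ~ U(0,1), k = 5 nearest
minority neighbours), then per-feature standardization and a linear
max-margin SVM fit in the dual (n ≪ d), with C chosen from {10⁻³, 10⁻¹,
10} by stratified ≤5-fold cross-validation on the training half only.
Ten repeats; accuracy, sensitivity (+1 class), and specificity (−1
class) are averaged with their across-repeat SEs.  Trial-averaged test
sets at level n are means of n same-class test trials drawn without
replacement into disjoint groups (leftovers discarded); training is
untouched, and levels with too few test trials are skipped with a
warning.  Synthetic SMOTE rows carry provenance id −1 and an assertion
inside the evaluation loop guarantees they never reach a test half.

## Statistics

Paired t (two-tailed, Cohen's dz = mean(d)/sd(d); identical inputs give
t = 0, p = 1, while a non-zero constant difference raises); one-way
fixed-effects ANOVA with η² = SS_between/SS_total; Bonferroni post-hocs
as pooled-variance two-sample t-tests with p×m capped at 1 (the variant
is unstated in the protocol's source; pooled variance is the documented
choice).  A-priori sample sizes come from the noncentral t (ncp = dz√n,
df = n−1) and noncentral F (λ = f²N, df = (k−1, N−k)) distributions,
iterating n upward; ANOVA sizes are constrained to equal groups, so N is
a multiple of k.  These reproduce the study's planned sizes exactly
(n = 20 at dz = 0.67; N = 60 at f = 0.42, k = 3).

## Decision rule

Chance level for an accuracy on n test samples is the one-sided exact
binomial bound: the smallest k/n with P(X ≥ k) ≤ α under Binomial(n,
0.5) (at n = 100, α = 0.05 this is 0.59; for n ≤ 4 no count qualifies
and the bound degenerates to 1.0, which a strict comparison never
exceeds).  Chance comparisons use **balanced** accuracy (mean of
sensitivity and specificity): on imbalanced test sets a majority-biased
null classifier scores the majority proportion (e.g. 0.667 at 2:1),
which would sit above a bound centred on 0.5; balanced accuracy stays at
0.5 under the null for any imbalance.  Raw accuracy remains what tables
report.

The ladder: (a) if no active-mode stimulus contrast (m1) is above chance
at single trials, it is re-tested at averaging levels 2–5; if still
none, `no_evidence`.  (b/c) With m1 passed, the verdict is
`consciousness_detected` if any active-vs-breathing mode contrast (m2)
is above chance, or if any m2 contrast shows a trial-averaging gain
exceeding twice the across-repeat SE of the paired per-repeat gain
(acc₅ − acc₁); otherwise `potentially_conscious`.  The paired-gain SE is
used because the averaged-level accuracy (tiny test sets) has
several-fold larger spread than the single-trial accuracy, and a
threshold built on the latter passes null subjects far too often.  The
published procedure is a flowchart without numeric cutoffs; this ladder
is the package's formalization and every report carries a note saying
so.  The gain-based rule is not monotone in the single-trial accuracy
taken alone (raising acc₁ shrinks the gain), so the monotonicity
property is stated — and tested — for joint shifts of a contrast's
accuracies, which preserve gains.

## Problem sizes

The generator's paradigm defaults are the full protocol.  Cohort-level
evaluation (and the end-to-end operating-characteristics check) uses a
scaled configuration the package defines once in
`pipeline.cohort_config`: one block each of active and breathing,
80/40/20/20 stimuli, 250 Hz.  These sizes give the half-split classifier
at least 20 training trials per minority class — below that the
mode-contrast accuracies degrade toward chance — while a 40-subject
cohort runs in minutes on one core.  At these sizes the fixed-seed
cohort yields 19–20/20 conscious detections and 0/20 unconscious false
positives.  Analysis drivers and tests state their seeds explicitly; all
randomness flows from per-call integer seeds through
`numpy.random.default_rng` (classifier repeats derive per-repeat seeds
via `SeedSequence.spawn`).

## Known limitations

* EOG regression removes linearly EOG-correlated activity only; it is a
  deterministic stand-in for component-based artifact removal and will
  subtract genuine frontal signal that covaries with the EOG.
* The exact binomial chance bound treats the mean over 10 correlated
  half-split repeats as a single n-trial accuracy; this is conservative
  in the variance direction but ignores repeat correlation.
* Difference-wave components (N400/P600) at cohort trial counts
  (20 novels per class) carry window-mean SEs near 1.5 µV, so
  single-subject component tables are noisy; the classifier-based
  metrics, not the component table, drive the verdict.
* The mode-contrast ANOVA on within-subject data reproduces the source
  protocol's between-group design choice verbatim rather than a
  repeated-measures correction.
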