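# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of the `streamdecode` pipeline. Empirical claims
below are the quantities the test suite and `scripts/acceptance.py`
themselves compute; nothing here reports a number the code does not
produce.

## Stimulus model

Sequences consist of HLH- triplets: 100 ms pure tones separated by 50 ms
within a triplet and 200 ms between triplets, giving an exactly 600 ms
triplet period; a 250-triplet sequence lasts 150 s. The L tone lies Δf
semitones (4 or 6) below the H tone, L = H·2^(−Δf/12). The default H
frequency is 1017 Hz. Filler material between sequences (a timing tone, 33
random tones drawn log-uniformly from 200–2000 Hz, a warning tone, long
silences) totals just under 40 s and exists to disrupt carry-over of the
previous sequence's perceptual context; it is represented as an events
table only and is never epoched.

## Percept-phase model

Perception alternates between integrated and segregated phases. Phase
durations are log-normal — the analysis log-transforms durations, implying
approximate log-normality, and log-normal phase durations are the standard
description of bistable alternation. Defaults (neutral condition, midpoint
of the two Δf levels):

| parameter | default | units / meaning |
|---|---|---|
| median initial integrated phase | 12 s | first phase is longer |
| median subsequent phase (either percept) | 6.8 s | "alternates every few seconds" |
| σ of log duration | 0.55 | within-participant variability |
| between-participant SD (log scale) | 0.30 | stable individual alternation bias |
| intention multiplier (non-neutral conditions) | 1.54 | lengthens instructed percept's phases, shortens the other's, symmetrically |
| Δf multiplier | 1.25 | Δf = 6 favors segregation, Δf = 4 integration |
| first-report latency | 2 s | the interval before it carries no percept |

These values were calibrated jointly so that (a) the mean
attempt-segregation minus attempt-integration difference in reported
percent segregation is ≈ 36–37 percentage points, (b) neutral percent
segregation sits near 50% with Δf = 6 above Δf = 4, and (c) the median
epoch retention rate under the 1.5 s press guard is ≈ 56–58% of the 5000
available epochs per participant. The first phase is integrated with
probability 1 by default; a press marks each phase onset, and the final
phase is truncated at the sequence end and flagged incomplete (incomplete
phases never enter duration statistics).

## Neural model

Each triplet evokes three gamma-shaped deflections (shape 3, peaking 55 ms
after each tone onset, amplitudes 3.2/2.7/3.0 source units). When the phase
governing a triplet's onset is segregated, a raised-cosine positivity
confined to 216–288 ms post triplet onset with peak amplitude 0.32 units is
added. Noise is Gaussian with power spectrum ∝ 1/f plus an equal-weight
white floor, band-limited to the 0.278–30 Hz analysis band, unit standard
deviation.

Participant templates multiply the whole response by a log-normal amplitude
factor (σ = 0.35), jitter each tone's latency (SD 8 ms), and flip the
global polarity with probability 0.15 — modeling individuals whose source
orientation yields a percept effect opposite in sign to the group.

Calibration targets, all verified by simulation in the test suite: group
window effect with averaged-variance d ≈ 0.3–0.4 (window t ≈ 4 at n = 23),
a significant positive cluster overlapping the 216–288 ms window in ≥ 80%
of 23-participant cohorts, neutral decoding accuracy ≈ 53–54% (maximum
across participants typically < 61%), and chance accuracy when the effect
amplitude is zero.

Two generation paths exist. The *full path* synthesizes continuous 1000 Hz
recordings that are then FIR-filtered, downsampled and epoched from events
tables. The *fast path* (`simulate_labeled_epochs`,
`simulate_cohort_epochs`) draws analysis-ready epochs directly at 250 Hz:
the evoked waveforms are passed through the same 30 Hz low-pass kernel and
mean-centered (emulating the high-pass's DC rejection of a periodic
signal), and noise is drawn in-band per epoch. The fast path differs from
the full path in two respects: epoch noise is independent across epochs
(continuous 1/f noise correlates neighboring epochs), and the high-pass's
attenuation of percept-phase-timescale modulation of the segregation bump
is approximated by mean-centering. Repeated stochastic validations use the
fast path; the full path is exercised by the end-to-end integration tests
and the command-line pipeline.

## Preprocessing

Hamming-windowed linear-phase FIR sinc filters with the −6 dB point at the
cutoff: low-pass 30 Hz (6.667 Hz transition band) and high-pass 0.278 Hz
(0.556 Hz transition band). Kernel length is ceil(3.3/normalized transition
bandwidth), rounded to odd; the DC gain is pinned exactly (1 for low-pass,
0 for high-pass) by spreading the residual over all taps. Filters are
applied zero-phase after reflect padding, so output length equals input
length and there is no onset transient from an implicit zero boundary.
Downsampling to 250 Hz is integer decimation; the 30 Hz low-pass already
prevents aliasing. The high-pass period, 1/0.278 Hz = 3.6 s, equals the
shortest possible onset-to-onset interval between retained epochs carrying
different percept reports, so drift slower than one guard-to-guard span
cannot masquerade as a percept difference.

## Epoching and labeling

Epochs are 600 ms, one per triplet onset, no baseline correction (the
stimulus repeats without a silent baseline; because the press guard ensures
carry-over comes only from same-percept triplets, epoch time is effectively
circular). Onsets in seconds are mapped to sample indices by rounding to
the nearest sample; the epoch window is half-open [onset, onset + 0.6).
An epoch is retained iff its onset is ≥ 1.5 s after the most recent press
(or sequence start) and its end is ≥ 1.5 s before the next press (or
sequence end) — strict application of the printed guard. Labels are the
percept of the most recent press at or before the epoch onset; epochs
before the first report are labeled integrated (an optional flag instead
drops everything before the first segregated report, the standard
sensitivity analysis). An epoch whose onset coincides exactly with a press
is always excluded by the guard, so its attribution never arises.
Participants enter the neural analyses only if every neutral Δf × percept
cell holds ≥ 55 retained epochs (configurable).

## Behavioral statistics

Percent segregation uses the interval from the first press to the sequence
end as denominator (the unreported pre-first-press interval carries no
percept; configurable). Percentages are logit-transformed and durations
log-transformed before averaging; means are back-transformed for
reporting. Exact 0/100% values are rejected in strict mode; the pipeline
falls back to an empirical-logit correction of 1/(2n + 2) only where a
complete table is required. Sequences enter duration analyses only if the
first reported phase was integrated and at least two completed phases
followed; participants with any empty Δf × condition cell under this rule
are excluded from behavioral group tests.

One-way repeated-measures ANOVAs use pingouin, with Huynh–Feldt ε applied
to the degrees of freedom for the p value (uncorrected dfs are reported
alongside; ε ≡ 1 for two-level factors). Partial η² receives a 2000-sample
percentile bootstrap CI over participants (the bootstrap recomputes F with
a direct sum-of-squares decomposition that is unit-tested against
pingouin). Paired t tests report two Cohen's d variants: `d` =
mean(diff)/SD(diff) (d_z, the quantity whose noncentral-t pivot gives the
CI) and `d_av` = mean(diff)/pooled SD of the two conditions, the smaller
number conventionally reported for strongly correlated repeated measures.
Within-participant condition CIs use Cousineau centering with the Morey
√(k/(k−1)) correction.

## Univariate analysis

Neutral epochs are averaged per Δf × percept cell; the two Δf levels get
equal weight regardless of cell sizes, removing the stimulus confound from
the percept comparison. The cluster test thresholds pointwise paired t
values at the two-sided critical t for α = 0.05, forms maximal
contiguous same-sign suprathreshold runs scored by mass (sum of t), and
builds the null from the maximum |cluster mass| under within-participant
sign flips of the difference wave (the max-statistic reading, which
controls family-wise error). The reported p counts the observed statistic
in the null, so the minimum attainable p is 1/(n_perm + 1). An exhaustive
2^n enumeration is available for small n and is checked against the Monte
Carlo null. Window statistics average the samples whose latency t satisfies
216 ≤ t ≤ 288 ms inclusive on the 4 ms grid (19 samples at 250 Hz). The
four intention contrasts are ½(AH + AL) − AI, AH − AI, AL − AI and
AH − AL on window values, each tested with a paired t.

**Expected-vs-observed (univariate).** The expected non-neutral response
mixes the neutral percept means by the percentages of each percept
*reported* in that condition. The pipeline measures those percentages as
the share of retained epochs carrying each report label — the same epoch
grid the neural averages use — rather than as percent of reported time.
The two differ systematically (the press guard removes epochs
asymmetrically from short and long phases), and using time-based
percentages would make the comparison reject even for a perfectly accurate
reporter; the epoch-share reading makes expected and observed commensurate,
so the test is a pure bias detector.

## Decoding

Per participant and Δf, linear SVMs (C = 1) classify integrated vs
segregated neutral epochs from the 150 time-sample features. Per repeat,
the larger class is subsampled without replacement to the smaller class's
count; stratified 5-fold cross-validation is repeated 100 times (500
fold-evaluations). Features are standardized with training-fold statistics
only, stored and reused for test folds and non-neutral epochs — the
leakage-free reading of "standardized values" (a shared-standardization
mode is not provided). The default solver is liblinear's squared-hinge
primal formulation, which converges in a handful of iterations on these
standardized, weakly separable epochs and is orders of magnitude faster
than the classical SMO solver at realistic cell sizes; the libsvm solver
remains available and the two are cross-checked for agreement in the test
suite. Class order fixes the sign convention: positive decision values, and
hence positive (corrected) weights, mean a more positive response favors
segregated.

Haufe correction computes activation patterns as training-fold covariance ×
weight vector, averaged over the 500 models, with Ledoit–Wolf shrinkage by
default for conditioning on small subsamples (zero shrinkage reproduces the
exact identity pattern_j ∝ cov(x_j, decision) and is used in the oracle
test). Per-participant patterns are normalized to unit Euclidean norm
before averaging over Δf and participants.

Non-neutral epochs are classified by all 500 models regardless of report;
the percentage classified as segregated is the mean over models of the
per-model percentage (equivalently the mean per-epoch vote). The
accuracy-adjusted expected difference multiplies each reported segregation
percentage (epoch-share basis, as above) by (accuracy − 50)/50 — chance
classifiers carry no signal, perfect ones reproduce reports — forms
½(AH + AL) − AI of the adjusted values, averages over Δf, and compares to
the observed classified difference with a paired t.

## Validation design

The validation suite covers: worked-example arithmetic (sequence and
filler durations, semitone formula, 150 features, 500 evaluations, the
3.6 s guard geometry); null calibration (cluster-test family-wise
false-positive rate within [0.03, 0.07] over 200 twelve-participant null
cohorts at 100 permutations; decoder accuracy within 50 ± 3% under label
shuffling); effect recovery (significant window-overlapping positive
cluster in ≥ 80% of 25 calibrated 23-participant cohorts; intention-effect
sign recovered by both the univariate and the classified-percentage
contrasts); and bias-test behavior (both expected-vs-observed tests
non-significant in ≥ 90% of 25 accurate-reporter cohorts, and both
rejecting in ≥ 80% of 25 cohorts with a deliberately biased reporter —
reports driven by an exaggerated intention multiplier of 3 while the
neural percept process ignores instructions entirely). Cohort sizes,
permutation counts and decoder repeats in these simulations are scaled to
keep each check to seconds-to-minutes; all stochastic checks run under
fixed seeds.

The biased reporter is modeled by decoupling two phase processes: reports
(which drive epoch labels, guard masking and behavioral percentages)
follow the fully intention-modulated process, while the neural percept
follows a process whose intention multipliers are raised to an attenuation
exponent (1 = accurate reporting, 0 = pure response bias).

## What passing tests do and do not show

The generator reproduces the statistical skeleton of the real experiment —
timing, schedule, phase dynamics, evoked structure, between-participant
heterogeneity, guard-driven retention — but not sensor-level reality: no
head movement, eye or cardiac artifacts, no line noise, no dipole-fitting
uncertainty, stationary noise within and across sequences, and epoch noise
that is exactly in-band. Passing validation therefore shows the analysis
machinery is correct and calibrated under the assumed data-generating
process; it cannot certify preprocessing choices against artifacts the
generator does not produce (those steps — tSSS, ICA, line-noise removal —
are outside this pipeline, which starts at source waveforms).

## Numerical conventions and degenerate inputs

Time is 0-based seconds from sequence start throughout; events tables
store onsets with microsecond precision. Equal-variance paired tests with
zero-variance differences return an infinite t and are flagged rather than
raising. The logit transform rejects 0/100% in strict mode. Cluster
p values are exact proportions, never interpolated. Filter design rejects
cutoffs at or above Nyquist; resampling accepts only integer decimation
factors. All randomness in a run derives from a single integer seed via
spawned generator streams; reports embed the seed and settings.
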