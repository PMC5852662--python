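# streamdecode

Simulation and analysis pipeline linking subjective reports of bistable
auditory streaming to triplet-locked neural responses in auditory cortex.

## The scientific problem

A repeating pattern of high (H) and low (L) pure tones, HLH-HLH-, is
perceptually bistable: listeners hear it either as one *integrated*
galloping stream or as two *segregated* isochronous streams, alternating
between the two every few seconds. Whether listeners can voluntarily
influence this perceptual organization is hard to establish from button
presses alone — instructions to "try to hear segregation" could change the
*reports* without changing the *percept* (a response bias).

The analysis implemented here addresses that question with stimulus-locked
neural evidence. During neutral listening, epochs of auditory-cortex source
activity time-locked to each 600 ms HLH- triplet are labeled by the
concurrently reported percept. Two percept signatures are derived:

* **Univariate** — the group-level evoked difference: segregated reports
  evoke a more positive response 216–288 ms after triplet onset (66–138 ms
  after the L tone), assessed with a cluster-based permutation test
  (pointwise paired *t* values, clusters scored by mass, null from
  within-participant sign flips of the difference wave, 1000 permutations,
  α = 0.05).
* **Multivariate** — a per-participant, per-Δf linear SVM (C = 1) trained
  on the 150 standardized time samples of each epoch, with balanced class
  subsampling and 5-fold × 100-repeat cross-validation (500
  fold-evaluations). Feature weights are made interpretable with the Haufe
  activation-pattern transformation (training covariance × weight vector).

Both signatures are then applied to epochs from the intention conditions
(attempt integration, attend high, attend low). The key bias controls
compare what is *observed* against what accurate reports would *predict*:
the neutral percept means mixed by the reported percept percentages
(univariate), and the reported percentages scaled by
(accuracy − 50)/50 (multivariate). Agreement indicates the reported
intention effect is perceptual, not a response bias.

Because the original MEG recordings are not publicly deposited, the package
includes a first-class synthetic-data module that generates the full study
structure — 250-triplet sequences at Δf ∈ {4, 6} semitones, four
instruction conditions, log-normal percept phases with a long initial
integrated phase, continuous source waveforms with a calibrated
segregation positivity, participant-template variability including
sign-reversed individuals — so every stage of the analysis is testable end
to end.

## Worked example

```python
import numpy as np
from streamdecode import synthetic_data as sd
from streamdecode.config import PipelineConfig
from streamdecode.pipeline import stage_univariate, stage_decode

percept, neural = sd.PerceptParams(), sd.NeuralParams()
epochs, reports = sd.simulate_cohort_epochs(23, percept, neural, seed=42)

cfg = PipelineConfig(min_cell=30, repeats=5, n_perm=500)
uni = stage_univariate(epochs, cfg, np.random.default_rng(0))
dec = stage_decode(epochs, cfg, np.random.default_rng(1))

print("cluster p      :", uni["cluster"]["p"])
print("window t, d_av :", uni["window_effect"]["stats"]["t"],
      uni["window_effect"]["stats"]["d_av"])
print("mean accuracy  :", dec["mean_accuracy"])
print("bias test p    :", dec["expected_vs_observed"]["stats"]["p"])
```

Output from this exact snippet:

```
cluster p      : 0.001996007984031936
window t, d_av : 8.572248251195324 0.43037817496629965
mean accuracy  : 53.67430163006412
bias test p    : 0.9989467312153476
```

Reading: this 23-participant synthetic cohort shows a significant
segregated-vs-integrated cluster (p ≈ 0.002; the smallest value 500
permutations can resolve is 1/501), a clear window-specific effect (an
averaged-variance Cohen's d ≈ 0.43; the t value varies across cohorts with
how many sign-reversed participants were drawn), single-trial decoding
slightly but reliably above the 50% chance level (≈ 54%), and no spurious
response bias: the accuracy-adjusted expected intention effect matches the
observed classified effect (p ≈ 1.0, non-significant, as it should be when
reports are accurate by construction).

The same pipeline runs from the shell over on-disk cohorts
(float32 recordings + TSV events):

```bash
stream-decode run-all --seed 1 --out out/
cat out/results/report.md
```

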