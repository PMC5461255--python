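# vocopred

Predicting the intelligibility of noise-vocoded speech from a cognitive
test battery.

Noise-vocoded speech — speech whose band envelopes modulate noise carriers
— simulates the spectrally degraded percept delivered by a cochlear implant
(CI). People differ enormously in how well they understand it, and those
differences track cognitive abilities: working memory, verbal learning,
vocabulary, the ability to read visually degraded text, task switching.
`vocopred` implements, as a tested and reusable pipeline, the full analysis
chain for studies that try to predict vocoded-speech understanding from
such a battery:

* a **channel (noise) vocoder** for CI simulation: 128-point STFT at 75%
  overlap of 16 kHz audio, 10 non-overlapping log-spaced bands, per-band
  envelope = √(band energy), noise carriers with a 3.5 dB/octave spectral
  spread outside their band (simulating current spread in an electrically
  stimulated cochlea);
* **open-set sentence scoring** of seven-word sentences (words correct per
  sentence, 0–7), the per-subject **median over 60 test trials** used as
  the response *y*, block-of-ten learning curves and group comparisons;
* **derivation of 13 canonical predictors** from eight cognitive tests
  (TRT, WST vocabulary, Operation Span, four verbal-learning scores, two
  lexical-decision RT differences, four trail-making switching costs, the
  Stroop distraction-sensitivity difference);
* a from-scratch **single-response PLS regression** (orthogonal-scores /
  NIPALS) with **VIP** (variable importance in projection) scores and
  explained-variance accounting;
* the two-step inference engine: **VIP selection nested inside
  leave-one-out cross-validation**, paired sign-flip **permutation tests**
  of each component's prediction-error reduction, MSEP sweeps over the
  number of selected variables, per-age-group significance tests, a final
  selection-free LOOCV evaluation (cross-validated Pearson *r*), and
  robustness reruns excluding zero scorers;
* a **calibrated synthetic battery generator** (single latent
  cognitive-efficiency factor, signed loadings, two age groups matching
  the published group means/SDs) so every stage is testable without the
  original human data.

## The model in brief

For centered (and unit-variance scaled) predictors X and centered response
y, each PLS component a extracts w_a ∝ Xᵀy (unit norm), scores t_a = X w_a,
loadings p_a = Xᵀt_a / t_aᵀt_a, q_a = yᵀt_a / t_aᵀt_a, then deflates
X ← X − t_a p_aᵀ. Variable importance is

VIP_j = √( p · Σ_a SS_a (w_ja/‖w_a‖)² / Σ_a SS_a ),  SS_a = q_a² t_aᵀt_a,

so Σ_j VIP_j² = p. Selection (top-j variables by VIP of a preliminary
2-component model) happens **inside** every leave-one-out training fold;
ranking once on the full sample leaks the held-out response into the model
choice and optimistically biases the MSEP — the package ships the leaky
variant only as a diagnostic, and a test verifies the bias is real.

## Worked example

```bash
vocopred demo --seed 3 --nperm 199 --out demo_run
```

prints

```
report written to demo_run/report.json
selected variables: OperationSpan, Verbal_learning, TRT, CTMT_1_5, Recognition, WST
recovered signal variables: CTMT_1_5, OperationSpan, Recognition, TRT, Verbal_learning
```

The demo generates a 41-subject battery (21 young, 20 older) from the
bundled calibration, along with 60 sentence trials per subject and raw
test records; re-derives the 13 predictors from the raw records; runs the
variable-count sweep with nested selection; and evaluates the top-6
variable set in a selection-free LOOCV. In this run the six selected
variables contain all five of the generator's latent-signal variables
(TRT, Operation Span, verbal learning, recognition, trail-making subtest
5) plus WST; `report.json` holds the sweep table (p-value and MSEP per
variable count and component), the cross-validated correlations, the
per-age-group p-values and the learning curves. With `--seed` fixed the
report is byte-identical across runs.

The same analysis runs on your own data via the canonical CSV schema
(`subject_id, age_group, TRT, WST, OperationSpan, Verbal_learning, Recall,
Recognition, RT_word, RT_freq, CTMT_1_2, CTMT_1_3, CTMT_1_4, CTMT_1_5,
Distraction_sensitivity, y_median`):

```bash
vocopred analyze --data battery.csv --sweep 2:13 --nperm 10000 --seed 42 \
    --report out/ --exclude-zero-scores
```

and audio is vocoded with

```bash
vocode --in clean.wav --out vocoded.wav --bands 10 --fft 128 --overlap 0.75 \
    --slope 3.5 --seed 7
```

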