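# Methods

This note documents the models and procedures implemented in `vocopred`,
the defaults and why they were chosen, and what the synthetic-data tests
do and do not establish about real data.

## PLS regression core

`vocopred.pls` implements single-response partial least squares by the
orthogonal-scores (NIPALS) algorithm. With one response the weight vector
has the closed form w = Xᵀy/‖Xᵀy‖ per component, so no inner iteration is
needed. X is deflated by t pᵀ after each component; y is deflated by q t as
well — irrelevant for single-response predictions but kept for numerical
symmetry with the classical presentation. Out-of-sample predictions use
the regression coefficients b_a = W_a (P_aᵀW_a)⁻¹ q_{1..a}.

**Scaling.** Predictors are standardized to unit variance inside the model
by default. The 13 battery variables mix counts (0–75), reaction times in
milliseconds (hundreds) and seconds (tens); unscaled PLS would be dominated
by the largest-variance RT difference. `scale=False` (CLI `--no-scale`)
preserves the alternative, and the test suite exercises both modes. The
response is centered only.

**VIP.** Variable importance in projection follows the standard
Wold/Chong–Jun definition with SS_a = q_a² t_aᵀt_a (response variance
explained by component a); Σ VIP² = p is asserted to 1e-8 in the tests.

**Degenerate inputs.** A zero-variance predictor raises an error naming
the variable; component counts above min(n−1, p) truncate with a warning;
a response residual orthogonal to X stops extraction early (a constant y
yields a zero-component model that predicts the mean).

## Nested selection and inference

The inference engine fixes the model at two components throughout. For
each candidate variable count j (2 … 13) and each leave-one-out fold:
rank the variables by VIP of a preliminary 2-component model fitted *on
the training fold only*, keep the top j (VIP ties broken by canonical
variable order), refit, and predict the held-out subject with the null
(training-mean), 1- and 2-component models. Selecting on the full sample
instead is implemented only as the `leaky=True` diagnostic; an acceptance
test verifies on zero-signal data that the leaky variant's MSEP is
optimistically low relative to the honest nested procedure.

**Component significance.** The prediction errors of nested models are
compared by a paired sign-flip permutation test: d_i = e²_ref,i −
e²_model,i, statistic = mean(d), null generated by independent random sign
flips, one-sided p = (#{permuted ≥ observed}+1)/(B+1) with B = 10000 by
default. The sign-flip scheme is one of several defensible randomization
tests on paired errors; it is declared here as this package's choice and
is swappable. Its type-I error at α = 0.05 is verified to lie in
[0.035, 0.065] under an exchangeable null.

**Per-age-group tests** reuse the whole-sample out-of-fold errors (the
model is always trained on both groups) and restrict only the paired
differences entering the test to one group.

**Final evaluation.** The chosen variable set is re-evaluated by LOOCV
without selection; the package reports the Pearson correlation between
out-of-fold predictions and the measured response for the 1- and
2-component models plus rMSEP for null/1/2. Its permutation p-value
permutes the response and recomputes the *entire* LOOCV for each
permutation: at n ≈ 40 this is cheap, and it makes the null distribution
itself cross-validated rather than optimistically narrow.

**Multiple testing.** No correction is applied across the j-sweep; the
sweep is a model-selection display, not a family of confirmatory tests.

**Exhaustive subset regression** (OLS over all subsets up to a size cap,
LOOCV via the PRESS identity e_i/(1−h_ii)) is included as an independent
cross-check of the PLS selection, not as part of the primary chain.

## Noise vocoder

`VocoderSpec` defaults: 16 kHz sample rate, 128-point FFT, 75% overlap
(hop 32), 10 bands, 3.5 dB/octave spread slope. Choices the algorithm
description leaves open, fixed here:

* **Analysis window**: periodic Hann — satisfies constant overlap-add at
  75% overlap.
* **Band range**: low edge 80 Hz by default, high edge Nyquist; both
  configurable. Nominal band edges are an exact geometric progression.
  Because the 125 Hz bin spacing of a 128-point FFT is wider than the
  lowest nominal bands, bins are assigned by rounding the edges to bin
  boundaries with strict monotonicity enforced — the usual channel-vocoder
  convention — so every band is non-empty and every bin from the low edge
  to Nyquist belongs to exactly one band.
* **Carriers**: seeded white Gaussian noise shaped in the FFT domain —
  unit gain inside the band, 10^(−slope·octaves/20) outside, zero at DC —
  normalized to unit RMS. One seed stream (`noise_seed`) serves all bands
  in band order; the transform is bit-reproducible.
* **Envelopes**: √(Σ band-bin power) per frame, upsampled to audio rate by
  linear interpolation between frame centers.
* **Level**: output RMS renormalized to input RMS.

The STFT zero-pads on the right so the last frame is complete; frame count
is 1 for signals up to one window, else ⌈(N−128)/32⌉+1.

A note on envelope fidelity: noise carriers have intrinsic envelope
fluctuations (large for one-bin bands), and the shallow 3.5 dB/octave
spread deliberately leaks energy into neighboring bands. Envelope-transfer
tests therefore compare ~40 ms smoothed envelopes and use a signal whose
amplitude modulation is shared across bands, as in running speech at
syllabic rate. Per-band independent modulations would partially decorrelate
neighboring bands — that is the simulated spread of excitation at work,
not a defect.

## Scoring

Sentence scoring is case-insensitive exact token matching after
punctuation stripping, order-free, each of the seven target words
creditable once (multiset intersection; equivalent to maximum bipartite
matching with equality edges, which the tests verify by solving the
assignment problem). No lemmatization or partial-word credit — German
morphological variants count as wrong. The subject response is the median
over the 60 test trials, which for integer scores lies on the
integer/half-integer lattice. Group learning curves take the median across
subjects of per-subject block-of-ten medians; the group comparison reports
both pooled-variance and Welch t statistics.

## Predictor derivation

The 13 predictors are pure functions of the raw records; missing raw
fields propagate to a flagged missing predictor (never zero), and subjects
with missing predictors are excluded from the analysis view (mirroring
participants who abort a test). The free-recall score is trial 7 − trial 5
(consolidation after delay) by default; because the sign convention is
ambiguous in the source descriptions, `recall_sign="t5_minus_t7"` flips
it. Lexical-decision RTs are means over correct responses per condition;
Stroop times are per-task medians.

## Synthetic battery generator

One standard-normal latent "cognitive efficiency" factor per subject
drives both predictors and response:

x_j = μ_{g,j} + σ_{g,j}(λ_j z + √(1−λ_j²) ε_j),
y* = μ*_g + σ_{g,y}(β z + √(1−β²) ε_y),

with group-specific means and SDs taken from the bundled calibration
(`data/table1.yaml`), signed loadings λ (negative for reaction-time
variables, where lower is better), and response loading β = 0.85. The
final response snaps y* to the half-integer lattice, clips to [0, 7], and
with probability `floor_mass` (default 0.15, emulating the observed ~15%
zero scorers) replaces the subject's score with 0.

**Mean calibration.** Lattice snapping, clipping and floor inflation all
shift the mean of the final response away from the location parameter, so
the generator solves for μ*_g by quadrature (4001-point normal quantile
grid) and Brent root finding such that the *expected final response*
equals the configured group mean exactly. Predictor marginals are plain
Gaussians — their means and SDs match the calibration without adjustment.
The realized response SD is somewhat below the configured value (clipping
compresses the tails); only the means are calibration targets.

**Default loadings.** Five predictors carry the latent signal — TRT 0.80,
Operation Span 0.75, verbal learning 0.70, recognition 0.65, trail-making
subtest-5 cost −0.75 — values in the range typical for loadings of
cognitive tests on a general factor. WST (vocabulary) deliberately loads
0: it is the one selected variable expected to surface through the second
PLS component rather than the general factor, and its group-mean pattern
(older above young) runs against the response, so giving it a positive
general-factor loading would be internally inconsistent.
`strong_loadings()` provides the strong-signal regime used by the recovery
acceptance test (signal loadings |0.80–0.85|, β = 0.9, floor off — the
floor models unpredictable zero scorers, a separate robustness condition);
`null_loadings()` zeroes everything for leakage and calibration
diagnostics.

**Trial records.** Each subject's 60 sentence trials (6 learning blocks of
10) draw integer scores from a binomial model with a probit-linked ability
matching the subject's response and a mild learning gradient over blocks,
then receive a rank-preserving adjustment forcing the median to equal the
subject's battery response exactly. Raw test records are reconstructed by
inverting the derivation (arbitrary positive bases for the RT tasks, an
increasing verbal-learning profile); the round trip through
`derive_predictors` is exact to rounding for every subject whose values
lie inside the physical test ranges. Because the Gaussian marginals are
unbounded, a minority of simulated subjects exceed those ranges (most
often recognition, whose ceiling of 15 sits ~0.5 SD above the young-group
mean); for them the raw records saturate at the test limits and the
inversion is not exact. `synthetic.representable` flags such subjects, and
the pipeline report counts them.

**What the generator does not emulate:** test-retest reliability, session
or order effects, non-Gaussian marginals and ceiling compression of the
real tests, age-specific factor structure, and any second latent
dimension beyond the WST device above. Passing recovery tests therefore
show that the selection machinery finds a planted single-factor signal at
the study's sample size — not that the original study's selected set is
correct.

## Problem sizes and determinism

The test suite runs the heavier Monte-Carlo checks at 200 replicates
(anti-leakage, recovery) and 500 replicates (generator calibration), with
B = 999 flips inside the 2000-replicate permutation-calibration check —
sizes chosen so the whole suite completes in well under a minute per check
while leaving the Monte-Carlo error far smaller than the tested margins.
All randomness flows through `numpy.random.SeedSequence` spawning; every
reported analysis records its seed, and fixed seed + config reproduces
reports byte-identically.

## Known limitations

* The component-significance permutation scheme is a declared choice; the
  randomization test literature offers variants (e.g. permuting fold
  assignments) that this package does not implement.
* Two PLS components are hard-wired into the inference chain (configurable
  in the core fit); rank-deficient training folds truncate silently to the
  feasible maximum.
* The vocoder does not implement sinusoidal carriers, electrode-specific
  CI models, or dB SPL loudness calibration.
* Subgroup tests require ≥ 2 subjects per group and inherit the power
  limits of n ≈ 20 per group.
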