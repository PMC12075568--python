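# Methods

This note records the modelling assumptions, parameter defaults, numerical
choices and known limitations of the pipeline. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Problem setting

The pipeline is a binary screen (0 = normal, 1 = abnormal) over two
per-subject modalities: a numeric behavioral series (activity, sleep or
questionnaire trajectories; possibly with missing cells and corrupted rows)
and a voiced speech sample. The two branches are cleaned, featurized and
classified separately and fused by weighted voting, on the premise that
behavioral data carries slow trait-like signal while voice quality carries
state-like signal.

When the two modalities arrive as *separate cohorts* rather than joint
recordings, the package pairs them by stable label-sorted row order
(`align_and_concat`). This protocol makes the table shapes compatible, but
rows from unrelated cohorts are not the same subject; conclusions drawn from
such a pairing rest entirely on the pairing convention. The synthetic
generator therefore produces *genuinely* paired subjects, and the end-to-end
claims in this package are made on those.

## Behavioral cleaning

- **KNN imputation.** Distance between rows is the plain Euclidean distance
  over the features both rows observe, on raw (unscaled) values — imputation
  precedes scaling in the stage order, so no scaled space exists yet.
  Imputed values come only from originally observed cells, never from other
  imputations; ties among equidistant donors go to the lower row index.
  Default K = 5 (the method text leaves K open; 5 is common practice at
  cohort sizes of 10²–10³). On held-out rows the donor pool is the training
  table only.
- **Min–Max scaling.** A constant training feature maps to 0 (any constant
  is information-free); at inference, out-of-range values are clipped so the
  [0, 1] invariant survives without refitting.
- **Isolation forest.** Random-split trees on subsamples of
  min(256, n) rows, depth-capped at ceil(log2(subsample)); unresolved leaves
  add the reference path length c(size). The anomaly score uses
  `c(n) = 2(ln(n−1) + r)` with r = 0.5772 as the normalizer — note this
  reference differs from the harmonic-number form used elsewhere in the
  anomaly-detection literature; it is the form this pipeline defines, with
  c(n) = 0 for n < 2. Defaults: 100 trees, score threshold 0.6 (scores are
  in (0, 1]; 0.5 is the "average difficulty" landmark, and 0.6 flags points
  clearly easier to isolate than average). Outlier removal is fit on
  training rows and applied to training rows only, never to held-out data.

## Voice chain

Defaults: 16 kHz mono, 25 ms frames (N = 400), 10 ms hop (S = 160), Hann
window, 26 Mel filters over 0–8 kHz, 13 cepstral coefficients, log floor
1e-10 — standard narrow-band speech analysis settings.

- **Framing.** Frames are half-open sample intervals [tS, tS+N), 0-based,
  shared by the energy series and the spectrogram; no padding, so a signal
  yields floor((L−N)/S)+1 frames.
- **Spectral gating.** The per-frequency threshold is the 20th percentile of
  |X(f, ·)| across frames (lower-interpolation convention): for mostly
  voiced recordings the low quantile of each frequency track estimates its
  noise floor. A scalar threshold is also accepted. Gating is idempotent and
  never increases energy.
- **Reconstruction.** ISTFT is normalized weighted overlap-add (division by
  the summed squared window), exact wherever coverage is non-negligible;
  edge samples with < 0.1% of peak coverage are zeroed rather than
  amplified. The acoustic-quality measures are computed on this
  reconstructed, gated waveform: gating artifacts (frame-boundary amplitude
  modulation) inflate measured jitter/shimmer *uniformly across classes*,
  which preserves contrasts but means absolute values on gated audio are not
  comparable to ungated ones. The parameter-recovery checks therefore run on
  the raw synthesized waveform.
- **MFCC.** Triangular Mel filters are peak-normalized to 1 and their
  centers equally spaced on mel(f) = 2595·log10(1 + f/700). The cepstrum is
  the cosine sum over log Mel energies for n = 1..13 — the DC cepstral term
  is excluded, so a spectrally flat (or silent, floored) frame yields all
  zeros. Per-coefficient summaries are mean, variance, and *standardized*
  skewness m3/m2^{3/2} and excess kurtosis m4/m2² − 3, both defined as 0
  at zero variance. A `literal_moments` flag evaluates an alternative
  non-standardized moment form (subtracting mean/variance inside the power)
  for comparison; it is dimensionally inconsistent and not used by default.
- **Glottal cycles.** The dominant normalized-autocorrelation lag in the
  50–500 Hz range guides peak-picking (window ±35% of the period around each
  expected mark), with parabolic sub-sample refinement. The autocorrelation
  is normalized by the energies of the two overlapping segments, removing
  the shrinking-overlap bias, and the smallest lag within 0.02 of the
  maximum is chosen to avoid octave errors. A normalized peak below 0.3
  declares the signal unvoiced; unvoiced recordings get NaN quality values,
  later imputed with training-set medians. Cycle amplitude is the
  interpolated peak magnitude at the cycle's own mark (a window max would
  blend in the neighbouring pulse). Jitter divides by T_i as defined
  (asymmetric), not by the mean period. HNR converts the normalized
  autocorrelation peak ρ via P_h/P_n = ρ/(1−ρ), capped at ±60 dB.

## Warping distance

The recursion adds a skip penalty α·p to both off-diagonal moves; the
diagonal is free. With w ≡ 1 and p = 0 it reduces exactly to classical DTW
(verified against exhaustive path enumeration). Backtracking prefers
diagonal, then vertical — a pure determinism convention. Defaults: w ≡ 1
(an optional Gaussian near-diagonal weighting is provided), α = 1, and
p = 0.1 × the mean absolute level of the training series, making the
penalty scale-aware. Behavioral features take the distance to one medoid
template per class; medoids are searched over at most 30 training series
per class (the medoid of a homogeneous class is stable well below that),
computed on training data only.

## Feature selection

Each round removes exactly the lowest-weighted surviving feature and then
recomputes every weight on the survivors — the recomputation is the point:
rankings shift as correlated features leave. Weight sources per branch:
behavioral = the average of normalized impurity importances from the
weighted forest and normalized split-gain importances from the boosting
machine; voice = permutation importance of the hybrid SVM–KNN on a held-out
quarter (5 shuffles per feature, averaged, clipped at 0) — the K-NN member
has no native importance, so a model-agnostic measure covers the pair.
Weight ties break lexicographically by feature name. The selection-stage
models are deliberately smaller than the final classifiers (50 trees /
50 boosting rounds with early stopping): rankings stabilize long before the
full ensemble does. A `classic_rfe` flag freezes the initial ranking for
comparison. Default target: half the features, minimum 4.

## Classifiers

- **Weighted forest.** 100 trees, depth ≤ 20, min split 4, √p features per
  split, bootstrap sampling. Tree weights ∝ out-of-bag accuracy
  (`tree_weight="importance"` switches to total impurity decrease);
  trees with an empty out-of-bag set get the neutral weight 0.5 before
  normalization. Uniform weights reduce the vote exactly to a plain forest
  majority.
- **Boosting.** Leaf-wise growth: the leaf with the largest
  sum-of-squared-error gain splits next, until 20 leaves, depth 5 or
  min 10 rows per leaf. Rounds fit the negative log-loss gradient
  y − σ(F) starting from the log-odds prior, stepped by ρ = 0.1; training
  stops early when the log-loss improvement drops below 1e-6 (default cap
  100 rounds). Leaf values are mean residuals — first-order steps, so a
  single round on a cleanly split sample equals the hand-computed gradient
  step.
- **Hybrid SVM–KNN.** RBF-kernel SVM (C = 0.1) for the confident region,
  K = 5 nearest neighbours (Euclidean) inside the ambiguous margin band.
  The switch tests the *magnitude* |f(x)| against δ = 0.2: switching on the
  signed value would route every negative-class point to the K-NN branch,
  contradicting the confidence rationale. δ = 0 gives pure SVM, δ = ∞ pure
  K-NN, and the K-NN-routed set grows monotonically with δ.
- **Balancing.** SMOTE (k = 5, interpolation on segments to minority
  neighbours) raises the minority and random undersampling lowers the
  majority, both to the midpoint of the two class counts, leaving them
  equal within 1. Balancing runs on the joined behavioral+voice feature
  matrix so the branches stay row-aligned, and on training rows only.
- **Fusion.** Weights ∝ each classifier's accuracy on an internal
  stratified 20% validation split (the classifiers are then refit on all
  balanced rows); the fused call is abnormal when the weighted abnormal
  share strictly exceeds 0.5 — an exact tie returns normal, the
  conservative choice for a screen. Weights are global, not per class.
- **Seeding.** One master seed is split per stage via `SeedSequence`, so a
  refit with the same seed reproduces weights, splits and predictions
  exactly.

The framework contains no neural-network components, so techniques specific
to them (batch normalization, dropout) have no counterpart here;
regularization lives in the tree/kernel hyperparameters above.

## Synthetic cohort generator

- **Behavioral.** Per-subject Gaussian AR(1) series (φ = 0.6, giving the
  temporal correlation the warping distance needs), class 1 shifted by
  `class_shift` marginal standard deviations with a ×1.5 innovation-variance
  multiplier. Missing cells are Bernoulli per cell; outlier rows (Bernoulli
  per row) receive ±8σ spikes on 30% of their cells. Ground-truth flags are
  always returned.
- **Voice.** Glottal-pulse source: the first 5 harmonics with 1/k roll-off,
  phase reset per cycle, each pulse centred inside its own cycle so its
  peak amplitude is unambiguously that cycle's A_i. Per-cycle period and
  amplitude perturbations are Gaussian, **scaled by √π/2** so that the
  *expected measured* jitter/shimmer — the mean relative consecutive-cycle
  difference the analyzer computes — equals the requested target (for iid
  N(0, σ) perturbations the mean absolute consecutive difference is 2σ/√π).
  White noise is added at the power implied by the HNR target. Defaults:
  f0 = 150 Hz, 1 s at 16 kHz, jitter 0.5%, shimmer 2%, HNR 25 dB — a
  plausibly healthy sustained vowel. At 25 dB HNR the noise adds a
  measured-jitter floor of roughly 1 percentage point through sub-sample
  mark error; the recovery checks therefore isolate one parameter at a time
  with the others at their clean extremes.
- **What it does not emulate.** Real speech prosody, phonetic content,
  formant structure, channel/recording variability, or any clinical
  covariate structure. Passing tests demonstrate that the pipeline recovers
  the signal it defines, not that the same separation exists in clinical
  recordings.

## Study conditions and problem sizes

The recovery and end-to-end checks run at fixed, declared sizes: voice
recovery on 1 s voices, 3 seeds per target (jitter and shimmer targets
0.5/1/2/4%, HNR 5/10/20 dB, pitch 100/220/300 Hz); feature-selection
recovery with 2 informative (2σ) + 8 noise features at n = 200 over
20 seeds; the strong-separation experiment at 100 subjects per class with a
3σ behavioral shift and 1% vs 4% jitter contrast (80:20 split); the
shuffled-label null re-uses those extracted features over 5 permutation
seeds; the effect-size sweep runs 60 subjects per class at shifts
{0, 0.5, 1, 2, 3}σ with the class-1 jitter target rising 1 percentage point
per σ, 3 repetitions each. The abnormal-class voice contrast scales with
the behavioral shift by design: the sweep parameter indexes overall
condition severity across both modalities.

## Known limitations

- The label-sorted pairing protocol for unrelated cohorts is implemented as
  specified but is scientifically meaningful only for genuinely paired data.
- Jitter/shimmer are the plain relative local forms; perturbation-quotient
  variants (RAP, PPQ5, APQ11) are out of scope.
- The fused decision is uncalibrated (majority-style voting, no
  probabilities), and only the binary normal/abnormal decision is supported.
- Measured voice quality on spectrally gated audio is biased upward by
  reconstruction artifacts; contrasts remain valid, absolute values do not.
- The isolation-forest threshold (0.6) and imputation K (5) are practice
  defaults, not tuned values.
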