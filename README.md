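# neurovibe

Multi-modal early screening for mental-health disorders from **behavioral
time series** and **voice acoustics**.

Screening questionnaire or activity data rarely tells the whole story, and
neither does a voice sample alone: behavioral signals reflect long-term
patterns while voice quality reacts to current state. This package fuses the
two. It is aimed at digital-health researchers who want a fully inspectable,
deterministic reference pipeline — every stage is plain Python on numpy /
scipy / scikit-learn, every stochastic step takes a seed, and a synthetic
two-modality cohort generator makes the whole chain testable without any
clinical data.

## The method

For each subject with a behavioral series and a voice recording:

1. **Behavioral cleaning** — KNN imputation of missing cells (Euclidean
   distance over mutually observed features), Min–Max scaling to [0, 1], and
   isolation-forest outlier removal with anomaly score
   `s(x) = 2^(−l(x)/c(n))`, `c(n) = 2(ln(n−1) + 0.5772)`.
2. **Voice cleaning** — short-time energy segmentation, STFT, per-frequency
   spectral gating against an estimated noise floor, overlap-add
   reconstruction.
3. **Feature extraction** —
   *behavioral block*: population mean/variance/skewness of the series plus
   constrained-DTW distances to one class-medoid template per class, where
   the warping recursion
   `D(i,j) = w(i,j)|a_i − b_j| + min{D(i−1,j)+αp, D(i,j−1)+αp, D(i−1,j−1)}`
   penalizes insertions and deletions by a skip cost `αp`;
   *voice block*: pitch `f0 = 1/T̄`, jitter
   `(1/(N−1)) Σ |T_i − T_{i+1}|/T_i`, shimmer (same on cycle amplitudes),
   HNR `10·log10(P_harm/P_noise)`, and mean/variance/skewness/kurtosis of
   each MFCC coefficient across frames.
4. **Feature selection** — recursive elimination that removes the
   lowest-weighted feature and **recomputes all weights every round**
   (forest + boosting importances for the behavioral block, permutation
   importance of the hybrid classifier for the voice block).
5. **Classification** — SMOTE + random undersampling for class balance, then
   a weighted random forest (trees vote with out-of-bag-accuracy weights,
   `F(x) ∝ Σ_t w_t f_t(x)`) and a leaf-wise gradient-boosting machine on the
   behavioral block, a margin-switched SVM–KNN hybrid on the voice block
   (SVM when `|f(x)| > δ`, otherwise the local K-NN vote), fused by weighted
   voting `Y = argmax_c Σ_i w_i·1[y_i = c]` with weights earned on an
   internal validation split.

## A worked example

```python
from neurovibe import (BehavioralGenSpec, VoiceGenSpec, PipelineConfig,
                       gen_paired_dataset, run_experiment)

dataset = gen_paired_dataset(
    BehavioralGenSpec(n_per_class=50, class_shift=2.0, seed=0),
    VoiceGenSpec(jitter_target=0.01, seed=0),   # normal voices
    VoiceGenSpec(jitter_target=0.03, seed=0))   # abnormal voices
result = run_experiment(dataset, PipelineConfig(seed=0), train_fraction=0.8)
print(result.report.accuracy, result.model.fusion_weights)
```

prints

```
held-out accuracy:    1.000
MCC:                  1.000
fusion weights (IRF, GBM, hybrid SVM-KNN): [0.34  0.34  0.319]
```

(from `examples/04_full_pipeline.py`): with a 2σ behavioral shift and vocal
jitter raised from 1% to 3% in the abnormal class, the held-out subjects are
separated perfectly and all three classifiers earn near-equal fusion weight.
The other scripts under `examples/` demonstrate voice parameter recovery,
behavioral cleaning and the warping distance in isolation.

A thin CLI mirrors the pipeline stages:

```bash
neurovibe simulate --n 40 --seed 7 --out data/
neurovibe preprocess-behavior --data data/behavior.csv --out clean.csv
neurovibe extract-voice --wav-dir data/ --out voice.csv
neurovibe train --behavior beh.csv --voice voice.csv --model-out model/
neurovibe evaluate --model model/ --behavior beh.csv --voice voice.csv --out metrics.csv
```

## Layout

- `src/neurovibe/pipeline_io.py` — CSV/WAV/YAML I/O, the label-sorted
  row-pairing protocol, logging
- `src/neurovibe/behavioral_preprocess.py` — imputation, scaling, isolation
  forest
- `src/neurovibe/voice_dsp.py` — energy, STFT/ISTFT, gating, Mel bank, MFCC
- `src/neurovibe/feature_extraction.py` — series moments, constrained DTW,
  glottal-cycle voice quality, MFCC statistics
- `src/neurovibe/mrfe.py` — recursive feature elimination with weight
  recomputation
- `src/neurovibe/ensemble.py` — balancing, the three classifiers, fusion
- `src/neurovibe/evaluation.py` — confusion metrics, stratified splitting
- `src/neurovibe/synthetic_data.py` — the two-modality cohort generator
- `src/neurovibe/workflow.py` — end-to-end orchestration
- `docs/methods.md` — modelling assumptions, defaults and limitations
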