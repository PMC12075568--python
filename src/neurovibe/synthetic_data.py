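"""Synthetic two-modality fixtures.

Behavioral side: per-subject Gaussian AR(1) series; the abnormal class adds a
mean shift (expressed in units of the marginal AR(1) standard deviation) and
a variance multiplier.  Missing cells and additive outliers are injected at
configurable rates, and ground-truth flags are always returned so detection
stages can be scored against the injection.

Voice side: a quasi-periodic glottal-pulse source — per cycle, the first five
harmonics with 1/k amplitude roll-off and a phase reset at the cycle start —
with per-cycle period jitter, per-cycle amplitude shimmer and additive white
noise scaled to a target harmonics-to-noise ratio.  The Gaussian cycle
perturbations are calibrated (scaled by sqrt(pi)/2) so that the *expected
measured* jitter/shimmer — the mean relative consecutive-cycle difference the
analysis chain computes — equals the requested target, since for iid N(0,s)
perturbations E|d_i - d_{i+1}| = 2s/sqrt(pi).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .pipeline_io import (BehavioralTable, VoiceRecording, write_behavioral,
                          write_wav)

#: sqrt(pi)/2 — makes E[measured consecutive-difference ratio] = target
_CONSEC_DIFF_CALIBRATION = math.sqrt(math.pi) / 2.0


@dataclass
class BehavioralGenSpec:
    n_per_class: int = 100
    series_length: int = 40
    class_shift: float = 1.0          # class-1 mean shift, in marginal sigma
    var_multiplier: float = 1.5       # class-1 innovation variance multiplier
    missing_rate: float = 0.05
    outlier_rate: float = 0.02        # fraction of rows flagged as outliers
    outlier_magnitude: float = 8.0    # additive spike size, in marginal sigma
    ar_coeff: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.missing_rate < 1 and 0 <= self.outlier_rate < 1):
            raise ValueError("rates must be in [0, 1)")
        if self.series_length < 3:
            raise ValueError("series length must be >= 3")
        if not -1 < self.ar_coeff < 1:
            raise ValueError("AR(1) coefficient must be in (-1, 1)")
        if self.n_per_class < 2:
            raise ValueError("need at least 2 subjects per class")


@dataclass
class VoiceGenSpec:
    f0: float = 150.0                 # Hz
    duration: float = 1.0             # seconds
    rate: int = 16000                 # Hz
    jitter_target: float = 0.005      # expected measured cycle jitter (ratio)
    shimmer_target: float = 0.02      # expected measured cycle shimmer (ratio)
    hnr_target: float = 25.0          # dB
    n_harmonics: int = 5
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.f0 < self.rate / 2:
            raise ValueError("f0 must be in (0, rate/2)")
        if self.jitter_target >= 0.5 or self.jitter_target < 0:
            raise ValueError("infeasible jitter target")
        if self.shimmer_target < 0:
            raise ValueError("shimmer target must be >= 0")
        if self.duration * self.rate < 2 * self.rate / self.f0:
            raise ValueError("duration too short for two cycles")


def gen_behavioral(spec: BehavioralGenSpec,
                   ) -> tuple[BehavioralTable, dict]:
    """Labeled behavioral series table plus ground-truth injection flags.

    Returns ``(table, truth)`` where ``truth`` has boolean ``outlier_rows``
    (length 2n) and the boolean ``missing_mask`` (subjects x time steps).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, L, phi = spec.n_per_class, spec.series_length, spec.ar_coeff
    sigma_marginal = 1.0 / math.sqrt(1.0 - phi ** 2)

    def simulate(n_subj, shift, var_mult):
        innov_sd = math.sqrt(var_mult)
        x = np.empty((n_subj, L))
        x[:, 0] = rng.normal(0.0, sigma_marginal * innov_sd, n_subj)
        for t in range(1, L):
            x[:, t] = phi * x[:, t - 1] + rng.normal(0.0, innov_sd, n_subj)
        return x + shift * sigma_marginal

    X = np.vstack([simulate(n, 0.0, 1.0),
                   simulate(n, spec.class_shift, spec.var_multiplier)])
    y = np.concatenate([np.zeros(n, dtype=int), np.ones(n, dtype=int)])

    outlier_rows = rng.random(2 * n) < spec.outlier_rate
    for i in np.flatnonzero(outlier_rows):
        n_cells = max(1, int(round(0.3 * L)))
        cols = rng.choice(L, size=n_cells, replace=False)
        signs = rng.choice((-1.0, 1.0), size=n_cells)
        X[i, cols] += signs * spec.outlier_magnitude * sigma_marginal

    missing_mask = rng.random((2 * n, L)) < spec.missing_rate
    # keep every column and row partly observed so imputation stays defined
    full_cols = missing_mask.all(axis=0)
    missing_mask[0, full_cols] = False
    full_rows = missing_mask.all(axis=1)
    missing_mask[full_rows, 0] = False
    X_missing = np.where(missing_mask, np.nan, X)

    columns = [f"t{t:03d}" for t in range(L)]
    table = BehavioralTable(pd.DataFrame(X_missing, columns=columns),
                            pd.Series(y, name="label"))
    truth = {"outlier_rows": outlier_rows, "missing_mask": missing_mask,
             "clean": X, "spec": asdict(spec)}
    return table, truth


def gen_voice(spec: VoiceGenSpec, label: int = 0, subject_id: str = "",
              ) -> VoiceRecording:
    """One synthetic quasi-periodic voice recording.

    Cycle k spans a fractional sample interval of length T0*(1 + e_k) where
    e_k ~ N(0, (calibrated jitter)^2); within the cycle the waveform is
    A_k * sum_{h=1..H} (1/h) cos(h * phase), phase rising 0..2*pi across the
    cycle, so every cycle starts at its amplitude peak (an unambiguous
    cycle mark).  White noise is added at the power implied by the HNR
    target, and the result is normalized to 95% full scale.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_samples = int(round(spec.duration * spec.rate))
    t0_samples = spec.rate / spec.f0
    jitter_sd = _CONSEC_DIFF_CALIBRATION * spec.jitter_target
    shimmer_sd = _CONSEC_DIFF_CALIBRATION * spec.shimmer_target
    harmonics = np.arange(1, spec.n_harmonics + 1)

    # pulse peak positions q_i by period accumulation; each pulse is centred
    # inside its own cycle so its peak amplitude is unambiguously A_i
    periods, peaks = [], []
    q = t0_samples / 2.0
    while q < n_samples + t0_samples:
        peaks.append(q)
        period = t0_samples * (1.0 + float(
            np.clip(rng.normal(0.0, jitter_sd), -0.45, 0.45))) \
            if jitter_sd > 0 else t0_samples
        periods.append(period)
        q += period
    amps = np.maximum(1.0 + rng.normal(0.0, shimmer_sd, len(peaks)), 0.05) \
        if shimmer_sd > 0 else np.ones(len(peaks))

    x = np.zeros(n_samples)
    bounds = [0.0] + [(peaks[i] + peaks[i + 1]) / 2.0
                      for i in range(len(peaks) - 1)] + [float(n_samples)]
    for i, (q_i, p_i, a_i) in enumerate(zip(peaks, periods, amps)):
        lo = max(int(math.ceil(bounds[i])), 0)
        hi = min(int(math.ceil(bounds[i + 1])), n_samples)
        if hi <= lo:
            continue
        phase = 2.0 * math.pi * (np.arange(lo, hi) - q_i) / p_i
        x[lo:hi] = a_i * ((np.cos(np.outer(harmonics, phase))
                           / harmonics[:, None]).sum(axis=0))

    p_harmonic = float(np.mean(x ** 2))
    if np.isfinite(spec.hnr_target) and p_harmonic > 0:
        p_noise = p_harmonic / (10.0 ** (spec.hnr_target / 10.0))
        x = x + rng.normal(0.0, math.sqrt(p_noise), n_samples)
    peak = np.max(np.abs(x))
    if peak > 0:
        x = 0.95 * x / peak
    return VoiceRecording(x, spec.rate, label=label, subject_id=subject_id)


@dataclass
class PairedDataset:
    behavior: BehavioralTable
    recordings: list
    truth: dict
    manifest: dict


def gen_paired_dataset(behavior_spec: BehavioralGenSpec,
                       voice_spec_class0: VoiceGenSpec,
                       voice_spec_class1: VoiceGenSpec,
                       out_dir: str | Path | None = None) -> PairedDataset:
    """Genuinely paired per-subject behavioral + voice data, one shared label.

    Per-subject voice seeds are spawned deterministically from the behavioral
    spec's seed.  When ``out_dir`` is given, writes ``behavior.csv``, one WAV
    per subject and ``manifest.json`` with the ground-truth parameters.
    """
    behavior_spec.validate()
    voice_spec_class0.validate()
    voice_spec_class1.validate()
    table, truth = gen_behavioral(behavior_spec)
    labels = table.labels.to_numpy()
    seed_seq = np.random.SeedSequence(behavior_spec.seed).spawn(len(labels) + 1)
    recordings = []
    for i, label in enumerate(labels):
        spec = voice_spec_class1 if label == 1 else voice_spec_class0
        per_subject = VoiceGenSpec(**{**asdict(spec), "seed": int(
            seed_seq[i + 1].generate_state(1)[0] % (2 ** 31 - 1))})
        recordings.append(gen_voice(per_subject, label=int(label),
                                    subject_id=f"subj{i:04d}"))
    manifest = {
        "n_subjects": len(labels),
        "behavior_spec": asdict(behavior_spec),
        "voice_spec_class0": asdict(voice_spec_class0),
        "voice_spec_class1": asdict(voice_spec_class1),
        "outlier_rows": truth["outlier_rows"].astype(int).tolist(),
        "labels": labels.tolist(),
        "subject_ids": [r.subject_id for r in recordings],
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_behavioral(table, out_dir / "behavior.csv")
        for rec in recordings:
            write_wav(rec, out_dir / f"{rec.subject_id}.wav")
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return PairedDataset(table, recordings, truth, manifest)
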