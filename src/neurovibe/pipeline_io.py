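"""I/O and dataset plumbing.

Reads and writes the concrete formats the pipeline touches — CSV feature
tables, PCM WAV audio, YAML config, JSON reports — and implements the
label-sorted row-pairing protocol that joins the behavioral and voice feature
tables into one multi-modal table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

logger = logging.getLogger("neurovibe")

DEFAULT_MISSING_TOKENS = ("", "NA", "NaN")

_INT16_FULL_SCALE = 32767.0


@dataclass
class BehavioralTable:
    """Subjects x numeric features plus a binary label per subject.

    ``data`` holds the feature matrix (cells may be NaN = missing); ``labels``
    is aligned with ``data`` row-for-row, values in {0 = normal, 1 = abnormal}.
    """

    data: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        if len(self.data) < 1:
            raise ValueError("behavioral table needs at least one subject")
        if self.data.shape[1] < 1:
            raise ValueError("behavioral table needs at least one feature")
        if len(self.labels) != len(self.data):
            raise ValueError("labels and feature rows differ in length")
        lab = np.asarray(self.labels)
        if not np.isin(lab, (0, 1)).all():
            raise ValueError("non-binary label: labels must be 0 or 1")
        if self.data.isna().all(axis=0).any():
            bad = self.data.columns[self.data.isna().all(axis=0)][0]
            raise ValueError(f"feature column entirely missing: {bad!r}")
        self.labels = pd.Series(lab.astype(int), index=self.data.index,
                                name=self.labels.name or "label")

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    def copy(self) -> "BehavioralTable":
        return BehavioralTable(self.data.copy(), self.labels.copy())


@dataclass
class VoiceRecording:
    """A mono waveform with its sampling rate and subject metadata."""

    samples: np.ndarray
    rate: int
    label: int = 0
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.label not in (0, 1):
            raise ValueError("non-binary label")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate


def read_behavioral(path: str | Path, label_column: str = "label",
                    missing_tokens: tuple[str, ...] = DEFAULT_MISSING_TOKENS,
                    ) -> BehavioralTable:
    """Read a CSV of per-subject numeric features plus a binary label column.

    Cells equal to one of ``missing_tokens`` become missing; any other
    non-numeric feature cell is rejected.
    """
    df = pd.read_csv(path, na_values=list(missing_tokens),
                     keep_default_na=False, skipinitialspace=True)
    if df.empty:
        raise ValueError(f"empty behavioral file: {path}")
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not found in {path}")
    labels = df[label_column]
    if labels.isna().any():
        raise ValueError("missing label value")
    lab = pd.to_numeric(labels, errors="coerce")
    if lab.isna().any() or not np.isin(lab.to_numpy(), (0, 1)).all():
        raise ValueError("non-binary label")
    features = df.drop(columns=[label_column])
    numeric = features.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~features.isna()
    if bad.to_numpy().any():
        col = features.columns[bad.any(axis=0)][0]
        raise ValueError(f"non-numeric feature cell in column {col!r}")
    return BehavioralTable(numeric, lab.astype(int))


def write_behavioral(table: BehavioralTable, path: str | Path,
                     label_column: str = "label") -> None:
    out = table.data.copy()
    out[label_column] = table.labels.to_numpy()
    out.to_csv(path, index=False)


def read_wav(path: str | Path, label: int = 0, subject_id: str = "",
             ) -> VoiceRecording:
    """Read a PCM WAV file; stereo is averaged to mono, samples scaled to [-1, 1]."""
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max)
        samples = data.astype(float) / scale
    else:
        samples = data.astype(float)
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    return VoiceRecording(np.clip(samples, -1.0, 1.0), int(rate),
                          label=label, subject_id=subject_id or Path(path).stem)


def write_wav(rec: VoiceRecording, path: str | Path) -> None:
    """Write a recording as 16-bit PCM WAV."""
    clipped = np.clip(rec.samples, -1.0, 1.0)
    pcm = np.round(clipped * _INT16_FULL_SCALE).astype(np.int16)
    wavfile.write(path, rec.rate, pcm)


def _sort_by_label(features: pd.DataFrame, labels: pd.Series,
                   ) -> tuple[pd.DataFrame, pd.Series]:
    order = np.argsort(labels.to_numpy(), kind="stable")
    return features.iloc[order].reset_index(drop=True), \
        labels.iloc[order].reset_index(drop=True)


def align_and_concat(behavior: BehavioralTable, voice: BehavioralTable,
                     ) -> BehavioralTable:
    """Pair the two modality tables by label order and join them column-wise.

    Both tables are stably sorted by label; row i of one is then paired with
    row i of the other, so per-class counts must match.  The joined table has
    all behavioral columns followed by all voice columns and a single shared
    label column.
    """
    for cls in (0, 1):
        nb = int((behavior.labels == cls).sum())
        nv = int((voice.labels == cls).sum())
        if nb != nv:
            raise ValueError(
                f"per-class count mismatch for class {cls}: "
                f"behavioral has {nb}, voice has {nv}")
    beh_f, beh_l = _sort_by_label(behavior.data, behavior.labels)
    voi_f, _ = _sort_by_label(voice.data, voice.labels)
    voi_f = voi_f.rename(columns={
        c: (f"{c}_voice" if c in beh_f.columns else c) for c in voi_f.columns})
    combined = pd.concat([beh_f, voi_f], axis=1)
    return BehavioralTable(combined, beh_l)


def setup_logging(level: int = logging.INFO) -> None:
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(level)
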