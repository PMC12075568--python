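"""Confusion-matrix metrics and stratified data splitting.

The abnormal class (label 1) is the positive class throughout.  Metrics with
a zero denominator are reported as missing (NaN) rather than 0, so degenerate
evaluations cannot silently inflate a score.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    specificity: float
    sensitivity: float
    f1: float
    mcc: float
    npv: float
    fpr: float
    fnr: float

    def to_dict(self) -> dict:
        return {k: (None if isinstance(v, float) and math.isnan(v) else v)
                for k, v in asdict(self).items()}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def confusion(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch between truth and prediction")
    for arr in (y_true, y_pred):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
    return ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()))


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """All nine reported metrics from the confusion counts."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    if counts.n <= 0:
        raise ValueError("empty confusion table")
    precision = _ratio(tp, tp + fp)
    sensitivity = _ratio(tp, tp + fn)
    specificity = _ratio(tn, tn + fp)
    f1 = (_ratio(2 * precision * sensitivity, precision + sensitivity)
          if not (math.isnan(precision) or math.isnan(sensitivity))
          else float("nan"))
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / mcc_den if mcc_den > 0 else float("nan")
    return MetricsReport(
        accuracy=(tp + tn) / counts.n,
        precision=precision,
        specificity=specificity,
        sensitivity=sensitivity,
        f1=f1,
        mcc=mcc,
        npv=_ratio(tn, tn + fn),
        fpr=1.0 - specificity if not math.isnan(specificity) else float("nan"),
        fnr=1.0 - sensitivity if not math.isnan(sensitivity) else float("nan"))


def stratified_split(y, train_fraction: float, seed: int = 0,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/test index split preserving per-class
    proportions within one subject; both sides keep >= 1 member per class."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    y = np.asarray(y, dtype=int)
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        if len(members) < 2:
            raise ValueError(f"class {cls} has fewer than 2 members")
        perm = rng.permutation(members)
        n_train = int(round(train_fraction * len(members)))
        n_train = min(max(n_train, 1), len(members) - 1)
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    return (np.sort(np.concatenate(train_idx)),
            np.sort(np.concatenate(test_idx)))


def stratified_kfold(y, n_folds: int, seed: int = 0) -> list[np.ndarray]:
    """Test-index folds with near-equal per-class allocation."""
    y = np.asarray(y, dtype=int)
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for cls in np.unique(y):
        members = rng.permutation(np.flatnonzero(y == cls))
        for i, idx in enumerate(members):
            folds[i % n_folds].append(int(idx))
    return [np.sort(np.asarray(f, dtype=int)) for f in folds]
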