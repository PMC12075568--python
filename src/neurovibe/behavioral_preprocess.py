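"""Behavioral table cleaning.

Three stages, applied in this order: KNN imputation of missing cells
(Euclidean distance over mutually observed features, unscaled), Min-Max
scaling of every feature into [0, 1], and isolation-forest outlier scoring
and removal.

The isolation forest scores a point x by the average number of random splits
needed to isolate it over an ensemble of random binary trees, normalized to

    s(x) = 2 ** (-l(x) / c(n)),     c(n) = 2 * (ln(n - 1) + r),

with r = 0.5772 (Euler's constant) and n the per-tree subsample size.  Short
average paths (easy to isolate) push s toward 1; deep paths push it toward 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .pipeline_io import BehavioralTable

EULER_R = 0.5772


def knn_impute(table: BehavioralTable, k: int,
               donors: BehavioralTable | None = None) -> BehavioralTable:
    """Replace each missing cell by the mean of that feature over the K
    nearest complete-in-that-feature rows.

    Distances are Euclidean over the features observed in *both* rows, taken
    on the raw (unscaled) values; ties among equidistant donors are broken by
    the lower row index.  Observed cells are never changed, and all distances
    are computed against the original values (imputed values never feed later
    imputations).  ``donors`` restricts the donor pool to another table
    (e.g. training rows when imputing held-out rows); by default the table
    donates to itself.
    """
    if k < 1:
        raise ValueError("K must be >= 1")
    X = table.data.to_numpy(dtype=float)
    n, p = X.shape
    observed = ~np.isnan(X)
    if observed.all():
        return table.copy()
    if (~observed).all(axis=0).any():
        col = table.data.columns[(~observed).all(axis=0)][0]
        raise ValueError(f"feature column {col!r} has no observed values")
    self_donating = donors is None
    D = X if self_donating else donors.data.to_numpy(dtype=float)
    d_observed = observed if self_donating else ~np.isnan(D)
    out = X.copy()
    for i in range(n):
        missing_cols = np.flatnonzero(~observed[i])
        if missing_cols.size == 0:
            continue
        # distance from row i to every donor over mutually observed features
        shared = observed[i] & d_observed        # (n_d, p) mutual-feature mask
        diff = np.where(shared, X[i] - np.where(d_observed, D, 0.0), 0.0)
        dist = np.sqrt((diff ** 2).sum(axis=1))
        dist = np.where(shared.any(axis=1), dist, np.inf)
        if self_donating:
            dist[i] = np.inf
        for j in missing_cols:
            pool = np.flatnonzero(d_observed[:, j] & np.isfinite(dist))
            if pool.size < k:
                raise ValueError(
                    f"only {pool.size} donor rows observe feature "
                    f"{table.data.columns[j]!r}; K={k} required")
            order = pool[np.lexsort((pool, dist[pool]))][:k]
            out[i, j] = D[order, j].mean()
    data = pd.DataFrame(out, index=table.data.index, columns=table.data.columns)
    return BehavioralTable(data, table.labels.copy())


@dataclass
class ScalingParams:
    """Per-feature training minima and maxima for Min-Max scaling."""

    x_min: pd.Series
    x_max: pd.Series

    def __post_init__(self) -> None:
        if (self.x_min > self.x_max).any():
            raise ValueError("x_min must be <= x_max per feature")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "x_min": self.x_min.to_dict(), "x_max": self.x_max.to_dict()}))

    @classmethod
    def from_json(cls, path: str | Path) -> "ScalingParams":
        d = json.loads(Path(path).read_text())
        return cls(pd.Series(d["x_min"]), pd.Series(d["x_max"]))


def fit_min_max(table: BehavioralTable) -> ScalingParams:
    if table.data.isna().to_numpy().any():
        raise ValueError("impute missing cells before scaling")
    return ScalingParams(table.data.min(axis=0), table.data.max(axis=0))


def apply_min_max(table: BehavioralTable, params: ScalingParams,
                  ) -> BehavioralTable:
    """Map features into [0, 1] with the training range; out-of-range values
    (at inference) are clipped.  A constant training feature maps to 0."""
    span = (params.x_max - params.x_min).reindex(table.data.columns)
    lo = params.x_min.reindex(table.data.columns)
    scaled = (table.data - lo).div(span.where(span > 0, np.inf), axis=1)
    return BehavioralTable(scaled.clip(0.0, 1.0), table.labels.copy())


def average_bst_path_length(n: int) -> float:
    """Reference path length c(n) = 2*(ln(n-1) + r); 0 when n < 2."""
    if n < 2:
        return 0.0
    return 2.0 * (math.log(n - 1) + EULER_R)


def _build_tree(X: np.ndarray, idx: np.ndarray, depth: int, cap: int,
                rng: np.random.Generator) -> dict:
    if len(idx) <= 1 or depth >= cap:
        return {"size": int(len(idx))}
    sub = X[idx]
    spans = sub.max(axis=0) - sub.min(axis=0)
    candidates = np.flatnonzero(spans > 0)
    if candidates.size == 0:
        return {"size": int(len(idx))}
    feat = int(rng.choice(candidates))
    lo, hi = sub[:, feat].min(), sub[:, feat].max()
    cut = float(rng.uniform(lo, hi))
    left = idx[X[idx, feat] < cut]
    right = idx[X[idx, feat] >= cut]
    if len(left) == 0 or len(right) == 0:     # degenerate draw at the boundary
        return {"size": int(len(idx))}
    return {"feature": feat, "cut": cut,
            "left": _build_tree(X, left, depth + 1, cap, rng),
            "right": _build_tree(X, right, depth + 1, cap, rng)}


def _path_length(tree: dict, x: np.ndarray) -> float:
    depth = 0.0
    node = tree
    while "feature" in node:
        node = node["left"] if x[node["feature"]] < node["cut"] else node["right"]
        depth += 1.0
    return depth + average_bst_path_length(node["size"])


@dataclass
class IForestModel:
    trees: list
    subsample: int
    n_trees: int
    seed: int
    feature_names: list = field(default_factory=list)

    def path_lengths(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.array([[_path_length(t, x) for t in self.trees] for x in X]
                        ).mean(axis=1)

    def score(self, X: np.ndarray) -> np.ndarray:
        """Anomaly scores s(x) in (0, 1]; higher = more anomalous."""
        return score_from_path_length(self.path_lengths(X), self.subsample)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "trees": self.trees, "subsample": self.subsample,
            "n_trees": self.n_trees, "seed": self.seed,
            "feature_names": self.feature_names}))

    @classmethod
    def from_json(cls, path: str | Path) -> "IForestModel":
        return cls(**json.loads(Path(path).read_text()))


def score_from_path_length(l: np.ndarray | float, n: int) -> np.ndarray:
    c = average_bst_path_length(n)
    if c <= 0:
        raise ValueError("subsample too small for a defined score")
    return 2.0 ** (-np.asarray(l, dtype=float) / c)


def iforest_fit(table: BehavioralTable | np.ndarray, n_trees: int = 100,
                subsample: int = 256, seed: int = 0) -> IForestModel:
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    if isinstance(table, BehavioralTable):
        X = table.data.to_numpy(dtype=float)
        names = table.feature_names
    else:
        X = np.atleast_2d(np.asarray(table, dtype=float))
        names = [f"f{i}" for i in range(X.shape[1])]
    n = len(X)
    size = min(subsample, n)
    if size < 2:
        raise ValueError("subsample must be >= 2")
    cap = math.ceil(math.log2(size))
    rng = np.random.default_rng(seed)
    trees = []
    for _ in range(n_trees):
        idx = rng.choice(n, size=size, replace=False)
        trees.append(_build_tree(X, idx, 0, cap, rng))
    return IForestModel(trees, size, n_trees, seed, names)


def remove_outliers(table: BehavioralTable, model: IForestModel,
                    score_threshold: float = 0.6) -> BehavioralTable:
    """Drop rows with anomaly score >= threshold; each class must keep >= 2 rows."""
    if not 0 < score_threshold < 1:
        raise ValueError("score_threshold must be in (0, 1)")
    scores = model.score(table.data.to_numpy(dtype=float))
    keep = scores < score_threshold
    labels = table.labels.to_numpy()
    for cls in np.unique(labels):
        if (keep & (labels == cls)).sum() < 2:
            raise ValueError(
                f"outlier removal would leave class {cls} with fewer than 2 rows")
    return BehavioralTable(table.data.loc[keep].copy(),
                           table.labels.loc[keep].copy())
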