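"""The classifier core.

Two modality branches feed a weighted-vote fusion:

* behavioral branch — an improved random forest (IRF) whose trees vote with
  performance-derived weights, F(x) ~ sum_t w_t * f_t(x), plus a leaf-wise
  gradient-boosting machine trained on the log loss;
* voice branch — a hybrid SVM-KNN that answers with the SVM label when the
  point is far from the decision boundary (|f(x)| > delta) and falls back to
  the local K-nearest-neighbour vote inside the ambiguous margin band.

Class imbalance is handled before training by SMOTE oversampling of the
minority class combined with random undersampling of the majority class.
Fusion weights are proportional to each classifier's accuracy on an internal
stratified validation split; the final binary call is abnormal when the
weighted abnormal share exceeds the decision threshold (ties go to normal).
"""

from __future__ import annotations

import json
import math
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .config import PipelineConfig
from .evaluation import stratified_split
from . import mrfe as mrfe_module


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# class balancing
# ---------------------------------------------------------------------------

def smote_oversample(X_minority: np.ndarray, k: int, n_new: int,
                     seed: int | np.random.Generator = 0,
                     lam: float | None = None) -> np.ndarray:
    """Synthetic minority rows on segments to k-nearest minority neighbours.

    Each synthetic row is x + lam * (x_nn - x) with lam ~ Uniform(0, 1) (or
    the fixed ``lam`` when given, for testing), x a random minority row and
    x_nn one of its k nearest minority neighbours (Euclidean, self excluded).
    """
    X = np.atleast_2d(np.asarray(X_minority, dtype=float))
    n = len(X)
    if n <= k:
        raise ValueError(f"minority count {n} must exceed k={k}")
    if n_new <= 0:
        return np.empty((0, X.shape[1]))
    rng = seed if isinstance(seed, np.random.Generator) else _rng(seed)
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    neighbours = np.argsort(d2, axis=1, kind="stable")[:, :k]
    base = rng.integers(0, n, size=n_new)
    pick = rng.integers(0, k, size=n_new)
    lams = np.full(n_new, lam) if lam is not None else rng.uniform(0, 1, n_new)
    nn = X[neighbours[base, pick]]
    return X[base] + lams[:, None] * (nn - X[base])


def random_undersample(X_majority: np.ndarray, keep_fraction: float,
                       seed: int | np.random.Generator = 0) -> np.ndarray:
    """Uniform subsample (without replacement) of the majority-class rows."""
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    X = np.atleast_2d(np.asarray(X_majority, dtype=float))
    n_keep = int(round(keep_fraction * len(X)))
    if n_keep < 2:
        raise ValueError("undersampling would leave fewer than 2 rows")
    rng = seed if isinstance(seed, np.random.Generator) else _rng(seed)
    idx = np.sort(rng.choice(len(X), size=n_keep, replace=False))
    return X[idx]


def balance_classes(X: np.ndarray, y: np.ndarray, smote_k: int = 5,
                    seed: int | np.random.Generator = 0,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """SMOTE the minority up and undersample the majority down to a common
    count (the midpoint of the two class sizes); already-balanced data is
    returned unchanged.  Resulting class counts are equal within 1.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts[0] == counts[1]:
        return X.copy(), y.copy()
    minority = int(np.argmin(counts))
    majority = 1 - minority
    target = int(math.ceil((counts[0] + counts[1]) / 2))
    rng = seed if isinstance(seed, np.random.Generator) else _rng(seed)
    X_min = X[y == minority]
    X_maj = X[y == majority]
    k_eff = min(smote_k, len(X_min) - 1)
    if k_eff < 1:
        raise ValueError("minority class too small for SMOTE")
    synthetic = smote_oversample(X_min, k_eff, target - len(X_min), rng)
    X_maj_kept = random_undersample(X_maj, target / len(X_maj), rng)
    X_bal = np.vstack([X_min, synthetic, X_maj_kept])
    y_bal = np.concatenate([
        np.full(len(X_min) + len(synthetic), minority),
        np.full(len(X_maj_kept), majority)]).astype(int)
    return X_bal, y_bal


# ---------------------------------------------------------------------------
# improved random forest
# ---------------------------------------------------------------------------

@dataclass
class IRFModel:
    """Random forest whose trees vote with normalized performance weights."""

    trees: list
    weights: np.ndarray
    seed: int
    feature_names: list = field(default_factory=list)

    def vote_share(self, X) -> np.ndarray:
        """Weighted share of the abnormal (1) vote per sample; shares of the
        two classes sum to 1."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        votes = np.stack([t.predict(X) for t in self.trees])   # (T, n)
        return (self.weights[:, None] * (votes == 1)).sum(axis=0)

    def predict(self, X) -> np.ndarray:
        return (self.vote_share(X) > 0.5).astype(int)

    def feature_importances(self) -> np.ndarray:
        imp = np.stack([t.feature_importances_ for t in self.trees])
        return (self.weights[:, None] * imp).sum(axis=0)

    def with_uniform_weights(self) -> "IRFModel":
        w = np.full(len(self.trees), 1.0 / len(self.trees))
        return IRFModel(self.trees, w, self.seed, self.feature_names)


def train_irf(X, y, n_trees: int = 100, max_depth: int = 20,
              min_split: int = 4, seed: int = 0,
              tree_weight: str = "oob") -> IRFModel:
    """Bootstrap trees with sqrt(p) feature subsets per split; tree weights
    are proportional to out-of-bag accuracy (``tree_weight="importance"``
    weights by total impurity decrease instead).
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    n = len(X)
    rng = _rng(seed)
    trees, raw_weights = [], []
    for t in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        tree = DecisionTreeClassifier(
            max_depth=max_depth, min_samples_split=min_split,
            max_features="sqrt",
            random_state=int(rng.integers(0, 2 ** 31 - 1)))
        tree.fit(X[boot], y[boot])
        trees.append(tree)
        if tree_weight == "importance":
            raw = tree.tree_.compute_feature_importances(normalize=False).sum()
        else:
            raw = (tree.predict(X[oob]) == y[oob]).mean() if len(oob) else 0.5
        raw_weights.append(float(raw))
    w = np.asarray(raw_weights)
    w = w / w.sum() if w.sum() > 0 else np.full(n_trees, 1.0 / n_trees)
    return IRFModel(trees, w, seed)


# ---------------------------------------------------------------------------
# leaf-wise gradient boosting
# ---------------------------------------------------------------------------

def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


class _LeafWiseTree:
    """Regression tree grown leaf-wise: the leaf with the largest SSE gain is
    split next, until the leaf cap, the depth cap or no admissible split."""

    def __init__(self, max_leaves: int, max_depth: int, min_leaf: int):
        self.max_leaves = max_leaves
        self.max_depth = max_depth
        self.min_leaf = min_leaf
        self.nodes: list[dict] = []
        self.feature_gain: np.ndarray | None = None

    @staticmethod
    def _best_split(X, r, idx, min_leaf):
        """Best (gain, feature, threshold) for one leaf; gain is the SSE
        reduction of splitting, vectorized per feature by prefix sums."""
        best = (0.0, None, None)
        rr = r[idx]
        total = rr.sum()
        n = len(idx)
        for f in range(X.shape[1]):
            v = X[idx, f]
            order = np.argsort(v, kind="stable")
            vs, rs = v[order], rr[order]
            csum = np.cumsum(rs)
            n_left = np.arange(1, n)
            valid = (vs[1:] > vs[:-1]) & (n_left >= min_leaf) \
                & (n - n_left >= min_leaf)
            if not valid.any():
                continue
            left_sum = csum[:-1]
            gain = (left_sum ** 2 / n_left
                    + (total - left_sum) ** 2 / (n - n_left)
                    - total ** 2 / n)
            gain = np.where(valid, gain, -np.inf)
            j = int(np.argmax(gain))
            if gain[j] > best[0] + 1e-12:
                best = (float(gain[j]), f, float((vs[j] + vs[j + 1]) / 2.0))
        return best

    def fit(self, X, r):
        n, p = X.shape
        self.feature_gain = np.zeros(p)
        self.nodes = [{"idx": np.arange(n), "depth": 0,
                       "value": float(r.mean()) if n else 0.0}]
        leaves = [0]
        while len(leaves) < self.max_leaves:
            # pick the splittable leaf with the largest gain
            best_leaf, best_split = None, (0.0, None, None)
            for leaf_id in leaves:
                node = self.nodes[leaf_id]
                if node["depth"] >= self.max_depth or \
                        len(node["idx"]) < 2 * self.min_leaf:
                    continue
                if "cached_split" not in node:
                    node["cached_split"] = self._best_split(
                        X, r, node["idx"], self.min_leaf)
                if node["cached_split"][1] is not None and \
                        node["cached_split"][0] > best_split[0]:
                    best_leaf, best_split = leaf_id, node["cached_split"]
            if best_leaf is None:
                break
            gain, f, threshold = best_split
            node = self.nodes[best_leaf]
            idx = node["idx"]
            mask = X[idx, f] <= threshold
            for child_idx in (idx[mask], idx[~mask]):
                self.nodes.append({
                    "idx": child_idx, "depth": node["depth"] + 1,
                    "value": float(r[child_idx].mean())})
            node.update({"feature": f, "threshold": threshold,
                         "left": len(self.nodes) - 2,
                         "right": len(self.nodes) - 1})
            node.pop("cached_split", None)
            leaves.remove(best_leaf)
            leaves.extend([node["left"], node["right"]])
            self.feature_gain[f] += gain
        for node in self.nodes:          # training indices are not persisted
            node.pop("idx", None)
            node.pop("cached_split", None)
        return self

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty(len(X))
        for i, x in enumerate(X):
            node = self.nodes[0]
            while "feature" in node:
                node = self.nodes[node["left"]
                                  if x[node["feature"]] <= node["threshold"]
                                  else node["right"]]
            out[i] = node["value"]
        return out


@dataclass
class GBMModel:
    init_score: float
    trees: list
    learning_rate: float
    feature_gain: np.ndarray
    feature_names: list = field(default_factory=list)

    def raw_score(self, X, n_rounds: int | None = None) -> np.ndarray:
        """Additive score after ``n_rounds`` boosting rounds (all by default);
        staged scores are reproducible round by round."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        score = np.full(len(X), self.init_score)
        use = self.trees if n_rounds is None else self.trees[:n_rounds]
        for tree in use:
            score += self.learning_rate * tree.predict(X)
        return score

    def predict_proba(self, X) -> np.ndarray:
        return _sigmoid(self.raw_score(X))

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) > 0.5).astype(int)


def train_gbm(X, y, learning_rate: float = 0.1, max_leaves: int = 20,
              max_depth: int = 5, min_leaf: int = 10, rounds: int = 100,
              tol: float = 1e-6) -> GBMModel:
    """Leaf-wise gradient boosting on the log loss.

    F_0 is the empirical log-odds prior; each round fits a leaf-wise
    regression tree to the negative gradient y - sigmoid(F) and adds
    ``learning_rate`` times its prediction.  Training stops early when the
    round-to-round log-loss improvement falls below ``tol``.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    prior = y.mean()
    init = math.log(prior / (1.0 - prior))
    F = np.full(len(y), init)
    trees = []
    feature_gain = np.zeros(X.shape[1])
    prev_loss = np.inf
    for _ in range(rounds):
        p = _sigmoid(F)
        residual = y - p
        tree = _LeafWiseTree(max_leaves, max_depth, min_leaf).fit(X, residual)
        trees.append(tree)
        feature_gain += tree.feature_gain
        F = F + learning_rate * tree.predict(X)
        p = np.clip(_sigmoid(F), 1e-12, 1 - 1e-12)
        loss = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        if prev_loss - loss < tol:
            break
        prev_loss = loss
    return GBMModel(init, trees, learning_rate, feature_gain)


# ---------------------------------------------------------------------------
# hybrid SVM-KNN
# ---------------------------------------------------------------------------

@dataclass
class HybridSVMKNN:
    svm: SVC
    knn: KNeighborsClassifier
    delta: float

    def decision_values(self, X) -> np.ndarray:
        return np.asarray(self.svm.decision_function(np.atleast_2d(X)))

    def predict_with_audit(self, X) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(labels, branch per sample, SVM decision values); branch is
        ``"svm"`` when |f(x)| > delta, else ``"knn"``."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        f = self.decision_values(X)
        use_svm = np.abs(f) > self.delta
        labels = np.empty(len(X), dtype=int)
        if use_svm.any():
            labels[use_svm] = self.svm.predict(X[use_svm])
        if (~use_svm).any():
            labels[~use_svm] = self.knn.predict(X[~use_svm])
        branch = np.where(use_svm, "svm", "knn")
        return labels, branch, f

    def predict(self, X) -> np.ndarray:
        return self.predict_with_audit(X)[0]


def train_hybrid(X, y, kernel: str = "rbf", C: float = 0.1, k: int = 5,
                 delta: float = 0.2, seed: int = 0) -> HybridSVMKNN:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if k >= len(X):
        raise ValueError(f"K={k} must be smaller than n={len(X)}")
    if delta < 0:
        raise ValueError("delta must be >= 0")
    svm = SVC(kernel=kernel, C=C, random_state=seed)
    svm.fit(X, y)
    knn = KNeighborsClassifier(n_neighbors=k, metric="euclidean")
    knn.fit(X, y)
    return HybridSVMKNN(svm, knn, float(delta))


def hybrid_predict(model: HybridSVMKNN, x) -> tuple[int, str, float]:
    """One-sample prediction with its audit trail (label, branch, f(x))."""
    labels, branch, f = model.predict_with_audit(np.atleast_2d(x))
    return int(labels[0]), str(branch[0]), float(f[0])


# ---------------------------------------------------------------------------
# fusion
# ---------------------------------------------------------------------------

def weighted_vote(predictions, weights, decision_threshold: float = 0.5) -> int:
    """Fuse per-classifier binary labels: abnormal (1) iff the weighted
    abnormal share strictly exceeds the threshold; an exact tie is normal."""
    predictions = np.asarray(predictions, dtype=int)
    weights = np.asarray(weights, dtype=float)
    if len(predictions) != len(weights) or len(predictions) < 1:
        raise ValueError("predictions and weights must have equal length >= 1")
    total = weights.sum()
    if total <= 0:
        raise ValueError("weights must not all be zero")
    share_abnormal = weights[predictions == 1].sum() / total
    return int(share_abnormal > decision_threshold)


# ---------------------------------------------------------------------------
# the fused model
# ---------------------------------------------------------------------------

@dataclass
class EnsembleModel:
    irf: IRFModel
    gbm: GBMModel
    hybrid: HybridSVMKNN
    fusion_weights: np.ndarray          # (irf, gbm, hybrid), sums to 1
    behavior_features: list             # MRFE-selected column names
    voice_features: list
    behavior_columns: list              # full input column order
    voice_columns: list
    voice_medians: pd.Series
    config: PipelineConfig

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "fusion_weights": self.fusion_weights.tolist(),
            "behavior_features": self.behavior_features,
            "voice_features": self.voice_features,
            "behavior_columns": self.behavior_columns,
            "voice_columns": self.voice_columns,
            "voice_medians": self.voice_medians.to_dict(),
            "config": self.config.to_dict(),
        }
        (directory / "model.json").write_text(json.dumps(meta, indent=2))
        with open(directory / "components.pkl", "wb") as fh:
            pickle.dump({"irf": self.irf, "gbm": self.gbm,
                         "hybrid": self.hybrid}, fh)

    @classmethod
    def load(cls, directory: str | Path) -> "EnsembleModel":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        with open(directory / "components.pkl", "rb") as fh:
            comps = pickle.load(fh)
        return cls(comps["irf"], comps["gbm"], comps["hybrid"],
                   np.asarray(meta["fusion_weights"]),
                   meta["behavior_features"], meta["voice_features"],
                   meta["behavior_columns"], meta["voice_columns"],
                   pd.Series(meta["voice_medians"]),
                   PipelineConfig.from_dict(meta["config"]))


def _spawn_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2 ** 31 - 1))
            for s in np.random.SeedSequence(seed).spawn(n)]


def fit_neurovibenet(behavior_X: pd.DataFrame, voice_X: pd.DataFrame, y,
                     config: PipelineConfig | None = None) -> EnsembleModel:
    """Fit the full fused model on aligned per-subject feature tables.

    Stages: fill unvoiced voice-quality gaps with training medians, balance
    the classes (SMOTE + undersampling on the joined feature space so the two
    branches stay row-aligned), run feature elimination per branch, train the
    three classifiers, and derive fusion weights from validation accuracy on
    an internal stratified split before refitting on all balanced rows.
    """
    config = config or PipelineConfig()
    y = np.asarray(y, dtype=int)
    if len(behavior_X) != len(voice_X) or len(behavior_X) != len(y):
        raise ValueError("behavior, voice and label lengths differ")
    if len(np.unique(y)) < 2:
        raise ValueError("fit: both classes must be present")
    seeds = _spawn_seeds(config.seed, 6)

    from .feature_extraction import impute_unvoiced
    voice_X, medians = impute_unvoiced(voice_X)
    if behavior_X.isna().to_numpy().any():
        behavior_X = behavior_X.fillna(behavior_X.median(axis=0))

    joined = pd.concat([behavior_X.reset_index(drop=True),
                        voice_X.reset_index(drop=True)], axis=1)
    X_bal, y_bal = balance_classes(joined.to_numpy(dtype=float), y,
                                   config.smote_k, seeds[0])
    bal = pd.DataFrame(X_bal, columns=joined.columns)
    beh_cols = list(behavior_X.columns)
    voi_cols = list(voice_X.columns)
    beh_bal, voi_bal = bal[beh_cols], bal[voi_cols]

    sel_beh, _ = mrfe_module.mrfe_select(
        beh_bal, y_bal, config.mrfe_target(len(beh_cols), "behavioral"),
        "behavioral", seeds[1], config)
    sel_voi, _ = mrfe_module.mrfe_select(
        voi_bal, y_bal, config.mrfe_target(len(voi_cols), "voice"),
        "voice", seeds[2], config)

    Xb = beh_bal[sel_beh].to_numpy(dtype=float)
    Xv = voi_bal[sel_voi].to_numpy(dtype=float)

    # fusion weights from an internal stratified validation split
    tr, va = stratified_split(y_bal, 1.0 - config.fusion_val_fraction, seeds[3])
    accs = []
    irf_v = train_irf(Xb[tr], y_bal[tr], config.irf_n_trees,
                      config.irf_max_depth, config.irf_min_split, seeds[4],
                      config.tree_weight)
    accs.append((irf_v.predict(Xb[va]) == y_bal[va]).mean())
    gbm_v = train_gbm(Xb[tr], y_bal[tr], config.gbm_learning_rate,
                      config.gbm_leaves, config.gbm_max_depth,
                      config.gbm_min_leaf, config.gbm_rounds, config.gbm_tol)
    accs.append((gbm_v.predict(Xb[va]) == y_bal[va]).mean())
    hyb_v = train_hybrid(Xv[tr], y_bal[tr], config.svm_kernel, config.svm_C,
                         min(config.knn_k, len(tr) - 1), config.hybrid_delta,
                         seeds[5])
    accs.append((hyb_v.predict(Xv[va]) == y_bal[va]).mean())
    accs = np.asarray(accs, dtype=float)
    fusion = accs / accs.sum() if accs.sum() > 0 else np.full(3, 1 / 3)

    # refit on all balanced rows
    irf = train_irf(Xb, y_bal, config.irf_n_trees, config.irf_max_depth,
                    config.irf_min_split, seeds[4], config.tree_weight)
    gbm = train_gbm(Xb, y_bal, config.gbm_learning_rate, config.gbm_leaves,
                    config.gbm_max_depth, config.gbm_min_leaf,
                    config.gbm_rounds, config.gbm_tol)
    hybrid = train_hybrid(Xv, y_bal, config.svm_kernel, config.svm_C,
                          min(config.knn_k, len(Xv) - 1),
                          config.hybrid_delta, seeds[5])
    return EnsembleModel(irf, gbm, hybrid, fusion, list(sel_beh),
                         list(sel_voi), beh_cols, voi_cols, medians, config)


def predict(model: EnsembleModel, behavior_X: pd.DataFrame,
            voice_X: pd.DataFrame) -> pd.DataFrame:
    """Fused predictions with a full audit trail per subject.

    Columns: the fused ``label``, the three per-classifier votes, the hybrid
    branch flag and the SVM decision value.
    """
    missing = ([c for c in model.behavior_features
                if c not in behavior_X.columns]
               + [c for c in model.voice_features if c not in voice_X.columns])
    if missing:
        raise ValueError(f"missing selected features: {missing}")
    voice_X = voice_X.fillna(model.voice_medians)
    Xb = behavior_X[model.behavior_features].to_numpy(dtype=float)
    Xv = voice_X[model.voice_features].to_numpy(dtype=float)
    irf_votes = model.irf.predict(Xb)
    gbm_votes = model.gbm.predict(Xb)
    hyb_votes, branch, decision = model.hybrid.predict_with_audit(Xv)
    fused = [weighted_vote([a, b, c], model.fusion_weights,
                           model.config.decision_threshold)
             for a, b, c in zip(irf_votes, gbm_votes, hyb_votes)]
    return pd.DataFrame({
        "label": fused, "irf_vote": irf_votes, "gbm_vote": gbm_votes,
        "hybrid_vote": hyb_votes, "hybrid_branch": branch,
        "svm_decision": decision})
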