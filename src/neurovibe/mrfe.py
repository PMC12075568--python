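"""Modified recursive feature elimination.

Standard RFE ranks features once and strips from the bottom; the modified
variant recomputes every feature weight after each single removal, so the
ranking tracks the shifting dependencies of the shrinking feature set.  Each
round removes exactly the rank-1 (smallest-weight) feature, ties broken by
feature name, until the target count is reached.

Weights come from the branch's own classifiers: the behavioral branch
averages the normalized impurity importances of the weighted random forest
with the normalized split-gain importances of the gradient-boosting machine;
the voice branch uses permutation importance of the hybrid SVM-KNN measured
on a held-out fold (5 shuffles per feature, averaged, clipped at 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .evaluation import stratified_split


@dataclass
class EliminationRound:
    round: int
    removed: str
    weight: float
    rank: int
    survivors: list


def _normalize(v: np.ndarray) -> np.ndarray:
    v = np.clip(np.asarray(v, dtype=float), 0.0, None)
    s = v.sum()
    return v / s if s > 0 else np.full(len(v), 1.0 / len(v))


def compute_weights(X: pd.DataFrame, y, branch: str, seed: int = 0,
                    config: PipelineConfig | None = None) -> pd.Series:
    """Non-negative feature weights summing to 1 for one branch."""
    from . import ensemble  # deferred: ensemble imports this module

    config = config or PipelineConfig()
    if X.shape[1] < 1:
        raise ValueError("no features")
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    Xa = X.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)

    if branch == "behavioral":
        irf = ensemble.train_irf(
            Xa, y, n_trees=config.wsel_irf_trees,
            max_depth=config.irf_max_depth, min_split=config.irf_min_split,
            seed=seed, tree_weight=config.tree_weight)
        gbm = ensemble.train_gbm(
            Xa, y, config.gbm_learning_rate, config.gbm_leaves,
            config.gbm_max_depth, min(config.gbm_min_leaf, max(2, len(y) // 8)),
            config.wsel_gbm_rounds, config.gbm_tol)
        w = 0.5 * _normalize(irf.feature_importances()) \
            + 0.5 * _normalize(gbm.feature_gain)
    elif branch == "voice":
        tr, ho = stratified_split(y, 0.75, seed)
        hybrid = ensemble.train_hybrid(
            Xa[tr], y[tr], config.svm_kernel, config.svm_C,
            min(config.knn_k, len(tr) - 1), config.hybrid_delta, seed)
        base = (hybrid.predict(Xa[ho]) == y[ho]).mean()
        drops = np.zeros(X.shape[1])
        for j in range(X.shape[1]):
            for _ in range(config.wsel_perm_shuffles):
                perm = Xa[ho].copy()
                perm[:, j] = rng.permutation(perm[:, j])
                drops[j] += base - (hybrid.predict(perm) == y[ho]).mean()
        w = _normalize(drops / config.wsel_perm_shuffles)
    else:
        raise ValueError(f"unknown branch {branch!r}")
    return pd.Series(_normalize(w), index=X.columns)


def rank_weights(weights: pd.Series) -> pd.Series:
    """Rank 1 = smallest weight; ties broken by feature-name order."""
    order = sorted(weights.index, key=lambda name: (weights[name], name))
    return pd.Series({name: i + 1 for i, name in enumerate(order)},
                     dtype=int).reindex(weights.index)


def mrfe_select(X: pd.DataFrame, y, target_count: int, branch: str,
                seed: int = 0, config: PipelineConfig | None = None,
                weight_fn=None,
                ) -> tuple[list, list[EliminationRound]]:
    """Iteratively remove the rank-1 feature, recomputing weights each round.

    ``weight_fn(X, y, round_seed) -> pd.Series`` may replace the built-in
    weight computation (used by tests and by the ``classic_rfe`` mode, which
    freezes the initial weights instead of recomputing).
    Returns the surviving feature names (input order) and the full trace.
    """
    config = config or PipelineConfig()
    m = X.shape[1]
    if not 1 <= target_count <= m:
        raise ValueError(f"target_count {target_count} out of range 1..{m}")
    round_seeds = np.random.SeedSequence(seed).spawn(max(m - target_count, 1))
    seeds = [int(s.generate_state(1)[0] % (2 ** 31 - 1)) for s in round_seeds]

    def default_weight_fn(Xs, ys, round_seed):
        return compute_weights(Xs, ys, branch, round_seed, config)

    fn = weight_fn or default_weight_fn
    survivors = list(X.columns)
    trace: list[EliminationRound] = []
    frozen = None
    for r in range(m - target_count):
        if config.classic_rfe:
            if frozen is None:
                frozen = fn(X[survivors], y, seeds[0])
            weights = frozen[survivors]
            weights = weights / weights.sum() if weights.sum() > 0 else weights
        else:
            weights = fn(X[survivors], y, seeds[r])
        ranks = rank_weights(weights)
        victim = ranks.idxmin()
        trace.append(EliminationRound(
            round=r + 1, removed=victim, weight=float(weights[victim]),
            rank=int(ranks[victim]),
            survivors=[c for c in survivors if c != victim]))
        survivors.remove(victim)
    return survivors, trace


def trace_to_frame(trace: list[EliminationRound]) -> pd.DataFrame:
    """Elimination trace as a table (one row per removal round)."""
    return pd.DataFrame([{
        "round": t.round, "removed": t.removed, "weight": t.weight,
        "rank": t.rank, "n_survivors": len(t.survivors)} for t in trace])
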