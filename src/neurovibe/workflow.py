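"""End-to-end orchestration: raw paired data in, fitted model and metrics out.

The stages mirror the screening pipeline: behavioral cleaning (impute, scale,
outlier removal — all fit on training rows only), per-subject feature
extraction for both modalities (class-medoid templates computed on training
data only), ensemble fitting and held-out evaluation.

Modality preparation (imputation, scaling, voice DSP) is label-free given a
split, so :func:`prepare_modalities` can be computed once and reused across
label permutations — e.g. for null (shuffled-label) experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import behavioral_preprocess as bp
from . import ensemble as ens
from . import feature_extraction as fx
from .config import PipelineConfig
from .evaluation import confusion, metrics, stratified_split
from .pipeline_io import BehavioralTable
from .synthetic_data import PairedDataset

#: class-medoid search is restricted to this many training series per class
MEDOID_SEARCH_CAP = 30


@dataclass
class PreparedModalities:
    """Label-free, split-dependent intermediate state."""

    beh_train: pd.DataFrame     # imputed + scaled training series (rows kept)
    beh_test: pd.DataFrame
    voice_train: pd.DataFrame   # per-recording voice vectors (NaN if unvoiced)
    voice_test: pd.DataFrame
    train_idx: np.ndarray       # surviving training subject indices
    test_idx: np.ndarray
    skip_penalty: float


def prepare_modalities(dataset: PairedDataset, config: PipelineConfig,
                       train_idx: np.ndarray, test_idx: np.ndarray,
                       ) -> PreparedModalities:
    table = dataset.behavior
    train_tab = BehavioralTable(table.data.iloc[train_idx].reset_index(drop=True),
                                table.labels.iloc[train_idx].reset_index(drop=True))
    test_tab = BehavioralTable(table.data.iloc[test_idx].reset_index(drop=True),
                               table.labels.iloc[test_idx].reset_index(drop=True))

    train_imp = bp.knn_impute(train_tab, config.impute_k)
    test_imp = bp.knn_impute(test_tab, config.impute_k, donors=train_tab)
    scaling = bp.fit_min_max(train_imp)
    train_scaled = bp.apply_min_max(train_imp, scaling)
    test_scaled = bp.apply_min_max(test_imp, scaling)

    forest = bp.iforest_fit(train_scaled, config.iforest_n_trees,
                            config.iforest_subsample, config.seed)
    kept = bp.remove_outliers(train_scaled, forest, config.iforest_threshold)
    kept_pos = train_scaled.data.index.get_indexer(kept.data.index)
    surviving = train_idx[kept_pos]

    voice_rows = {}
    for idx in np.concatenate([surviving, test_idx]):
        voice_rows[idx] = fx.extract_voice_vector(dataset.recordings[idx],
                                                  config)
    voice_train = pd.DataFrame([voice_rows[i] for i in surviving])
    voice_test = pd.DataFrame([voice_rows[i] for i in test_idx])

    p = fx.default_skip_penalty(kept.data.to_numpy(), [],
                                config.idtw_p_scale) \
        if config.idtw_p_scale > 0 else 0.0
    return PreparedModalities(
        kept.data.reset_index(drop=True), test_scaled.data,
        voice_train.reset_index(drop=True), voice_test.reset_index(drop=True),
        surviving, test_idx, p)


def behavior_feature_tables(prep: PreparedModalities, y_train: np.ndarray,
                            config: PipelineConfig, seed: int = 0,
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Series moments plus IDTW distances to per-class medoid templates.

    Medoids are searched over (a capped subsample of) training series only.
    """
    rng = np.random.default_rng(seed)
    templates = {}
    train_series = prep.beh_train.to_numpy(dtype=float)
    for cls in (0, 1):
        members = np.flatnonzero(np.asarray(y_train) == cls)
        if members.size == 0:
            raise ValueError(f"no training subjects in class {cls}")
        if members.size > MEDOID_SEARCH_CAP:
            members = np.sort(rng.choice(members, MEDOID_SEARCH_CAP,
                                         replace=False))
        pool = [train_series[i] for i in members]
        templates[f"class{cls}"] = pool[fx.idtw_medoid(
            pool, config.idtw_alpha, prep.skip_penalty)]

    def build(frame: pd.DataFrame) -> pd.DataFrame:
        rows = [fx.extract_behavior_vector(row, templates, config.idtw_alpha,
                                           prep.skip_penalty)
                for row in frame.to_numpy(dtype=float)]
        return pd.DataFrame(rows).reset_index(drop=True)

    return build(prep.beh_train), build(prep.beh_test)


@dataclass
class ExperimentResult:
    model: ens.EnsembleModel
    report: object                  # MetricsReport
    predictions: pd.DataFrame
    y_test: np.ndarray


def fit_and_evaluate(prep: PreparedModalities, y: np.ndarray,
                     config: PipelineConfig) -> ExperimentResult:
    """Fit the fused model on the prepared training rows, evaluate held-out."""
    y = np.asarray(y, dtype=int)
    y_train = y[prep.train_idx]
    y_test = y[prep.test_idx]
    beh_train, beh_test = behavior_feature_tables(prep, y_train, config,
                                                  config.seed)
    model = ens.fit_neurovibenet(beh_train, prep.voice_train, y_train, config)
    preds = ens.predict(model, beh_test, prep.voice_test)
    report = metrics(confusion(y_test, preds["label"].to_numpy()))
    return ExperimentResult(model, report, preds, y_test)


def run_experiment(dataset: PairedDataset, config: PipelineConfig | None = None,
                   train_fraction: float = 0.8) -> ExperimentResult:
    """The full pipeline on one paired dataset with a stratified split."""
    config = config or PipelineConfig()
    y = dataset.behavior.labels.to_numpy()
    train_idx, test_idx = stratified_split(y, train_fraction, config.seed)
    prep = prepare_modalities(dataset, config, train_idx, test_idx)
    return fit_and_evaluate(prep, y, config)
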