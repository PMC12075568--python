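"""Pipeline configuration.

All tunables of every stage live in one flat dataclass.  On disk the config is
YAML with a flat ``stage.parameter`` namespace (dots map to underscores in the
attribute names), e.g.::

    impute.k: 5
    iforest.n_trees: 100
    gbm.learning_rate: 0.1

Every run logs the fully resolved config so results can be reproduced.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # global
    seed: int = 0

    # behavioral preprocessing
    impute_k: int = 5
    iforest_n_trees: int = 100
    iforest_subsample: int = 256
    iforest_threshold: float = 0.6

    # voice DSP
    rate: int = 16000
    frame: int = 400          # 25 ms at 16 kHz
    hop: int = 160            # 10 ms
    window: str = "hann"
    segment_rel_threshold: float = 0.1
    segment_min_frames: int = 3
    gate_noise_percentile: float = 20.0
    mel_filters: int = 26
    mel_f_low: float = 0.0
    mel_f_high: float = 8000.0
    mfcc_n_coeffs: int = 13
    log_floor: float = 1e-10

    # voice quality
    f0_min: float = 50.0
    f0_max: float = 500.0
    voicing_threshold: float = 0.3

    # feature extraction
    idtw_alpha: float = 1.0
    idtw_p_scale: float = 0.1      # p = scale * mean absolute series level
    idtw_weight: str = "uniform"   # or "gaussian"
    idtw_gaussian_band: float = 2.0
    literal_moments: bool = False

    # MRFE
    mrfe_target_behavior: int | None = None   # default: half the features, min 4
    mrfe_target_voice: int | None = None
    classic_rfe: bool = False
    wsel_irf_trees: int = 50
    wsel_gbm_rounds: int = 50
    wsel_perm_shuffles: int = 5

    # ensemble
    smote_k: int = 5
    irf_n_trees: int = 100
    irf_max_depth: int = 20
    irf_min_split: int = 4
    tree_weight: str = "oob"       # or "importance"
    gbm_learning_rate: float = 0.1
    gbm_leaves: int = 20
    gbm_max_depth: int = 5
    gbm_min_leaf: int = 10
    gbm_rounds: int = 100
    gbm_tol: float = 1e-6
    svm_kernel: str = "rbf"
    svm_C: float = 0.1
    knn_k: int = 5
    hybrid_delta: float = 0.2
    fusion_val_fraction: float = 0.2
    decision_threshold: float = 0.5

    def mrfe_target(self, n_features: int, branch: str) -> int:
        explicit = (self.mrfe_target_behavior if branch == "behavioral"
                    else self.mrfe_target_voice)
        if explicit is not None:
            return explicit
        return min(n_features, max(4, n_features // 2))

    # -- flat YAML round trip ------------------------------------------------

    _PREFIXES = (
        "impute_", "iforest_", "segment_", "gate_", "mel_", "mfcc_", "log_",
        "f0_", "voicing_", "idtw_", "mrfe_", "classic_", "wsel_",
        "smote_", "irf_", "tree_", "gbm_", "svm_", "knn_", "hybrid_",
        "fusion_", "decision_",
    )

    @classmethod
    def _flat_key(cls, attr: str) -> str:
        for pref in cls._PREFIXES:
            if attr.startswith(pref):
                return pref[:-1] + "." + attr[len(pref):]
        return attr

    def to_dict(self) -> dict:
        return {self._flat_key(f.name): getattr(self, f.name)
                for f in dataclasses.fields(self)}

    @classmethod
    def from_dict(cls, flat: dict) -> "PipelineConfig":
        valid = {f.name for f in dataclasses.fields(cls)}
        kwargs = {}
        for key, value in flat.items():
            attr = key.replace(".", "_")
            if attr not in valid:
                raise ValueError(f"unknown config key: {key!r}")
            kwargs[attr] = value
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def validate(self) -> None:
        if self.impute_k < 1:
            raise ValueError("impute.k must be >= 1")
        if not 0 < self.iforest_threshold < 1:
            raise ValueError("iforest.threshold must be in (0, 1)")
        if not 0 < self.segment_rel_threshold < 1:
            raise ValueError("segment.rel_threshold must be in (0, 1)")
        if not 0 < self.gate_noise_percentile < 100:
            raise ValueError("gate.noise_percentile must be in (0, 100)")
        if self.mel_filters < 2:
            raise ValueError("mel.filters must be >= 2")
        if not self.mel_f_low < self.mel_f_high <= self.rate / 2:
            raise ValueError("need mel.f_low < mel.f_high <= rate/2")
        if self.mfcc_n_coeffs > self.mel_filters:
            raise ValueError("mfcc.n_coeffs must be <= mel.filters")
        if self.idtw_alpha < 0 or self.idtw_p_scale < 0:
            raise ValueError("IDTW penalties must be non-negative")
        if not 0 < self.fusion_val_fraction < 1:
            raise ValueError("fusion.val_fraction must be in (0, 1)")
        if self.hybrid_delta < 0 and not math.isinf(self.hybrid_delta):
            raise ValueError("hybrid.delta must be >= 0")
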