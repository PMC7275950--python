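"""Random-forest species classifier over embedded sequence vectors.

The forest is a standard Gini-impurity, bootstrap-aggregated ensemble with
unlimited tree depth. ``max_features`` is an absolute count of candidate
features per split (the tuned value of 2 out of 100 embedding dimensions
gives highly decorrelated trees), not a fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .embedding import LabeledDataset
from .errors import ModelFormatError

_MODEL_FORMAT = "its2vec-rf-v1"


@dataclass(frozen=True)
class RFConfig:
    """Forest hyperparameters. ``max_features`` is an absolute feature count."""

    n_estimators: int = 100
    max_features: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        if self.max_features < 1:
            raise ValueError("max_features must be >= 1")


@dataclass
class RFModel:
    """A trained forest plus its config and label <-> SH mapping."""

    forest: RandomForestClassifier
    config: RFConfig
    label_map: dict[int, str]
    lineage_map: dict[int, str] | None = None

    @property
    def n_features(self) -> int:
        return int(self.forest.n_features_in_)


def train_rf(data: LabeledDataset, config: RFConfig | None = None) -> RFModel:
    """Fit a random forest on an embedded, labeled dataset.

    Requires at least two classes and ``max_features`` no larger than the
    embedding dimension. Seeded runs are reproducible.
    """
    config = config or RFConfig()
    n_classes = np.unique(data.y).size
    if n_classes < 2:
        raise ValueError(f"need >= 2 classes to train, got {n_classes}")
    if config.max_features > data.X.shape[1]:
        raise ValueError(
            f"max_features={config.max_features} exceeds feature "
            f"dimension {data.X.shape[1]}")
    forest = RandomForestClassifier(
        n_estimators=config.n_estimators,
        max_features=config.max_features,
        criterion="gini",
        max_depth=None,
        bootstrap=True,
        random_state=config.seed,
        n_jobs=1,
    )
    forest.fit(data.X, data.y)
    return RFModel(forest=forest, config=config,
                   label_map=dict(data.label_map),
                   lineage_map=dict(data.lineage_map) if data.lineage_map else None)


def predict(model: RFModel, X: np.ndarray) -> np.ndarray:
    """Predict one integer class label per row (majority vote over trees)."""
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"query matrix has {X.shape[1] if X.ndim == 2 else 'non-2D'} "
            f"columns, model expects {model.n_features}")
    return model.forest.predict(X).astype(np.int64)


def save_model(model: RFModel, path: str | Path) -> None:
    joblib.dump(
        {
            "format": _MODEL_FORMAT,
            "config": model.config,
            "label_map": model.label_map,
            "lineage_map": model.lineage_map,
            "forest": model.forest,
        },
        path,
    )


def load_model(path: str | Path) -> RFModel:
    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise ModelFormatError(f"{path}: cannot read model file ({exc})") from exc
    if not isinstance(payload, dict) or payload.get("format") != _MODEL_FORMAT:
        raise ModelFormatError(
            f"{path}: not a {_MODEL_FORMAT} model file")
    return RFModel(forest=payload["forest"], config=payload["config"],
                   label_map=payload["label_map"],
                   lineage_map=payload.get("lineage_map"))
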