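"""Evaluation protocol: multi-class metrics, per-subset cross-validation, and
hyperparameter grid searches.

Metrics
-------
Accuracy, precision, recall, and the Matthews correlation coefficient (MCC).
The binary definitions are

    Accuracy  = (TP + TN) / (TP + TN + FP + FN)
    Recall    = TP / (TP + FN)
    Precision = TP / (TP + FP)
    MCC       = (TP*TN - FP*FN) /
                sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

For the multi-class case, precision and recall are support-weighted
one-vs-rest aggregates of the binary forms (under which recall coincides
exactly with accuracy for single-label classification), and MCC is the
standard multi-class generalization computed from the full confusion matrix,
which reduces to the binary formula when there are two classes. A degenerate
MCC denominator (a zero factor) yields MCC = 0.

Cross-validation
----------------
ITSset_m is evaluated with m-fold CV in which every fold holds exactly one
sequence per SH (ITSset_10 is first subsampled to 5 per SH and gets 5-fold
CV). Per-fold metrics are computed on the held-out fold only; the headline
number is the mean across folds, reported with the sample (n-1) standard
deviation. The k-mer embedding is shared across folds (trained unsupervised
on the full corpus) unless the caller opts into per-fold retraining.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    matthews_corrcoef,
    multilabel_confusion_matrix,
    precision_score,
    recall_score,
)

from ._seeds import derive_seed
from .classifier import RFConfig, predict, train_rf
from .dataset_builder import (
    EVAL_SUBSAMPLE_TARGET,
    MAX_PER_SH,
    ITSSubset,
    make_cv_folds,
    partition_subsets,
    subsample_for_eval,
)
from .embedding import (
    EmbeddingModel,
    EmbeddingParams,
    LabeledDataset,
    build_corpus,
    train_embedding,
    vectorize_dataset,
)
from .errors import ConsistencyError
from .seqio import SequenceRecord

logger = logging.getLogger(__name__)

#: the full RF tuning grid: max_features 2..10, n_estimators 50..500
DEFAULT_MAX_FEATURES_GRID: tuple[int, ...] = tuple(range(2, 11))
DEFAULT_N_ESTIMATORS_GRID: tuple[int, ...] = tuple(range(50, 501, 50))


@dataclass(frozen=True)
class MetricsReport:
    """Metrics of one evaluation. Accuracy/precision/recall are percentages."""

    accuracy: float
    precision: float
    recall: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "mcc": self.mcc}


def confusion_counts(
    y_true: Sequence[int], y_pred: Sequence[int], labels: Sequence[int] | None = None
) -> pd.DataFrame:
    """Per-class one-vs-rest TP/FP/FN/TN counts (rows indexed by class label)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if labels is None:
        labels = np.unique(np.concatenate([y_true, y_pred]))
    mcm = multilabel_confusion_matrix(y_true, y_pred, labels=labels)
    return pd.DataFrame(
        {
            "TP": mcm[:, 1, 1], "FP": mcm[:, 0, 1],
            "FN": mcm[:, 1, 0], "TN": mcm[:, 0, 0],
            "support": [(y_true == c).sum() for c in labels],
        },
        index=pd.Index(labels, name="class"),
    )


def compute_metrics(
    y_true: Sequence[int], y_pred: Sequence[int], labels: Sequence[int] | None = None
) -> MetricsReport:
    """Accuracy, support-weighted precision/recall, and multi-class MCC.

    Classes absent from ``y_pred`` contribute precision 0 at their support
    weight. Raises on empty or length-mismatched inputs.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"label vectors differ in length: {y_true.shape} vs {y_pred.shape}")
    if y_true.size == 0:
        raise ValueError("cannot compute metrics on empty label vectors")
    if labels is None:
        labels = np.unique(np.concatenate([y_true, y_pred]))
    accuracy = accuracy_score(y_true, y_pred)
    precision = precision_score(y_true, y_pred, labels=labels,
                                average="weighted", zero_division=0)
    recall = recall_score(y_true, y_pred, labels=labels,
                          average="weighted", zero_division=0)
    mcc = matthews_corrcoef(y_true, y_pred)
    return MetricsReport(
        accuracy=100.0 * accuracy,
        precision=100.0 * precision,
        recall=100.0 * recall,
        mcc=float(mcc),
    )


@dataclass
class CVReport:
    """Per-fold metrics plus their mean and sample (n-1) standard deviation."""

    folds: list[MetricsReport]

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    def _stat(self, fn) -> MetricsReport:
        arrays = {
            name: np.array([getattr(f, name) for f in self.folds])
            for name in ("accuracy", "precision", "recall", "mcc")
        }
        return MetricsReport(**{name: float(fn(v)) for name, v in arrays.items()})

    @property
    def mean(self) -> MetricsReport:
        return self._stat(np.mean)

    @property
    def std(self) -> MetricsReport:
        if len(self.folds) < 2:
            return MetricsReport(0.0, 0.0, 0.0, 0.0)
        return self._stat(lambda v: np.std(v, ddof=1))

    def to_frame(self) -> pd.DataFrame:
        rows = [{"fold": str(i), **f.as_dict()} for i, f in enumerate(self.folds)]
        rows.append({"fold": "mean", **self.mean.as_dict()})
        rows.append({"fold": "std", **self.std.as_dict()})
        return pd.DataFrame(rows)


def run_cv(
    subset: ITSSubset,
    model: EmbeddingModel,
    rf_config: RFConfig | None = None,
    seed: int = 0,
    subsample_to: int | None = None,
    apply_large_subset_rule: bool = True,
) -> CVReport:
    """m-fold cross-validation of the RF classifier on one ITSset.

    The fold plan puts exactly one record of every SH in each fold, so every
    class occurs in every training split. ``subsample_to`` randomly reduces
    the subset to that many sequences per SH first; when it is None and
    ``apply_large_subset_rule`` holds, the fully-capped subset (ITSset_10) is
    reduced to 5 per SH and evaluated with 5-fold CV, while ITSset_2..9 keep
    their natural m-fold protocol.
    """
    rf_config = rf_config or RFConfig()
    if subsample_to is None and apply_large_subset_rule and subset.m >= MAX_PER_SH:
        subsample_to = EVAL_SUBSAMPLE_TARGET
    if subsample_to is not None and subsample_to < subset.m:
        subset = subsample_for_eval(subset, subsample_to,
                                    seed=derive_seed(seed, "cv-subsample"))
    n_folds = subset.m
    plan = make_cv_folds(subset, n_folds, seed=derive_seed(seed, "cv-folds"))
    data = vectorize_dataset(subset, model)
    fold_of = np.array([plan.assignment[i] for i in range(len(subset.records))])
    folds: list[MetricsReport] = []
    labels = np.arange(subset.n_classes)
    for fold in range(n_folds):
        test_mask = fold_of == fold
        if test_mask.sum() != subset.n_classes:
            raise ConsistencyError(
                f"fold {fold} holds {int(test_mask.sum())} records, "
                f"expected one per SH ({subset.n_classes})")
        train_data = LabeledDataset(
            X=data.X[~test_mask], y=data.y[~test_mask],
            label_map=data.label_map, lineage_map=data.lineage_map,
        )
        rf = train_rf(
            train_data,
            RFConfig(n_estimators=rf_config.n_estimators,
                     max_features=rf_config.max_features,
                     seed=derive_seed(seed, "cv-rf", fold)),
        )
        y_pred = predict(rf, data.X[test_mask])
        folds.append(compute_metrics(data.y[test_mask], y_pred, labels=labels))
    return CVReport(folds=folds)


def evaluate_records(
    records: Sequence[SequenceRecord],
    emb_params: EmbeddingParams | None = None,
    rf_config: RFConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Embed a record set once, then cross-validate every ITSset_m in it.

    Returns a long-format table: one row per (m, fold) plus mean/std rows.
    """
    emb_params = emb_params or EmbeddingParams()
    subsets = partition_subsets(records)
    corpus = build_corpus(records, emb_params.k)
    model = train_embedding(corpus, emb_params)
    frames = []
    for m, subset in sorted(subsets.items()):
        report = run_cv(subset, model, rf_config, seed=derive_seed(seed, "cv", m))
        frame = report.to_frame()
        frame.insert(0, "m", m)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def enumerate_rf_grid(
    max_features_values: Sequence[int] = DEFAULT_MAX_FEATURES_GRID,
    n_estimators_values: Sequence[int] = DEFAULT_N_ESTIMATORS_GRID,
) -> list[tuple[int, int]]:
    """Row-major enumeration of the RF tuning grid (the default grid
    spans 9 x 10 = 90 configurations)."""
    return [(mf, ne) for mf in max_features_values for ne in n_estimators_values]


def _fold_assignment_from_labels(y: np.ndarray, seed: int) -> tuple[np.ndarray, int]:
    """Per-class fold assignment for an m-regular labeled dataset.

    Every class must have the same count m; returns (fold index per row, m).
    """
    labels, counts = np.unique(y, return_counts=True)
    if not (counts == counts[0]).all():
        raise ConsistencyError("dataset is not m-regular; per-class counts differ")
    n_folds = int(counts[0])
    fold_of = np.empty(y.shape[0], dtype=np.int64)
    for label in labels:
        rows = np.flatnonzero(y == label)
        rng = np.random.default_rng(derive_seed(seed, "label-folds", int(label)))
        fold_of[rows] = rng.permutation(n_folds)
    return fold_of, n_folds


def grid_search_rf(
    dataset: LabeledDataset,
    max_features_values: Sequence[int] = DEFAULT_MAX_FEATURES_GRID,
    n_estimators_values: Sequence[int] = DEFAULT_N_ESTIMATORS_GRID,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-validate the forest over a (max_features, n_estimators) grid.

    The dataset must be m-regular; each cell is evaluated with the same
    m-fold one-per-class fold plan. Rows are emitted in row-major grid order,
    per fold plus mean/std aggregate rows — ready for heat-map pivoting.
    """
    fold_of, n_folds = _fold_assignment_from_labels(dataset.y, seed)
    labels = np.unique(dataset.y)
    rows = []
    for mf, ne in enumerate_rf_grid(max_features_values, n_estimators_values):
        folds = []
        for fold in range(n_folds):
            test_mask = fold_of == fold
            train_data = LabeledDataset(
                X=dataset.X[~test_mask], y=dataset.y[~test_mask],
                label_map=dataset.label_map, lineage_map=dataset.lineage_map,
            )
            rf = train_rf(train_data, RFConfig(
                n_estimators=ne, max_features=mf,
                seed=derive_seed(seed, "grid-rf", mf, ne, fold)))
            y_pred = predict(rf, dataset.X[test_mask])
            folds.append(compute_metrics(dataset.y[test_mask], y_pred,
                                         labels=labels))
        report = CVReport(folds=folds)
        frame = report.to_frame()
        frame.insert(0, "n_estimators", ne)
        frame.insert(0, "max_features", mf)
        rows.append(frame)
    return pd.concat(rows, ignore_index=True)


def grid_search_embedding(
    records: Sequence[SequenceRecord],
    k_values: Sequence[int],
    w_values: Sequence[int],
    rf_config: RFConfig | None = None,
    seed: int = 0,
    base_params: EmbeddingParams | None = None,
) -> pd.DataFrame:
    """Full embed + CV evaluation for every (k, window) grid cell.

    For each cell a fresh embedding is trained on the whole record corpus and
    every ITSset_m in the records is cross-validated. Returns a long-format
    table with one row per (k, window, m, fold) plus aggregate rows.
    """
    base = base_params or EmbeddingParams()
    frames = []
    for k in k_values:
        for w in w_values:
            params = EmbeddingParams(
                k=k, window=w, dim=base.dim, epochs=base.epochs,
                min_count=base.min_count, negative_samples=base.negative_samples,
                alpha=base.alpha, min_alpha=base.min_alpha,
                subsample=base.subsample,
                seed=derive_seed(seed, "grid-emb", k, w),
                deterministic=base.deterministic,
            )
            frame = evaluate_records(records, params, rf_config,
                                     seed=derive_seed(seed, "grid-cv", k, w))
            frame.insert(0, "window", w)
            frame.insert(0, "k", k)
            frames.append(frame)
    return pd.concat(frames, ignore_index=True)
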