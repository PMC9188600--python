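"""Relief-F feature ranking and leave-one-out Gaussian-SVM classification.

Feature tables are pandas DataFrames with the metadata columns
``subject_id``, ``group`` ("pd" = positive class, "control" = negative),
``phoneme`` and ``repetition``; every other column is a feature. Each
recording (repetition) is one classification sample.

Relief-F weights a feature by how much it separates each sample from its
k nearest same-class neighbors (hits) versus its k nearest other-class
neighbors (misses), on min-max scaled features. The classifier is a
support vector machine with a Gaussian (RBF) kernel, evaluated by
leave-one-out cross-validation with per-fold z-scoring, and summarized by
accuracy, sensitivity and specificity from the pooled confusion counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .errors import InsufficientClassError, InvalidArgumentError

__all__ = [
    "META_COLUMNS",
    "ClassificationReport",
    "feature_columns",
    "relief_f",
    "loocv_svm",
    "confusion_metrics",
    "combine_phonemes",
]

log = logging.getLogger(__name__)

META_COLUMNS = ("subject_id", "group", "phoneme", "repetition")
POSITIVE_LABEL = "pd"


@dataclass
class ClassificationReport:
    """Pooled leave-one-out confusion counts and derived metrics (in %)."""

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    selected_features: list[str]
    predictions: pd.DataFrame

    def to_dict(self) -> dict:
        return dict(
            tp=self.tp, tn=self.tn, fp=self.fp, fn=self.fn,
            accuracy=self.accuracy, sensitivity=self.sensitivity,
            specificity=self.specificity,
            selected_features=list(self.selected_features),
        )


def feature_columns(table: pd.DataFrame) -> list[str]:
    """All non-metadata columns, in table order."""
    return [c for c in table.columns if c not in META_COLUMNS]


def _validate(table: pd.DataFrame, features: list[str]) -> tuple[np.ndarray, np.ndarray]:
    if "group" not in table.columns:
        raise InvalidArgumentError("feature table lacks a 'group' column")
    if len(set(features)) != len(features):
        raise InvalidArgumentError("feature names must be unique")
    X = table[features].to_numpy(dtype=float)
    if np.any(~np.isfinite(X)):
        raise InvalidArgumentError("feature table contains missing/non-finite values")
    y = (table["group"].to_numpy() == POSITIVE_LABEL).astype(int)
    return X, y


def relief_f(table: pd.DataFrame, k: int = 10, features=None) -> list[tuple[str, float]]:
    """Relief-F feature weights, sorted by descending weight.

    Features are min-max scaled to [0, 1]; for each of the m samples, its k
    nearest hits and k nearest misses (Euclidean distance) each contribute
    -diff/(m k) and +diff/(m k) to a feature's weight, where diff is the
    scaled absolute feature difference. Ties in weight break by feature
    name, so the ranking is deterministic.
    """
    if features is None:
        features = feature_columns(table)
    X, y = _validate(table, features)
    m = len(X)
    for cls in (0, 1):
        if np.sum(y == cls) < k + 1:
            raise InsufficientClassError(
                f"class {cls} has {np.sum(y == cls)} samples; need >= {k + 1}"
            )
    span = X.max(axis=0) - X.min(axis=0)
    span[span == 0] = 1.0  # constant features scale to 0 diff everywhere
    Z = (X - X.min(axis=0)) / span

    weights = np.zeros(len(features))
    d2 = np.sum((Z[:, None, :] - Z[None, :, :]) ** 2, axis=2)
    np.fill_diagonal(d2, np.inf)
    for i in range(m):
        same = np.where(y == y[i])[0]
        same = same[same != i]
        diff_cls = np.where(y != y[i])[0]
        hits = same[np.argsort(d2[i, same], kind="stable")[:k]]
        misses = diff_cls[np.argsort(d2[i, diff_cls], kind="stable")[:k]]
        weights -= np.abs(Z[hits] - Z[i]).mean(axis=0) / m
        weights += np.abs(Z[misses] - Z[i]).mean(axis=0) / m

    order = sorted(range(len(features)), key=lambda j: (-weights[j], features[j]))
    return [(features[j], float(weights[j])) for j in order]


def loocv_svm(
    table: pd.DataFrame,
    gamma="scale",
    c: float = 1.0,
    features=None,
) -> ClassificationReport:
    """Leave-one-out Gaussian-kernel SVM evaluation.

    Each sample is predicted by an SVM trained on all other samples;
    features are z-scored with the training fold's mean/SD only (no
    leakage). Deterministic given the table's row order.
    """
    if features is None:
        features = feature_columns(table)
    X, y = _validate(table, features)
    if len(np.unique(y)) < 2:
        raise InvalidArgumentError("need both classes present")
    for cls in (0, 1):
        if np.sum(y == cls) < 2:
            raise InvalidArgumentError("need >= 2 samples per class")

    n = len(X)
    pred = np.empty(n, dtype=int)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        mu = X[mask].mean(axis=0)
        sd = X[mask].std(axis=0)
        sd[sd == 0] = 1.0
        clf = SVC(kernel="rbf", gamma=gamma, C=c)
        clf.fit((X[mask] - mu) / sd, y[mask])
        pred[i] = clf.predict(((X[i] - mu) / sd)[None, :])[0]

    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    accuracy, sensitivity, specificity = confusion_metrics(tp, tn, fp, fn)
    predictions = table[[c for c in META_COLUMNS if c in table.columns]].copy()
    predictions["true"] = y
    predictions["predicted"] = pred
    return ClassificationReport(tp, tn, fp, fn, accuracy, sensitivity, specificity,
                                list(features), predictions)


def confusion_metrics(tp: int, tn: int, fp: int, fn: int) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) in percent from confusion counts."""
    if min(tp, tn, fp, fn) < 0 or tp + tn + fp + fn == 0:
        raise InvalidArgumentError("counts must be >= 0 with a positive total")
    accuracy = 100.0 * (tp + tn) / (tp + tn + fp + fn)
    sensitivity = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
    specificity = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    return accuracy, sensitivity, specificity


def combine_phonemes(tables, feature_subset=None) -> pd.DataFrame:
    """Concatenate per-phoneme feature tables into one table per
    (subject, repetition), with phoneme-prefixed feature names.

    Rows lacking any of the phonemes are dropped (count logged). The
    phoneme column of the result holds the '+'-joined phoneme list.
    """
    tables = list(tables)
    if not tables:
        raise InvalidArgumentError("no tables to combine")
    merged = None
    phonemes = []
    for t in tables:
        phoneme = str(t["phoneme"].iloc[0]) if len(t) else "?"
        phonemes.append(phoneme)
        feats = feature_subset or feature_columns(t)
        sub = t[["subject_id", "group", "repetition", *feats]].copy()
        sub = sub.rename(columns={f: f"{phoneme}_{f}" for f in feats})
        # suffix phoneme names when the same phoneme appears more than once
        if merged is not None:
            clash = [c for c in sub.columns
                     if c in merged.columns and c not in ("subject_id", "group", "repetition")]
            sub = sub.rename(columns={c: f"{c}#{phonemes.count(phoneme)}" for c in clash})
            before = len(merged)
            merged = merged.merge(sub, on=["subject_id", "group", "repetition"], how="inner")
            dropped = before - len(merged)
            if dropped:
                log.info("combine_phonemes: dropped %d rows missing phoneme %s",
                         dropped, phoneme)
        else:
            merged = sub
    if merged is None or len(merged) == 0:
        raise InvalidArgumentError("no common (subject, repetition) rows across phonemes")
    merged.insert(2, "phoneme", "+".join(phonemes))
    return merged
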