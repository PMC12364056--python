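"""Distance-based nearest-neighbor evaluation protocols.

Two protocols operate on a precomputed algebraic distance matrix: a
leave-one-out 1-NN annotation test (each sequence is classified by its single
nearest neighbor), and a 5-NN classifier assessed by stratified 5-fold
cross-validation repeated over 30 seeds.  Metrics beyond plain accuracy are
macro-averaged so small families weigh equally; classes with fewer than 15
members are dropped beforehand to control imbalance.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import (
    accuracy_score,
    balanced_accuracy_score,
    f1_score,
    precision_score,
    recall_score,
)
from sklearn.model_selection import StratifiedKFold

from .distance import DistanceMatrix

logger = logging.getLogger(__name__)

METRICS = ("acc", "balanced_acc", "macro_f1", "macro_recall", "macro_precision")


def filter_min_class_size(labels: Mapping[str, str], min_size: int = 15) -> dict[str, str]:
    """Keep only samples whose class has at least ``min_size`` members."""
    counts = Counter(labels.values())
    dropped = sorted(c for c, n in counts.items() if n < min_size)
    if dropped:
        logger.info("dropping %d classes below %d members: %s", len(dropped), min_size, dropped)
    kept = {sid: lab for sid, lab in labels.items() if counts[lab] >= min_size}
    if not kept:
        raise ValueError(f"no classes have >= {min_size} members")
    return kept


def _ordered_labels(dm: DistanceMatrix, labels: Mapping[str, str]) -> np.ndarray:
    missing = [sid for sid in dm.ids if sid not in labels]
    if missing:
        raise ValueError(f"unlabeled samples: {missing[:5]}")
    return np.array([labels[sid] for sid in dm.ids])


def loo_1nn(dm: DistanceMatrix, labels: Mapping[str, str]) -> tuple[float, pd.DataFrame]:
    """Leave-one-out 1-NN accuracy plus per-sample verdicts.

    Each sample's nearest *other* sample decides its predicted class; distance
    ties are resolved toward the lexicographically smallest neighbor id.
    """
    if len(dm.ids) < 2:
        raise ValueError("need at least 2 samples")
    y = _ordered_labels(dm, labels)
    rows = []
    for i, sid in enumerate(dm.ids):
        others = [(dm.D[i, j], dm.ids[j], j) for j in range(len(dm.ids)) if j != i]
        _, nn_id, j = min(others)
        rows.append(
            {
                "id": sid,
                "label": y[i],
                "neighbor": nn_id,
                "predicted": y[j],
                "correct": y[i] == y[j],
            }
        )
    verdicts = pd.DataFrame(rows)
    return float(verdicts["correct"].mean()), verdicts


class PositionalKNN(ClassifierMixin, BaseEstimator):
    """k-NN on precomputed distances with fully deterministic tie handling.

    ``fit`` takes the train-vs-train distance block (only its row order and
    labels matter); ``predict`` takes a test-vs-train distance block.
    Neighbor ties are broken by training-sample order; vote ties by the
    candidate class with the smaller summed neighbor distance, then the
    lexicographically smaller class name.
    """

    def __init__(self, n_neighbors: int = 5):
        self.n_neighbors = n_neighbors

    def fit(self, X: np.ndarray, y: Sequence) -> "PositionalKNN":
        y = np.asarray(y)
        if len(y) != np.asarray(X).shape[1]:
            raise ValueError("X must have one column per training sample")
        if self.n_neighbors > len(y):
            raise ValueError("n_neighbors exceeds the training set size")
        self.classes_ = np.unique(y)
        self.y_ = y
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = []
        for row in X:
            order = np.lexsort((np.arange(len(row)), row))[: self.n_neighbors]
            votes: dict = {}
            for idx in order:
                lab = self.y_[idx]
                cnt, s = votes.get(lab, (0, 0.0))
                votes[lab] = (cnt + 1, s + row[idx])
            winner = min(votes, key=lambda lab: (-votes[lab][0], votes[lab][1], str(lab)))
            out.append(winner)
        return np.asarray(out)


@dataclass(frozen=True)
class ClassificationReport:
    """Per-(seed, fold) metrics and their aggregates over all runs."""

    rows: pd.DataFrame  # columns: seed, fold + METRICS
    mean: dict[str, float]
    std: dict[str, float]


def _fold_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    return {
        "acc": accuracy_score(y_true, y_pred),
        "balanced_acc": balanced_accuracy_score(y_true, y_pred),
        "macro_f1": f1_score(y_true, y_pred, average="macro", zero_division=0),
        "macro_recall": recall_score(y_true, y_pred, average="macro", zero_division=0),
        "macro_precision": precision_score(y_true, y_pred, average="macro", zero_division=0),
    }


def knn_cv(
    dm: DistanceMatrix,
    labels: Mapping[str, str],
    k: int = 5,
    folds: int = 5,
    seeds: int | Sequence[int] = 30,
) -> ClassificationReport:
    """Stratified k-fold cross-validated k-NN over repeated seeds.

    ``seeds`` may be a count (canonical seed list 0..seeds-1) or an explicit
    sequence.  Every class must have at least ``folds`` members.
    """
    y = _ordered_labels(dm, labels)
    counts = Counter(y)
    if len(counts) < 2:
        raise ValueError("need at least 2 classes for cross-validation")
    small = sorted(c for c, n in counts.items() if n < folds)
    if small:
        raise ValueError(f"classes smaller than {folds} members: {small}")
    seed_list = list(range(seeds)) if isinstance(seeds, int) else list(seeds)
    records = []
    idx = np.arange(len(y))
    for seed in seed_list:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        for fold, (train, test) in enumerate(skf.split(idx, y)):
            clf = PositionalKNN(n_neighbors=k).fit(dm.D[np.ix_(train, train)], y[train])
            y_pred = clf.predict(dm.D[np.ix_(test, train)])
            records.append({"seed": seed, "fold": fold, **_fold_metrics(y[test], y_pred)})
    rows = pd.DataFrame(records)
    return ClassificationReport(
        rows=rows,
        mean={m: float(rows[m].mean()) for m in METRICS},
        std={m: float(rows[m].std(ddof=0)) for m in METRICS},
    )


def write_report_tsv(report: ClassificationReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        report.rows.to_csv(fh, sep="\t", index=False)
        fh.write(
            "# aggregate_mean\t"
            + "\t".join(f"{m}={report.mean[m]:.6f}" for m in METRICS)
            + "\n# aggregate_std\t"
            + "\t".join(f"{m}={report.std[m]:.6f}" for m in METRICS)
            + "\n"
        )
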