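"""Confusion-count metrics, stratified k-fold CV, and independent testing.

Six metrics are derived from the confusion counts: sensitivity Sn =
TP/(TP+FN), specificity Sp = TN/(TN+FP), precision Pre = TP/(TP+FP),
accuracy Acc = (TP+TN)/total, balanced accuracy BAcc = (Sn+Sp)/2, and the
Matthews correlation coefficient.  Cross-validation reports pooled
confusion counts (summed over folds, then converted to metrics); the
per-fold reports are also returned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .sequence_io import SequenceWindow, SiteDataset


@dataclass
class MetricsReport:
    """Confusion counts plus the six derived metrics.

    Metrics with a zero denominator are ``nan`` (undefined), except MCC
    which is defined as 0 when its denominator vanishes.
    """

    TP: int
    TN: int
    FP: int
    FN: int
    Sn: float = field(init=False)
    Sp: float = field(init=False)
    Pre: float = field(init=False)
    Acc: float = field(init=False)
    BAcc: float = field(init=False)
    MCC: float = field(init=False)

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")
        total = self.TP + self.TN + self.FP + self.FN
        if total == 0:
            raise ValueError("at least one count must be positive")

        def ratio(num: int, den: int) -> float:
            return num / den if den else math.nan

        self.Sn = ratio(self.TP, self.TP + self.FN)
        self.Sp = ratio(self.TN, self.TN + self.FP)
        self.Pre = ratio(self.TP, self.TP + self.FP)
        self.Acc = (self.TP + self.TN) / total
        self.BAcc = (self.Sn + self.Sp) / 2
        denom = math.sqrt(
            (self.TP + self.FP)
            * (self.TP + self.FN)
            * (self.TN + self.FP)
            * (self.TN + self.FN)
        )
        self.MCC = (
            (self.TP * self.TN - self.FP * self.FN) / denom if denom else 0.0
        )

    def as_dict(self) -> dict[str, float]:
        return {
            "TP": self.TP,
            "TN": self.TN,
            "FP": self.FP,
            "FN": self.FN,
            "Sn": self.Sn,
            "Sp": self.Sp,
            "Pre": self.Pre,
            "Acc": self.Acc,
            "BAcc": self.BAcc,
            "MCC": self.MCC,
        }


def compute_metrics(TP: int, TN: int, FP: int, FN: int) -> MetricsReport:
    """Build a :class:`MetricsReport` from the four confusion counts."""
    return MetricsReport(TP=TP, TN=TN, FP=FP, FN=FN)


def metrics_from_predictions(
    y_true: Sequence[int], y_pred: Sequence[int]
) -> MetricsReport:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    return compute_metrics(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        TN=int(np.sum((y_true == 0) & (y_pred == 0))),
        FP=int(np.sum((y_true == 0) & (y_pred == 1))),
        FN=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def kfold_split(
    labels: Sequence[int], k: int, seed: int
) -> list[np.ndarray]:
    """Label-stratified partition into k folds of test indices.

    Fold sizes differ by at most one per class; reproducible from ``seed``.
    """
    labels = np.asarray(labels)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test_idx for _, test_idx in skf.split(np.zeros(len(labels)), labels)]


def cross_validate(
    windows: Sequence[SequenceWindow],
    labels: Sequence[int],
    trainer: Callable[[list[SequenceWindow], np.ndarray], Callable],
    k: int = 5,
    seed: int = 0,
) -> tuple[MetricsReport, list[MetricsReport]]:
    """k-fold CV with pooled confusion counts.

    ``trainer(train_windows, train_labels)`` returns a predictor mapping a
    window list to 0/1 calls.  Returns the pooled report (counts summed
    over folds) and the per-fold reports.
    """
    labels = np.asarray(labels)
    folds = kfold_split(labels, k, seed)
    pooled = np.zeros(4, dtype=int)  # TP TN FP FN
    per_fold = []
    all_idx = np.arange(len(labels))
    for test_idx in folds:
        train_mask = np.ones(len(labels), dtype=bool)
        train_mask[test_idx] = False
        train_idx = all_idx[train_mask]
        predictor = trainer(
            [windows[i] for i in train_idx], labels[train_idx]
        )
        y_pred = np.asarray(predictor([windows[i] for i in test_idx]))
        y_true = labels[test_idx]
        rep = metrics_from_predictions(y_true, y_pred)
        per_fold.append(rep)
        pooled += np.array([rep.TP, rep.TN, rep.FP, rep.FN])
    return compute_metrics(*pooled.tolist()), per_fold


def independent_test(
    predict_fn: Callable[[list[SequenceWindow]], Sequence[int]],
    test: SiteDataset,
    tags: dict[str, str] | None = None,
) -> dict[str, MetricsReport]:
    """Evaluate a predictor on an independent dataset.

    ``tags`` optionally maps protein id -> species tag; per-tag reports are
    returned under their tag alongside the pooled report under ``"all"``.
    """
    windows = list(test.positives) + list(test.negatives)
    y_true = np.array(
        [1] * len(test.positives) + [0] * len(test.negatives)
    )
    y_pred = np.asarray(predict_fn(windows))
    reports = {"all": metrics_from_predictions(y_true, y_pred)}
    if tags:
        tag_values = sorted(set(tags.values()))
        for tag in tag_values:
            mask = np.array(
                [tags.get(w.source[0]) == tag for w in windows]
            )
            if mask.any():
                reports[tag] = metrics_from_predictions(
                    y_true[mask], y_pred[mask]
                )
    return reports


def metrics_table(reports: dict[str, MetricsReport]) -> pd.DataFrame:
    """Tabulate reports in the conventional column order."""
    rows = []
    for name, rep in reports.items():
        row = {"dataset": name}
        row.update(rep.as_dict())
        rows.append(row)
    cols = ["dataset", "TP", "TN", "FP", "FN", "Sn", "Sp", "Pre", "Acc", "BAcc", "MCC"]
    return pd.DataFrame(rows)[cols]
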