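"""F-score ranking of physicochemical properties and forward selection.

The F-score of one numeric feature measures between-class mean separation
relative to pooled within-class spread:

    F = [ (x+ - x)^2 + (x- - x)^2 ] /
        [ (1/(n+ - 1)) * sum_k (x+_k - x+)^2
          + (1/(n- - 1)) * sum_k (x-_k - x-)^2 ]

where x, x+ and x- are the overall, positive-class and negative-class means.
It is symmetric in the class labels and invariant under a common affine
transform of both classes.  When both classes are constant with different
means the score is reported as ``inf`` (perfect separation); when constant
and equal it is 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .encoding import AAindexEntry, encode_physicochemical
from .sequence_io import SequenceWindow


def fscore(pos_values: Sequence[float], neg_values: Sequence[float]) -> float:
    """F-score between two samples of one numeric feature.

    Returns ``math.inf`` for the degenerate zero-within-variance case with
    unequal means, 0.0 when both classes are constant and equal.
    """
    pos = np.asarray(pos_values, dtype=float)
    neg = np.asarray(neg_values, dtype=float)
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("each class needs at least 2 values")
    grand = np.concatenate([pos, neg]).mean()
    mp, mn = pos.mean(), neg.mean()
    numerator = (mp - grand) ** 2 + (mn - grand) ** 2
    denominator = pos.var(ddof=1) + neg.var(ddof=1)
    if denominator == 0.0:
        return math.inf if numerator > 0.0 else 0.0
    return float(numerator / denominator)


@dataclass
class FScoreTable:
    """Per-(property, position) F-scores with position-averaged ranking."""

    scores: pd.DataFrame  # columns: property, position, fscore
    averages: pd.DataFrame  # columns: property, avg_fscore, rank

    def ranked_ids(self) -> list[str]:
        return self.averages["property"].tolist()

    def to_tsv(self, path: str) -> None:
        merged = self.scores.merge(self.averages, on="property")
        merged.to_csv(path, sep="\t", index=False)


def rank_properties(
    positives: Sequence[SequenceWindow],
    negatives: Sequence[SequenceWindow],
    entries: Sequence[AAindexEntry],
    include_na: bool = False,
) -> FScoreTable:
    """Rank property scales by the window-averaged per-position F-score.

    Each property is encoded positionwise over both classes; the F-score is
    computed per position, then averaged over the window.  Entries flagged
    as containing NA values are skipped unless ``include_na``.  Ties in the
    average break by accession id.  Degenerate (infinite) position scores
    propagate to an infinite average, sorting those properties first.
    """
    usable = [e for e in entries if include_na or not e.has_na]
    if not usable:
        raise ValueError("no usable property entries")
    w = len(positives[0].residues)
    n = w // 2
    rows = []
    for entry in usable:
        pos_mat = np.stack(
            [encode_physicochemical(win, entry).values for win in positives]
        )
        neg_mat = np.stack(
            [encode_physicochemical(win, entry).values for win in negatives]
        )
        for p in range(w):
            rows.append(
                {
                    "property": entry.id,
                    "position": p - n,
                    "fscore": fscore(pos_mat[:, p], neg_mat[:, p]),
                }
            )
    scores = pd.DataFrame(rows)
    averages = (
        scores.groupby("property", as_index=False)["fscore"]
        .mean()
        .rename(columns={"fscore": "avg_fscore"})
    )
    averages = averages.sort_values(
        ["avg_fscore", "property"], ascending=[False, True]
    ).reset_index(drop=True)
    averages["rank"] = np.arange(1, len(averages) + 1)
    return FScoreTable(scores=scores, averages=averages)


@dataclass
class SelectionStep:
    property_id: str
    accuracy: float
    accepted: bool


def forward_select(
    ranked_ids: Sequence[str],
    evaluator: Callable[[list[str]], float],
    k: int = 20,
    patience: int = 3,
) -> tuple[list[SelectionStep], list[str]]:
    """Greedy forward selection of ranked properties into a base model.

    ``evaluator(selected_ids)`` returns the CV accuracy of the base model
    augmented with the given property blocks; it is called first with the
    empty list to set the baseline.  Properties are added in rank order; an
    addition is kept only if it improves on the best accuracy so far.
    Selection stops early after ``patience`` consecutive non-improving
    additions.  Returns the full trace and the best accepted prefix.
    """
    if k > len(ranked_ids):
        warnings.warn(
            f"k={k} exceeds the {len(ranked_ids)} available properties; "
            "truncating",
            stacklevel=2,
        )
        k = len(ranked_ids)
    best_acc = evaluator([])
    selected: list[str] = []
    trace: list[SelectionStep] = []
    stale = 0
    for prop in ranked_ids[:k]:
        acc = evaluator(selected + [prop])
        accepted = acc > best_acc
        trace.append(SelectionStep(prop, acc, accepted))
        if accepted:
            selected.append(prop)
            best_acc = acc
            stale = 0
        else:
            stale += 1
            if stale >= patience:
                break
    return trace, selected
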