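"""Tree-level prediction values, category bands and ROC/AUC evaluation.

A tree's prediction value is the frequency-weighted average of the
network's first output over every identification class that produces the
tree: value = sum_k w_k * y1(x_k) / sum_k w_k, a convex combination in
[0, 1].  The second output is carried along for audit.

Values are banded into five categories.  The cut points are reconstructed
from the published (value, category) pairs — e.g. 0.40451 is Unclassifiable
while 0.39903 is Not-RNA-Like, fixing the 0.40 boundary; 0.81259 is
Highly-RNA-Like while 0.75935 is RNA-Like, bracketing 0.80:

    value >= 0.80        Highly-RNA-Like
    0.60 <= value < 0.80 RNA-Like
    0.40 <  value < 0.60 Unclassifiable
    0.20 <  value <= 0.40 Not-RNA-Like
    value <= 0.20        Highly-Not-RNA-Like

No published value sits exactly on 0.80, 0.60, 0.40 or 0.20, so boundary
membership is a convention: the RNA-like side is closed at 0.80/0.60 and
the not-RNA-like side closed at 0.40/0.20.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .catalog import Catalog, CatalogEntry
from .merge import MergeDataVector, MergeRow, data_vectors_for
from .mlp import MLPParams, forward_batch

__all__ = [
    "CATEGORIES",
    "TreePrediction",
    "categorize",
    "tree_prediction",
    "predict_all",
    "roc_curve",
    "roc_auc",
]

# most to least RNA-like
CATEGORIES = (
    "Highly-RNA-Like",
    "RNA-Like",
    "Unclassifiable",
    "Not-RNA-Like",
    "Highly-Not-RNA-Like",
)


@dataclass(frozen=True)
class TreePrediction:
    rag_index: str
    color: str
    value: float  # first network output, weighted-averaged
    vector2: float  # second output, kept for audit
    category: str


def categorize(value: float) -> str:
    """Five-band category of a prediction value in [0, 1]."""
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"prediction value {value} outside [0, 1]")
    if value >= 0.80:
        return "Highly-RNA-Like"
    if value >= 0.60:
        return "RNA-Like"
    if value > 0.40:
        return "Unclassifiable"
    if value > 0.20:
        return "Not-RNA-Like"
    return "Highly-Not-RNA-Like"


def tree_prediction(
    result: CatalogEntry,
    vectors: list[MergeDataVector],
    params: MLPParams,
) -> TreePrediction:
    """Weighted-average network output over all classes producing ``result``."""
    if not vectors:
        raise ValueError(
            f"tree {result.index} has no merge data vectors; it is not "
            "expressible as a merge of catalog trees"
        )
    X = np.asarray([v.features for v in vectors], dtype=float)
    w = np.asarray([v.weight for v in vectors], dtype=float)
    if np.any(w <= 0):
        raise ValueError("vector weights must be positive")
    Y = forward_batch(params, X)
    y1, y2 = (w @ Y) / w.sum()
    return TreePrediction(result.index, result.color, float(y1), float(y2),
                          categorize(float(y1)))


def predict_all(
    orders: list[int],
    params: MLPParams,
    catalog: Catalog,
    rows: list[MergeRow],
    which: str = "all",
) -> list[TreePrediction]:
    """Predictions for every catalog tree of the given orders.

    ``which`` restricts the rows: "all", "classified" (red/black) or
    "unknown".  Output is sorted by (order, z).
    """
    if which == "classified":
        entries = catalog.classified(orders=orders)
    elif which == "unknown":
        entries = catalog.unknown(orders=orders)
    elif which == "all":
        entries = [e for e in catalog if e.order in orders]
    else:
        raise ValueError(f"unknown selection {which!r}")
    preds = []
    for entry in sorted(entries, key=lambda e: (e.order, e.z)):
        vecs = data_vectors_for(entry, rows, catalog)
        preds.append(tree_prediction(entry, vecs, params))
    return preds


def roc_curve(scores, labels) -> np.ndarray:
    """ROC points (fpr, tpr) from a threshold sweep over all distinct scores.

    ``labels`` are truthy for the positive (RNA-like) class.  The sweep
    includes the +/- infinity endpoints, so the curve runs from (0, 0) to
    (1, 1); tied scores move diagonally in one step.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-d sequences")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both a positive and a negative example")
    order = np.argsort(-scores, kind="stable")
    s, l = scores[order], labels[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:  # group tied scores
            tp += l[j]
            fp += not l[j]
            j += 1
        points.append((fp / n_neg, tp / n_pos))
        i = j
    return np.asarray(points)


def roc_auc(scores, labels) -> tuple[np.ndarray, float]:
    """ROC curve and trapezoidal AUC.

    Equals the Mann-Whitney statistic: the probability that a random
    positive outscores a random negative, ties counted half.
    """
    pts = roc_curve(scores, labels)
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return pts, auc
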