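"""Metrics: document-level classification report, exact-match entity
report, and the attention-matrix export for heatmap rendering.

All scores are on the percent scale.  F combines the aggregated precision
and recall as F = 2PR / (P + R).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "MetricsReport",
    "f_score",
    "classification_report",
    "entity_report",
    "export_attention",
    "read_attention",
]


def f_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision < 0 or recall < 0:
        raise ValueError("precision and recall must be non-negative")
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f_score: float
    averaging: str
    per_class: dict = field(default_factory=dict)
    support: dict = field(default_factory=dict)

    def rounded(self, ndigits: int = 2) -> dict:
        return {
            "accuracy": round(self.accuracy, ndigits),
            "precision": round(self.precision, ndigits),
            "recall": round(self.recall, ndigits),
            "f_score": round(self.f_score, ndigits),
        }


def classification_report(gold: Sequence[int], predicted: Sequence[int]) -> MetricsReport:
    """Document-level metrics.

    Accuracy is the fraction correct; precision and recall are
    support-weighted averages over the classes present in the gold
    labels; F combines the weighted P and R.
    """
    gold = list(gold)
    predicted = list(predicted)
    if len(gold) != len(predicted):
        raise ValueError(
            f"gold has {len(gold)} labels but predictions have {len(predicted)}"
        )
    if not gold:
        raise ValueError("cannot score an empty label list")
    classes = sorted(set(gold) | set(predicted))
    accuracy = 100.0 * sum(g == p for g, p in zip(gold, predicted)) / len(gold)
    per_class: dict = {}
    support: dict = {}
    weighted_p = weighted_r = 0.0
    total_support = len(gold)
    for c in classes:
        tp = sum(1 for g, p in zip(gold, predicted) if g == c and p == c)
        fp = sum(1 for g, p in zip(gold, predicted) if g != c and p == c)
        fn = sum(1 for g, p in zip(gold, predicted) if g == c and p != c)
        prec = 100.0 * tp / (tp + fp) if tp + fp else 0.0
        rec = 100.0 * tp / (tp + fn) if tp + fn else 0.0
        n_c = tp + fn
        per_class[c] = {"precision": prec, "recall": rec, "f_score": f_score(prec, rec)}
        support[c] = n_c
        weighted_p += prec * n_c / total_support
        weighted_r += rec * n_c / total_support
    return MetricsReport(
        accuracy=accuracy,
        precision=weighted_p,
        recall=weighted_r,
        f_score=f_score(weighted_p, weighted_r),
        averaging="weighted",
        per_class=per_class,
        support=support,
    )


def entity_report(gold_mentions: Sequence, predicted_mentions: Sequence) -> MetricsReport:
    """Entity-level exact-match metrics, micro-averaged over documents.

    A predicted mention counts as correct only if its span, category and
    time attribute all match a gold mention.  Both arguments are lists of
    per-document mention lists.
    """
    if len(gold_mentions) != len(predicted_mentions):
        raise ValueError("gold and predicted corpora differ in size")

    def keys(mentions):
        return {(m.start, m.end, m.category, m.time_attr) for m in mentions}

    tp = fp = fn = 0
    for gold, pred in zip(gold_mentions, predicted_mentions):
        g, p = keys(gold), keys(pred)
        tp += len(g & p)
        fp += len(p - g)
        fn += len(g - p)
    prec = 100.0 * tp / (tp + fp) if tp + fp else 0.0
    rec = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    accuracy = 100.0 * tp / (tp + fp + fn) if tp + fp + fn else 100.0
    return MetricsReport(
        accuracy=accuracy,
        precision=prec,
        recall=rec,
        f_score=f_score(prec, rec),
        averaging="micro",
        support={"gold": tp + fn, "predicted": tp + fp},
    )


# ---------------------------------------------------------------------------
# Attention export (heatmap payload)
# ---------------------------------------------------------------------------


def export_attention(records: Sequence, path, doc_id: str = "") -> None:
    """Write attention rows as TSV: one row per risk factor, one column
    per character position; every row of weights sums to 1."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("doc_id\tfactor_index\tsurface\tweights\n")
        for rec in records:
            weights = np.asarray(rec.weights, dtype=np.float64)
            if weights.min() < 0 or abs(weights.sum() - 1.0) > 1e-6:
                raise ValueError("attention row must be non-negative and sum to 1")
            cells = "\t".join(repr(float(w)) for w in weights)
            fh.write(f"{doc_id or rec.doc_id}\t{rec.factor_index}\t{rec.surface}\t{cells}\n")


def read_attention(path) -> list:
    """Read the TSV back as (doc_id, factor_index, surface, weights) tuples."""
    rows = []
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    for line in lines[1:]:
        cells = line.split("\t")
        rows.append(
            (cells[0], int(cells[1]), cells[2], np.array([float(x) for x in cells[3:]]))
        )
    return rows
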