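"""Evaluation metrics: per-class P/R/F, micro overall, accuracy, AUC-ROC.

For single-label binary classification the micro-averaged overall
precision, recall and F-score all equal accuracy — which is why report
tables show three identical "overall" columns. AUC-ROC uses the exact
tie-aware Mann-Whitney rank formulation: the probability that a random
positive scores above a random negative, ties counted one half.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .records import NEGATIVE, POSITIVE, SentenceRecord, ValidationError

__all__ = [
    "ConfusionCounts",
    "EvaluationReport",
    "confusion_counts",
    "prf",
    "auc_roc",
    "evaluate_predictions",
    "evaluate",
    "format_report_table",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def swapped(self) -> "ConfusionCounts":
        """Counts with the roles of the two classes exchanged."""
        return ConfusionCounts(tp=self.tn, fp=self.fn, fn=self.fp, tn=self.tp)


def confusion_counts(
    predictions: Sequence[str], truths: Sequence[str]
) -> ConfusionCounts:
    """Tally TP/FP/FN/TN with positive = bleeding present."""
    if len(predictions) != len(truths):
        raise ValidationError(
            f"length mismatch: {len(predictions)} predictions, {len(truths)} truths"
        )
    tp = fp = fn = tn = 0
    for p, t in zip(predictions, truths):
        if p not in (POSITIVE, NEGATIVE) or t not in (POSITIVE, NEGATIVE):
            raise ValidationError(f"labels must be binary, got ({p!r}, {t!r})")
        if p == POSITIVE:
            tp += t == POSITIVE
            fp += t == NEGATIVE
        else:
            fn += t == POSITIVE
            tn += t == NEGATIVE
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def prf(counts: ConfusionCounts, positive_class: str = POSITIVE) -> tuple[float, float, float]:
    """Precision, recall, F1 for one class; zero denominators give 0."""
    c = counts if positive_class == POSITIVE else counts.swapped()
    if c.tp + c.fp == 0 or c.tp + c.fn == 0:
        warnings.warn("zero denominator in precision/recall; reporting 0", stacklevel=2)
    precision = c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0
    recall = c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f


def auc_roc(scores: Sequence[float], truths: Sequence[str]) -> float:
    """Tie-aware rank AUC: P(score_pos > score_neg) + 0.5 P(equal)."""
    scores = np.asarray(scores, dtype=np.float64)
    is_pos = np.array([t == POSITIVE for t in truths])
    if len(scores) != len(is_pos):
        raise ValidationError("scores and truths differ in length")
    n_pos, n_neg = int(is_pos.sum()), int((~is_pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC-ROC requires both classes in the truths")
    ranks = rankdata(scores)  # average ranks handle ties
    return float((ranks[is_pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass(frozen=True)
class EvaluationReport:
    per_class: dict  # class -> {"precision","recall","f_score"}
    overall: dict  # micro-averaged {"precision","recall","f_score"}
    accuracy: float
    auc_roc: float | None
    confusion: ConfusionCounts

    def to_dict(self) -> dict:
        return {
            "per_class": self.per_class,
            "overall": self.overall,
            "accuracy": self.accuracy,
            "auc_roc": self.auc_roc,
            "confusion": {
                "tp": self.confusion.tp,
                "fp": self.confusion.fp,
                "fn": self.confusion.fn,
                "tn": self.confusion.tn,
            },
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def evaluate_predictions(
    predictions: Sequence[str],
    truths: Sequence[str],
    scores: Sequence[float] | None = None,
    average: str = "micro",
) -> EvaluationReport:
    """Assemble the full report from labels (and scores, for AUC).

    Micro averaging aggregates counts over instances, so for binary
    single-label data overall precision = recall = F = accuracy; a
    macro average (unweighted class mean) is available via `average`.
    AUC is omitted (None) when scores are absent or only one class is
    present in the truths.
    """
    counts = confusion_counts(predictions, truths)
    if counts.n == 0:
        raise ValidationError("cannot evaluate an empty prediction set")
    per_class = {}
    for cls in (POSITIVE, NEGATIVE):
        p, r, f = prf(counts, positive_class=cls)
        per_class[cls] = {"precision": p, "recall": r, "f_score": f}
    accuracy = (counts.tp + counts.tn) / counts.n
    if average == "micro":
        overall = {"precision": accuracy, "recall": accuracy, "f_score": accuracy}
    elif average == "macro":
        overall = {
            key: (per_class[POSITIVE][key] + per_class[NEGATIVE][key]) / 2
            for key in ("precision", "recall", "f_score")
        }
    else:
        raise ValidationError(f"unknown average {average!r}")
    auc: float | None = None
    if scores is not None:
        n_pos = sum(t == POSITIVE for t in truths)
        if 0 < n_pos < len(truths):
            auc = auc_roc(scores, truths)
    return EvaluationReport(
        per_class=per_class,
        overall=overall,
        accuracy=accuracy,
        auc_roc=auc,
        confusion=counts,
    )


def evaluate(bundle, records: Sequence[SentenceRecord], average: str = "micro") -> EvaluationReport:
    """Score a trained model bundle on labeled records and build a report.

    Works identically on balanced and naturally imbalanced corpora.
    """
    from .training import predict_corpus  # local import: avoid cycle

    if not records:
        raise ValidationError("cannot evaluate on an empty corpus")
    truths = [r.label for r in records]
    if any(t not in (POSITIVE, NEGATIVE) for t in truths):
        raise ValidationError("evaluation requires labeled records")
    scores, predictions = predict_corpus(bundle, records)
    return evaluate_predictions(predictions, truths, scores=scores, average=average)


def format_report_table(reports: dict[str, EvaluationReport]) -> str:
    """Aligned text table: per-class and overall P/R/F plus AUC per model."""
    header = (
        f"{'Model':<24}"
        f"{'Pos-P':>8}{'Pos-R':>8}{'Pos-F':>8}"
        f"{'Neg-P':>8}{'Neg-R':>8}{'Neg-F':>8}"
        f"{'Ov-P':>8}{'Ov-R':>8}{'Ov-F':>8}{'AUC':>8}"
    )
    lines = [header]
    for name, rep in reports.items():
        pos, neg, ov = rep.per_class[POSITIVE], rep.per_class[NEGATIVE], rep.overall
        auc = f"{rep.auc_roc:8.3f}" if rep.auc_roc is not None else f"{'n/a':>8}"
        lines.append(
            f"{name:<24}"
            f"{pos['precision']:8.3f}{pos['recall']:8.3f}{pos['f_score']:8.3f}"
            f"{neg['precision']:8.3f}{neg['recall']:8.3f}{neg['f_score']:8.3f}"
            f"{ov['precision']:8.3f}{ov['recall']:8.3f}{ov['f_score']:8.3f}{auc}"
        )
    return "\n".join(lines)
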