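"""Binary confusion-matrix tallies and the derived percentage metrics.

The positive class is configurable and defaults to normal (non-fatigued)
driving, so that recall measures how much genuinely alert driving the
classifier recognises and precision the cost of flagging alert driving as
fatigued.  Metrics are reported as percentages rounded to one decimal; by
default F1 is computed from the already-rounded precision and recall
("round-first"), with an exact mode available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Sequence

__all__ = ["ConfusionMatrix", "MetricsReport", "confusion", "metrics"]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int
    positive: Hashable = "non_fatigue"

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def swap_positive(self) -> "ConfusionMatrix":
        """The same tally seen from the other class's point of view."""
        return ConfusionMatrix(
            tp=self.tn, tn=self.tp, fp=self.fn, fn=self.fp, positive=("~", self.positive)
        )


@dataclass(frozen=True)
class MetricsReport:
    """Percentages to one decimal; a metric whose denominator is zero is None."""

    accuracy: float | None
    recall: float | None
    precision: float | None
    f1: float | None
    rounding: str = "round_first"

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "recall": self.recall,
            "precision": self.precision,
            "f1": self.f1,
            "rounding": self.rounding,
        }


def confusion(
    predictions: Sequence, truths: Sequence, positive: Hashable = "non_fatigue"
) -> ConfusionMatrix:
    """Tally a 2x2 confusion matrix with the declared positive class."""
    if len(predictions) != len(truths):
        raise ValueError(
            f"length mismatch: {len(predictions)} predictions vs {len(truths)} truths"
        )
    if len(truths) == 0:
        raise ValueError("need at least one sample")
    tp = tn = fp = fn = 0
    for p, t in zip(predictions, truths):
        if t == positive:
            if p == positive:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive:
                fp += 1
            else:
                tn += 1
    return ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn, positive=positive)


def _pct(num: float, den: float) -> float | None:
    return None if den == 0 else 100.0 * num / den


def metrics(cm: ConfusionMatrix, *, rounding: str = "round_first") -> MetricsReport:
    """Accuracy, recall, precision and F1 from a confusion matrix.

    Accuracy = (TP+TN)/(TP+TN+FP+FN), Recall = TP/(TP+FN),
    Precision = TP/(TP+FP), F1 = 2*Pre*Rec/(Pre+Rec), all as percentages.
    In ``round_first`` mode (default) precision and recall are rounded to
    one decimal before entering the F1 formula; ``exact`` defers all
    rounding to the end.  Zero-denominator metrics come back as None
    rather than 0.
    """
    if rounding not in ("round_first", "exact"):
        raise ValueError("rounding must be 'round_first' or 'exact'")
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = _pct(cm.tp + cm.tn, cm.total)
    recall = _pct(cm.tp, cm.tp + cm.fn)
    precision = _pct(cm.tp, cm.tp + cm.fp)
    if recall is None or precision is None or (precision + recall) == 0:
        f1 = None
    else:
        pre, rec = precision, recall
        if rounding == "round_first":
            pre, rec = round(pre, 1), round(rec, 1)
        f1 = 2.0 * pre * rec / (pre + rec)
    rnd = lambda x: None if x is None else round(x, 1)  # noqa: E731
    return MetricsReport(
        accuracy=rnd(accuracy),
        recall=rnd(recall),
        precision=rnd(precision),
        f1=rnd(f1),
        rounding=rounding,
    )
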