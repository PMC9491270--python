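"""Per-class precision/recall/F1 plus accuracy, and the cross-domain harness.

Reports mirror the two-row layout used for binary depression classification
results: one accuracy per run and precision/recall/F1 for each of the
non-depression (0) and depression (1) classes.  The 0/0 convention for all
ratio metrics is 0, so a degenerate constant-positive classifier on balanced
data reports precision 0.5 / recall 1.0 / F1 0.6667 for the positive class
and 0/0/0 for the negative class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .features import FeatureMatrix, encode_posts
from .models import TrainedClassifier, predict


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class ClassMetrics:
    precision: float
    recall: float
    f1: float


@dataclass
class EvalReport:
    accuracy: float
    per_class: dict[int, ClassMetrics]
    n: int
    domain: str = "in_domain"
    counts: Optional[ConfusionCounts] = None  # for positive class 1

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "n": self.n,
            "domain": self.domain,
            "per_class": {
                str(c): {"precision": m.precision, "recall": m.recall, "f1": m.f1}
                for c, m in self.per_class.items()
            },
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_table(self) -> str:
        """Text table in the (label, accuracy, precision, recall, F1) layout."""
        names = {0: "non-depression", 1: "depression"}
        lines = [f"{'Label':<16}{'Accuracy':>10}{'Precision':>11}{'Recall':>9}{'F1-score':>10}"]
        for cls in (0, 1):
            m = self.per_class[cls]
            acc = f"{self.accuracy:.4f}" if cls == 0 else ""
            lines.append(f"{names[cls]:<16}{acc:>10}{m.precision:>11.4f}{m.recall:>9.4f}{m.f1:>10.4f}")
        return "\n".join(lines)


def confusion_counts(
    y_true: Sequence[int], y_pred: Sequence[int], positive_class: int = 1
) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    pos_t = y_true == positive_class
    pos_p = y_pred == positive_class
    return ConfusionCounts(
        tp=int((pos_t & pos_p).sum()),
        fp=int((~pos_t & pos_p).sum()),
        fn=int((pos_t & ~pos_p).sum()),
        tn=int((~pos_t & ~pos_p).sum()),
    )


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def precision_recall_f1(counts: ConfusionCounts) -> tuple[float, float, float]:
    """precision = tp/(tp+fp), recall = tp/(tp+fn), F1 their harmonic mean;
    0/0 is defined as 0."""
    precision = _safe_div(counts.tp, counts.tp + counts.fp)
    recall = _safe_div(counts.tp, counts.tp + counts.fn)
    f1 = _safe_div(2 * precision * recall, precision + recall)
    return precision, recall, f1


def report_from_predictions(
    y_true: Sequence[int], y_pred: Sequence[int], domain: str = "in_domain"
) -> EvalReport:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) == 0:
        raise ValueError("cannot evaluate on an empty set")
    per_class = {}
    for cls in (0, 1):
        c = confusion_counts(y_true, y_pred, positive_class=cls)
        p, r, f1 = precision_recall_f1(c)
        per_class[cls] = ClassMetrics(p, r, f1)
    accuracy = float((y_true == y_pred).mean())
    return EvalReport(
        accuracy=accuracy,
        per_class=per_class,
        n=len(y_true),
        domain=domain,
        counts=confusion_counts(y_true, y_pred, positive_class=1),
    )


def evaluate(trained: TrainedClassifier, test: FeatureMatrix, domain: str = "in_domain") -> EvalReport:
    """Accuracy plus both classes' precision/recall/F1 on an untouched
    (never resampled) evaluation split."""
    if len(test) == 0:
        raise ValueError("cannot evaluate on an empty set")
    _, y_pred = predict(trained, test.X)
    return report_from_predictions(test.y, y_pred, domain=domain)


def cross_domain_evaluate(
    trained: TrainedClassifier,
    token_lists: Sequence[Sequence[str]],
    labels: Sequence[int],
) -> EvalReport:
    """Evaluate a classifier trained on corpus A against labeled corpus B.

    B is encoded with A's frozen vocabulary (out-of-vocabulary tokens map to
    the unknown index), so the report is directly comparable with the
    in-domain report.
    """
    if trained.vocabulary is None:
        raise ValueError("trained classifier carries no vocabulary mapping; cannot encode the target domain")
    if len(token_lists) == 0:
        raise ValueError("target-domain corpus is empty")
    fm = encode_posts(token_lists, trained.vocabulary, trained.config.max_len, labels=labels)
    return evaluate(trained, fm, domain="cross_domain")
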