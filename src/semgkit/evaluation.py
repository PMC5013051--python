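"""Accuracy, top-k error, chance level and per-subject aggregation.

For a balanced ``n``-class problem the chance level is ``100 / n``
percent; with ~51 classes (50 movements + rest) it is below 2%, so the
accuracy-to-chance ratio is the comparable quantity across studies with
different class counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "EvaluationReport",
    "score",
    "chance_level",
    "accuracy_chance_ratio",
    "aggregate_subjects",
    "binomial_chance_interval",
]


@dataclass
class EvaluationReport:
    """Classification scores for one evaluation set."""

    overall_accuracy: float  # percent
    per_class_accuracy: dict[int, float]  # percent per class id
    topk_errors: dict[int, float]  # fraction per k
    n_classes: int
    n_samples: int
    chance: float  # percent
    accuracy_chance_ratio: float
    confusion: np.ndarray | None = field(default=None, repr=False)

    @property
    def top1_error(self) -> float:
        return self.topk_errors[1]

    @property
    def top5_error(self) -> float | None:
        return self.topk_errors.get(5)

    def to_json(self) -> str:
        payload = {
            "overall_accuracy": self.overall_accuracy,
            "per_class_accuracy": {str(k): v for k, v in self.per_class_accuracy.items()},
            "topk_errors": {str(k): v for k, v in self.topk_errors.items()},
            "n_classes": self.n_classes,
            "n_samples": self.n_samples,
            "chance": self.chance,
            "accuracy_chance_ratio": self.accuracy_chance_ratio,
        }
        return json.dumps(payload, indent=2)

    def to_delimited(self) -> str:
        lines = ["metric\tvalue", f"overall_accuracy\t{self.overall_accuracy:.4f}"]
        for k, err in sorted(self.topk_errors.items()):
            lines.append(f"top{k}_error\t{err:.6f}")
        lines.append(f"chance\t{self.chance:.4f}")
        lines.append(f"accuracy_chance_ratio\t{self.accuracy_chance_ratio:.4f}")
        return "\n".join(lines)


def chance_level(n_classes: int) -> float:
    """Expected accuracy (percent) of uniform random prediction."""
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    return 100.0 / n_classes


def accuracy_chance_ratio(accuracy: float, n_classes: int) -> float:
    """How many times above chance an accuracy (in percent) lies."""
    return accuracy / chance_level(n_classes)


def score(
    predicted,
    true_labels,
    k_list: tuple[int, ...] = (1, 5),
    n_classes: int | None = None,
    with_confusion: bool = False,
) -> EvaluationReport:
    """Score predictions against true labels.

    ``predicted`` is either an ``(n, n_classes)`` score/probability
    matrix (required for any k > 1) or a 1-D label vector (top-1 only).
    Top-k error is the fraction of samples whose true label is absent
    from the k highest-scoring classes; ties are broken toward the lowest
    class id, so the result is deterministic.
    """
    true_labels = np.asarray(true_labels).astype(int).ravel()
    predicted = np.asarray(predicted)
    n = true_labels.size
    if predicted.shape[0] != n:
        raise ValueError("predicted and true_labels must have equal length")

    if predicted.ndim == 1:
        pred_labels = predicted.astype(int)
        if n_classes is None:
            n_classes = int(max(pred_labels.max(initial=0), true_labels.max(initial=0))) + 1
        bad_k = [k for k in k_list if k > 1]
        if bad_k:
            raise ValueError(f"top-{max(bad_k)} error requires class scores, got labels only")
        topk = {1: float(np.mean(pred_labels != true_labels))}
    else:
        if n_classes is None:
            n_classes = predicted.shape[1]
        if predicted.shape[1] != n_classes:
            raise ValueError("score matrix width does not match n_classes")
        if max(k_list) > n_classes:
            raise ValueError(f"k={max(k_list)} exceeds n_classes={n_classes}")
        # stable sort on -scores keeps ascending class-id order among ties
        order = np.argsort(-predicted, axis=1, kind="stable")
        pred_labels = order[:, 0]
        topk = {}
        for k in sorted(k_list):
            hit = (order[:, :k] == true_labels[:, None]).any(axis=1)
            topk[int(k)] = float(np.mean(~hit)) if n else 0.0

    overall = 100.0 * (1.0 - topk[1])
    per_class: dict[int, float] = {}
    for cls in np.unique(true_labels):
        mask = true_labels == cls
        per_class[int(cls)] = float(100.0 * np.mean(pred_labels[mask] == cls))

    confusion = None
    if with_confusion:
        confusion = np.zeros((n_classes, n_classes), dtype=int)
        np.add.at(confusion, (true_labels, pred_labels), 1)

    return EvaluationReport(
        overall_accuracy=overall,
        per_class_accuracy=per_class,
        topk_errors=topk,
        n_classes=int(n_classes),
        n_samples=int(n),
        chance=chance_level(int(n_classes)),
        accuracy_chance_ratio=accuracy_chance_ratio(overall, int(n_classes)),
        confusion=confusion,
    )


def aggregate_subjects(per_subject_accuracies: list[float]) -> tuple[float, float, str]:
    """Mean and across-subject standard deviation (n-1 denominator).

    Returns ``(mean, std, formatted)`` with the conventional
    ``"mm.mm ± ss.ss%"`` formatting; a single subject yields std 0 with a
    degenerate-cohort flag in the formatted string.
    """
    acc = np.asarray(list(per_subject_accuracies), dtype=float)
    if acc.size == 0:
        raise ValueError("need at least one subject")
    mean = float(acc.mean())
    if acc.size == 1:
        return mean, 0.0, f"{mean:.2f} ± 0.00% (single subject)"
    std = float(acc.std(ddof=1))
    return mean, std, f"{mean:.2f} ± {std:.2f}%"


def binomial_chance_interval(
    n_samples: int, n_classes: int, confidence: float = 0.99
) -> tuple[float, float]:
    """Exact binomial interval (as accuracy fractions) around chance.

    The band within which the accuracy of a label-independent predictor
    falls with the given probability on ``n_samples`` balanced trials.
    """
    if n_samples < 1 or n_classes < 1:
        raise ValueError("n_samples and n_classes must be >= 1")
    p = 1.0 / n_classes
    lo, hi = stats.binom.interval(confidence, n_samples, p)
    return float(lo) / n_samples, float(hi) / n_samples
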