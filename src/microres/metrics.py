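"""Evaluation protocol: UF1, UAR, accuracy and leave-one-subject-out folds.

The micro-expression benchmarks are small and class-imbalanced, so the
community scores with class-balanced metrics over per-class confusion counts:

    UF1      = (1/C) * sum_i  2 TP_i / (2 TP_i + FP_i + FN_i)   (macro F1)
    UAR      = (1/C) * sum_i  TP_i / N_i                        (balanced acc.)
    Accuracy = (sum_i TP_i) / N

Evaluation uses leave-one-subject-out (LOSO) cross-validation: each fold
holds out every clip of one subject.  Composite-dataset scoring pools the
predictions of all folds and computes UF1/UAR once over the pool (the
MEGC2019 convention), rather than averaging per-fold scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .clipio import ClipAnnotation

__all__ = [
    "ConfusionCounts", "confusion", "uf1", "uar", "accuracy",
    "per_class_f1", "per_class_recall", "loso_splits", "LosoFold",
    "evaluation_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-class TP/FP/FN and support, in a fixed class order."""

    classes: tuple
    tp: tuple[int, ...]
    fp: tuple[int, ...]
    fn: tuple[int, ...]
    support: tuple[int, ...]  # N_i: number of true examples per class

    def __post_init__(self) -> None:
        c = len(self.classes)
        for name in ("tp", "fp", "fn", "support"):
            vals = getattr(self, name)
            if len(vals) != c:
                raise ValueError(f"{name} must have one entry per class")
            if any(v < 0 for v in vals):
                raise ValueError(f"{name} counts must be non-negative")
        if any(t > n for t, n in zip(self.tp, self.support)):
            raise ValueError("TP_i cannot exceed class support N_i")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def n_total(self) -> int:
        return int(sum(self.support))


def confusion(
    true_labels: Sequence, pred_labels: Sequence, classes: Sequence
) -> ConfusionCounts:
    """Per-class confusion counts for labels drawn from ``classes``."""
    if len(true_labels) != len(pred_labels):
        raise ValueError("true and predicted label lists differ in length")
    if len(true_labels) == 0:
        raise ValueError("cannot build confusion counts from empty inputs")
    index = {c: i for i, c in enumerate(classes)}
    c = len(classes)
    mat = np.zeros((c, c), dtype=int)  # rows: true, cols: predicted
    for t, p in zip(true_labels, pred_labels):
        if t not in index or p not in index:
            raise ValueError(f"label pair ({t!r}, {p!r}) outside classes {classes}")
        mat[index[t], index[p]] += 1
    tp = np.diag(mat)
    fp = mat.sum(axis=0) - tp
    fn = mat.sum(axis=1) - tp
    return ConfusionCounts(
        classes=tuple(classes), tp=tuple(int(v) for v in tp),
        fp=tuple(int(v) for v in fp), fn=tuple(int(v) for v in fn),
        support=tuple(int(v) for v in mat.sum(axis=1)),
    )


def per_class_f1(counts: ConfusionCounts) -> list[float]:
    """F1 per class; a class with TP = FP = FN = 0 contributes 0 (0/0 case)."""
    out = []
    for tp, fp, fn in zip(counts.tp, counts.fp, counts.fn):
        denom = 2 * tp + fp + fn
        out.append(2 * tp / denom if denom > 0 else 0.0)
    return out


def per_class_recall(counts: ConfusionCounts) -> list[float]:
    if any(n == 0 for n in counts.support):
        raise ValueError("recall undefined for a class with zero support")
    return [tp / n for tp, n in zip(counts.tp, counts.support)]


def uf1(counts: ConfusionCounts) -> float:
    """Unweighted (macro) F1 over classes."""
    if counts.n_classes == 0:
        raise ValueError("no classes")
    return float(np.mean(per_class_f1(counts)))


def uar(counts: ConfusionCounts) -> float:
    """Unweighted average recall (balanced accuracy)."""
    if counts.n_classes == 0:
        raise ValueError("no classes")
    return float(np.mean(per_class_recall(counts)))


def accuracy(counts: ConfusionCounts) -> float:
    if counts.n_total == 0:
        raise ValueError("no examples")
    return float(sum(counts.tp) / counts.n_total)


class LosoFold(NamedTuple):
    subject_id: str
    train_indices: tuple[int, ...]
    test_indices: tuple[int, ...]


def loso_splits(annotations: Sequence[ClipAnnotation]) -> list[LosoFold]:
    """Leave-one-subject-out folds, ordered by subject id.

    Each fold tests on every clip of one subject and trains on the rest;
    the test folds partition the clip list.
    """
    subjects = sorted({a.subject_id for a in annotations})
    if len(subjects) < 2:
        raise ValueError("LOSO requires at least two distinct subjects")
    folds = []
    for s in subjects:
        test = tuple(i for i, a in enumerate(annotations) if a.subject_id == s)
        trainset = tuple(i for i, a in enumerate(annotations) if a.subject_id != s)
        folds.append(LosoFold(subject_id=s, train_indices=trainset, test_indices=test))
    return folds


def evaluation_report(
    true_labels: Sequence, pred_labels: Sequence, classes: Sequence,
    fold_of: Sequence | None = None,
) -> dict:
    """Pooled UF1/UAR/accuracy report over (typically cross-fold) predictions."""
    counts = confusion(true_labels, pred_labels, classes)
    report = {
        "uf1": uf1(counts),
        "uar": uar(counts),
        "accuracy": accuracy(counts),
        "per_class_f1": dict(zip(counts.classes, per_class_f1(counts))),
        "per_class_recall": dict(zip(counts.classes, per_class_recall(counts))),
        "n": counts.n_total,
    }
    if fold_of is not None:
        folds = {}
        for f in sorted(set(fold_of)):
            sel = [i for i, g in enumerate(fold_of) if g == f]
            folds[str(f)] = {
                "n": len(sel),
                "accuracy": float(np.mean(
                    [true_labels[i] == pred_labels[i] for i in sel]
                )),
            }
        report["folds"] = folds
    return report
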