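"""Confusion matrices, class precision / recall, and the stress test.

Convention (deliberate and easy to trip over): confusion-matrix ROWS are
PREDICTED classes and COLUMNS are TRUE classes — class precision is a row
statistic and class recall a column statistic.  Many libraries use the
transpose.  Percentages are displayed rounded half-up to 2 decimals;
full precision is kept internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import CLASSES, TrainedClassifier, predict

__all__ = [
    "ConfusionMatrix",
    "MetricReport",
    "confusion",
    "metrics",
    "stress_test",
    "round_half_up",
]


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round with ties away from zero (display convention)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """Predicted-vs-true counts; ``counts[p, t]`` has rows = predicted."""

    counts: np.ndarray
    classes: tuple[str, ...] = CLASSES

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        k = len(self.classes)
        if c.shape != (k, k):
            raise ValueError(f"expected a {k}x{k} count matrix, got {c.shape}")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=[f"pred_{c}" for c in self.classes],
            columns=[f"true_{c}" for c in self.classes],
        )


def confusion(
    pred: Sequence[str], truth: Sequence[str], classes: Sequence[str] = CLASSES
) -> ConfusionMatrix:
    """Count prediction/truth pairs into a rows-=-predicted matrix."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if len(pred) != len(truth):
        raise ValueError(f"length mismatch: {len(pred)} predictions, {len(truth)} truths")
    idx = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for p, t in zip(pred, truth):
        if p not in idx:
            raise ValueError(f"unknown predicted label {p!r}")
        if t not in idx:
            raise ValueError(f"unknown true label {t!r}")
        counts[idx[p], idx[t]] += 1
    return ConfusionMatrix(counts, tuple(classes))


@dataclass(frozen=True)
class MetricReport:
    """Per-class precision/recall and overall accuracy, in percent.

    Metrics whose denominator is zero (an empty predicted row or true
    column) are ``None`` and listed in ``undefined`` rather than being
    reported as 0.
    """

    matrix: ConfusionMatrix
    precision: dict[str, float | None]
    recall: dict[str, float | None]
    overall: float
    fold_accuracies: np.ndarray | None = None
    undefined: tuple[str, ...] = field(default_factory=tuple)

    def display(self) -> pd.DataFrame:
        """Rounded (half-up, 2 decimals) metric table for printing."""
        rows = []
        for c in self.matrix.classes:
            rows.append(
                {
                    "class": c,
                    "precision_pct": None
                    if self.precision[c] is None
                    else round_half_up(self.precision[c]),
                    "recall_pct": None
                    if self.recall[c] is None
                    else round_half_up(self.recall[c]),
                }
            )
        df = pd.DataFrame(rows)
        df.attrs["overall_pct"] = round_half_up(self.overall)
        return df

    def text_block(self) -> str:
        """Confusion matrix and metrics formatted as an aligned text table."""
        cls = self.matrix.classes
        width = max(12, max(len(c) for c in cls) + 7)
        header = "".join(f"{'true ' + c:>{width}}" for c in cls) + f"{'precision':>{width}}"
        lines = [" " * 16 + header]
        for i, c in enumerate(cls):
            prec = self.precision[c]
            cells = "".join(f"{self.matrix.counts[i, j]:>{width}}" for j in range(len(cls)))
            ptxt = "undef" if prec is None else f"{round_half_up(prec):.2f}%"
            lines.append(f"{'pred. ' + c:<16}" + cells + f"{ptxt:>{width}}")
        rec = "".join(
            f"{('undef' if self.recall[c] is None else f'{round_half_up(self.recall[c]):.2f}%'):>{width}}"
            for c in cls
        )
        lines.append(f"{'class recall':<16}" + rec)
        lines.append(f"overall accuracy: {round_half_up(self.overall):.2f}%")
        return "\n".join(lines)


def metrics(cm: ConfusionMatrix, fold_accuracies: np.ndarray | None = None) -> MetricReport:
    """Class precision (row-wise), class recall (column-wise), overall.

    precision_c = counts[c, c] / row-total_c;
    recall_c    = counts[c, c] / column-total_c;
    overall     = trace / total — all multiplied by 100.
    """
    if cm.total == 0:
        raise ValueError("cannot compute metrics for an empty confusion matrix")
    precision: dict[str, float | None] = {}
    recall: dict[str, float | None] = {}
    undefined: list[str] = []
    for i, c in enumerate(cm.classes):
        row = int(cm.counts[i].sum())
        col = int(cm.counts[:, i].sum())
        if row == 0:
            precision[c] = None
            undefined.append(f"precision[{c}]")
        else:
            precision[c] = 100.0 * cm.counts[i, i] / row
        if col == 0:
            recall[c] = None
            undefined.append(f"recall[{c}]")
        else:
            recall[c] = 100.0 * cm.counts[i, i] / col
    overall = 100.0 * float(np.trace(cm.counts)) / cm.total
    return MetricReport(
        matrix=cm,
        precision=precision,
        recall=recall,
        overall=overall,
        fold_accuracies=fold_accuracies,
        undefined=tuple(undefined),
    )


def stress_test(
    model: TrainedClassifier,
    stress_images: Sequence[tuple[str, object]],
    truth: Sequence[str],
) -> tuple[MetricReport, pd.DataFrame]:
    """Evaluate a trained model on held-out low-quality images.

    ``stress_images`` are (image_id, GrayImage-or-feature-vector) pairs
    that must be disjoint (by id) from the model's training manifest.
    Nothing is re-fit: prediction uses the stored normalizer and subset.
    Returns the metric report and a per-image verdict table.
    """
    if len(stress_images) == 0:
        raise ValueError("stress set is empty")
    if len(stress_images) != len(truth):
        raise ValueError("stress images and truth labels differ in length")
    ids = [img_id for img_id, _ in stress_images]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate image ids in the stress set")
    if model.train_ids is not None:
        overlap = sorted(set(ids) & set(model.train_ids))
        if overlap:
            raise ValueError(
                f"stress set overlaps the training manifest: {overlap[:5]}"
                f"{'...' if len(overlap) > 5 else ''}"
            )
    preds = [predict(model, x) for _, x in stress_images]
    report = metrics(confusion(preds, truth, model.classes))
    verdicts = pd.DataFrame(
        {
            "image_id": ids,
            "predicted": preds,
            "true": list(truth),
            "correct": [p == t for p, t in zip(preds, truth)],
        }
    )
    return report, verdicts
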