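"""Confusion-matrix accumulation and IoU / mIoU evaluation.

Per-class intersection-over-union is computed from the pixel confusion
matrix ``p`` (rows: ground truth, columns: prediction):

    IoU_i = p_ii / (row_i + col_i - p_ii)

and mIoU is the unweighted mean over all classes.  Metrics are accumulated
over the whole evaluation set (one global matrix), not averaged per image.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "UndefinedMetricError",
    "accumulate_confusion",
    "iou_per_class",
    "mean_iou",
    "miou_from_class_ious",
    "report_table",
]


class UndefinedMetricError(ValueError):
    """Raised when IoU is requested from an empty confusion matrix."""


@dataclass
class ConfusionMatrix:
    """K x K pixel-count table; entry (i, j) = truth i predicted as j."""

    num_classes: int = 3
    counts: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.counts is None:
            self.counts = np.zeros((self.num_classes, self.num_classes), dtype=np.int64)
        else:
            self.counts = np.asarray(self.counts, dtype=np.int64)
            if self.counts.shape != (self.num_classes, self.num_classes):
                raise ValueError(
                    f"counts must be {self.num_classes}x{self.num_classes}, got {self.counts.shape}"
                )
            if np.any(self.counts < 0):
                raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if other.num_classes != self.num_classes:
            raise ValueError("cannot add confusion matrices of different K")
        return ConfusionMatrix(self.num_classes, self.counts + other.counts)


def accumulate_confusion(cm: ConfusionMatrix, pred, truth) -> ConfusionMatrix:
    """Add one (pred, truth) label-map pair into ``cm`` (in place)."""
    pred = np.asarray(getattr(pred, "classes", pred)).ravel()
    truth = np.asarray(getattr(truth, "classes", truth)).ravel()
    if pred.shape != truth.shape:
        raise ValueError(f"pred/truth size mismatch: {pred.shape} vs {truth.shape}")
    k = cm.num_classes
    if pred.size and (pred.min() < 0 or pred.max() >= k or truth.min() < 0 or truth.max() >= k):
        raise ValueError(f"labels out of range for K={k}")
    cm.counts += np.bincount(truth * k + pred, minlength=k * k).reshape(k, k)
    return cm


def iou_per_class(cm: ConfusionMatrix, empty_class: str = "one") -> np.ndarray:
    """Per-class IoU from the confusion matrix.

    A class absent from both prediction and truth has an empty union;
    ``empty_class='one'`` scores it 1.0 with a warning (sensible for small
    batches where e.g. no metal occurs), ``'nan'`` marks it for exclusion.
    """
    if cm.total == 0:
        raise UndefinedMetricError("confusion matrix is empty")
    diag = np.diag(cm.counts).astype(np.float64)
    union = cm.counts.sum(axis=0) + cm.counts.sum(axis=1) - diag
    ious = np.empty(cm.num_classes)
    for i in range(cm.num_classes):
        if union[i] == 0:
            if empty_class == "one":
                warnings.warn(
                    f"class {i} absent from prediction and truth; IoU set to 1.0",
                    stacklevel=2,
                )
                ious[i] = 1.0
            else:
                ious[i] = np.nan
        else:
            ious[i] = diag[i] / union[i]
    return ious


def mean_iou(cm: ConfusionMatrix, empty_class: str = "one") -> float:
    """Unweighted mean of per-class IoU."""
    ious = iou_per_class(cm, empty_class=empty_class)
    return float(np.nanmean(ious)) if empty_class == "nan" else float(ious.mean())


def miou_from_class_ious(ious) -> float:
    """Arithmetic mean of already-computed per-class IoU values."""
    ious = np.asarray(ious, dtype=np.float64)
    if ious.size == 0:
        raise ValueError("no class IoUs given")
    return float(ious.mean())


def report_table(rows: dict[str, "list[float]"], class_names=("back", "tooth", "metal")):
    """Render named per-class IoU rows the way segmentation papers print them.

    Values come in as fractions, go out x100 with 2 decimals plus the row
    mean (mIoU); the best value in each column is starred (ties to the
    first row).  Returns ``(text_table, csv_table)``.
    """
    if not rows:
        raise ValueError("no rows to report")
    k = len(class_names)
    table = {}
    for name, vals in rows.items():
        vals = list(vals)
        if len(vals) != k:
            raise ValueError(f"row {name!r} has {len(vals)} entries, expected {k}")
        table[name] = [100.0 * v for v in vals] + [100.0 * miou_from_class_ious(vals)]
    cols = [f"IoU_{c}" for c in class_names] + ["mIoU"]
    data = np.array(list(table.values()))
    best = data.argmax(axis=0)

    name_w = max(len("Method"), *(len(n) for n in table))
    text = io.StringIO()
    text.write("Method".ljust(name_w) + "  " + "  ".join(c.rjust(10) for c in cols) + "\n")
    csv = io.StringIO()
    csv.write("method," + ",".join(cols) + "\n")
    for r, (name, vals) in enumerate(table.items()):
        cells = [
            (f"*{v:.2f}" if best[c] == r else f"{v:.2f}").rjust(10)
            for c, v in enumerate(vals)
        ]
        text.write(name.ljust(name_w) + "  " + "  ".join(cells) + "\n")
        csv.write(name + "," + ",".join(f"{v:.2f}" for v in vals) + "\n")
    return text.getvalue(), csv.getvalue()
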