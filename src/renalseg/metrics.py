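"""Segmentation evaluation: DSC, precision, recall, per-side reports.

Left/right scoring uses a vertical dividing line at the spine: under the
default radiological display convention the patient's anatomical-left
kidney appears on the image right (columns greater than the dividing
column). Per-side metrics are aggregated over slices by pooling pixel
counts (micro-average); a per-slice macro-average is available as well.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ConfusionCounts", "KidneyReport", "confusion", "dsc",
           "precision_recall", "split_left_right", "evaluate"]


@dataclass
class ConfusionCounts:
    """Pixel tallies: tp = kidney correctly predicted, fp = background
    predicted as kidney, fn = kidney predicted as background."""

    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn)

    @property
    def dsc(self) -> float:
        denom = 2 * self.tp + self.fp + self.fn
        return 2 * self.tp / denom if denom else 1.0

    @property
    def precision(self) -> float:
        denom = self.tp + self.fp
        return self.tp / denom if denom else 1.0

    @property
    def recall(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else 1.0


@dataclass
class KidneyReport:
    """Per-side evaluation summary."""

    side: str  # "left" | "right"
    dsc: float
    precision: float
    recall: float
    counts: ConfusionCounts
    n_slices: int


def _check_pair(pred, true):
    pred = np.asarray(pred).astype(bool)
    true = np.asarray(true).astype(bool)
    if pred.shape != true.shape:
        raise ValueError(f"mask shape mismatch: {pred.shape} vs {true.shape}")
    return pred, true


def confusion(pred_mask, true_mask) -> ConfusionCounts:
    """Exact pixel counts of a binary prediction against the reference."""
    pred, true = _check_pair(pred_mask, true_mask)
    return ConfusionCounts(
        tp=int(np.count_nonzero(pred & true)),
        fp=int(np.count_nonzero(pred & ~true)),
        fn=int(np.count_nonzero(~pred & true)),
    )


def dsc(pred_mask, true_mask) -> float:
    """Dice similarity coefficient 2|E∩F| / (|E| + |F|); 1.0 when both empty."""
    pred, true = _check_pair(pred_mask, true_mask)
    denom = int(np.count_nonzero(pred)) + int(np.count_nonzero(true))
    if denom == 0:
        return 1.0
    return 2.0 * np.count_nonzero(pred & true) / denom


def precision_recall(counts: ConfusionCounts) -> tuple[float, float]:
    return counts.precision, counts.recall


def split_left_right(mask, dividing_column: int,
                     convention: str = "radiological"):
    """Split a mask at the spine into (anatomical-left, anatomical-right).

    The dividing column itself is excluded from both sides; OR-ing the two
    halves restores the mask everywhere else. Under ``radiological`` display
    the anatomical left is the image right (columns > dividing column);
    ``neurological`` swaps the naming.
    """
    mask = np.asarray(mask)
    width = mask.shape[-1]
    if not 0 <= dividing_column < width:
        raise ValueError(f"dividing column {dividing_column} outside [0, {width})")
    cols = np.arange(width)
    image_right = np.where(cols > dividing_column, mask, 0)
    image_left = np.where(cols < dividing_column, mask, 0)
    if convention == "radiological":
        return image_right, image_left
    if convention == "neurological":
        return image_left, image_right
    raise ValueError(f"unknown display convention: {convention!r}")


def evaluate(predict, test_samples, dividing_column: int | None = None,
             convention: str = "radiological",
             average: str = "pooled") -> tuple[KidneyReport, KidneyReport]:
    """Score a predictor per side over a test set.

    ``predict`` is a callable mapping a (H, W) image in [0, 1] to a binary
    mask (a model's ``predict_mask`` bound method, or an oracle in tests).
    ``average='pooled'`` pools pixel counts across slices (default);
    ``'macro'`` averages per-slice metrics. The dividing column defaults to
    the image vertical midline.
    """
    test_samples = list(test_samples)
    if not test_samples:
        raise ValueError("empty test set")
    if average not in ("pooled", "macro"):
        raise ValueError("average must be 'pooled' or 'macro'")

    per_side_counts = {"left": ConfusionCounts(), "right": ConfusionCounts()}
    per_side_macro = {"left": [], "right": []}
    for sample in test_samples:
        image = np.asarray(sample.image)
        true = np.asarray(sample.mask).astype(bool)
        div = dividing_column if dividing_column is not None else image.shape[1] // 2
        pred = np.asarray(predict(image)).astype(bool)
        if pred.shape != true.shape:
            raise ValueError("prediction shape differs from mask shape")
        pred_sides = split_left_right(pred, div, convention)
        true_sides = split_left_right(true, div, convention)
        for side, p, t in zip(("left", "right"), pred_sides, true_sides):
            c = confusion(p, t)
            per_side_counts[side] = per_side_counts[side] + c
            per_side_macro[side].append((c.dsc, c.precision, c.recall))

    reports = []
    for side in ("left", "right"):
        counts = per_side_counts[side]
        if average == "pooled":
            d, p, r = counts.dsc, counts.precision, counts.recall
        else:
            d, p, r = (float(np.mean(v)) for v in zip(*per_side_macro[side]))
        reports.append(KidneyReport(side=side, dsc=d, precision=p, recall=r,
                                    counts=counts, n_slices=len(test_samples)))
    return reports[0], reports[1]
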