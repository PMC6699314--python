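"""Dice and IoU evaluation of predicted label maps.

Per class k (RV = 2, myocardium = 3, LV = 4; the background is not scored):

    Dice_k = 2 |Y_k ∩ T_k| / (|Y_k| + |T_k|)
    IoU_k  =   |Y_k ∩ T_k| / |Y_k ∪ T_k|

where Y_k and T_k are the predicted and ground-truth pixel sets of class k.
The two are linked by IoU = Dice / (2 - Dice).  Empty-set rule: when a
class is empty in both prediction and truth the instance is excluded from
the means (configurable to count as 1 instead); when it is empty in
exactly one, the score is 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dataio import LabelMap
from .errors import ContractError

FOREGROUND_CLASSES = (2, 3, 4)
CLASS_NAMES = {2: "RV", 3: "Myocardium", 4: "LV"}

#: Sentinel returned when a class is absent from both masks.
EXCLUDED = None


def _masks(pred: LabelMap | np.ndarray, truth: LabelMap | np.ndarray, k: int):
    p = pred.labels if isinstance(pred, LabelMap) else np.asarray(pred)
    t = truth.labels if isinstance(truth, LabelMap) else np.asarray(truth)
    if p.shape != t.shape:
        raise ContractError(f"prediction shape {p.shape} != truth shape {t.shape}")
    return p == k, t == k


def dice_coefficient(pred, truth, k: int) -> float | None:
    """Dice overlap of class ``k``; ``EXCLUDED`` (None) when both masks are
    empty, 0.0 when exactly one is."""
    yk, tk = _masks(pred, truth, k)
    ny, nt = int(yk.sum()), int(tk.sum())
    if ny == 0 and nt == 0:
        return EXCLUDED
    inter = int((yk & tk).sum())
    return 2.0 * inter / (ny + nt)


def iou(pred, truth, k: int) -> float | None:
    """Intersection-over-union of class ``k`` with the same empty-set rules."""
    yk, tk = _masks(pred, truth, k)
    ny, nt = int(yk.sum()), int(tk.sum())
    if ny == 0 and nt == 0:
        return EXCLUDED
    inter = int((yk & tk).sum())
    return inter / (ny + nt - inter)


@dataclass
class ClassMetrics:
    dice_mean: float
    iou_mean: float
    n_included: int
    n_excluded: int
    dice_values: list[float] = field(default_factory=list)
    iou_values: list[float] = field(default_factory=list)


@dataclass
class MetricsReport:
    """Per-class and mean Dice/IoU over a list of images."""

    per_class: dict[int, ClassMetrics]
    mean_dice: float
    mean_iou: float
    n_images: int
    n_excluded: int

    def to_table(self) -> str:
        lines = ["class\tname\tn\tdice\tiou"]
        for k, cm in sorted(self.per_class.items()):
            lines.append(
                f"{k}\t{CLASS_NAMES.get(k, str(k))}\t{cm.n_included}\t"
                f"{cm.dice_mean:.4f}\t{cm.iou_mean:.4f}"
            )
        lines.append(f"mean\t-\t{self.n_images}\t{self.mean_dice:.4f}\t{self.mean_iou:.4f}")
        return "\n".join(lines)


def evaluate(
    preds: Sequence,
    truths: Sequence,
    classes: Sequence[int] = FOREGROUND_CLASSES,
    empty_rule: str = "exclude",
) -> MetricsReport:
    """Per-image, per-class Dice/IoU aggregated by unweighted means over the
    included entries.

    ``empty_rule`` controls both-empty instances: ``"exclude"`` drops them
    from the means, ``"one"`` scores them as a perfect 1.0.
    """
    if len(preds) == 0 or len(preds) != len(truths):
        raise ContractError("need equal-length, non-empty prediction/truth lists")
    if empty_rule not in ("exclude", "one"):
        raise ContractError(f"unknown empty rule {empty_rule!r}")
    per_class: dict[int, ClassMetrics] = {}
    n_excluded_total = 0
    for k in classes:
        dices, ious, excluded = [], [], 0
        for p, t in zip(preds, truths):
            d = dice_coefficient(p, t, k)
            j = iou(p, t, k)
            if d is EXCLUDED:
                if empty_rule == "one":
                    dices.append(1.0)
                    ious.append(1.0)
                else:
                    excluded += 1
                continue
            dices.append(d)
            ious.append(j)
        n_excluded_total += excluded
        per_class[k] = ClassMetrics(
            dice_mean=float(np.mean(dices)) if dices else float("nan"),
            iou_mean=float(np.mean(ious)) if ious else float("nan"),
            n_included=len(dices),
            n_excluded=excluded,
            dice_values=dices,
            iou_values=ious,
        )
    class_dice = [cm.dice_mean for cm in per_class.values() if cm.n_included > 0]
    class_iou = [cm.iou_mean for cm in per_class.values() if cm.n_included > 0]
    return MetricsReport(
        per_class=per_class,
        mean_dice=float(np.mean(class_dice)) if class_dice else float("nan"),
        mean_iou=float(np.mean(class_iou)) if class_iou else float("nan"),
        n_images=len(preds),
        n_excluded=n_excluded_total,
    )


def mean_foreground_dice(
    pred_batch: np.ndarray, truth_batch: np.ndarray, classes: Sequence[int] = FOREGROUND_CLASSES
) -> float:
    """Fast batched mean Dice over foreground classes for training logs:
    mean over all included (image, class) pairs."""
    if pred_batch.shape != truth_batch.shape:
        raise ContractError("batch shapes differ")
    values = []
    for i in range(pred_batch.shape[0]):
        for k in classes:
            d = dice_coefficient(pred_batch[i], truth_batch[i], k)
            if d is not EXCLUDED:
                values.append(d)
    return float(np.mean(values)) if values else float("nan")
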