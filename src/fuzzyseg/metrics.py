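"""Segmentation evaluation: binary area metrics and multi-class IoU.

Binary metrics compare the predicted pixel set ``Ar`` with the ground-truth
set ``Am``::

    TPR = |Ar n Am| / |Am|            FPR = |Ar \\ Am| / |Am|
    JI  = |Ar n Am| / |Ar u Am|       DSC = 2|Ar n Am| / (|Ar| + |Am|)
    AER = (|Ar u Am| - |Ar n Am|) / |Am|

FPR and AER are normalized by the ground-truth area, so both can exceed 1.
Multi-class IoU accumulates per-class intersection/union counts over a whole
split before dividing (dataset-level convention, stable for images missing a
class); mIoU is the unweighted mean over classes, background included.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CLASS_NAMES = ("background", "fat", "mammary", "muscle", "tumor")
# Display palette: background black, fat green, mammary yellow, muscle blue, tumor red.
CLASS_PALETTE = ((0, 0, 0), (0, 255, 0), (255, 255, 0), (0, 0, 255), (255, 0, 0))

__all__ = ["CLASS_NAMES", "CLASS_PALETTE", "BinaryAreaMetrics", "binary_area_metrics",
           "MulticlassIoU", "MetricsReport", "aggregate_folds"]


class UndefinedMetricError(ValueError):
    """Raised when a ratio's denominator (the ground-truth area) is empty."""


@dataclass
class BinaryAreaMetrics:
    tpr: float
    fpr: float
    ji: float
    dsc: float
    aer: float

    def as_dict(self) -> dict[str, float]:
        return {"TPR": self.tpr, "FPR": self.fpr, "JI": self.ji, "DSC": self.dsc, "AER": self.aer}


def binary_area_metrics(pred_mask: np.ndarray, gt_mask: np.ndarray) -> BinaryAreaMetrics:
    """Area-overlap ratios between a predicted and a ground-truth binary mask."""
    pred = np.asarray(pred_mask).astype(bool)
    gt = np.asarray(gt_mask).astype(bool)
    if pred.shape != gt.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {gt.shape}")
    am = int(gt.sum())
    if am == 0:
        raise UndefinedMetricError("ground-truth mask is empty; area ratios are undefined")
    inter = int((pred & gt).sum())
    union = int((pred | gt).sum())
    ar = int(pred.sum())
    return BinaryAreaMetrics(
        tpr=inter / am,
        fpr=(union - am) / am,
        ji=inter / union if union else 1.0,
        dsc=2 * inter / (ar + am),
        aer=(union - inter) / am,
    )


class MulticlassIoU:
    """Accumulates per-class intersection/union counts across images."""

    def __init__(self, num_classes: int):
        self.num_classes = num_classes
        self.intersection = np.zeros(num_classes, dtype=np.int64)
        self.union = np.zeros(num_classes, dtype=np.int64)

    def update(self, pred: np.ndarray, gt: np.ndarray) -> "MulticlassIoU":
        pred = np.asarray(pred)
        gt = np.asarray(gt)
        if pred.shape != gt.shape:
            raise ValueError(f"mask shapes differ: {pred.shape} vs {gt.shape}")
        for c in range(self.num_classes):
            p = pred == c
            g = gt == c
            self.intersection[c] += int((p & g).sum())
            self.union[c] += int((p | g).sum())
        return self

    def per_class_iou(self) -> np.ndarray:
        """IoU per class; NaN (with a warning) where a class never occurs."""
        iou = np.full(self.num_classes, np.nan)
        present = self.union > 0
        iou[present] = self.intersection[present] / self.union[present]
        absent = np.flatnonzero(~present)
        if absent.size:
            warnings.warn(f"classes {absent.tolist()} absent from both prediction and "
                          "ground truth; their IoU is undefined and excluded from mIoU",
                          stacklevel=2)
        return iou

    def miou(self) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return float(np.nanmean(self.per_class_iou()))


@dataclass
class MetricsReport:
    """Evaluation summary for one split/fold.

    ``per_image`` holds one row per image (binary tumor-area metrics where a
    tumor is present); the IoU fields are dataset-level accumulations.
    """

    per_class_iou: np.ndarray
    miou: float
    tpr: float = np.nan
    fpr: float = np.nan
    ji: float = np.nan
    dsc: float = np.nan
    aer: float = np.nan
    n_images: int = 0
    n_excluded_empty_gt: int = 0
    per_image: pd.DataFrame | None = field(default=None, repr=False)

    def summary(self) -> dict:
        return {
            "mIoU": self.miou,
            "per_class_IoU": {CLASS_NAMES[i] if i < len(CLASS_NAMES) else str(i): float(v)
                              for i, v in enumerate(self.per_class_iou)},
            "TPR": self.tpr, "FPR": self.fpr, "JI": self.ji, "DSC": self.dsc, "AER": self.aer,
            "n_images": self.n_images,
            "n_excluded_empty_gt": self.n_excluded_empty_gt,
        }

    def write(self, out_dir, stem: str = "metrics") -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / f"{stem}.json").write_text(json.dumps(self.summary(), indent=2))
        if self.per_image is not None:
            self.per_image.to_csv(out_dir / f"{stem}_per_image.csv", index=False)


def evaluate_masks(preds: list[np.ndarray], gts: list[np.ndarray], num_classes: int,
                   tumor_class: int = 4) -> MetricsReport:
    """Score a list of predicted masks against ground truths.

    Binary tumor-area metrics are averaged per image; images whose ground
    truth contains no tumor are excluded from that average (the denominator
    is the tumor area) and counted in ``n_excluded_empty_gt``.
    """
    acc = MulticlassIoU(num_classes)
    rows = []
    excluded = 0
    for i, (p, g) in enumerate(zip(preds, gts)):
        acc.update(p, g)
        if (g == tumor_class).any():
            m = binary_area_metrics(p == tumor_class, g == tumor_class)
            rows.append({"image": i, **m.as_dict()})
        else:
            excluded += 1
    if excluded:
        logger.info("excluded %d images with empty tumor ground truth from area metrics", excluded)
    df = pd.DataFrame(rows)
    means = df[["TPR", "FPR", "JI", "DSC", "AER"]].mean() if len(df) else None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        per_class = acc.per_class_iou()
    return MetricsReport(
        per_class_iou=per_class,
        miou=acc.miou(),
        tpr=float(means["TPR"]) if means is not None else np.nan,
        fpr=float(means["FPR"]) if means is not None else np.nan,
        ji=float(means["JI"]) if means is not None else np.nan,
        dsc=float(means["DSC"]) if means is not None else np.nan,
        aer=float(means["AER"]) if means is not None else np.nan,
        n_images=len(preds),
        n_excluded_empty_gt=excluded,
        per_image=df,
    )


def aggregate_folds(reports: list[MetricsReport]) -> MetricsReport:
    """Unweighted mean of every metric across folds."""
    if not reports:
        raise ValueError("need at least one fold report")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        per_class = np.nanmean(np.stack([r.per_class_iou for r in reports]), axis=0)
    mean = lambda attr: float(np.nanmean([getattr(r, attr) for r in reports]))
    return MetricsReport(
        per_class_iou=per_class,
        miou=mean("miou"),
        tpr=mean("tpr"), fpr=mean("fpr"), ji=mean("ji"), dsc=mean("dsc"), aer=mean("aer"),
        n_images=sum(r.n_images for r in reports),
        n_excluded_empty_gt=sum(r.n_excluded_empty_gt for r in reports),
    )
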