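"""Segmentation evaluation: pixel metrics and seedling-count agreement.

Per image, predicted and ground-truth binary masks give a pixel
confusion (TP, FP, FN, TN) from which

    Dice = 2TP / (2TP + FP + FN)
    IoU  = TP / (TP + FP + FN)
    FPR  = FP / (FP + TN)

are computed; batch-level mDice/mIoU/mFPR are unweighted means over
images.  Conventions keep batch means defined on plant-free images: an
empty-vs-empty comparison scores Dice = IoU = 1 (flagged), and FPR is
undefined (flagged, excluded from the mean with a logged count) when an
image has no true background.

Counting accuracy is summarized by ordinary least squares of predicted
on true counts and its coefficient of determination R².
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PixelConfusion",
    "ImageMetrics",
    "CountRegression",
    "confusion",
    "dice_iou_fpr",
    "mean_metrics",
    "count_regression",
    "write_report",
]

logger = logging.getLogger(__name__)


@dataclass
class PixelConfusion:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class ImageMetrics:
    dice: float
    iou: float
    fpr: float  # NaN when undefined
    empty_convention: bool = False
    fpr_undefined: bool = False


@dataclass
class CountRegression:
    pairs: list[tuple[float, float]]
    slope: float
    intercept: float
    r2: float


def confusion(pred_mask: np.ndarray, truth_mask: np.ndarray) -> PixelConfusion:
    """Pixel-level confusion counts; masks must share dimensions."""
    pred = np.asarray(pred_mask, dtype=bool)
    truth = np.asarray(truth_mask, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(
            f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    tp = int(np.logical_and(pred, truth).sum())
    fp = int(np.logical_and(pred, ~truth).sum())
    fn = int(np.logical_and(~pred, truth).sum())
    tn = int(np.logical_and(~pred, ~truth).sum())
    return PixelConfusion(tp=tp, fp=fp, fn=fn, tn=tn)


def dice_iou_fpr(c: PixelConfusion) -> ImageMetrics:
    """Per-image Dice, IoU and FPR with degenerate-case conventions."""
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:  # empty prediction vs empty truth
        logger.info("empty-vs-empty image: Dice = IoU = 1 by convention")
        dice, iou, empty = 1.0, 1.0, True
    else:
        dice = 2 * c.tp / denom
        iou = c.tp / (c.tp + c.fp + c.fn)
        empty = False
    if c.fp + c.tn == 0:
        logger.info("no true background pixels: FPR undefined")
        fpr, fpr_undef = float("nan"), True
    else:
        fpr, fpr_undef = c.fp / (c.fp + c.tn), False
    return ImageMetrics(dice=dice, iou=iou, fpr=fpr,
                        empty_convention=empty, fpr_undefined=fpr_undef)


def mean_metrics(batch: list[ImageMetrics]) -> tuple[float, float, float]:
    """Unweighted per-image means (mDice, mIoU, mFPR).

    Flagged-undefined FPR entries are excluded from the FPR mean with a
    logged count; mFPR is NaN if every entry was undefined.
    """
    if not batch:
        raise ValueError("empty batch")
    mdice = float(np.mean([m.dice for m in batch]))
    miou = float(np.mean([m.iou for m in batch]))
    defined = [m.fpr for m in batch if not m.fpr_undefined]
    n_excluded = len(batch) - len(defined)
    if n_excluded:
        logger.info("mFPR excludes %d undefined image(s)", n_excluded)
    mfpr = float(np.mean(defined)) if defined else float("nan")
    return mdice, miou, mfpr


def count_regression(pairs: list[tuple[float, float]]) -> CountRegression:
    """OLS of predicted counts on true counts, with R² = 1 − SSres/SStot."""
    if len(pairs) < 3:
        raise ValueError("count regression needs at least 3 image pairs")
    pred = np.array([p[0] for p in pairs], dtype=np.float64)
    true = np.array([p[1] for p in pairs], dtype=np.float64)
    if np.allclose(true, true[0]):
        raise ValueError("true counts are constant; R² undefined")
    res = stats.linregress(true, pred)
    fitted = res.slope * true + res.intercept
    ss_res = float(((pred - fitted) ** 2).sum())
    ss_tot = float(((pred - pred.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return CountRegression(pairs=list(pairs), slope=float(res.slope),
                           intercept=float(res.intercept), r2=r2)


def write_report(out_dir: str | Path,
                 per_image: list[dict],
                 stage_groups: dict[str, list[str]] | None = None,
                 regression: CountRegression | None = None) -> None:
    """Emit the batch metrics CSV and a stage-grouped summary JSON.

    ``per_image`` rows carry image_id, dice, iou, fpr and optionally
    pred_count/true_count; ``stage_groups`` maps a stage name to the
    image ids it contains (a single "all" group is used if omitted).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(per_image)
    df.to_csv(out_dir / "metrics.csv", index=False, float_format="%.6g")

    groups = stage_groups or {"all": [row["image_id"] for row in per_image]}
    summary: dict[str, dict] = {}
    by_id = {row["image_id"]: row for row in per_image}
    for stage, ids in groups.items():
        ms = [ImageMetrics(dice=by_id[i]["dice"], iou=by_id[i]["iou"],
                           fpr=by_id[i].get("fpr", float("nan")),
                           fpr_undefined=not math.isfinite(
                               by_id[i].get("fpr", float("nan"))))
              for i in ids if i in by_id]
        if not ms:
            continue
        mdice, miou, mfpr = mean_metrics(ms)
        summary[stage] = {"mDice": round(mdice, 6), "mIoU": round(miou, 6),
                          "mFPR": None if math.isnan(mfpr) else round(mfpr, 6),
                          "n_images": len(ms)}
    if regression is not None:
        summary["counting"] = {"slope": round(regression.slope, 6),
                               "intercept": round(regression.intercept, 6),
                               "r2": round(regression.r2, 6),
                               "n_images": len(regression.pairs)}
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
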