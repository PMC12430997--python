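"""Segmentation metrics and seedling-count regression over a batch.

Segments ten seeded scenes of varying density with the fallback
backend and summarizes quality the way a field evaluation would:
mDice / mIoU / mFPR over images, plus ordinary least squares of
predicted on true counts with its R².
"""

import numpy as np

import paddyscan as ps
from paddyscan.evaluate import (confusion, count_regression, dice_iou_fpr,
                                mean_metrics)
from paddyscan.segmentation import FallbackBackend
from paddyscan.synthetic import SceneConfig, generate_scene

metrics, pairs = [], []
for i in range(10):
    truth = generate_scene(SceneConfig(seed=i, n_plants=18 + 3 * i))
    img = ps.normalize(truth.image, "unit")
    bmap = ps.multi_otsu_threshold(ps.exgr(img), n_classes=2)
    prompts = ps.components_to_prompts(bmap, min_area=20)
    seg = ps.segment(img, prompts, FallbackBackend(n_classes=2))
    metrics.append(dice_iou_fpr(confusion(seg.union_mask,
                                          truth.label_map > 0)))
    pairs.append((seg.n_instances, truth.counts))

mdice, miou, mfpr = mean_metrics(metrics)
reg = count_regression(pairs)
print(f"mDice {mdice:.4f}   mIoU {miou:.4f}   mFPR {mfpr:.5f}")
print(f"counting: slope {reg.slope:.3f}  intercept {reg.intercept:.2f}  "
      f"R² {reg.r2:.4f}")
# R² near 1 with slope near 1 means predicted stand counts track the
# true planting density across scenes — the practical agronomic check.
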