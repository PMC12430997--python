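"""Optional replication on real UAV imagery with the foundation segmenter.

Reports (does not assert) per-stage segmentation metrics of the full
pipeline — ExGR prompting + point-prompted foundation segmenter —
against user-supplied ground-truth masks, mirroring a stage-wise field
evaluation.  Requires external downloads that are not part of the test
suite: a directory of RGB field images, matching ground-truth masks
(``<image>_labels.png``), and a promptable-segmenter checkpoint (e.g.
the ViT-H checkpoint ``sam_vit_h_4b8939.pth``).

Usage:
    python scripts/replicate_field_eval.py \
        --images data/stage1 --truth data/stage1_masks \
        --checkpoint sam_vit_h_4b8939.pth --out results/stage1
"""

from __future__ import annotations

import argparse
import sys
from pathlib import Path

import numpy as np


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--images", type=Path, required=True,
                        help="directory of RGB field images")
    parser.add_argument("--truth", type=Path, required=True,
                        help="directory of ground-truth mask images")
    parser.add_argument("--checkpoint", type=Path, required=True,
                        help="promptable-segmenter checkpoint file")
    parser.add_argument("--out", type=Path, default=Path("results/replication"))
    args = parser.parse_args()

    missing = [str(p) for p in (args.images, args.truth, args.checkpoint)
               if not p.exists()]
    if missing:
        print("replication inputs not available (external downloads "
              "required):", ", ".join(missing), file=sys.stderr)
        print("nothing to do; the offline test suite does not depend on "
              "this script.", file=sys.stderr)
        return 2

    import imageio.v3 as iio

    import paddyscan as ps
    from paddyscan.evaluate import confusion, dice_iou_fpr, mean_metrics
    from paddyscan.segmentation import foundation_adapter, segment

    backend = foundation_adapter(args.checkpoint)
    metrics = []
    for path in sorted(args.images.glob("*")):
        if path.suffix.lower() not in (".png", ".jpg", ".jpeg", ".tif",
                                       ".tiff"):
            continue
        truth_path = args.truth / f"{path.stem}_labels.png"
        if not truth_path.exists():
            print(f"no ground truth for {path.stem}; skipped")
            continue
        img = ps.normalize(ps.read_image(path), "unit")
        bmap = ps.multi_otsu_threshold(ps.exgr(img), n_classes=3)
        prompts = ps.components_to_prompts(bmap, min_area=20)
        seg = segment(img, prompts, backend)
        truth = np.asarray(iio.imread(truth_path)) > 0
        m = dice_iou_fpr(confusion(seg.union_mask, truth))
        metrics.append(m)
        print(f"{path.stem}: dice={m.dice:.4f} iou={m.iou:.4f} "
              f"fpr={m.fpr:.4f} instances={seg.n_instances}")
    if metrics:
        mdice, miou, mfpr = mean_metrics(metrics)
        print(f"\nmDice={mdice:.4f}  mIoU={miou:.4f}  mFPR={mfpr:.4f} "
              f"over {len(metrics)} image(s)  [reported, not asserted]")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
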