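"""Promptable instance segmentation behind a pluggable backend contract.

Each backend answers one question: *given an image and a single point,
which masks might contain that point, and with what confidence?*  Three
backends exist:

* ``foundation_adapter`` wraps an external promptable foundation
  segmenter (a ViT-H checkpoint queried point-by-point, no fine-tuning).
* :class:`FallbackBackend` is a self-contained classical segmenter —
  flood fill on the ExGR map above the vegetation threshold — so the
  whole pipeline runs offline.
* the synthetic module's oracle backend returns ground truth, for
  pixel-exact end-to-end testing of everything around the segmenter.

:func:`segment` queries the backend once per prompt, keeps one candidate
mask per prompt, then resolves overlaps: masks that mostly coincide
(IoU above ``merge_iou``) are merged into one instance — duplicate
prompts landing in the same plant produce one seedling, not two — while
lightly-overlapping instances split contested pixels by nearest prompt.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Protocol, runtime_checkable

import numpy as np
from scipy import ndimage

from .imaging import RGBImage, exgr
from .prompting import PromptSet, multi_otsu_threshold

__all__ = [
    "ConfigurationError",
    "SegmenterBackend",
    "InstanceSegmentation",
    "segment",
    "FallbackBackend",
    "fallback_segment",
    "foundation_adapter",
]

logger = logging.getLogger(__name__)


class ConfigurationError(RuntimeError):
    """A backend cannot be constructed (missing checkpoint/library)."""


@runtime_checkable
class SegmenterBackend(Protocol):
    """Contract: point-promptable mask proposer.

    ``predict`` returns one or more ``(mask, score)`` candidates for a
    point, each mask H×W boolean and each score in [0, 1].
    """

    name: str
    capabilities: set

    def predict(self, img: RGBImage,
                point: tuple[float, float]) -> list[tuple[np.ndarray, float]]:
        ...


@dataclass
class InstanceSegmentation:
    """Per-image instance label map plus per-instance masks.

    ``label_map`` holds 0 for background and k for instance k; instance
    ids are consecutive 1..K.  ``instances`` carries, per instance, the
    prompt point that produced it and the backend's confidence.  The
    union binary mask (Algorithm-level output ``M``) is derived, not
    stored.
    """

    label_map: np.ndarray
    instances: list[dict] = field(default_factory=list)
    source_id: str = ""

    @property
    def n_instances(self) -> int:
        return len(self.instances)

    @property
    def union_mask(self) -> np.ndarray:
        return self.label_map > 0

    def instance_mask(self, instance_id: int) -> np.ndarray:
        return self.label_map == instance_id

    def counts(self) -> int:
        return self.n_instances


def _pick_candidate(candidates: list[tuple[np.ndarray, float]],
                    point: tuple[float, float],
                    policy: str) -> tuple[np.ndarray, float] | None:
    """Reduce a multimask answer to one candidate.

    ``best_score`` keeps the backend's highest-confidence mask;
    ``smallest`` keeps the smallest-area mask containing the prompt,
    which resists over-segmentation-prone scenes.
    """
    candidates = [(m, s) for m, s in candidates if m.any()]
    if not candidates:
        return None
    if policy == "best_score":
        return max(candidates, key=lambda c: c[1])
    if policy == "smallest":
        r, c = int(round(point[0])), int(round(point[1]))
        containing = [cand for cand in candidates if cand[0][r, c]]
        pool = containing or candidates
        return min(pool, key=lambda cand: cand[0].sum())
    raise ValueError(f"unknown multimask policy {policy!r}")


def _prompt_near_mask(mask: np.ndarray, point: tuple[float, float]) -> bool:
    """True if the prompt pixel is in the mask or within 1 px of it."""
    r, c = int(round(point[0])), int(round(point[1]))
    h, w = mask.shape
    r0, r1 = max(r - 1, 0), min(r + 2, h)
    c0, c1 = max(c - 1, 0), min(c + 2, w)
    return bool(mask[r0:r1, c0:c1].any())


def segment(img: RGBImage, prompts: PromptSet, backend: SegmenterBackend,
            multimask_policy: str = "best_score",
            merge_iou: float = 0.5) -> InstanceSegmentation:
    """Run the backend per prompt and assemble an instance segmentation.

    Per prompt, the backend's candidates are reduced to one mask (see
    ``multimask_policy``); masks not touching their prompt (beyond 1 px,
    an anti-aliased-boundary allowance) are discarded.  Masks with
    pairwise IoU above ``merge_iou`` are merged into a single instance;
    remaining contested pixels go to the instance whose prompt is
    nearest.  Deterministic for fixed inputs.
    """
    h, w = img.shape
    accepted: list[tuple[np.ndarray, tuple[float, float], float]] = []
    for point in prompts.points:
        try:
            candidates = backend.predict(img, point)
        except Exception as exc:
            logger.warning("backend %s failed on prompt %s: %s",
                           getattr(backend, "name", "?"), point, exc)
            continue
        picked = _pick_candidate(candidates, point, multimask_policy)
        if picked is None:
            logger.info("no candidate mask for prompt %s", point)
            continue
        mask, score = picked
        if not _prompt_near_mask(mask, point):
            logger.info("mask does not contain prompt %s; discarded", point)
            continue
        accepted.append((mask.astype(bool), point, float(score)))

    if not accepted:
        return InstanceSegmentation(
            label_map=np.zeros((h, w), dtype=np.int32),
            instances=[], source_id=img.id)

    # union-find merge of near-duplicate masks (IoU > merge_iou)
    n = len(accepted)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    areas = [m.sum() for m, _, _ in accepted]
    for i in range(n):
        for j in range(i + 1, n):
            inter = np.logical_and(accepted[i][0], accepted[j][0]).sum()
            if inter == 0:
                continue
            union = areas[i] + areas[j] - inter
            if union > 0 and inter / union > merge_iou:
                parent[find(j)] = find(i)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    merged: list[tuple[np.ndarray, tuple[float, float], float]] = []
    for root in sorted(groups, key=lambda r: min(groups[r])):
        members = groups[root]
        mask = np.zeros((h, w), dtype=bool)
        for i in members:
            mask |= accepted[i][0]
        first = min(members)
        score = max(accepted[i][2] for i in members)
        merged.append((mask, accepted[first][1], score))

    # contested pixels (light overlap) go to the nearest prompt
    label_map = np.zeros((h, w), dtype=np.int32)
    coverage = np.zeros((h, w), dtype=np.int32)
    for mask, _, _ in merged:
        coverage += mask
    rows, cols = np.nonzero(coverage > 0)
    best_dist = np.full(rows.shape, np.inf)
    for k, (mask, point, _) in enumerate(merged, start=1):
        inside = mask[rows, cols]
        dist = np.hypot(rows - point[0], cols - point[1])
        take = inside & (dist < best_dist)
        best_dist[take] = dist[take]
        label_map[rows[take], cols[take]] = k

    # renumber consecutively, dropping instances emptied by the split
    instances = []
    new_map = np.zeros_like(label_map)
    next_id = 1
    for k, (mask, point, score) in enumerate(merged, start=1):
        final = label_map == k
        if not final.any():
            logger.info("instance from prompt %s lost all pixels", point)
            continue
        new_map[final] = next_id
        instances.append({"instance_id": next_id, "prompt": point,
                          "score": score})
        next_id += 1

    return InstanceSegmentation(label_map=new_map, instances=instances,
                                source_id=img.id)


# --------------------------------------------------------------------------
# classical fallback backend


def fallback_segment(img: RGBImage, point: tuple[float, float],
                     threshold: float | None = None,
                     max_radius: int | None = None,
                     n_classes: int = 2,
                     snap_radius: int = 5) -> tuple[np.ndarray, float]:
    """Region-grow a seedling mask from a seed point on the ExGR map.

    Pixels with ExGR at or above the vegetation threshold (multi-Otsu on
    this image's ExGR if not given) are flood-filled 8-connected from the
    seed, optionally clipped to ``max_radius`` around it.  A sub-threshold
    seed snaps to the nearest above-threshold pixel within ``snap_radius``
    px; failing that, an empty mask with score 0 is returned.  The score
    is the region's mean ExGR rescaled to [0, 1] by the image's ExGR
    range.
    """
    index = exgr(img)
    if threshold is None:
        threshold = multi_otsu_threshold(index, n_classes=n_classes).thresholds[-1]
    veg = index.values >= threshold
    h, w = veg.shape
    r, c = int(round(point[0])), int(round(point[1]))
    r = min(max(r, 0), h - 1)
    c = min(max(c, 0), w - 1)
    if not veg[r, c]:
        rr, cc = np.nonzero(veg)
        if rr.size == 0:
            return np.zeros_like(veg), 0.0
        d2 = (rr - r) ** 2 + (cc - c) ** 2
        k = int(np.argmin(d2))
        if d2[k] > snap_radius ** 2:
            return np.zeros_like(veg), 0.0
        r, c = int(rr[k]), int(cc[k])
    if max_radius is not None:
        yy, xx = np.ogrid[:h, :w]
        veg = veg & ((yy - r) ** 2 + (xx - c) ** 2 <= max_radius ** 2)
    labeled, _ = ndimage.label(veg, structure=np.ones((3, 3), dtype=int))
    mask = labeled == labeled[r, c]
    vmin, vmax = index.values.min(), index.values.max()
    span = vmax - vmin
    score = float((index.values[mask].mean() - vmin) / span) if span > 0 else 1.0
    return mask, min(max(score, 0.0), 1.0)


class FallbackBackend:
    """Offline classical backend: thresholded-ExGR flood fill per prompt.

    Caches the per-image ExGR map and its multi-Otsu vegetation threshold
    so repeated prompts on one image are cheap.
    """

    name = "fallback"
    capabilities = {"point_prompt"}

    def __init__(self, n_classes: int = 2, max_radius: int | None = None,
                 snap_radius: int = 5):
        self.n_classes = n_classes
        self.max_radius = max_radius
        self.snap_radius = snap_radius
        # single-entry cache holding the image itself: identity keyed on
        # the live object, never on a reusable address
        self._last: tuple[RGBImage, float] | None = None

    def _threshold(self, img: RGBImage) -> float:
        if self._last is None or self._last[0] is not img:
            index = exgr(img)
            self._last = (img, multi_otsu_threshold(
                index, n_classes=self.n_classes).thresholds[-1])
        return self._last[1]

    def predict(self, img: RGBImage,
                point: tuple[float, float]) -> list[tuple[np.ndarray, float]]:
        mask, score = fallback_segment(
            img, point, threshold=self._threshold(img),
            max_radius=self.max_radius, snap_radius=self.snap_radius)
        return [(mask, score)]


# --------------------------------------------------------------------------
# foundation-model adapter


def foundation_adapter(checkpoint_path: str | Path,
                       model_type: str = "vit_h") -> SegmenterBackend:
    """Wrap an external promptable foundation segmenter as a backend.

    Requires the ``segment-anything`` library and a matching checkpoint
    (the zero-shot ViT-H predictor is queried per point prompt with
    multimask output; no fine-tuning).  Raises
    :class:`ConfigurationError` naming the offline fallback when the
    library or checkpoint is unavailable.
    """
    checkpoint_path = Path(checkpoint_path)
    if not checkpoint_path.exists():
        raise ConfigurationError(
            f"segmenter checkpoint not found: {checkpoint_path}; "
            "use the 'fallback' backend for offline runs"
        )
    try:
        import torch  # noqa: F401
        from segment_anything import SamPredictor, sam_model_registry
    except ImportError as exc:
        raise ConfigurationError(
            "the 'segment-anything' library (and torch) is not installed; "
            "use the 'fallback' backend for offline runs"
        ) from exc

    try:
        sam = sam_model_registry[model_type](checkpoint=str(checkpoint_path))
    except Exception as exc:
        raise ConfigurationError(
            f"could not load checkpoint {checkpoint_path} as {model_type}: {exc}"
        ) from exc
    if torch.cuda.is_available():  # pragma: no cover - hardware specific
        sam = sam.to("cuda")
    else:
        logger.warning("no GPU available; foundation segmenter runs on CPU")
    predictor = SamPredictor(sam)

    class _FoundationBackend:
        name = "foundation"
        capabilities = {"point_prompt"}

        def __init__(self) -> None:
            self._current_image: RGBImage | None = None

        def predict(self, img: RGBImage, point):
            if self._current_image is not img:
                arr = img.pixels if img.scale == "uint8" else img.pixels * 255
                predictor.set_image(arr.astype(np.uint8))
                self._current_image = img
            xy = np.array([[point[1], point[0]]])  # predictor wants (x, y)
            masks, scores, _ = predictor.predict(
                point_coords=xy, point_labels=np.array([1]),
                multimask_output=True)
            out = [(m.astype(bool), float(np.clip(s, 0, 1)))
                   for m, s in zip(masks, scores)]
            return out

    return _FoundationBackend()
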