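"""Point-prompt generation from a vegetation-index map.

The automatic prompting stage turns an ExGR map into one hint point per
candidate seedling: multi-Otsu thresholding isolates the most-vegetated
intensity class, connected-component analysis finds candidate plants,
and each surviving component contributes its bounding box and the box's
geometric center as a point prompt for the promptable segmenter.

Coordinates are (row, col), 0-based.  Boxes are half-open on their max
edges; prompt points use the pixel-center convention, so the center of a
component spanning rows 10–14 is row 12.0.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.filters import threshold_multiotsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .imaging import IndexMap

__all__ = [
    "BinaryMap",
    "PromptSet",
    "multi_otsu_threshold",
    "components_to_prompts",
]


@dataclass
class BinaryMap:
    """Candidate-vegetation mask with the thresholds that produced it."""

    mask: np.ndarray
    thresholds: list[float]
    n_classes: int
    source_id: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class PromptSet:
    """Per-image bounding boxes and center-point prompts.

    ``boxes[i]`` is ``(row_min, col_min, row_max, col_max)`` half-open on
    the max edges; ``points[i]`` is the real-valued (row, col) center of
    that box and always lies inside it.
    """

    boxes: list[tuple[int, int, int, int]] = field(default_factory=list)
    points: list[tuple[float, float]] = field(default_factory=list)
    component_ids: list[int] = field(default_factory=list)
    source_id: str = ""

    def __post_init__(self) -> None:
        if not (len(self.boxes) == len(self.points) == len(self.component_ids)):
            raise ValueError("boxes, points and component_ids must align")
        for box, pt in zip(self.boxes, self.points):
            r0, c0, r1, c1 = box
            if not (r0 <= pt[0] < r1 and c0 <= pt[1] < c1):
                raise ValueError(f"point {pt} outside its box {box}")

    def __len__(self) -> int:
        return len(self.boxes)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["component_id", "row_min", "col_min", "row_max",
                        "col_max", "point_row", "point_col"])
            for cid, box, pt in zip(self.component_ids, self.boxes, self.points):
                w.writerow([cid, *box, f"{pt[0]:.6g}", f"{pt[1]:.6g}"])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "source_id": self.source_id,
            "prompts": [
                {"component_id": cid, "box": list(box), "point": list(pt)}
                for cid, box, pt in zip(self.component_ids, self.boxes,
                                        self.points)
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PromptSet":
        payload = json.loads(Path(path).read_text())
        prompts = payload["prompts"]
        return cls(
            boxes=[tuple(p["box"]) for p in prompts],
            points=[tuple(p["point"]) for p in prompts],
            component_ids=[p["component_id"] for p in prompts],
            source_id=payload.get("source_id", ""),
        )


def multi_otsu_threshold(index: IndexMap, n_classes: int = 3,
                         nbins: int = 256) -> BinaryMap:
    """Threshold an index map into ``n_classes`` and keep the top class.

    The real-valued index is binned into ``nbins`` equal-width bins over
    its observed range; the ``n_classes − 1`` thresholds maximize the
    between-class variance of that histogram.  The returned mask marks
    ``index >= highest threshold`` — the most-vegetated class.
    """
    if n_classes not in (2, 3, 4):
        raise ValueError(f"n_classes must be 2, 3 or 4, got {n_classes}")
    values = index.values
    if np.unique(values).size < n_classes:
        raise ValueError(
            f"index map has fewer than {n_classes} distinct values; "
            "degenerate input — try n_classes=2 or check the image"
        )
    try:
        thresholds = threshold_multiotsu(values, classes=n_classes,
                                         nbins=nbins)
    except ValueError as exc:
        raise ValueError(
            f"multi-Otsu with {n_classes} classes failed ({exc}); "
            "try n_classes=2"
        ) from exc
    mask = values >= thresholds[-1]
    return BinaryMap(mask=mask, thresholds=[float(t) for t in thresholds],
                     n_classes=n_classes, source_id=index.source_id)


def components_to_prompts(bmap: BinaryMap, min_area: int = 20,
                          connectivity: int = 8,
                          center: str = "box") -> PromptSet:
    """Connected components → bounding boxes and center-point prompts.

    Components smaller than ``min_area`` pixels are discarded (sensor
    noise at typical UAV resolutions).  ``center="box"`` uses the
    bounding-box geometric center (the pipeline default); ``"centroid"``
    uses the component's pixel centroid.  Components are ordered by
    (row_min, col_min) so prompt ids are deterministic.

    An empty mask yields an empty prompt set — a valid zero-seedling
    observation, not an error.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    if center not in ("box", "centroid"):
        raise ValueError("center must be 'box' or 'centroid'")
    labeled = cc_label(bmap.mask, connectivity=1 if connectivity == 4 else 2)
    entries = []
    for region in regionprops(labeled):
        if region.area < min_area:
            continue
        r0, c0, r1, c1 = region.bbox
        if center == "box":
            pt = ((r0 + r1 - 1) / 2.0, (c0 + c1 - 1) / 2.0)
        else:
            pt = tuple(region.centroid)
        entries.append(((r0, c0, r1, c1), pt))
    entries.sort(key=lambda e: (e[0][0], e[0][1]))
    return PromptSet(
        boxes=[e[0] for e in entries],
        points=[e[1] for e in entries],
        component_ids=list(range(1, len(entries) + 1)),
        source_id=bmap.source_id,
    )
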