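"""Seeded synthetic paddy scenes with ground truth.

The generator emulates what the segmentation-and-health pipeline
actually consumes from a nadir UAV view of a rice field: green,
roughly-elliptical plants with leaf-like lobes on a quasi-regular
planting grid, over a textured soil or flooded background, across three
growth stages of increasing size, density and overlap.  It is not a
radiative or 3-D plant model — it controls exactly the cues the
pipeline uses (vegetation-index contrast, shape, texture) and provides
exact instance ground truth, counts and planted anomalies.

Anomalous plants emulate stressed seedlings: hue shifted toward
yellow/brown (default (+25, −12, 0) channel units against a healthy
inter-plant colour jitter of sd 6 — a shift of several sd), undersized
(default half the linear size), with a rougher boundary.

All randomness flows from one seed through named substreams
(placement, shape, colour, anomaly choice, background, noise), and
every substream consumes a fixed number of draws regardless of the
stage parameters — so the three stages of a series share the planting
grid, per-plant identities and anomaly choices exactly.

Ground-truth occupancy is the pre-noise alpha ≥ 0.5 region of each
plant; where plants overlap, the later-drawn plant owns the contested
pixels, which defines the counting truth at the mature stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import gaussian_filter

from .imaging import RGBImage
from .segmentation import InstanceSegmentation

__all__ = [
    "STAGE_PRESETS",
    "AnomalySpec",
    "SceneConfig",
    "SceneTruth",
    "generate_scene",
    "stage_series",
    "oracle_backend",
    "truth_segmentation",
    "write_scene",
]

#: growth-stage presets: radius (mean, sd) in px and overlap probability,
#: non-decreasing early → mid → mature
STAGE_PRESETS = {
    "early": {"radius": (12.0, 1.0), "overlap_prob": 0.0},
    "mid": {"radius": (16.0, 1.5), "overlap_prob": 0.15},
    "mature": {"radius": (20.0, 2.0), "overlap_prob": 0.35},
}

_HEALTHY_RGB = np.array([62.0, 142.0, 58.0])  # healthy canopy, uint8 units
_COLOR_JITTER_SD = 6.0                        # per-plant, per-channel
_SOIL_RGB = np.array([120.0, 92.0, 62.0])
_FLOOD_RGB = np.array([58.0, 66.0, 80.0])


@dataclass
class AnomalySpec:
    """How a planted anomaly differs from a healthy plant.

    ``hue_shift`` is added to the plant's (R, G, B) in uint8 channel
    units; ``size_factor`` scales the linear radius; ``boundary_roughness``
    is the relative amplitude of radial boundary noise; ``mottle`` is the
    relative amplitude of intra-plant chlorotic/necrotic speckling, the
    texture signature of leaf stress.
    """

    hue_shift: tuple[float, float, float] = (35.0, -20.0, 5.0)
    size_factor: float = 0.5
    boundary_roughness: float = 0.15
    mottle: float = 0.35


@dataclass
class SceneConfig:
    image_size: tuple[int, int] = (384, 384)
    stage: str = "early"
    n_plants: int = 40
    grid_jitter: float = 2.0
    plant_radius: tuple[float, float] | None = None  # None → stage preset
    overlap_prob: float | None = None                # None → stage preset
    background: str = "soil"
    anomaly_fraction: float = 0.05
    anomaly_spec: AnomalySpec = field(default_factory=AnomalySpec)
    noise_sd: float = 2.0
    seed: int = 0

    def resolved_radius(self) -> tuple[float, float]:
        return self.plant_radius or STAGE_PRESETS[self.stage]["radius"]

    def resolved_overlap(self) -> float:
        if self.overlap_prob is not None:
            return self.overlap_prob
        return STAGE_PRESETS[self.stage]["overlap_prob"]


@dataclass
class SceneTruth:
    image: RGBImage
    label_map: np.ndarray
    counts: int
    anomaly_ids: set[int]
    plants: list[dict]
    config: SceneConfig


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    names = ["placement", "shape", "color", "anomaly", "background", "noise"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.Generator(np.random.PCG64(c))
            for n, c in zip(names, children)}


def _grid_layout(n: int, h: int, w: int) -> tuple[int, int]:
    rows = max(int(np.floor(np.sqrt(n * h / w))), 1)
    cols = int(np.ceil(n / rows))
    return rows, cols


def _boundary_radius(theta: np.ndarray, rad: float, lobes: int,
                     phase: float, sharpness: float, core: float,
                     rough_coeffs: np.ndarray, roughness: float) -> np.ndarray:
    """Polar boundary of a lobed plant: a solid core with ``lobes``
    leaf-like petals, optionally perturbed by smooth radial noise."""
    petals = np.abs(np.cos(lobes * (theta - phase) / 2.0)) ** sharpness
    r = rad * (core + (1.0 - core) * petals)
    if roughness > 0:
        noise = np.zeros_like(theta)
        for k, (a, p) in enumerate(rough_coeffs, start=2):
            noise += a * np.cos(k * theta + p)
        noise /= max(len(rough_coeffs), 1) ** 0.5
        r = r * np.clip(1.0 + roughness * noise, 0.4, 1.6)
    return r


def generate_scene(cfg: SceneConfig) -> SceneTruth:
    """Render one scene; bit-identical for a fixed config and seed."""
    h, w = cfg.image_size
    n = cfg.n_plants
    rng = _substreams(cfg.seed)
    rad_mean, rad_sd = cfg.resolved_radius()
    overlap_prob = cfg.resolved_overlap()

    rows, cols = _grid_layout(n, h, w)
    sy, sx = h / rows, w / cols
    max_extent = rad_mean + 3.0 * rad_sd
    if min(sy, sx) < 2.0 * rad_mean and overlap_prob == 0.0:
        max_n = int(h // (2 * rad_mean)) * int(w // (2 * rad_mean))
        raise ValueError(
            f"{n} plants of radius ~{rad_mean} cannot fit without overlap in "
            f"{h}x{w}; at most {max_n} are feasible"
        )

    # -- placement substream: fixed draw count, independent of stage params
    pr = rng["placement"]
    jitter = pr.normal(0.0, cfg.grid_jitter, size=(n, 2))
    overlap_u = pr.uniform(size=n)
    neighbor_angle = pr.uniform(0.0, 2 * np.pi, size=n)

    centers = np.empty((n, 2))
    for i in range(n):
        r_i, c_i = divmod(i, cols)
        cy = (r_i + 0.5) * sy + jitter[i, 0]
        cx = (c_i + 0.5) * sx + jitter[i, 1]
        if overlap_u[i] < overlap_prob:
            # pull toward a neighbouring row/column to create overlap
            cy += 0.45 * sy * np.sin(neighbor_angle[i])
            cx += 0.45 * sx * np.cos(neighbor_angle[i])
        centers[i] = (np.clip(cy, max_extent, h - 1 - max_extent),
                      np.clip(cx, max_extent, w - 1 - max_extent))

    # -- shape substream
    sr = rng["shape"]
    # truncated at ±2 sd: transplanted seedlings are size-graded, so
    # extreme-tail plant sizes are unrealistic
    # transplanted seedlings are fairly uniform rosettes: narrow draws
    radius_u = np.clip(sr.normal(0.0, 1.0, size=n), -2.0, 2.0)
    lobes = sr.integers(5, 7, size=n)
    phase = sr.uniform(0.0, 2 * np.pi, size=n)
    sharp = sr.uniform(1.8, 2.2, size=n)
    core = sr.uniform(0.55, 0.62, size=n)
    elong = sr.uniform(0.85, 1.0, size=n)
    orient = sr.uniform(0.0, np.pi, size=n)
    rough_coeffs = sr.normal(0.0, 1.0, size=(n, 4, 2))  # k = 2..5: (amp, phase)
    mottle_seed = sr.integers(0, 2**31, size=n)  # per-plant speckle stream

    # -- colour substream
    cr = rng["color"]
    # clipped at ±1.5 sd: canopy colour variation within one uniformly
    # managed paddy is bounded
    plant_rgb = _HEALTHY_RGB + np.clip(
        cr.normal(0.0, _COLOR_JITTER_SD, size=(n, 3)),
        -1.5 * _COLOR_JITTER_SD, 1.5 * _COLOR_JITTER_SD)

    # -- anomaly substream: a seeded permutation picks the planted anomalies
    ar = rng["anomaly"]
    order = ar.permutation(n)
    n_anom = int(round(cfg.anomaly_fraction * n))
    anomaly_idx = set(int(i) for i in order[:n_anom])

    # -- background
    br = rng["background"]
    base = _SOIL_RGB if cfg.background == "soil" else _FLOOD_RGB
    field_noise = gaussian_filter(br.normal(0.0, 1.0, size=(h, w)), sigma=3.0)
    sd = field_noise.std()
    field_noise = field_noise / sd * 6.0 if sd > 0 else field_noise
    weights = (np.array([1.0, 0.9, 0.8]) if cfg.background == "soil"
               else np.array([0.8, 0.9, 1.0]))
    image = base[None, None, :] + field_noise[..., None] * weights
    if cfg.background == "flooded":
        speckle = br.uniform(size=(h, w)) < 0.01  # specular glints
        image[speckle] += 45.0

    label_map = np.zeros((h, w), dtype=np.int32)
    plants: list[dict] = []
    spec = cfg.anomaly_spec
    for i in range(n):
        anomalous = i in anomaly_idx
        rad = max(rad_mean + radius_u[i] * rad_sd, 2.0)
        roughness = 0.0
        color = plant_rgb[i].copy()
        if anomalous:
            rad *= spec.size_factor
            roughness = spec.boundary_roughness
            color += np.asarray(spec.hue_shift)
        color = np.clip(color, 0.0, 255.0)

        ext = int(np.ceil(rad * 1.3)) + 2
        cy, cx = centers[i]
        r0, r1 = max(int(cy) - ext, 0), min(int(cy) + ext + 1, h)
        c0, c1 = max(int(cx) - ext, 0), min(int(cx) + ext + 1, w)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        dy, dx = yy - cy, xx - cx
        # elongation: rotate into the plant frame, stretch the minor axis
        co, si = np.cos(orient[i]), np.sin(orient[i])
        u = co * dx + si * dy
        v = (-si * dx + co * dy) / elong[i]
        rho = np.hypot(u, v)
        theta = np.arctan2(v, u)
        boundary = _boundary_radius(theta, rad, int(lobes[i]), phase[i],
                                    sharp[i], core[i], rough_coeffs[i],
                                    roughness)
        alpha = np.clip(boundary - rho + 0.5, 0.0, 1.0)
        occupied = alpha >= 0.5
        pixel_color = np.broadcast_to(color[None, None, :],
                                      alpha.shape + (3,)).copy()
        if anomalous and spec.mottle > 0:
            # chlorotic/necrotic speckling: smooth multiplicative
            # brightness field from a per-plant stream (stage-invariant)
            prng = np.random.Generator(np.random.PCG64(int(mottle_seed[i])))
            fieldn = gaussian_filter(prng.normal(size=alpha.shape), sigma=1.5)
            sdn = fieldn.std()
            if sdn > 0:
                fieldn = fieldn / sdn
            pixel_color = np.clip(
                pixel_color * (1.0 + spec.mottle * fieldn[..., None]),
                0.0, 255.0)
        patch = image[r0:r1, c0:c1, :]
        image[r0:r1, c0:c1, :] = (alpha[..., None] * pixel_color
                                  + (1.0 - alpha[..., None]) * patch)
        lm = label_map[r0:r1, c0:c1]
        lm[occupied] = i + 1  # later plant wins contested pixels
        plants.append({"instance_id": i + 1, "center": (float(cy), float(cx)),
                       "radius": float(rad), "anomalous": anomalous,
                       "color": [float(c) for c in color]})

    image += rng["noise"].normal(0.0, cfg.noise_sd, size=image.shape)
    image = np.clip(image, 0.0, 255.0)

    present = set(np.unique(label_map)) - {0}
    counts = len(present)
    anomaly_ids = {i + 1 for i in anomaly_idx if (i + 1) in present}
    img = RGBImage(image, scale="uint8",
                   id=f"scene-{cfg.stage}-seed{cfg.seed}")
    return SceneTruth(image=img, label_map=label_map, counts=counts,
                      anomaly_ids=anomaly_ids, plants=plants, config=cfg)


def stage_series(base_cfg: SceneConfig) -> list[SceneTruth]:
    """The same planted field observed at early, mid and mature stages.

    The series shares the seed, hence the planting grid, per-plant shape
    and colour identities and the anomaly choices; only the stage
    presets (radius, overlap) differ.
    """
    series = []
    for stage in ("early", "mid", "mature"):
        cfg = replace(base_cfg, stage=stage, plant_radius=None,
                      overlap_prob=None)
        series.append(generate_scene(cfg))
    return series


class _OracleBackend:
    """Ground-truth backend: a point returns the true instance mask
    containing it (or the nearest instance within ``snap`` px) with
    score 1.0, else an empty mask with score 0."""

    name = "oracle"
    capabilities = {"point_prompt"}

    def __init__(self, truth: SceneTruth, snap: float = 2.0):
        self.truth = truth
        self.snap = snap

    def predict(self, img, point):
        lm = self.truth.label_map
        h, w = lm.shape
        r = min(max(int(round(point[0])), 0), h - 1)
        c = min(max(int(round(point[1])), 0), w - 1)
        k = lm[r, c]
        if k == 0:
            s = int(np.ceil(self.snap))
            r0, r1 = max(r - s, 0), min(r + s + 1, h)
            c0, c1 = max(c - s, 0), min(c + s + 1, w)
            window = lm[r0:r1, c0:c1]
            ys, xs = np.nonzero(window)
            if ys.size:
                d2 = (ys + r0 - point[0]) ** 2 + (xs + c0 - point[1]) ** 2
                j = int(np.argmin(d2))
                if d2[j] <= self.snap ** 2:
                    k = window[ys[j], xs[j]]
        if k == 0:
            return [(np.zeros_like(lm, dtype=bool), 0.0)]
        return [(lm == k, 1.0)]


def oracle_backend(truth: SceneTruth, snap: float = 2.0) -> _OracleBackend:
    return _OracleBackend(truth, snap=snap)


def truth_segmentation(truth: SceneTruth) -> InstanceSegmentation:
    """The ground-truth label map as an :class:`InstanceSegmentation`
    (consecutively renumbered), for testing the feature/anomaly stages
    in isolation from prompting quality."""
    lm = truth.label_map
    ids = sorted(set(np.unique(lm)) - {0})
    new_map = np.zeros_like(lm)
    instances = []
    for new_id, old in enumerate(ids, start=1):
        new_map[lm == old] = new_id
        center = next(p["center"] for p in truth.plants
                      if p["instance_id"] == old)
        instances.append({"instance_id": new_id, "prompt": center,
                          "score": 1.0, "truth_id": int(old)})
    return InstanceSegmentation(label_map=new_map, instances=instances,
                                source_id=truth.image.id)


def write_scene(truth: SceneTruth, out_dir: str | Path) -> None:
    """Materialize a scene: image PNG, 16-bit label PNG, truth JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = truth.image.id
    iio.imwrite(out_dir / f"{stem}.png",
                np.clip(np.rint(truth.image.pixels), 0, 255).astype(np.uint8))
    iio.imwrite(out_dir / f"{stem}_labels.png",
                truth.label_map.astype(np.uint16))
    cfg = truth.config
    payload = {
        "image": f"{stem}.png",
        "counts": truth.counts,
        "anomaly_ids": sorted(truth.anomaly_ids),
        "config": {
            "image_size": list(cfg.image_size), "stage": cfg.stage,
            "n_plants": cfg.n_plants, "grid_jitter": cfg.grid_jitter,
            "background": cfg.background,
            "anomaly_fraction": cfg.anomaly_fraction,
            "noise_sd": cfg.noise_sd, "seed": cfg.seed,
        },
        "plants": truth.plants,
    }
    (out_dir / f"{stem}_truth.json").write_text(json.dumps(payload, indent=2))
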