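"""Core image types, I/O, channel normalization and vegetation indices.

The pipeline's raw input is a nadir RGB view of a rice paddy.  Vegetation
is emphasised with linear chromatic indices:

* ``ExGR = 3·G − 2.4·R − B`` (excess green minus excess red), used to drive
  prompt generation — it pushes green canopy far above soil and water.
* ``ExG = 2·G − R − B`` (excess green), kept as a per-seedling spectral
  feature.

Indices are computed on whatever channel scale the image carries; the
recommended (and pipeline-default) scale is unit ``[0, 1]``, which keeps
index ranges comparable across 8- and 16-bit sources.  Chromatic
coordinates ``(R,G,B)/(R+G+B)`` are available as an alternative
normalization since both conventions appear in the vegetation-index
literature; downstream thresholding is histogram-driven and therefore
scale-robust either way.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = [
    "RGBImage",
    "IndexMap",
    "read_image",
    "write_image",
    "normalize",
    "exgr",
    "exg",
    "to_gray",
    "write_index",
    "read_index",
]

#: luminance weights (ITU-R BT.601), used for the GLCM grayscale
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class RGBImage:
    """An H×W×3 image with channel order fixed to (Red, Green, Blue).

    ``scale`` declares the value range: ``"uint8"`` for [0, 255] or
    ``"unit"`` for [0, 1].  Pixels are stored as float64 regardless, so
    the vegetation indices are exact linear forms.
    """

    pixels: np.ndarray
    scale: str = "uint8"
    id: str = ""
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(
                f"expected an H×W×3 array, got shape {self.pixels.shape}"
            )
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must be at least 1×1")
        if self.scale not in ("uint8", "unit"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite values")
        if self.pixels.min() < 0 or self.pixels.max() > self.scale_max:
            raise ValueError(
                f"values outside declared {self.scale} range "
                f"[0, {self.scale_max}]"
            )

    @property
    def scale_max(self) -> float:
        return 255.0 if self.scale == "uint8" else 1.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]

    @property
    def red(self) -> np.ndarray:
        return self.pixels[..., 0]

    @property
    def green(self) -> np.ndarray:
        return self.pixels[..., 1]

    @property
    def blue(self) -> np.ndarray:
        return self.pixels[..., 2]


@dataclass
class IndexMap:
    """A per-pixel real-valued vegetation index (or luminance) map."""

    values: np.ndarray
    index_name: str
    source_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError(f"index map must be 2-D, got {self.values.ndim}-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("index map contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def read_image(path: str | Path) -> RGBImage:
    """Read a PNG/JPEG/TIFF into an :class:`RGBImage`.

    8-bit input keeps its [0, 255] values (``scale="uint8"``); 16-bit
    input is rescaled to [0, 1] (``scale="unit"``).  An alpha channel is
    dropped; grayscale input is rejected.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - backend specific
        raise OSError(f"could not read image {path}: {exc}") from exc
    if arr.ndim == 2 or (arr.ndim == 3 and arr.shape[2] == 1):
        raise ValueError(
            f"{path} is grayscale (1 channel); a 3-channel RGB image is required"
        )
    if arr.ndim != 3 or arr.shape[2] not in (3, 4):
        raise ValueError(f"{path}: unsupported channel count {arr.shape[-1]}")
    arr = arr[..., :3]
    if arr.dtype == np.uint8:
        return RGBImage(arr.astype(np.float64), scale="uint8",
                        id=path.stem, bit_depth=8)
    if arr.dtype == np.uint16:
        return RGBImage(arr.astype(np.float64) / 65535.0, scale="unit",
                        id=path.stem, bit_depth=16)
    # float TIFFs: trust a [0,1] range
    arr = arr.astype(np.float64)
    if arr.max() > 1.0:
        raise ValueError(f"{path}: float image with values outside [0, 1]")
    return RGBImage(arr, scale="unit", id=path.stem, bit_depth=32)


def write_image(img: RGBImage, path: str | Path) -> None:
    """Write as 8-bit PNG (unit-scale images are rescaled to 0–255)."""
    arr = img.pixels if img.scale == "uint8" else img.pixels * 255.0
    iio.imwrite(Path(path), np.clip(np.rint(arr), 0, 255).astype(np.uint8))


def normalize(img: RGBImage, mode: str = "unit") -> RGBImage:
    """Channel normalization: ``none`` | ``unit`` | ``chromatic``.

    ``unit`` divides by the scale maximum (idempotent).  ``chromatic``
    maps each pixel to (R,G,B)/(R+G+B), with all-zero pixels mapped to
    (0,0,0).
    """
    if mode == "none":
        return img
    if mode == "unit":
        return RGBImage(img.pixels / img.scale_max, scale="unit",
                        id=img.id, bit_depth=img.bit_depth)
    if mode == "chromatic":
        total = img.pixels.sum(axis=2, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(total > 0, img.pixels / total, 0.0)
        return RGBImage(out, scale="unit", id=img.id, bit_depth=img.bit_depth)
    raise ValueError(f"unknown normalization mode {mode!r}")


def exgr(img: RGBImage) -> IndexMap:
    """Excess-green-minus-excess-red index, ``3G − 2.4R − B`` per pixel."""
    v = 3.0 * img.green - 2.4 * img.red - img.blue
    return IndexMap(v, "ExGR", source_id=img.id)


def exg(img: RGBImage) -> IndexMap:
    """Excess-green index, ``2G − R − B`` per pixel."""
    v = 2.0 * img.green - img.red - img.blue
    return IndexMap(v, "ExG", source_id=img.id)


def to_gray(img: RGBImage) -> IndexMap:
    """BT.601 luminance ``0.299R + 0.587G + 0.114B``, same scale as input."""
    v = img.pixels @ _LUMA
    return IndexMap(v, "gray", source_id=img.id)


def write_index(index: IndexMap, path: str | Path) -> None:
    """Persist an index map as float32 TIFF (``.tif``) or ``.npy``."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, index.values.astype(np.float32))
    elif path.suffix.lower() == ".npy":
        np.save(path, index.values)
    else:
        raise ValueError(f"unsupported index format {path.suffix!r}")


def read_index(path: str | Path, index_name: str = "") -> IndexMap:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        values = tifffile.imread(path)
    elif path.suffix.lower() == ".npy":
        values = np.load(path)
    else:
        raise ValueError(f"unsupported index format {path.suffix!r}")
    return IndexMap(values, index_name or path.stem, source_id=path.stem)
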