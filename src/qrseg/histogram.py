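"""Grayscale images, 3x3 local means, and the 2D intensity/local-mean histogram.

The joint histogram ``h(x, y)`` counts pixels whose intensity is ``x`` and
whose rounded 3x3-neighbourhood mean is ``y``.  It is the empirical joint
distribution of a pixel and its local context, and is the object every
entropy-based threshold criterion in this package operates on.  Axes are
0-based gray levels: rows index intensity ``x``, columns index the local
mean ``y``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

__all__ = [
    "GrayImage",
    "LocalMeanImage",
    "JointHistogram",
    "load_gray_image",
    "local_mean_image",
    "build_joint_histogram",
    "write_histogram_csv",
]

#: ITU-R BT.601 luma weights used to collapse colour inputs.
_LUMA = np.array([0.299, 0.587, 0.114])


def _round_half_up(a: np.ndarray) -> np.ndarray:
    """Round to nearest integer with ties going up (0.5 -> 1)."""
    return np.floor(np.asarray(a, dtype=float) + 0.5)


@dataclass(frozen=True)
class GrayImage:
    """An M x N raster of integer gray levels in ``[0, levels - 1]``."""

    pixels: np.ndarray
    levels: int = 256

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValueError(f"expected a 2D raster, got shape {arr.shape}")
        if arr.size == 0:
            raise ValueError("image has zero area")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.floor(arr)):
                raise ValueError("pixel values must be integers")
        arr = arr.astype(np.int64)
        if self.levels < 1:
            raise ValueError("levels must be positive")
        if arr.min() < 0 or arr.max() > self.levels - 1:
            raise ValueError(
                f"pixel values must lie in [0, {self.levels - 1}], "
                f"got range [{arr.min()}, {arr.max()}]"
            )
        object.__setattr__(self, "pixels", arr)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class LocalMeanImage:
    """Rounded 3x3 in-bounds window means of a :class:`GrayImage`."""

    means: np.ndarray
    levels: int = 256

    def __post_init__(self) -> None:
        arr = np.asarray(self.means).astype(np.int64)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("local-mean raster must be a non-empty 2D array")
        object.__setattr__(self, "means", arr)


@dataclass(frozen=True)
class JointHistogram:
    """L x L joint counts ``h(x, y)`` with normalized weights ``w(x, y)``.

    ``weights = counts / total`` where ``total`` is the pixel count, so the
    weights form a probability distribution over the (intensity, local mean)
    grid.
    """

    counts: np.ndarray
    total: int = field(init=False)
    levels: int = field(init=False)
    weights: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts).astype(np.int64)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("histogram counts must be a square matrix")
        if counts.min() < 0:
            raise ValueError("histogram counts must be non-negative")
        total = int(counts.sum())
        if total <= 0:
            raise ValueError("histogram must contain at least one pixel")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "total", total)
        object.__setattr__(self, "levels", counts.shape[0])
        object.__setattr__(self, "weights", counts / total)

    @property
    def intensity_domain(self) -> np.ndarray:
        """Occupied intensity levels S_f (rows with any mass)."""
        return np.flatnonzero(self.counts.sum(axis=1) > 0)

    @property
    def mean_domain(self) -> np.ndarray:
        """Occupied local-mean levels S_g (columns with any mass)."""
        return np.flatnonzero(self.counts.sum(axis=0) > 0)


def load_gray_image(path: str | Path, levels: int = 256) -> GrayImage:
    """Read a raster image from disk as an 8-bit grayscale :class:`GrayImage`.

    Colour inputs are collapsed with BT.601 luma weights; 16-bit inputs are
    rescaled to ``[0, 255]`` by ``round(v * 255 / 65535)``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = iio.imread(path)
    if arr.ndim == 3:
        if arr.shape[2] < 3:
            arr = arr[:, :, 0]
        else:
            arr = _round_half_up(arr[:, :, :3].astype(float) @ _LUMA)
    if arr.ndim != 2:
        raise ValueError(f"cannot interpret {path} as a grayscale raster")
    if arr.size == 0:
        raise ValueError(f"{path} decodes to a zero-area image")
    if arr.dtype == np.uint16 or (np.issubdtype(arr.dtype, np.integer) and arr.max() > 255):
        arr = _round_half_up(arr.astype(float) * 255.0 / 65535.0)
    return GrayImage(pixels=arr.astype(np.int64), levels=levels)


def local_mean_image(img: GrayImage) -> LocalMeanImage:
    """Mean of the in-bounds 3x3 neighbourhood (centre included) per pixel.

    Border pixels average only the neighbours inside the raster: 4 values at
    corners, 6 along edges, 9 in the interior.  Means are rounded half-up so
    they index histogram bins in ``[0, levels - 1]``.
    """
    pix = img.pixels.astype(float)
    kernel = np.ones((3, 3))
    sums = ndimage.correlate(pix, kernel, mode="constant", cval=0.0)
    counts = ndimage.correlate(np.ones_like(pix), kernel, mode="constant", cval=0.0)
    means = _round_half_up(sums / counts).astype(np.int64)
    return LocalMeanImage(means=means, levels=img.levels)


def build_joint_histogram(img: GrayImage, means: LocalMeanImage) -> JointHistogram:
    """Count (intensity, local mean) pairs into an L x L joint histogram."""
    if img.pixels.shape != means.means.shape:
        raise ValueError(
            f"image shape {img.pixels.shape} != local-mean shape {means.means.shape}"
        )
    L = img.levels
    flat = img.pixels.ravel() * L + means.means.ravel()
    counts = np.bincount(flat, minlength=L * L).reshape(L, L)
    return JointHistogram(counts=counts)


def write_histogram_csv(hist: JointHistogram, csv_path: str | Path,
                        sidecar: dict | None = None) -> None:
    """Export counts as an L-row CSV plus a JSON sidecar with {M, N, L, total}.

    ``sidecar`` supplies the image dimensions; the histogram itself only
    knows the pixel total.
    """
    csv_path = Path(csv_path)
    np.savetxt(csv_path, hist.counts, fmt="%d", delimiter=",")
    meta = {"L": hist.levels, "total": hist.total}
    if sidecar:
        meta.update(sidecar)
    csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
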