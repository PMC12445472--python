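"""End-to-end segmentation pipeline.

enhance (optional) -> local means -> joint histogram -> entropy-driven
threshold optimization -> class-mean reconstruction.

Only the row (intensity) thresholds shape the output image: each gray-level
class is replaced by the rounded mean of its member pixels.  The column
(local-mean) thresholds influence the fitness landscape only.  Threshold
``t_i`` closes the lower class, i.e. class ``i`` is
``{f : t_{i-1} < f <= t_i}`` with ``t_0`` below 0 and ``t_{k+1} = L - 1`` —
the same side convention the diagonal-rectangle partition uses, so a
threshold sitting exactly on a populated gray level groups that level with
the rectangle that scored it.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage import exposure

from .entropy import EntropyParams, entropy_objective
from .histogram import GrayImage, build_joint_histogram, local_mean_image
from .optimize import (
    OptimizerConfig,
    OptimizerResult,
    de_optimize,
    exhaustive_search,
    pso_optimize,
)

__all__ = ["SegmentedImage", "apply_thresholds", "segment_image", "enhance_contrast"]

logger = logging.getLogger(__name__)

ENHANCE_STRATEGIES = ("identity", "global_equalization", "clahe")


@dataclass(frozen=True)
class SegmentedImage:
    """Class-mean reconstruction of an image under given row thresholds."""

    pixels: np.ndarray
    class_means: tuple[int, ...]
    class_bounds: tuple[int, ...]
    levels: int = 256

    def as_gray_image(self) -> GrayImage:
        return GrayImage(pixels=self.pixels, levels=self.levels)


def _validate_row_thresholds(thresholds: Sequence[int], levels: int) -> np.ndarray:
    t = np.asarray(list(thresholds), dtype=np.int64)
    if t.size == 0:
        raise ValueError("at least one threshold is required")
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"thresholds must be strictly increasing: {t.tolist()}")
    if t[0] < 1 or t[-1] > levels - 2:
        raise ValueError(f"thresholds must lie in [1, {levels - 2}]: {t.tolist()}")
    return t


def apply_thresholds(img: GrayImage, row_thresholds: Sequence[int]) -> SegmentedImage:
    """Replace each gray-level class by the rounded mean of its members.

    Class ``i`` collects pixels with ``t_{i-1} < f <= t_i`` (first class
    from 0, last class up to ``L - 1``).  Empty classes produce no output
    level.
    """
    t = _validate_row_thresholds(row_thresholds, img.levels)
    pix = img.pixels
    labels = np.searchsorted(t, pix, side="left")
    out = pix.copy()
    means: list[int] = []
    for c in range(t.size + 1):
        mask = labels == c
        if not mask.any():
            continue
        mean = int(np.floor(pix[mask].mean() + 0.5))
        out[mask] = mean
        means.append(mean)
    return SegmentedImage(pixels=out, class_means=tuple(means),
                          class_bounds=tuple(int(x) for x in t), levels=img.levels)


def enhance_contrast(img: GrayImage, strategy: str = "identity") -> GrayImage:
    """Optional pre-segmentation contrast enhancement.

    ``identity`` returns the input unchanged; ``global_equalization`` and
    ``clahe`` apply the standard scikit-image enhancements, rescaled back to
    integer gray levels.  The hook exists so a caller can plug in any
    enhancement front-end before thresholding.
    """
    if strategy == "identity":
        return img
    L = img.levels
    scale = img.pixels.astype(float) / (L - 1) if L > 1 else img.pixels.astype(float)
    if strategy == "global_equalization":
        eq = exposure.equalize_hist(img.pixels, nbins=L)
    elif strategy == "clahe":
        eq = exposure.equalize_adapthist(scale)
    else:
        raise ValueError(f"unknown enhancement strategy {strategy!r}")
    out = np.floor(eq * (L - 1) + 0.5).astype(np.int64)
    return GrayImage(pixels=np.clip(out, 0, L - 1), levels=L)


_OPTIMIZERS = {
    "pso": pso_optimize,
    "de": de_optimize,
}


def segment_image(img: GrayImage, k: int,
                  params: EntropyParams | None = None,
                  config: OptimizerConfig | None = None,
                  method: str = "pso",
                  enhance: str = "identity",
                  exhaustive_cap: int = 10_000_000,
                  ) -> tuple[SegmentedImage, OptimizerResult]:
    """Run the full pipeline and return the segmented image and search result.

    The optimal row thresholds are applied to the image that was actually
    histogrammed (the enhanced image when ``enhance`` is not identity).
    """
    params = params or EntropyParams()
    config = config or OptimizerConfig()
    if method not in ("pso", "de", "exhaustive"):
        raise ValueError(f"unknown optimizer {method!r}")

    t0 = time.perf_counter()
    work = enhance_contrast(img, enhance)
    means = local_mean_image(work)
    hist = build_joint_histogram(work, means)
    t1 = time.perf_counter()
    objective = entropy_objective(hist, params)
    if method == "exhaustive":
        result = exhaustive_search(objective, k, work.levels, cap=exhaustive_cap)
    else:
        result = _OPTIMIZERS[method](objective, k, work.levels, config)
    t2 = time.perf_counter()
    segmented = apply_thresholds(work, result.best_X.rows)
    logger.info(
        "segment_image: method=%s mode=%s k=%d seed=%d enhance=%s "
        "hist=%.3fs search=%.3fs thresholds=%s fitness=%.6g iterations=%d",
        method, params.mode, k, config.seed, enhance,
        t1 - t0, t2 - t1, result.best_X.rows, result.best_fitness,
        result.iterations_used,
    )
    return segmented, result
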