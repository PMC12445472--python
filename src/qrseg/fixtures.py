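"""Synthetic grayscale images and histograms with known class structure.

The generator emulates what 2D-histogram thresholding exploits in real
photographs: spatially coherent regions of near-constant intensity.
Classes are laid out as contiguous horizontal bands (not scattered pixels)
so that 3x3 local means stay informative, with additive rounded Gaussian
noise clipped to the gray range.  Every image carries its ground-truth
label map, which makes threshold-recovery scoring possible: a recovered
threshold is correct when it separates two adjacent true class means.

The defaults — a 128 x 128 raster with class means (60, 128, 200), equal
class fractions and noise sigma 8 — give three well-separated modes
(gaps > 8 sigma) on the histogram diagonal, a regime comparable to the
clean multimodal benchmark photographs this family stands in for.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .histogram import GrayImage, JointHistogram

__all__ = [
    "FixtureSpec",
    "make_piecewise_image",
    "make_uniform_histogram",
    "make_random_histogram",
]


@dataclass(frozen=True)
class FixtureSpec:
    size: tuple[int, int] = (128, 128)
    class_means: tuple[int, ...] = (60, 128, 200)
    class_fractions: tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3)
    noise_sigma: float = 8.0
    seed: int = 0
    levels: int = 256

    def __post_init__(self) -> None:
        if len(self.class_means) != len(self.class_fractions) or not self.class_means:
            raise ValueError("class_means and class_fractions must match and be non-empty")
        means = self.class_means
        if any(b - a < 2 for a, b in zip(means, means[1:])):
            raise ValueError(f"class means must differ by at least 2: {means}")
        if any(m < 0 or m > self.levels - 1 for m in means):
            raise ValueError(f"class means must lie in [0, {self.levels - 1}]")
        if any(f <= 0 for f in self.class_fractions):
            raise ValueError("class fractions must be positive")
        if abs(sum(self.class_fractions) - 1.0) > 1e-9:
            raise ValueError("class fractions must sum to 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


def make_piecewise_image(spec: FixtureSpec) -> tuple[GrayImage, np.ndarray]:
    """Piecewise-constant band image plus its ground-truth label map.

    Rows are allocated to classes proportionally to ``class_fractions``
    (respected to within one row); pixels get the class mean plus rounded
    Gaussian noise, clipped to ``[0, levels - 1]``.
    """
    M, N = spec.size
    L = spec.levels
    rng = np.random.default_rng(spec.seed)
    edges = np.floor(np.cumsum(spec.class_fractions) * M + 0.5).astype(int)
    edges[-1] = M
    labels = np.zeros((M, N), dtype=np.int64)
    base = np.zeros((M, N), dtype=float)
    start = 0
    for cls, stop in enumerate(edges):
        labels[start:stop, :] = cls
        base[start:stop, :] = spec.class_means[cls]
        start = stop
    if spec.noise_sigma > 0:
        base = base + rng.normal(0.0, spec.noise_sigma, size=(M, N))
    pixels = np.clip(np.floor(base + 0.5), 0, L - 1).astype(np.int64)
    return GrayImage(pixels=pixels, levels=L), labels


def make_uniform_histogram(levels: int) -> JointHistogram:
    """One count in every cell: weights 1 / L**2 everywhere."""
    if levels < 2:
        raise ValueError("levels must be at least 2")
    return JointHistogram(counts=np.ones((levels, levels), dtype=np.int64))


def make_random_histogram(levels: int, occupied_cells: int, seed: int = 0,
                          max_count: int = 100) -> JointHistogram:
    """Random positive counts on a uniformly chosen set of occupied cells."""
    if not (1 <= occupied_cells <= levels * levels):
        raise ValueError(f"occupied_cells must lie in [1, {levels * levels}]")
    rng = np.random.default_rng(seed)
    cells = rng.choice(levels * levels, size=occupied_cells, replace=False)
    counts = np.zeros(levels * levels, dtype=np.int64)
    counts[cells] = rng.integers(1, max_count + 1, size=occupied_cells)
    return JointHistogram(counts=counts.reshape(levels, levels))
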