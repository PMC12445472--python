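"""Nine segmentation-quality metrics between a reference and a processed image.

The suite covers fidelity (PSNR, SSIM), brightness preservation (AMBE),
contrast change (CII, CIR, SD), and detail/information retention
(edge density, REC, SF).  All metrics except AMBE are higher-is-better.

Definitions fixed by this module (the package's contract):

* PSNR = 10 log10((L-1)^2 / MSE), capped at 100 dB when MSE = 0.
* SSIM: standard stabilized form, constants (0.01 (L-1))^2 and
  (0.03 (L-1))^2, uniform 8x8 sliding windows (population statistics),
  mean over all fully in-bounds windows.
* AMBE = |mean(reference) - mean(processed)|.
* CII = mean local contrast of processed / mean local contrast of
  reference, local contrast = (max - min) / (max + min + eps) over 3x3
  windows (reflect borders), eps = 1e-9.
* SD = population standard deviation of the processed image.
* Edge density = fraction of pixels whose Sobel gradient magnitude exceeds
  Otsu's threshold of the magnitude image.
* REC = |H(processed) - H(reference)| / max(H(reference), eps), Shannon
  entropy (nats) of the 1D intensity histograms.
* SF = sqrt(RF^2 + CF^2), row/column frequency = RMS of first differences
  along rows / columns.
* CIR = sum((c - c~)^2) / sum(c^2) over the 3x3 local-contrast maps of the
  reference (c) and processed (c~) images, restricted to windows with
  c > 0.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage
from skimage import filters

from .histogram import GrayImage

__all__ = ["MetricsReport", "compute_metrics", "METRIC_NAMES", "HIGHER_IS_BETTER"]

_EPS = 1e-9
_PSNR_CAP = 100.0

METRIC_NAMES = ("psnr", "ssim", "ambe", "cii", "sd", "edge_density", "rec", "cir", "sf")

#: Ranking direction per metric: AMBE is the only lower-is-better one.
HIGHER_IS_BETTER = {name: name != "ambe" for name in METRIC_NAMES}


@dataclass(frozen=True)
class MetricsReport:
    psnr: float
    ssim: float
    ambe: float
    cii: float
    sd: float
    edge_density: float
    rec: float
    cir: float
    sf: float

    def to_dict(self) -> dict[str, float]:
        return asdict(self)


def _as_array(img) -> np.ndarray:
    return np.asarray(getattr(img, "pixels", img), dtype=float)


def _window_sums(x: np.ndarray, w: int) -> np.ndarray:
    """Sums over all fully in-bounds w x w windows, via an integral image."""
    c = np.cumsum(np.cumsum(x, axis=0), axis=1)
    c = np.pad(c, ((1, 0), (1, 0)))
    return c[w:, w:] - c[:-w, w:] - c[w:, :-w] + c[:-w, :-w]


def _ssim(a: np.ndarray, b: np.ndarray, L: int) -> float:
    win = 8
    if min(a.shape) < win:
        win = min(a.shape)  # degenerate small images: one global window
    n = win * win
    mu_a = _window_sums(a, win) / n
    mu_b = _window_sums(b, win) / n
    var_a = np.maximum(_window_sums(a * a, win) / n - mu_a**2, 0.0)
    var_b = np.maximum(_window_sums(b * b, win) / n - mu_b**2, 0.0)
    cov = _window_sums(a * b, win) / n - mu_a * mu_b
    c1 = (0.01 * (L - 1)) ** 2
    c2 = (0.03 * (L - 1)) ** 2
    ssim_map = ((2 * mu_a * mu_b + c1) * (2 * cov + c2)) / (
        (mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2)
    )
    return float(np.clip(ssim_map.mean(), -1.0, 1.0))


def _local_contrast(x: np.ndarray) -> np.ndarray:
    mx = ndimage.maximum_filter(x, size=3, mode="reflect")
    mn = ndimage.minimum_filter(x, size=3, mode="reflect")
    return (mx - mn) / (mx + mn + _EPS)


def _shannon_1d(x: np.ndarray, L: int) -> float:
    counts = np.bincount(x.astype(np.int64).ravel(), minlength=L)
    p = counts[counts > 0] / x.size
    return float(-(p * np.log(p)).sum())


def _spatial_frequency(x: np.ndarray) -> float:
    rf2 = float(np.mean(np.diff(x, axis=1) ** 2)) if x.shape[1] > 1 else 0.0
    cf2 = float(np.mean(np.diff(x, axis=0) ** 2)) if x.shape[0] > 1 else 0.0
    return float(np.sqrt(rf2 + cf2))


def _edge_density(x: np.ndarray) -> float:
    mag = filters.sobel(x)
    if mag.max() <= mag.min():
        return 0.0
    thresh = filters.threshold_otsu(mag)
    return float((mag > thresh).mean())


def compute_metrics(reference: GrayImage, processed: GrayImage) -> MetricsReport:
    """All nine quality metrics of ``processed`` against ``reference``."""
    ref = _as_array(reference)
    proc = _as_array(processed)
    if ref.shape != proc.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {proc.shape}")
    L = getattr(reference, "levels", 256)

    mse = float(np.mean((ref - proc) ** 2))
    psnr = _PSNR_CAP if mse == 0.0 else min(
        10.0 * np.log10((L - 1) ** 2 / mse), _PSNR_CAP
    )

    ambe = float(abs(ref.mean() - proc.mean()))

    c_ref = _local_contrast(ref)
    c_proc = _local_contrast(proc)
    mc_ref, mc_proc = float(c_ref.mean()), float(c_proc.mean())
    if mc_ref == 0.0 and mc_proc == 0.0:
        cii = 1.0
    else:
        cii = mc_proc / max(mc_ref, _EPS)

    pos = c_ref > 0
    denom = float((c_ref[pos] ** 2).sum())
    cir = float(((c_ref[pos] - c_proc[pos]) ** 2).sum() / denom) if denom > 0 else 0.0

    h_ref = _shannon_1d(ref, L)
    h_proc = _shannon_1d(proc, L)
    rec = abs(h_proc - h_ref) / max(h_ref, _EPS)

    return MetricsReport(
        psnr=float(psnr),
        ssim=_ssim(ref, proc, L),
        ambe=ambe,
        cii=float(cii),
        sd=float(proc.std()),
        edge_density=_edge_density(proc),
        rec=float(rec),
        cir=cir,
        sf=_spatial_frequency(proc),
    )
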