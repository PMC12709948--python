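"""Reconstruction (MSE/PSNR, SSIM, MRAE) and segmentation (MIoU, PA, MPA) metrics.

Definitions
-----------
* ``MSE`` — mean squared difference; ``PSNR = 10 log10(MAX^2 / MSE)`` dB,
  capped at 100 dB (identical images have infinite PSNR).
* ``SSIM`` — mean of local structural similarity over 11x11 Gaussian windows
  (sigma 1.5) with ``c1 = (0.01 MAX)^2``, ``c2 = (0.03 MAX)^2``; only windows
  fully inside the image contribute, so constant images hit the closed form
  exactly. Multi-band images are averaged over bands.
* ``MRAE`` — mean over pixels of ``|X - Y| / max(Y, 1/255)``; Y is the
  reference, the denominator floor is one byte quantization step.
* ``MIoU`` — mean of the background and vegetation IoUs; a class absent from
  both prediction and ground truth contributes IoU 1 (vacuous agreement).
  Dataset-level scores average the per-image scores over the k test images.
* ``PA`` — fraction of pixels classified correctly; ``MPA`` — mean of
  per-class recalls over classes present in the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Sequence, Tuple, Union

import numpy as np
from scipy.ndimage import correlate1d

from .types import BinaryMask, SpectralImage

PSNR_CAP_DB = 100.0
MRAE_DENOM_FLOOR = 1.0 / 255.0
SSIM_SIGMA = 1.5
SSIM_RADIUS = 5  # 11x11 window


def _as_array(x) -> np.ndarray:
    if isinstance(x, SpectralImage):
        return np.asarray(x.pixels, dtype=np.float64)
    return np.asarray(x, dtype=np.float64)


def _check_shapes(x: np.ndarray, y: np.ndarray) -> None:
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")


def mse(x, y) -> float:
    x, y = _as_array(x), _as_array(y)
    _check_shapes(x, y)
    return float(np.mean((x - y) ** 2))


def psnr(x, y, max_value: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB, capped at 100."""
    err = mse(x, y)
    if err == 0.0:
        return PSNR_CAP_DB
    return float(min(10.0 * np.log10(max_value**2 / err), PSNR_CAP_DB))


def _gaussian_kernel(sigma: float = SSIM_SIGMA, radius: int = SSIM_RADIUS) -> np.ndarray:
    xs = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-(xs**2) / (2.0 * sigma**2))
    return k / k.sum()


def _local_mean(x: np.ndarray, k1d: np.ndarray, radius: int) -> np.ndarray:
    y = correlate1d(x, k1d, axis=-1, mode="constant", cval=0.0)
    y = correlate1d(y, k1d, axis=-2, mode="constant", cval=0.0)
    return y[radius:-radius, radius:-radius]


def ssim(x, y, max_value: float = 1.0) -> float:
    """Single-band structural similarity; see module docstring for windowing."""
    x, y = _as_array(x), _as_array(y)
    _check_shapes(x, y)
    if x.ndim != 2:
        raise ValueError("ssim operates on single-band images; use ssim_multiband")
    r = SSIM_RADIUS
    if x.shape[0] <= 2 * r or x.shape[1] <= 2 * r:
        raise ValueError(f"image smaller than the {2*r+1}x{2*r+1} SSIM window")
    k1d = _gaussian_kernel()
    c1 = (0.01 * max_value) ** 2
    c2 = (0.03 * max_value) ** 2
    mu_x = _local_mean(x, k1d, r)
    mu_y = _local_mean(y, k1d, r)
    sxx = _local_mean(x * x, k1d, r) - mu_x**2
    syy = _local_mean(y * y, k1d, r) - mu_y**2
    sxy = _local_mean(x * y, k1d, r) - mu_x * mu_y
    s = ((2 * mu_x * mu_y + c1) * (2 * sxy + c2)) / (
        (mu_x**2 + mu_y**2 + c1) * (sxx + syy + c2))
    return float(s.mean())


def ssim_multiband(x, y, max_value: float = 1.0) -> Tuple[float, np.ndarray]:
    """SSIM averaged over the trailing band axis; returns (mean, per-band)."""
    x, y = _as_array(x), _as_array(y)
    _check_shapes(x, y)
    per_band = np.array([ssim(x[..., b], y[..., b], max_value) for b in range(x.shape[-1])])
    return float(per_band.mean()), per_band


def mrae(x, y, denom_floor: float = MRAE_DENOM_FLOOR) -> float:
    """Mean relative absolute error; ``y`` is the reference (denominator)."""
    x, y = _as_array(x), _as_array(y)
    _check_shapes(x, y)
    return float(np.mean(np.abs(x - y) / np.maximum(y, denom_floor)))


@dataclass
class ReconstructionReport:
    mrae: float
    ssim: float
    psnr_db: float
    mrae_per_band: np.ndarray = field(default_factory=lambda: np.zeros(4))
    ssim_per_band: np.ndarray = field(default_factory=lambda: np.zeros(4))
    psnr_per_band: np.ndarray = field(default_factory=lambda: np.zeros(4))


def evaluate_reconstruction(recon: SpectralImage, target: SpectralImage,
                            max_value: float = 1.0) -> ReconstructionReport:
    x, y = _as_array(recon), _as_array(target)
    _check_shapes(x, y)
    s_mean, s_band = ssim_multiband(x, y, max_value)
    return ReconstructionReport(
        mrae=mrae(x, y),
        ssim=s_mean,
        psnr_db=psnr(x, y, max_value),
        mrae_per_band=np.array([mrae(x[..., b], y[..., b]) for b in range(4)]),
        ssim_per_band=s_band,
        psnr_per_band=np.array([psnr(x[..., b], y[..., b], max_value) for b in range(4)]),
    )


@dataclass
class SegmentationReport:
    """Two-class confusion and summary scores.

    ``counts[p, g]`` is the raw pixel count with prediction p and truth g
    (0 = background, 1 = vegetation); ``confusion`` is the same table with
    each ground-truth column normalized to percent (columns sum to 100).
    """

    counts: np.ndarray
    confusion: np.ndarray
    iou_background: float
    iou_vegetation: float
    miou: float
    pa: float
    mpa: float
    n_images: int = 1


def _report_from_counts(counts: np.ndarray, n_images: int = 1) -> SegmentationReport:
    col = counts.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        confusion = np.where(col > 0, 100.0 * counts / col, 0.0)
    ious = []
    for c in range(2):
        inter = counts[c, c]
        union = counts[c, :].sum() + counts[:, c].sum() - inter
        ious.append(1.0 if union == 0 else float(inter / union))
    total = counts.sum()
    pa = float((counts[0, 0] + counts[1, 1]) / total) if total else 1.0
    recalls = [counts[c, c] / counts[:, c].sum() for c in range(2) if counts[:, c].sum() > 0]
    mpa = float(np.mean(recalls)) if recalls else 1.0
    return SegmentationReport(counts, confusion, ious[0], ious[1],
                              float(np.mean(ious)), pa, mpa, n_images)


def confusion_and_miou(pred: BinaryMask, gt: BinaryMask) -> SegmentationReport:
    """Single-image confusion table, IoUs, MIoU, PA and MPA."""
    p = np.asarray(pred.labels if isinstance(pred, BinaryMask) else pred)
    g = np.asarray(gt.labels if isinstance(gt, BinaryMask) else gt)
    _check_shapes(p, g)
    counts = np.zeros((2, 2), dtype=np.int64)
    for pc in (0, 1):
        for gc in (0, 1):
            counts[pc, gc] = int(np.sum((p == pc) & (g == gc)))
    return _report_from_counts(counts)


Maskish = Union[BinaryMask, np.ndarray]


def aggregate(items: Union[Sequence[SegmentationReport],
                           Sequence[Tuple[Maskish, Maskish]]]) -> SegmentationReport:
    """Dataset-level report over k test images.

    MIoU / PA / MPA are the means of the per-image scores (the 1/k sum over
    samples); the confusion table is pooled over all pixels for transparency.
    """
    items = list(items)
    if not items:
        raise ValueError("nothing to aggregate")
    reports = [it if isinstance(it, SegmentationReport) else confusion_and_miou(*it)
               for it in items]
    counts = np.sum([r.counts for r in reports], axis=0)
    pooled = _report_from_counts(counts, n_images=len(reports))
    pooled.miou = float(np.mean([r.miou for r in reports]))
    pooled.iou_background = float(np.mean([r.iou_background for r in reports]))
    pooled.iou_vegetation = float(np.mean([r.iou_vegetation for r in reports]))
    pooled.pa = float(np.mean([r.pa for r in reports]))
    pooled.mpa = float(np.mean([r.mpa for r in reports]))
    return pooled
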