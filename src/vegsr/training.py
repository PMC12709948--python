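"""Training loop for the reconstruction models.

The loss is the composite ``MRAE + (1 - SSIM)``: MRAE keeps each
reconstructed band close to the reference pixel-for-pixel, the SSIM term
preserves local structure. Both terms are differentiable (the SSIM window is
an 11x11 Gaussian, sigma 1.5) and the training-time values match the
evaluation metrics exactly, so each epoch record satisfies
``loss == mrae + (1 - ssim)``.

Optimization is Adam on random crops with horizontal/vertical flips, cosine
learning-rate decay, everything seeded. Per-epoch metrics are computed on
the test split, optionally including the downstream segmentation MIoU
(VI fusion of the reconstruction + the uniform fixed threshold 0.2), which
is what reveals the early-epoch checkpoint effect under band misalignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from . import metrics, raster_io
from .fusion import fuse_vi
from .nn import autograd as ag
from .nn.autograd import Tensor
from .nn.models import Adam, ReconstructionModel, reconstruct
from .segmentation import segment_fixed
from .synthetic import SyntheticSample
from .types import BinaryMask, DatasetManifest, RGBImage, SpectralImage

SSIM_C1 = 0.01**2  # unit-scale MAX = 1
SSIM_C2 = 0.03**2


@dataclass
class TrainConfig:
    epochs: int = 10
    batch_size: int = 16
    learning_rate: float = 1e-3
    crop_size: int = 24
    seed: int = 0
    eval_segmentation_every: int = 1  # 0 disables the downstream evaluation
    eval_max_images: int = 8  # per-epoch metric subset of the test split
    vi_threshold: float = 0.2
    cosine_decay: bool = True
    flip_augment: bool = True

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.crop_size < 16:
            raise ValueError("crop_size must be >= 16 (SSIM needs an 11x11 interior)")


@dataclass
class EpochRecord:
    epoch: int
    loss: float
    mrae: float
    ssim: float
    psnr: float
    seg_miou: Optional[float] = None


def loss_tensor(recon: Tensor, target: np.ndarray) -> Tensor:
    """Differentiable ``MRAE + (1 - SSIM)`` for (N, 4, h, w) batches."""
    y = np.asarray(target, dtype=np.float32)
    inv_denom = 1.0 / np.maximum(y, np.float32(metrics.MRAE_DENOM_FLOOR))
    mrae_t = ag.mean(ag.mul(ag.absolute(recon - y), inv_denom))

    mu_x = ag.blur_valid(recon)
    mu_y = np.asarray(ag.blur_valid(Tensor(y)).data)
    sxx = ag.blur_valid(ag.mul(recon, recon)) - ag.mul(mu_x, mu_x)
    syy = np.asarray(ag.blur_valid(Tensor(y * y)).data) - mu_y * mu_y
    sxy = ag.blur_valid(ag.mul(recon, y)) - ag.mul(mu_x, mu_y)
    num = ag.mul(2.0 * ag.mul(mu_x, mu_y) + SSIM_C1, 2.0 * sxy + SSIM_C2)
    den = ag.mul(ag.mul(mu_x, mu_x) + mu_y * mu_y + SSIM_C1, sxx + syy + SSIM_C2)
    ssim_t = ag.mean(ag.div(num, den))
    return mrae_t + (1.0 - ssim_t)


def loss(recon: SpectralImage, target: SpectralImage) -> float:
    """Composite loss between two spectral images (evaluation path)."""
    x = np.asarray(recon.pixels, dtype=np.float64)
    y = np.asarray(target.pixels, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    s, _ = metrics.ssim_multiband(x, y)
    return metrics.mrae(x, y) + (1.0 - s)


# -- data plumbing ---------------------------------------------------------

@dataclass
class _Pair:
    rgb: np.ndarray  # (3, H, W) float32, unit scale
    spectral: np.ndarray  # (4, H, W) float32, unit scale
    mask: Optional[np.ndarray]  # (H, W) uint8 or None


def _chw(img) -> np.ndarray:
    return np.ascontiguousarray(
        np.asarray(img.to_unit().pixels, dtype=np.float32).transpose(2, 0, 1))


def _pairs_from_samples(samples: Sequence[SyntheticSample]) -> List[_Pair]:
    return [_Pair(_chw(s.rgb), _chw(s.spectral_noisy),
                  np.asarray(s.mask.labels)) for s in samples]


def _pairs_from_manifest(manifest: DatasetManifest, split: str) -> List[_Pair]:
    pairs = []
    for e in manifest.subset(split).entries:
        if not e.spectral_path:
            continue
        rgb = raster_io.read_rgb(e.rgb_path)
        spec = raster_io.read_spectral(e.spectral_path)
        mask = raster_io.read_mask(e.mask_path).labels if e.mask_path else None
        pairs.append(_Pair(_chw(rgb), _chw(spec), mask))
    return pairs


def _resolve_splits(data) -> Tuple[List[_Pair], List[_Pair]]:
    if isinstance(data, DatasetManifest):
        return _pairs_from_manifest(data, "train"), _pairs_from_manifest(data, "test")
    if isinstance(data, dict):
        return (_pairs_from_samples(data.get("train", [])),
                _pairs_from_samples(data.get("test", [])))
    raise TypeError("data must be a DatasetManifest or {'train': [...], 'test': [...]}")


def _random_crop(pair: _Pair, size: int, rng: np.random.Generator,
                 flip: bool) -> Tuple[np.ndarray, np.ndarray]:
    _, h, w = pair.rgb.shape
    if size >= min(h, w):
        x, y = pair.rgb, pair.spectral
    else:
        i = int(rng.integers(h - size + 1))
        j = int(rng.integers(w - size + 1))
        x = pair.rgb[:, i:i + size, j:j + size]
        y = pair.spectral[:, i:i + size, j:j + size]
    if flip:
        if rng.random() < 0.5:
            x, y = x[:, :, ::-1], y[:, :, ::-1]
        if rng.random() < 0.5:
            x, y = x[:, ::-1, :], y[:, ::-1, :]
    return np.ascontiguousarray(x), np.ascontiguousarray(y)


# -- evaluation ------------------------------------------------------------

def _evaluate_epoch(model: ReconstructionModel, pairs: List[_Pair],
                    config: TrainConfig, epoch: int) -> EpochRecord:
    subset = pairs[: config.eval_max_images] if config.eval_max_images else pairs
    mraes, ssims, psnrs, mious = [], [], [], []
    do_seg = (config.eval_segmentation_every > 0
              and epoch % config.eval_segmentation_every == 0)
    for p in subset:
        rgb = RGBImage(p.rgb.transpose(1, 2, 0).astype(np.float64), "unit")
        recon = reconstruct(model, rgb)
        target = SpectralImage(p.spectral.transpose(1, 2, 0).astype(np.float64), "unit")
        mraes.append(metrics.mrae(recon.pixels, target.pixels))
        s, _ = metrics.ssim_multiband(recon.pixels, target.pixels)
        ssims.append(s)
        psnrs.append(metrics.psnr(recon.pixels, target.pixels))
        if do_seg and p.mask is not None:
            pred = segment_fixed(fuse_vi(recon), config.vi_threshold)
            mious.append(metrics.confusion_and_miou(pred, BinaryMask(p.mask)).miou)
    m, s = float(np.mean(mraes)), float(np.mean(ssims))
    return EpochRecord(epoch=epoch, loss=m + (1.0 - s), mrae=m, ssim=s,
                       psnr=float(np.mean(psnrs)),
                       seg_miou=float(np.mean(mious)) if mious else None)


# -- the loop --------------------------------------------------------------

def train(model: ReconstructionModel, data,
          config: Optional[TrainConfig] = None,
          restore_best: Optional[str] = None,
          ) -> Tuple[ReconstructionModel, List[EpochRecord]]:
    """Fit ``model`` on the train split; metrics per epoch on the test split.

    ``data`` is a DatasetManifest (paths) or an in-memory dict
    ``{"train": [SyntheticSample...], "test": [...]}``. With
    ``restore_best`` in {"reconstruction", "segmentation"} the weights of the
    checkpoint chosen by :func:`select_checkpoint` are restored at the end.
    """
    config = config or TrainConfig()
    train_pairs, test_pairs = _resolve_splits(data)
    if not train_pairs:
        raise ValueError("no paired spectra in the train split")
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params(), lr=config.learning_rate)
    n = len(train_pairs)
    steps_per_epoch = max(1, math.ceil(n / config.batch_size))
    total_steps = config.epochs * steps_per_epoch
    history: List[EpochRecord] = []
    snapshots: Dict[int, list] = {}
    step = 0
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        for b in range(steps_per_epoch):
            idx = order[b * config.batch_size:(b + 1) * config.batch_size]
            if len(idx) == 0:
                continue
            crops = [_random_crop(train_pairs[i], config.crop_size, rng,
                                  config.flip_augment) for i in idx]
            x = np.stack([c[0] for c in crops])
            y = np.stack([c[1] for c in crops])
            if config.cosine_decay:
                opt.lr = config.learning_rate * 0.5 * (1 + math.cos(math.pi * step / total_steps))
            opt.zero_grad()
            out = model.forward(Tensor(x))
            loss_t = loss_tensor(out, y)
            loss_t.backward()
            opt.step()
            step += 1
        if test_pairs:
            history.append(_evaluate_epoch(model, test_pairs, config, epoch))
        else:
            history.append(EpochRecord(epoch, float("nan"), float("nan"),
                                       float("nan"), float("nan")))
        if restore_best is not None:
            snapshots[epoch] = model.state_dict()
    if restore_best is not None and test_pairs:
        best = select_checkpoint(history, restore_best)
        model.load_state(snapshots[best])
    return model, history


def select_checkpoint(history: Sequence[EpochRecord], criterion: str) -> int:
    """Best epoch (1-based): min loss or max downstream seg MIoU; ties -> earliest."""
    if not history:
        raise ValueError("empty history")
    if criterion == "reconstruction":
        losses = [r.loss for r in history]
        return history[int(np.argmin(losses))].epoch
    if criterion == "segmentation":
        scored = [r for r in history if r.seg_miou is not None]
        if not scored:
            raise ValueError("no segmentation records in history")
        mious = [r.seg_miou for r in scored]
        return scored[int(np.argmax(mious))].epoch
    raise ValueError(f"unknown criterion {criterion!r}")
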