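"""Band fusion: collapse a 4-band spectral image to a single index map.

Two strategies:

* VI-based — the normalized-difference form ``(C_i - C_j)/(C_i + C_j + eps)``
  applied to a chosen band pair; the default pair is (NIR, green), signed so
  vegetation comes out positive. Values live on the VI scale [-1, 1].
* Weight-based — a per-band weighted sum on the byte scale [0, 255] (the
  scale on which the adaptive-threshold bounds are defined), clipped.

A third mode applies the normalized-difference form directly to an RGB
channel pair (GB / RB / RG) — the no-reconstruction ablation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .types import BAND_INDEX, RGBImage, SpectralImage

VI_SCALE = "vi_scale"  # values in [-1, 1]
WEIGHT_SCALE = "weight_scale"  # values in [0, 255]

#: weights of the weight-based strategy: (green, red, red_edge, nir)
DEFAULT_WEIGHTS: Tuple[float, float, float, float] = (-1.0, 0.0, 1.0, 1.0)

_RGB_CHANNEL = {"R": 0, "G": 1, "B": 2}
RGB_PAIRS = ("GB", "RB", "RG")


@dataclass
class FusionConfig:
    strategy: str = "vi"  # vi | weight | rgb_pair
    band_i: int = BAND_INDEX["nir"]  # numerator-positive band
    band_j: int = BAND_INDEX["green"]
    weights: Tuple[float, float, float, float] = DEFAULT_WEIGHTS
    epsilon: float = 1e-6
    rgb_pair: str = "GB"

    def __post_init__(self) -> None:
        if self.strategy not in ("vi", "weight", "rgb_pair"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.band_i == self.band_j:
            raise ValueError("band_i and band_j must differ")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if len(self.weights) != 4:
            raise ValueError("weights must have 4 entries")
        if self.rgb_pair not in RGB_PAIRS:
            raise ValueError(f"rgb_pair must be one of {RGB_PAIRS}")


@dataclass
class FusedIndexMap:
    values: np.ndarray  # H x W
    scale: str  # VI_SCALE or WEIGHT_SCALE
    config: FusionConfig = field(default_factory=FusionConfig)
    id: str = ""

    @property
    def shape(self):
        return self.values.shape


def _band(img: SpectralImage, which) -> np.ndarray:
    idx = BAND_INDEX[which] if isinstance(which, str) else int(which)
    return np.asarray(img.pixels[:, :, idx], dtype=np.float64)


def fuse_vi(spectral: SpectralImage, band_i=BAND_INDEX["nir"],
            band_j=BAND_INDEX["green"], epsilon: float = 1e-6) -> FusedIndexMap:
    """Normalized-difference index ``(C_i - C_j)/(C_i + C_j + eps)``.

    With the default (NIR, green) pair this is an NDVI-style index on the
    reconstructed bands: positive over vegetation, negative over soil/film.
    """
    spectral = spectral.to_unit()
    bi = BAND_INDEX[band_i] if isinstance(band_i, str) else int(band_i)
    bj = BAND_INDEX[band_j] if isinstance(band_j, str) else int(band_j)
    cfg = FusionConfig(strategy="vi", band_i=bi, band_j=bj, epsilon=epsilon)
    ci, cj = _band(spectral, bi), _band(spectral, bj)
    values = (ci - cj) / (ci + cj + epsilon)
    return FusedIndexMap(values, VI_SCALE, cfg, spectral.id)


def fuse_weight(spectral: SpectralImage,
                weights: Sequence[float] = DEFAULT_WEIGHTS) -> FusedIndexMap:
    """Weighted band sum on the byte scale, clipped to [0, 255]."""
    if len(weights) != 4:
        raise ValueError("weights must have 4 entries")
    spectral = spectral.to_unit()
    cfg = FusionConfig(strategy="weight", weights=tuple(float(w) for w in weights))
    byte_bands = np.asarray(spectral.pixels, dtype=np.float64) * 255.0
    values = np.tensordot(byte_bands, np.asarray(weights, dtype=np.float64), axes=([2], [0]))
    return FusedIndexMap(np.clip(values, 0.0, 255.0), WEIGHT_SCALE, cfg, spectral.id)


def fuse_rgb_pair(rgb: RGBImage, pair: str = "GB", epsilon: float = 1e-6) -> FusedIndexMap:
    """Normalized difference of two RGB channels (first named channel is C_i)."""
    if pair not in RGB_PAIRS:
        raise ValueError(f"pair must be one of {RGB_PAIRS}, got {pair!r}")
    rgb = rgb.to_unit()
    cfg = FusionConfig(strategy="rgb_pair", rgb_pair=pair, epsilon=epsilon)
    ci = np.asarray(rgb.pixels[:, :, _RGB_CHANNEL[pair[0]]], dtype=np.float64)
    cj = np.asarray(rgb.pixels[:, :, _RGB_CHANNEL[pair[1]]], dtype=np.float64)
    return FusedIndexMap((ci - cj) / (ci + cj + epsilon), VI_SCALE, cfg, rgb.id)


def fuse(image, config: Optional[FusionConfig] = None) -> FusedIndexMap:
    """Dispatch on ``config.strategy``."""
    config = config or FusionConfig()
    if config.strategy == "vi":
        return fuse_vi(image, config.band_i, config.band_j, config.epsilon)
    if config.strategy == "weight":
        return fuse_weight(image, config.weights)
    return fuse_rgb_pair(image, config.rgb_pair, config.epsilon)
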