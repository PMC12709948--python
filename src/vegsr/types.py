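"""Core raster containers shared by every pipeline stage.

All rasters are numpy arrays in ``(H, W, C)`` layout with an explicit value
scale: ``"unit"`` for floats in [0, 1] (the internal compute scale) or
``"byte"`` for integers in [0, 255] (the on-disk scale for RGB and masks).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np

BAND_CENTERS_NM: Tuple[int, int, int, int] = (550, 660, 735, 790)
BAND_NAMES: Tuple[str, str, str, str] = ("green", "red", "red_edge", "nir")

#: index of each band in a SpectralImage, by name
BAND_INDEX = {name: i for i, name in enumerate(BAND_NAMES)}

_VALID_SCALES = ("unit", "byte")


def _check_scale(pixels: np.ndarray, value_scale: str) -> None:
    if value_scale not in _VALID_SCALES:
        raise ValueError(f"value_scale must be one of {_VALID_SCALES}, got {value_scale!r}")
    lo, hi = (0.0, 1.0) if value_scale == "unit" else (0, 255)
    if pixels.size and (pixels.min() < lo or pixels.max() > hi):
        raise ValueError(
            f"pixel values outside declared {value_scale} scale "
            f"[{lo}, {hi}]: range ({pixels.min()}, {pixels.max()})"
        )


@dataclass
class RGBImage:
    """H x W x 3 visible-light raster, channel order R, G, B."""

    pixels: np.ndarray
    value_scale: str = "unit"
    id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"RGBImage needs an H x W x 3 array, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("empty image")
        _check_scale(self.pixels, self.value_scale)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape[:2]

    def to_unit(self) -> "RGBImage":
        if self.value_scale == "unit":
            return self
        return RGBImage(self.pixels.astype(np.float64) / 255.0, "unit", self.id)

    def to_byte(self) -> "RGBImage":
        if self.value_scale == "byte":
            return self
        data = np.clip(np.rint(self.pixels * 255.0), 0, 255).astype(np.uint8)
        return RGBImage(data, "byte", self.id)


@dataclass
class SpectralImage:
    """H x W x 4 multispectral raster.

    Band order is fixed as (green 550 nm, red 660 nm, red-edge 735 nm,
    NIR 790 nm) — the four narrow bands of a typical UAV crop sensor.
    """

    pixels: np.ndarray
    value_scale: str = "unit"
    id: str = ""
    band_centers_nm: Tuple[int, ...] = BAND_CENTERS_NM
    band_names: Tuple[str, ...] = BAND_NAMES

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 4:
            raise ValueError(
                f"SpectralImage needs an H x W x 4 array, got shape {self.pixels.shape}"
            )
        if tuple(self.band_centers_nm) != BAND_CENTERS_NM:
            raise ValueError(f"band centers fixed as {BAND_CENTERS_NM}")
        _check_scale(self.pixels, self.value_scale)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape[:2]

    def band(self, name_or_index) -> np.ndarray:
        """Return one band as an H x W array; accepts a name or 0-based index."""
        idx = BAND_INDEX[name_or_index] if isinstance(name_or_index, str) else int(name_or_index)
        return self.pixels[:, :, idx]

    def to_unit(self) -> "SpectralImage":
        if self.value_scale == "unit":
            return self
        return SpectralImage(self.pixels.astype(np.float64) / 255.0, "unit", self.id)

    def to_byte(self) -> "SpectralImage":
        if self.value_scale == "byte":
            return self
        data = np.clip(np.rint(self.pixels * 255.0), 0, 255).astype(np.uint8)
        return SpectralImage(data, "byte", self.id)


@dataclass
class BinaryMask:
    """H x W labels: 0 = background, 1 = vegetation."""

    labels: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError(f"BinaryMask needs an H x W array, got shape {self.labels.shape}")
        vals = np.unique(self.labels)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError(f"mask values must be 0/1, got {vals}")
        self.labels = self.labels.astype(np.uint8)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.labels.shape

    @property
    def vegetation_fraction(self) -> float:
        return float(self.labels.mean()) if self.labels.size else 0.0


@dataclass
class PairedSample:
    """One dataset entry: RGB input, optional spectral target, optional mask."""

    rgb: RGBImage
    spectral: Optional[SpectralImage] = None
    mask: Optional[BinaryMask] = None
    split: str = "train"
    misaligned: bool = False  # spectral bands carry injected spatial offsets

    def __post_init__(self) -> None:
        if self.split not in ("train", "test"):
            raise ValueError(f"split must be train/test, got {self.split!r}")
        if self.spectral is not None and not self.misaligned:
            if self.spectral.shape != self.rgb.shape:
                raise ValueError(
                    f"rgb {self.rgb.shape} and spectral {self.spectral.shape} shapes differ"
                )


@dataclass
class ManifestEntry:
    id: str
    rgb_path: str
    spectral_path: str = ""
    mask_path: str = ""
    split: str = "train"


@dataclass
class DatasetManifest:
    """Ordered list of sample file references plus the split bookkeeping."""

    entries: list = field(default_factory=list)
    split_ratio: float = 0.9
    seed: int = 0

    def __len__(self) -> int:
        return len(self.entries)

    def subset(self, split: str) -> "DatasetManifest":
        return replace(self, entries=[e for e in self.entries if e.split == split])
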