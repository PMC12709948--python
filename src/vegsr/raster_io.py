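"""Raster and manifest I/O, patch extraction and dataset splitting.

Conventions (fixed across the package):

* RGB images: PNG/JPEG/TIFF with exactly 3 channels, read in R,G,B order,
  byte scale preserved on disk.
* Multispectral images: multi-page grayscale TIFF, page order = band order
  (green, red, red_edge, nir); integer and float32 data round-trip losslessly.
* Masks: single-channel PNG with {0, 255} on disk, {0, 1} in memory.
* Manifests: CSV with columns (id, rgb_path, spectral_path, mask_path, split).
"""

from __future__ import annotations

import os
from typing import List, Sequence, Union

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .types import BinaryMask, DatasetManifest, ManifestEntry, RGBImage, SpectralImage

Image = Union[RGBImage, SpectralImage]


def read_rgb(path: str) -> RGBImage:
    """Read a 3-channel image; errors on any other channel count."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    data = np.asarray(iio.imread(path))
    if data.ndim == 2 or data.shape[-1] != 3:
        n = 1 if data.ndim == 2 else data.shape[-1]
        raise ValueError(f"{path}: expected 3 channels, found {n}")
    scale = "byte" if np.issubdtype(data.dtype, np.integer) else "unit"
    return RGBImage(data, scale, id=os.path.splitext(os.path.basename(path))[0])


def write_rgb(img: RGBImage, path: str) -> None:
    data = img.to_byte().pixels
    iio.imwrite(path, data.astype(np.uint8))


def read_spectral(path: str) -> SpectralImage:
    """Read a 4-page TIFF into the fixed band order (green, red, red_edge, nir)."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    data = tifffile.imread(path)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 4-page TIFF, got array shape {data.shape}")
    if data.shape[0] == 4:  # pages-first layout
        data = np.moveaxis(data, 0, -1)
    if data.shape[-1] != 4:
        raise ValueError(f"{path}: expected 4 bands, found {data.shape}")
    scale = "byte" if np.issubdtype(data.dtype, np.integer) else "unit"
    return SpectralImage(data, scale, id=os.path.splitext(os.path.basename(path))[0])


def write_spectral(img: SpectralImage, path: str) -> None:
    """Write bands as TIFF pages in band order; dtype preserved (lossless)."""
    data = np.moveaxis(img.pixels, -1, 0)  # (4, H, W) pages
    tifffile.imwrite(path, np.ascontiguousarray(data))


def read_mask(path: str) -> BinaryMask:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    data = np.asarray(iio.imread(path))
    if data.ndim == 3:
        data = data[..., 0]
    return BinaryMask((data > 127).astype(np.uint8), id=os.path.splitext(os.path.basename(path))[0])


def write_mask(mask: BinaryMask, path: str) -> None:
    iio.imwrite(path, (mask.labels * 255).astype(np.uint8))


def extract_patches(image: Image, patch_size: int) -> List[Image]:
    """All non-overlapping ``patch_size`` tiles on a grid anchored at (0, 0).

    Tiles are returned row-major; residual right/bottom borders are discarded,
    so the count is ``floor(H/p) * floor(W/p)``. A patch size larger than the
    image yields an empty list.
    """
    if patch_size < 1:
        raise ValueError("patch_size must be >= 1")
    h, w = image.shape
    cls = type(image)
    patches: List[Image] = []
    for i in range(h // patch_size):
        for j in range(w // patch_size):
            tile = image.pixels[
                i * patch_size : (i + 1) * patch_size,
                j * patch_size : (j + 1) * patch_size,
            ]
            patches.append(cls(tile, image.value_scale, id=f"{image.id}_p{i}{j}"))
    return patches


def split_dataset(manifest: DatasetManifest, ratio: float = 0.9, seed: int = 0) -> DatasetManifest:
    """Assign train/test splits: |train| = round(ratio * n), shuffled by seed.

    The split is a deterministic function of (seed, entry order) and always a
    true partition. The rounded train count is clamped so neither split is
    empty.
    """
    n = len(manifest.entries)
    if n == 0:
        raise ValueError("cannot split an empty manifest")
    if not 0.0 < ratio < 1.0:
        raise ValueError(f"ratio must be in (0, 1), got {ratio}")
    n_train = int(round(ratio * n))
    n_train = min(max(n_train, 1), n - 1)
    order = np.random.default_rng(seed).permutation(n)
    train_idx = set(order[:n_train].tolist())
    entries = []
    for i, e in enumerate(manifest.entries):
        entries.append(
            ManifestEntry(e.id, e.rgb_path, e.spectral_path, e.mask_path,
                          "train" if i in train_idx else "test")
        )
    return DatasetManifest(entries, split_ratio=ratio, seed=seed)


def save_manifest(manifest: DatasetManifest, path: str) -> None:
    df = pd.DataFrame(
        [
            {"id": e.id, "rgb_path": e.rgb_path, "spectral_path": e.spectral_path,
             "mask_path": e.mask_path, "split": e.split}
            for e in manifest.entries
        ]
    )
    df.to_csv(path, index=False)


def load_manifest(path: str, check_paths: bool = True) -> DatasetManifest:
    df = pd.read_csv(path, keep_default_na=False)
    base = os.path.dirname(os.path.abspath(path))

    def _resolve(p: str) -> str:
        if not p:
            return ""
        return p if os.path.isabs(p) else os.path.join(base, p)

    entries = []
    for row in df.itertuples(index=False):
        e = ManifestEntry(str(row.id), _resolve(row.rgb_path),
                          _resolve(row.spectral_path), _resolve(row.mask_path), row.split)
        if check_paths:
            for p in (e.rgb_path, e.spectral_path, e.mask_path):
                if p and not os.path.exists(p):
                    raise FileNotFoundError(f"manifest {path} references missing file {p}")
        entries.append(e)
    return DatasetManifest(entries)
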