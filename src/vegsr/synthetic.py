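"""Synthetic paired RGB + multispectral field scenes with ground truth.

The generator emulates UAV crop imagery for the pipeline's offline tests:
a per-pixel class map (vegetation / soil / plastic mulch film) is drawn
either as thresholded smoothed random fields (``dense`` canopies) or as
periodic crop rows with per-plant blobs (``row_crop``); each class is then
rendered into the four narrow sensor bands (green, red, red-edge, NIR) and
into RGB from its reflectance signature. Vegetation shows the red-edge/NIR
rise that vegetation indices exploit; soil and film do not.

"Strong noise" — the residual per-band spatial misalignment left by fisheye
correction and manual alignment of a multi-lens sensor — is modelled as an
independent rigid sub-pixel translation of each spectral band, applied to
the training target only (the RGB input and the mask stay put).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import ndimage

from . import raster_io
from .types import BinaryMask, DatasetManifest, ManifestEntry, RGBImage, SpectralImage

CLASS_NAMES = ("vegetation", "soil", "film")
VEGETATION, SOIL, FILM = 0, 1, 2


@dataclass(frozen=True)
class SpectralSignature:
    """Mean reflectance of one surface class in the 4 sensor bands and in RGB.

    ``jitter_sd`` is a per-scene multiplicative spread applied to the means,
    emulating scene-to-scene radiometric variation (moisture, growth stage).
    """

    class_name: str
    reflectance_ms: Tuple[float, float, float, float]  # green, red, red_edge, nir
    reflectance_rgb: Tuple[float, float, float]
    jitter_sd: float = 0.02

    def __post_init__(self) -> None:
        for v in (*self.reflectance_ms, *self.reflectance_rgb):
            if not 0.0 <= v <= 1.0:
                raise ValueError("signature means must lie in [0, 1]")
        if self.class_name == "vegetation":
            g, r, re, nir = self.reflectance_ms
            if not (nir > r and re > r):
                raise ValueError("vegetation must show the red-edge rise (nir > red, red_edge > red)")


#: Default class radiometry. Vegetation has strong red absorption and a steep
#: red-edge/NIR rise; soil and film are spectrally flat-to-falling so their
#: (nir - green)/(nir + green) index is negative with a >= 2 sigma margin at
#: the default pixel noise — the separation the weak-supervision oracle rests on.
#: The RGB renderings are calibrated the opposite way: as in real field scenes,
#: no single two-channel ratio separates vegetation from soil cleanly (the
#: soil G-B contrast sits close to the vegetation one), while the full RGB
#: triple still determines the class — which is why a learned RGB-to-spectral
#: mapping outperforms direct channel-pair indices.
DEFAULT_SIGNATURES: Dict[str, SpectralSignature] = {
    "vegetation": SpectralSignature("vegetation", (0.10, 0.06, 0.45, 0.55), (0.15, 0.22, 0.10)),
    "soil": SpectralSignature("soil", (0.32, 0.36, 0.30, 0.26), (0.40, 0.32, 0.22)),
    "film": SpectralSignature("film", (0.64, 0.62, 0.60, 0.55), (0.75, 0.75, 0.72)),
}


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic field scene."""

    height: int = 64
    width: int = 64
    layout: str = "mixed"  # row_crop | dense | mixed
    target_veg_fraction: float = 0.3
    blob_scale: float = 6.0  # smoothing length of the vegetation field, px
    film_fraction: float = 0.1  # fraction of the full scene covered by mulch film
    illumination_gain: float = 1.0
    pixel_noise_sd: float = 0.02  # additive Gaussian sensor noise, unit scale
    strong_noise_px: float = 0.0  # max per-band translation magnitude
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 16 or self.width < 16:
            raise ValueError("scene must be at least 16 x 16")
        for f in (self.target_veg_fraction, self.film_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.layout not in ("row_crop", "dense", "mixed"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.pixel_noise_sd < 0 or self.strong_noise_px < 0:
            raise ValueError("noise magnitudes must be >= 0")
        if self.illumination_gain <= 0:
            raise ValueError("illumination_gain must be positive")


@dataclass
class SyntheticSample:
    rgb: RGBImage
    spectral_clean: SpectralImage
    spectral_noisy: SpectralImage
    mask: BinaryMask
    spec: SceneSpec
    band_offsets: Optional[np.ndarray] = None  # (4, 2) injected (dy, dx) per band


def _smooth_field(rng: np.random.Generator, h: int, w: int, scale: float) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=max(scale, 1e-6), mode="wrap")
    sd = f.std()
    return f / sd if sd > 0 else f


def _class_map(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.height, spec.width
    field = _smooth_field(rng, h, w, spec.blob_scale / 2.0)
    if spec.layout in ("row_crop", "mixed"):
        # periodic ridges along x: plants cluster on rows
        period = max(3.0 * spec.blob_scale, 8.0)
        phase = rng.uniform(0, 2 * np.pi)
        xs = np.arange(w)[None, :]
        ridge = np.cos(2 * np.pi * xs / period + phase) * np.ones((h, 1))
        amp = 1.5 if spec.layout == "row_crop" else 0.7
        field = field + amp * ridge
    # vegetation fraction made (approximately) exact by thresholding at the
    # field's own empirical quantile
    if spec.target_veg_fraction <= 0.0:
        veg = np.zeros((h, w), dtype=bool)
    elif spec.target_veg_fraction >= 1.0:
        veg = np.ones((h, w), dtype=bool)
    else:
        thr = np.quantile(field, 1.0 - spec.target_veg_fraction)
        veg = field > thr

    cmap = np.full((h, w), SOIL, dtype=np.uint8)
    cmap[veg] = VEGETATION
    if spec.film_fraction > 0.0 and not veg.all():
        film_field = _smooth_field(rng, h, w, spec.blob_scale)
        bg = ~veg
        n_film = min(int(round(spec.film_fraction * h * w)), int(bg.sum()))
        if n_film > 0:
            vals = film_field[bg]
            thr = np.partition(vals, len(vals) - n_film)[len(vals) - n_film]
            cmap[bg & (film_field >= thr)] = FILM
    return cmap


def _render(cmap: np.ndarray, signatures: Dict[str, SpectralSignature], spec: SceneSpec,
            rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
    h, w = cmap.shape
    ms = np.zeros((h, w, 4))
    rgb = np.zeros((h, w, 3))
    for idx, name in enumerate(CLASS_NAMES):
        sig = signatures[name]
        sel = cmap == idx
        if not sel.any():
            continue
        jit_ms = 1.0 + sig.jitter_sd * rng.standard_normal(4)
        jit_rgb = 1.0 + sig.jitter_sd * rng.standard_normal(3)
        ms[sel] = np.asarray(sig.reflectance_ms) * jit_ms
        rgb[sel] = np.asarray(sig.reflectance_rgb) * jit_rgb
    ms = ms * spec.illumination_gain + spec.pixel_noise_sd * rng.standard_normal(ms.shape)
    rgb = rgb * spec.illumination_gain + spec.pixel_noise_sd * rng.standard_normal(rgb.shape)
    return np.clip(ms, 0.0, 1.0), np.clip(rgb, 0.0, 1.0)


def generate_scene(spec: SceneSpec,
                   signatures: Optional[Dict[str, SpectralSignature]] = None) -> SyntheticSample:
    """Draw one paired scene; bitwise-deterministic under ``spec.seed``."""
    signatures = signatures or DEFAULT_SIGNATURES
    rng = np.random.default_rng(spec.seed)
    cmap = _class_map(spec, rng)
    ms, rgb = _render(cmap, signatures, spec, rng)
    sid = f"scene{spec.seed}"
    sample = SyntheticSample(
        rgb=RGBImage(rgb, "unit", sid),
        spectral_clean=SpectralImage(ms, "unit", sid),
        spectral_noisy=SpectralImage(ms, "unit", sid),
        mask=BinaryMask((cmap == VEGETATION).astype(np.uint8), sid),
        spec=spec,
    )
    if spec.strong_noise_px > 0:
        sample = inject_strong_noise(sample, spec.strong_noise_px,
                                     seed=int(rng.integers(2**31)))
    return sample


def inject_strong_noise(sample: SyntheticSample, magnitude_px: float,
                        seed: int = 0) -> SyntheticSample:
    """Translate each spectral band independently by a random sub-pixel offset.

    Offsets are drawn uniformly with |dy|, |dx| <= magnitude_px; resampling is
    bilinear with edge replication. RGB and mask are untouched; magnitude 0 is
    the identity.
    """
    if magnitude_px < 0:
        raise ValueError("magnitude_px must be >= 0")
    if magnitude_px == 0:
        return replace(sample, spectral_noisy=sample.spectral_clean,
                       band_offsets=np.zeros((4, 2)))
    rng = np.random.default_rng(seed)
    offsets = rng.uniform(-magnitude_px, magnitude_px, size=(4, 2))
    clean = sample.spectral_clean.pixels
    noisy = np.empty_like(clean)
    for b in range(4):
        noisy[:, :, b] = ndimage.shift(clean[:, :, b], shift=offsets[b],
                                       order=1, mode="nearest")
    noisy_img = SpectralImage(np.clip(noisy, 0.0, 1.0), "unit", sample.spectral_clean.id)
    return replace(sample, spectral_noisy=noisy_img, band_offsets=offsets)


#: default per-parameter (low, high) ranges for dataset generation; scalars fix a value
DEFAULT_SPEC_RANGES: Dict[str, object] = {
    "height": 64,
    "width": 64,
    "layout": ("row_crop", "dense", "mixed"),
    "target_veg_fraction": (0.15, 0.45),
    "blob_scale": (4.0, 8.0),
    "film_fraction": (0.0, 0.2),
    "illumination_gain": (0.8, 1.25),
    "pixel_noise_sd": 0.02,
    "strong_noise_px": 2.0,
}


def draw_specs(n: int, spec_ranges: Optional[Dict[str, object]] = None,
               seed: int = 0) -> list:
    """Draw ``n`` SceneSpecs uniformly from per-parameter ranges."""
    ranges = dict(DEFAULT_SPEC_RANGES)
    if spec_ranges:
        ranges.update(spec_ranges)
    rng = np.random.default_rng(seed)
    specs = []
    for k in range(n):
        kwargs = {}
        for key, val in ranges.items():
            if key == "layout":
                choices = (val,) if isinstance(val, str) else tuple(val)
                kwargs[key] = choices[int(rng.integers(len(choices)))]
            elif isinstance(val, tuple):
                lo, hi = val
                kwargs[key] = float(rng.uniform(lo, hi))
            else:
                kwargs[key] = val
        kwargs["height"] = int(kwargs["height"])
        kwargs["width"] = int(kwargs["width"])
        specs.append(SceneSpec(seed=int(rng.integers(2**31)), **kwargs))
    return specs


def generate_samples(n: int, spec_ranges: Optional[Dict[str, object]] = None,
                     seed: int = 0,
                     signatures: Optional[Dict[str, SpectralSignature]] = None) -> list:
    """In-memory dataset: n SyntheticSamples with specs drawn from the ranges."""
    return [generate_scene(s, signatures) for s in draw_specs(n, spec_ranges, seed)]


def generate_dataset(n: int, spec_ranges: Optional[Dict[str, object]] = None,
                     seed: int = 0, out_dir: str = ".",
                     split_ratio: float = 0.9) -> DatasetManifest:
    """Write n scenes (RGB PNG, noisy spectral TIFF, mask PNG) plus a manifest.

    The spectral file holds the *noisy* bands — the observation a real sensor
    would deliver — as float32; the clean spectra are not written. Returns the
    manifest with a deterministic ``split_ratio`` train/test split.
    """
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    os.makedirs(out_dir, exist_ok=True)
    entries = []
    for k, sample in enumerate(generate_samples(n, spec_ranges, seed)):
        sid = f"sample_{k:04d}"
        rgb_p = os.path.join(out_dir, f"{sid}_rgb.png")
        ms_p = os.path.join(out_dir, f"{sid}_ms.tif")
        mask_p = os.path.join(out_dir, f"{sid}_mask.png")
        raster_io.write_rgb(sample.rgb, rgb_p)
        raster_io.write_spectral(
            SpectralImage(sample.spectral_noisy.pixels.astype(np.float32), "unit", sid), ms_p)
        raster_io.write_mask(sample.mask, mask_p)
        entries.append(ManifestEntry(sid, rgb_p, ms_p, mask_p))
    manifest = raster_io.split_dataset(DatasetManifest(entries), ratio=split_ratio, seed=seed)
    raster_io.save_manifest(manifest, os.path.join(out_dir, "manifest.csv"))
    return manifest
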