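"""Threshold a fused index map into a binary vegetation mask.

Fixed mode compares each pixel to a constant ``t`` (strictly greater ->
vegetation; equality goes to background, the conservative class). Adaptive
mode derives the threshold from the global mean ``a`` of a byte-scale
weight-fused map:

    t = phi_h * a   if a > S_h
        phi_l * a   if a < S_l
        a           otherwise  (identity completion of the middle band)

with the default constants S_l = 145, S_h = 150, phi_l = 1.15,
phi_h = 0.9. The multipliers pull the threshold toward the mean from above
or below so bright and dark scenes both segment sensibly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import metrics
from .fusion import FusedIndexMap, VI_SCALE, WEIGHT_SCALE
from .types import BinaryMask

#: default adaptive-threshold constants (byte scale)
DEFAULT_S_L = 145.0
DEFAULT_S_H = 150.0
DEFAULT_PHI_L = 1.15
DEFAULT_PHI_H = 0.9

#: uniform fixed threshold on the VI scale used for comparisons
DEFAULT_VI_THRESHOLD = 0.2


@dataclass
class ThresholdConfig:
    mode: str = "fixed"  # fixed | adaptive
    t: float = DEFAULT_VI_THRESHOLD
    s_l: float = DEFAULT_S_L
    s_h: float = DEFAULT_S_H
    phi_l: float = DEFAULT_PHI_L
    phi_h: float = DEFAULT_PHI_H

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "adaptive"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.s_l >= self.s_h:
            raise ValueError("S_l must be < S_h")
        if self.phi_l <= 0 or self.phi_h <= 0:
            raise ValueError("phi_l and phi_h must be positive")


def segment_fixed(index_map: FusedIndexMap, t: float) -> BinaryMask:
    """Pixels strictly above ``t`` become vegetation; equality -> background."""
    values = np.asarray(index_map.values if isinstance(index_map, FusedIndexMap) else index_map)
    return BinaryMask((values > t).astype(np.uint8),
                      getattr(index_map, "id", ""))


def adaptive_threshold(index_map: FusedIndexMap,
                       cfg: Optional[ThresholdConfig] = None) -> float:
    """Mean-adaptive threshold for byte-scale weight-fused maps."""
    cfg = cfg or ThresholdConfig(mode="adaptive")
    values = np.asarray(index_map.values if isinstance(index_map, FusedIndexMap) else index_map)
    if values.size == 0:
        raise ValueError("empty map")
    a = float(values.mean())
    if a > cfg.s_h:
        return cfg.phi_h * a
    if a < cfg.s_l:
        return cfg.phi_l * a
    return a


def segment(index_map: FusedIndexMap, cfg: Optional[ThresholdConfig] = None) -> BinaryMask:
    """Apply the configured thresholding; checks the map-scale / mode pairing."""
    if cfg is None:
        cfg = (ThresholdConfig(mode="adaptive") if index_map.scale == WEIGHT_SCALE
               else ThresholdConfig(mode="fixed"))
    if cfg.mode == "adaptive":
        if index_map.scale != WEIGHT_SCALE:
            raise ValueError("adaptive thresholding is defined on byte-scale weight maps")
        return segment_fixed(index_map, adaptive_threshold(index_map, cfg))
    if index_map.scale == WEIGHT_SCALE and not 0.0 <= cfg.t <= 255.0:
        raise ValueError("fixed threshold outside the map's byte scale")
    if index_map.scale == VI_SCALE and not -1.0 <= cfg.t <= 1.0:
        raise ValueError("fixed threshold outside the map's VI scale")
    return segment_fixed(index_map, cfg.t)


def sweep_thresholds(index_map: FusedIndexMap, gt: BinaryMask,
                     grid: Sequence[float]) -> pd.DataFrame:
    """Segmentation quality along a threshold grid.

    Returns one row per ``t`` with MIoU, PA and MPA against ``gt``, plus a
    ``best`` flag on the argmax-MIoU row (ties -> smallest t).
    """
    grid = list(grid)
    if not grid:
        raise ValueError("threshold grid is empty")
    rows = []
    for t in grid:
        rep = metrics.confusion_and_miou(segment_fixed(index_map, t), gt)
        rows.append({"t": float(t), "miou": rep.miou, "pa": rep.pa, "mpa": rep.mpa})
    df = pd.DataFrame(rows).sort_values("t", kind="stable").reset_index(drop=True)
    df["best"] = False
    df.loc[df["miou"].idxmax(), "best"] = True  # idxmax takes the first max
    return df
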