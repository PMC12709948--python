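"""End-to-end runs and the four comparison experiments.

``run_pipeline`` chains simulate -> train -> reconstruct -> fuse -> segment
-> evaluate on the held-out split and writes every artifact (masks, fused
maps, history, reports, a resolved-config snapshot with its hash) into a run
directory. ``run_experiment`` produces the threshold-sweep, fusion-strategy,
epoch-effect and RGB-pair-ablation comparisons as data frames / CSV.

All randomness flows from one seed; each stage derives a stable sub-seed by
hashing the stage name, so stages never share streams.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import time
import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import metrics, raster_io
from .fusion import FusionConfig, fuse, fuse_rgb_pair, fuse_vi, fuse_weight, RGB_PAIRS
from .nn.models import ModelConfig, ReconstructionModel, build_model, default_config, reconstruct
from .segmentation import ThresholdConfig, segment, segment_fixed, sweep_thresholds
from .synthetic import SceneSpec, SyntheticSample, generate_samples
from .training import TrainConfig, train
from .types import BinaryMask

EXPERIMENTS = ("threshold_sweep", "fusion_compare", "epoch_effect", "ablation")


def stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage sub-seed below 2**31."""
    return zlib.crc32(f"{seed}:{stage}".encode()) & 0x7FFFFFFF


@dataclass
class PipelineConfig:
    n_scenes: int = 200
    scene_size: int = 64
    spec_ranges: Optional[Dict[str, object]] = None
    model: ModelConfig = field(default_factory=lambda: default_config("srcnet"))
    train: TrainConfig = field(default_factory=TrainConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    threshold: ThresholdConfig = field(default_factory=ThresholdConfig)
    seed: int = 0
    skip_reconstruction: bool = False  # oracle mode: fuse the clean spectra directly

    def resolved(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.resolved(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    report: metrics.SegmentationReport
    history: list
    per_image_miou: List[float]
    config_hash: str
    out_dir: Optional[str] = None


def _simulate(config: PipelineConfig) -> Dict[str, List[SyntheticSample]]:
    ranges = dict(config.spec_ranges or {})
    ranges.setdefault("height", config.scene_size)
    ranges.setdefault("width", config.scene_size)
    samples = generate_samples(config.n_scenes, ranges,
                               seed=stage_seed(config.seed, "simulate"))
    n_train = int(round(0.9 * len(samples)))
    return {"train": samples[:n_train], "test": samples[n_train:]}


def _segment_test_split(model: Optional[ReconstructionModel],
                        test: Sequence[SyntheticSample],
                        config: PipelineConfig):
    preds, fused_maps = [], []
    for s in test:
        if config.skip_reconstruction:
            if config.fusion.strategy == "rgb_pair":
                fused = fuse_rgb_pair(s.rgb, config.fusion.rgb_pair, config.fusion.epsilon)
            else:
                fused = fuse(s.spectral_clean, config.fusion)
        else:
            fused = fuse(reconstruct(model, s.rgb), config.fusion)
        preds.append(segment(fused, config.threshold))
        fused_maps.append(fused)
    return preds, fused_maps


def run_pipeline(config: PipelineConfig, out_dir: Optional[str] = None) -> PipelineResult:
    """simulate -> train -> reconstruct test split -> fuse -> segment -> evaluate."""
    t0 = time.time()
    stage = "simulate"
    try:
        data = _simulate(config)
        model, history = None, []
        if not config.skip_reconstruction:
            stage = "train"
            model = build_model(dataclasses.replace(
                config.model, init_seed=stage_seed(config.seed, "init")))
            tcfg = dataclasses.replace(config.train, seed=stage_seed(config.seed, "train"))
            model, history = train(model, data, tcfg)
        stage = "segment"
        preds, fused_maps = _segment_test_split(model, data["test"], config)
        stage = "evaluate"
        reports = [metrics.confusion_and_miou(p, s.mask)
                   for p, s in zip(preds, data["test"])]
        report = metrics.aggregate(reports)
    except Exception as err:  # surface which stage died
        raise RuntimeError(f"pipeline failed in stage '{stage}': {err}") from err

    result = PipelineResult(report=report, history=history,
                            per_image_miou=[r.miou for r in reports],
                            config_hash=config.hash(), out_dir=out_dir)
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        for i, (p, f) in enumerate(zip(preds, fused_maps)):
            raster_io.write_mask(p, os.path.join(out_dir, f"mask_{i:03d}.png"))
            import tifffile

            tifffile.imwrite(os.path.join(out_dir, f"fused_{i:03d}.tif"),
                             f.values.astype(np.float32))
        if history:
            pd.DataFrame([dataclasses.asdict(r) for r in history]).to_csv(
                os.path.join(out_dir, "history.csv"), index=False)
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            json.dump({"miou": report.miou, "pa": report.pa, "mpa": report.mpa,
                       "iou_background": report.iou_background,
                       "iou_vegetation": report.iou_vegetation,
                       "confusion_percent": report.confusion.tolist(),
                       "config_hash": result.config_hash,
                       "wall_time_s": round(time.time() - t0, 2)}, fh, indent=2)
        with open(os.path.join(out_dir, "config.json"), "w") as fh:
            json.dump({"hash": result.config_hash, "config": config.resolved()},
                      fh, indent=2, default=str)
    return result


# -- experiments -----------------------------------------------------------

def _experiment_threshold_sweep(config: PipelineConfig, grid=None) -> pd.DataFrame:
    """Segmentation quality of the trained SR route along a VI-threshold grid."""
    grid = list(grid) if grid is not None else [round(0.05 * k, 2) for k in range(9)]
    data = _simulate(config)
    model = build_model(dataclasses.replace(config.model,
                                            init_seed=stage_seed(config.seed, "init")))
    tcfg = dataclasses.replace(config.train, seed=stage_seed(config.seed, "train"))
    model, _ = train(model, data, tcfg)
    rows = []
    for t in grid:
        reps = []
        for s in data["test"]:
            pred = segment_fixed(fuse_vi(reconstruct(model, s.rgb)), t)
            reps.append(metrics.confusion_and_miou(pred, s.mask))
        agg = metrics.aggregate(reps)
        rows.append({"t": t, "miou": agg.miou, "pa": agg.pa, "mpa": agg.mpa})
    df = pd.DataFrame(rows)
    df["best"] = False
    df.loc[df["miou"].idxmax(), "best"] = True
    return df


def _experiment_fusion_compare(config: PipelineConfig) -> pd.DataFrame:
    """VI-based vs weight-based fusion on identical (oracle) spectra."""
    data = _simulate(config)
    rows = []
    for strategy, fuser, tcfg in (
        ("vi", lambda s: fuse_vi(s.spectral_clean), ThresholdConfig(mode="fixed")),
        ("weight", lambda s: fuse_weight(s.spectral_clean), ThresholdConfig(mode="adaptive")),
    ):
        reps = []
        for s in data["test"]:
            reps.append(metrics.confusion_and_miou(segment(fuser(s), tcfg), s.mask))
        agg = metrics.aggregate(reps)
        rows.append({"strategy": strategy, "miou": agg.miou, "pa": agg.pa, "mpa": agg.mpa})
    return pd.DataFrame(rows)


def _experiment_epoch_effect(config: PipelineConfig, noise_levels=(0.0, 3.0)) -> pd.DataFrame:
    """Per-epoch loss and downstream MIoU with and without band misalignment."""
    rows = []
    for noise in noise_levels:
        ranges = dict(config.spec_ranges or {})
        ranges["strong_noise_px"] = noise
        cfg = dataclasses.replace(config, spec_ranges=ranges)
        data = _simulate(cfg)
        model = build_model(dataclasses.replace(
            config.model, init_seed=stage_seed(config.seed, f"init{noise}")))
        tcfg = dataclasses.replace(config.train,
                                   seed=stage_seed(config.seed, f"train{noise}"))
        model, history = train(model, data, tcfg)
        for r in history:
            rows.append({"strong_noise_px": noise, "epoch": r.epoch, "loss": r.loss,
                         "mrae": r.mrae, "ssim": r.ssim, "seg_miou": r.seg_miou})
    return pd.DataFrame(rows)


def _experiment_ablation(config: PipelineConfig) -> pd.DataFrame:
    """Trained SR route vs direct RGB-channel-pair fusion on the same scenes."""
    data = _simulate(config)
    model = build_model(dataclasses.replace(config.model,
                                            init_seed=stage_seed(config.seed, "init")))
    tcfg = dataclasses.replace(config.train, seed=stage_seed(config.seed, "train"))
    model, _ = train(model, data, tcfg)
    rows = []
    t = config.train.vi_threshold
    reps = [metrics.confusion_and_miou(
        segment_fixed(fuse_vi(reconstruct(model, s.rgb)), t), s.mask)
        for s in data["test"]]
    agg = metrics.aggregate(reps)
    rows.append({"route": "sr", "miou": agg.miou, "pa": agg.pa, "mpa": agg.mpa})
    for pair in RGB_PAIRS:
        reps = [metrics.confusion_and_miou(
            segment_fixed(fuse_rgb_pair(s.rgb, pair), t), s.mask)
            for s in data["test"]]
        agg = metrics.aggregate(reps)
        rows.append({"route": f"rgb_{pair}", "miou": agg.miou, "pa": agg.pa, "mpa": agg.mpa})
    return pd.DataFrame(rows)


def run_experiment(name: str, config: Optional[PipelineConfig] = None,
                   out_dir: Optional[str] = None, **kwargs) -> pd.DataFrame:
    """Run one named experiment; writes ``<name>.csv`` (and a plot) if out_dir."""
    config = config or PipelineConfig()
    if name == "threshold_sweep":
        df = _experiment_threshold_sweep(config, kwargs.get("grid"))
    elif name == "fusion_compare":
        df = _experiment_fusion_compare(config)
    elif name == "epoch_effect":
        df = _experiment_epoch_effect(config, kwargs.get("noise_levels", (0.0, 3.0)))
    elif name == "ablation":
        df = _experiment_ablation(config)
    else:
        raise ValueError(f"unknown experiment {name!r}; choose from {EXPERIMENTS}")
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        df.to_csv(os.path.join(out_dir, f"{name}.csv"), index=False)
        _plot_experiment(name, df, os.path.join(out_dir, f"{name}.png"))
    return df


def _plot_experiment(name: str, df: pd.DataFrame, path: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    if name == "threshold_sweep":
        ax.plot(df["t"], df["miou"], marker="o")
        ax.set_xlabel("VI threshold t")
        ax.set_ylabel("MIoU")
    elif name == "epoch_effect":
        for noise, sub in df.groupby("strong_noise_px"):
            ax.plot(sub["epoch"], sub["seg_miou"], marker="o",
                    label=f"misalignment {noise} px")
        ax.set_xlabel("epoch")
        ax.set_ylabel("segmentation MIoU")
        ax.legend()
    else:
        key = "strategy" if "strategy" in df else "route"
        ax.bar(df[key], df["miou"])
        ax.set_ylabel("MIoU")
    ax.set_title(name.replace("_", " "))
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
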