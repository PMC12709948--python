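# vegsr

Weakly supervised segmentation of field vegetation from UAV RGB imagery via
**spectral reconstruction**: a small neural model maps an RGB image to the
four narrow bands of a crop-sensing multispectral camera (green 550 nm, red
660 nm, red-edge 735 nm, NIR 790 nm), the reconstructed bands are fused into
a vegetation-index map, and thresholding that map yields a binary
vegetation/background mask — **without any segmentation labels**. The
package is aimed at agricultural remote-sensing work where multispectral
hardware or pixel-level annotation is too expensive, and at method work on
RGB-to-spectral reconstruction and its downstream use.

## Method

Two reconstruction models are provided, both image-to-image operators
`RGB (H×W×3) → spectral (H×W×4)` on the unit scale:

* **SRCNet** — a dense-style convolutional network: each block's 3×3
  convolution output is concatenated with the block input and fused back to
  the base width by a 1×1 convolution, so features from every depth reach
  the output (default ≈ 0.19 M parameters).
* **SRANet** — a lightweight transformer-like network with **spectral
  self-attention**: queries/keys/values are per-channel descriptors with
  the flattened spatial positions as the feature axis, so attention relates
  spectral bands rather than pixels (default ≈ 0.03 M parameters).

Training minimizes the composite loss

```
L = MRAE(Ŷ, Y) + (1 − SSIM(Ŷ, Y))
```

with MRAE = mean |Ŷᵢ−Yᵢ|/Yᵢ and SSIM computed over 11×11 Gaussian windows.
The reconstruction Ŷ is then collapsed to a single index map either by the
VI (normalized-difference) rule

```
I_fv = (C_i − C_j) / (C_i + C_j)        (default: i = NIR, j = green)
```

or by a byte-scale weighted band sum `I_fw = Σ Wᵢ·Cᵢ` with
W = (−1, 0, 1, 1). Segmentation is `pixel > T_s → vegetation`, with a fixed
T_s (0.2 on the VI scale for uniform comparisons) or the mean-adaptive rule

```
T_s = 0.90·mean(I_fw)  if mean > 150
      1.15·mean(I_fw)  if mean < 145
      mean(I_fw)       otherwise
```

Quality is reported as MIoU / PA / MPA plus the per-class confusion table
for segmentation, and MRAE / SSIM / PSNR for reconstruction.

Because paired RGB–multispectral field data is not shippable, the package
includes a first-class **synthetic scene generator** (`vegsr.synthetic`)
producing paired RGB + 4-band scenes of vegetation / soil / plastic-film
classes in crop-row or dense layouts, with ground-truth masks and an
injectable **"strong noise"**: independent per-band sub-pixel translations
emulating the residual misalignment of multi-lens sensors. No neural-network
framework is assumed: the models run on a compact, gradient-checked
reverse-mode autodiff engine over numpy (`vegsr.nn`).

## Worked example

```python
import vegsr
from vegsr import metrics

# 200 paired synthetic scenes, 180 train / 20 test, 2 px band misalignment
samples = vegsr.generate_samples(200, seed=11)
data = {"train": samples[:180], "test": samples[180:]}

model = vegsr.build_srcnet()               # width 32, depth 6, ~0.19 M params
model, history = vegsr.train(model, data, vegsr.TrainConfig(epochs=10, seed=1))
print(f"final test loss {history[-1].loss:.3f}")

reps = [metrics.confusion_and_miou(
            vegsr.segment_fixed(vegsr.fuse_vi(vegsr.reconstruct(model, s.rgb)), 0.2),
            s.mask)
        for s in data["test"]]
print(f"segmentation MIoU {metrics.aggregate(reps).miou:.3f}")
```

prints (machine-dependent in the third decimal):

```
final test loss 0.661
segmentation MIoU 0.871
```

i.e. the loss has fallen from ~1.6 at epoch 1 to 0.66, and thresholding the
NDVI-style index of the *reconstructed* bands recovers the ground-truth
vegetation masks of 20 unseen scenes with MIoU 0.87 — while the best direct
RGB channel-pair index (the ablation without reconstruction) reaches only
≈ 0.60 on the same scenes (see `examples/04_threshold_sweep_and_ablation.py`).

The `examples/` directory holds one short narrative script per capability
(scene simulation, training, fusion + segmentation, threshold sweep +
ablation); `vegsr --help` exposes the same stages as a thin CLI
(`simulate`, `train`, `reconstruct`, `fuse`, `segment`, `evaluate`,
`pipeline`, `experiment`).

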