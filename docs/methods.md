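# Methods

This note documents the models, the synthetic data the package is tested
on, and the numerical and design choices a maintainer would want to know.

## Pipeline and assumptions

The pipeline assumes that vegetation is separable from background by its
reflectance *spectrum* — the chlorophyll absorption in the red band and the
steep red-edge/NIR rise — even when it is not cleanly separable in RGB.
Spectral reconstruction transfers that separability to plain RGB imagery:
a model trained once on paired RGB/multispectral data afterwards needs only
RGB input. Segmentation is then unsupervised downstream: a
normalized-difference index of the reconstructed bands is thresholded, so
no pixel labels enter training (masks are used for *evaluation* only).

Internal compute scale is unit [0, 1]; byte-scale inputs are divided by 255
on load. The one operation parameterized on the byte scale is the
mean-adaptive threshold (bounds 145/150 only make sense in [0, 255]), so
weight-fused maps are built on that scale explicitly.

## Reconstruction models

Both models are fully convolutional in space (any H, W ≥ 8 at inference;
output clamped to [0, 1] at inference only, so training gradients stay
clean).

**SRCNet** (default width 32, depth 6, growth 3, ≈ 0.19 M parameters):
stem 3×3 conv (3→w) → `depth` blocks of [3×3 conv w→g·w, ReLU,
channel-concat with block input, 1×1 fuse (g+1)·w→w] → head 3×3 conv
(w→4). The concatenation keeps early spatial detail available to the head;
there is no global residual path. The growth factor g exists because the
target size of the network (≈ 0.3 M) cannot be met by width-preserving
blocks at width 32 / depth 6 (which give only 0.07 M); g = 3 lands inside
the stated budget band [0.15, 0.45] M.

**SRANet** (default width 16, depth 3, 1 head, FFN expansion 2, ≈ 0.032 M
parameters): stem conv → `depth` blocks of [spectral self-attention +
residual; 3×3 conv FFN (w→2w, GELU, 2w→w) + residual] → head conv. The
attention treats *channels as tokens*: Q, K, V are 1×1-conv projections
reshaped to (heads, channels/heads, H·W); the attention matrix is
(channels × channels), softmax over key channels, scaled by 1/√(H·W). Its
cost is independent of how many pixels the image has, and it models
exactly the inter-band relationships the reconstruction needs. A
consequence worth knowing: the channel statistics pool over all positions,
so translation equivariance is only approximate for SRANet (exact, up to
boundary effects, for SRCNet).

Initialization is He-normal, seeded per model (`ModelConfig.init_seed`).
`ModelConfig.param_budget` optionally enforces a ±50 % size band at build
time.

### The autodiff engine

No tensor framework is assumed; `vegsr.nn.autograd` is a small
reverse-mode engine over float32 numpy arrays with exactly the operations
the models and loss need (conv2d stride-1/same via im2col, batched matmul,
softmax, ReLU/GELU, concat, reductions, and a Gaussian blur restricted to
fully covered windows). Every vector-Jacobian product is validated against
central finite differences in `tests/test_autograd.py`, and the full-model
directional derivative agrees with finite differences to < 1 %.

## Loss and metrics

Loss = MRAE + (1 − SSIM), unweighted, as a sum of the two evaluation
metrics — each epoch record satisfies `loss == mrae + (1 − ssim)` exactly
because the record is assembled from the metric values themselves.

* **MRAE** divides by the reference Y, which can be 0; the denominator is
  floored at 1/255 (one byte quantization step).
* **SSIM** uses an 11×11 Gaussian window (σ = 1.5), c1 = (0.01·MAX)²,
  c2 = (0.03·MAX)², averaged over the 4 bands. Only windows fully inside
  the image contribute (each side loses 5 px). This makes the
  constant-image closed form exact, keeps the operator self-adjoint under
  zero padding (so the training-time gradient is exact), and means images
  must be at least 12 px on a side. The differentiable loss term and the
  evaluation metric share the same window, so they agree to float32
  precision.
* **PSNR** = 10·log10(MAX²/MSE), capped at 100 dB for identical images.
* **MIoU** is the two-class mean IoU per image, averaged over the k test
  images; a class absent from both prediction and truth contributes IoU 1
  (vacuous agreement), which keeps all-background scenes well defined.
  PA/MPA are pixel accuracy and mean per-class recall, averaged per image
  the same way; the pooled confusion table is also reported (columns are
  normalized within each ground-truth class to percent).

## Fusion and segmentation

The VI rule uses (NIR − green)/(NIR + green + ε), ε = 1e-6, signed so that
vegetation is positive (consistent with "index > 0 means vegetation
cover" and with positive operating thresholds). The band pair is
configurable. Equality at the threshold goes to background — the
conservative class — since the strict inequalities of the rule leave it
open. The middle branch of the adaptive rule (mean between the bounds) is
completed as the identity, the unique continuous completion between the
two defined branches; the mean is global over the image. Thresholding is
monotone (vegetation count non-increasing in t) and idempotent on {0,1}
masks at t = 0.5; both are property-tested.

## Training

Adam, lr 1e-3 with cosine decay to 0, batch 16, random 24×24 crops with
horizontal/vertical flips, fully seeded. Crop 24 was chosen because the
one-CPU numpy engine hits a cache cliff above roughly 25 MB of per-step
intermediates (a 32-px crop at batch 16 is ~15× slower per step than a
24-px crop); with ~100 Adam steps per desk-scale run, lr 1e-3 is needed
for convergence (verified on the single-scene overfit oracle). Per-epoch
metrics are computed on (a subset of) the test split; optionally the
downstream segmentation MIoU (VI fusion + fixed 0.2, the uniform
comparison setting) is recorded per epoch, which is what exposes the
checkpoint-selection effect below.

`select_checkpoint` picks argmin-loss ("reconstruction") or
argmax-seg-MIoU ("segmentation"), ties to the earliest epoch.

## Synthetic scenes — what they emulate and what they do not

A scene is a class map (vegetation / soil / plastic mulch film) drawn from
thresholded smoothed Gaussian random fields; `row_crop` adds periodic
ridges so plants cluster in rows, `mixed` a weaker ridge. The vegetation
fraction is made near-exact per scene by thresholding the field at its own
empirical quantile. Film is carved out of the background by a second
smoothed field. Classes are rendered from mean reflectance signatures with
per-scene multiplicative jitter (sd 0.02), a scene illumination gain
(uniform 0.8–1.25 across a dataset), additive Gaussian pixel noise
(sd 0.02), and clipping to [0, 1].

Signature calibration is deliberate and two-sided:

* in the **spectral** bands, vegetation (0.10, 0.06, 0.45, 0.55) shows the
  red-edge rise while soil (0.32, 0.36, 0.30, 0.26) and film (0.64, 0.62,
  0.60, 0.55) are flat-to-falling, so the (NIR, green) index of every
  background class is negative with ≥ 2σ margin at the default pixel
  noise — this is the weak-supervision contract (clean spectra + threshold
  0 recover the mask with MIoU ≥ 0.95) and it is asserted, not assumed;
* in **RGB**, vegetation (0.15, 0.22, 0.10) and soil (0.40, 0.32, 0.22)
  are chosen so that no single two-channel normalized difference separates
  them cleanly (soil's G−B contrast 0.185 sits just below the 0.2
  operating threshold, within pixel-noise reach), while the full RGB
  triple still determines the class. This reproduces the field situation
  in which a learned RGB→spectral mapping genuinely outperforms direct
  RGB channel-pair indices, rather than making the ablation trivially
  lose.

"Strong noise" is modeled as an independent rigid sub-pixel translation of
each spectral band (uniform |dy|, |dx| ≤ magnitude, bilinear resampling,
edge replication), applied to the observed/training spectra only; RGB and
mask stay put. Translation is the minimal model of residual multi-lens
misalignment; rotation/scale residuals, fisheye distortion, mixed
boundary pixels, shadows, senescent vegetation and real radiometric
spectra are *not* modeled. Passing tests therefore demonstrate the
pipeline's internal correctness and the direction of the comparative
effects, not field-ready accuracy on real UAV data. Dataset defaults
(64×64 scenes, vegetation fraction 0.15–0.45, film 0–0.2, 2 px strong
noise) are the package's desk-scale study conditions.

## Desk-scale study sizes

The end-to-end study trains the default SRCNet on 180 synthetic 64×64
pairs for 10 epochs (~110 Adam steps, ~1 min on one CPU) and evaluates on
20 held-out scenes; the checkpoint-shift study trains the default SRANet
on 54 scenes of 48×48 for 10 epochs per arm (0 px vs 3 px misalignment,
5 seeds). These sizes are the package's chosen desk-scale defaults; all of
them are parameters, and larger runs only sharpen the same comparisons.

Observed behavior at these sizes: the reconstruction route reaches
segmentation MIoU ≈ 0.85–0.87 versus ≈ 0.60 for the best RGB pair; VI
fusion beats weight fusion (whose fixed byte-scale weights are not
invariant to illumination gain); with 3 px misalignment the
segmentation-best epoch precedes the loss-best epoch in the median (the
model first learns the inter-band mapping, then starts chasing the
displaced targets), while with 0 px the two checkpoints agree within
0.05 MIoU.

## Known limitations

* The engine is CPU-only, float32, stride-1/same convolutions only.
* SSIM (and hence the loss) requires images/crops ≥ 12 px per side.
* SRANet's global channel attention breaks exact translation
  equivariance; interior agreement is approximate.
* The generator's hard class boundaries make indices unrealistically
  bimodal near edges; real canopy mixing would soften every reported
  margin.
* Dataset-level PA/MPA are per-image averages; pooled-pixel variants can
  differ when scene sizes vary.
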