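"""The two RGB -> multispectral reconstruction models.

SRCNet is a small dense-style convolutional network: every block's 3x3
convolution output is channel-concatenated with the block input and fused
back to the base width by a 1x1 convolution, so features from every depth
survive to the head — the concatenation-heavy design that keeps spatial
detail when the training targets carry per-band misalignment.

SRANet is a lightweight transformer-like network whose attention operates
over the *spectral* (channel) dimension: queries, keys and values are
per-channel descriptors with the flattened spatial positions as the feature
axis, so the attention matrix is width x width regardless of image size.
Each block is attention + convolutional feed-forward, both with residual
connections.

Both are image-to-image operators: any H, W >= 8, unit-scale in and out.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass
from typing import Dict, List, Optional

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from ..types import RGBImage, SpectralImage


@dataclass
class ModelConfig:
    variant: str = "srcnet"  # srcnet | sranet
    width: int = 32
    depth: int = 6
    heads: int = 1  # sranet only
    growth: int = 3  # srcnet only: block conv expands width -> growth*width
    ffn_expand: int = 2  # sranet only
    init_seed: int = 0
    param_budget: Optional[int] = None

    def __post_init__(self) -> None:
        if self.width < 4 or self.depth < 1:
            raise ValueError("width must be >= 4 and depth >= 1")
        if self.variant not in ("srcnet", "sranet"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant == "sranet" and self.width % self.heads != 0:
            raise ValueError("width must be divisible by heads")


def default_config(variant: str) -> ModelConfig:
    if variant == "srcnet":
        return ModelConfig(variant="srcnet", width=32, depth=6, growth=3)
    if variant == "sranet":
        return ModelConfig(variant="sranet", width=16, depth=3, heads=1, ffn_expand=2)
    raise ValueError(f"unknown variant {variant!r}")


class Conv2d:
    """3x3 or 1x1 convolution layer owning its weight/bias tensors."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = c_in * k * k
        scale = np.sqrt(2.0 / fan_in)  # He init, matches the ReLU/GELU blocks
        self.weight = Tensor(rng.normal(0.0, scale, size=(c_out, c_in, k, k)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias)

    def params(self) -> List[Tensor]:
        return [self.weight, self.bias]


class _SRCBlock:
    def __init__(self, width: int, growth: int, rng):
        self.conv = Conv2d(width, growth * width, 3, rng)
        self.fuse = Conv2d((growth + 1) * width, width, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        y = ag.relu(self.conv(x))
        return self.fuse(ag.concat([x, y], axis=1))

    def params(self):
        return self.conv.params() + self.fuse.params()


class _SpectralAttention:
    """Multi-head self-attention across channels (spatial axis = features)."""

    def __init__(self, width: int, heads: int, rng):
        self.heads = heads
        self.q = Conv2d(width, width, 1, rng)
        self.k = Conv2d(width, width, 1, rng)
        self.v = Conv2d(width, width, 1, rng)
        self.proj = Conv2d(width, width, 1, rng)
        self.last_attention: Optional[np.ndarray] = None

    def __call__(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        hd, ch = self.heads, c // self.heads
        sp = h * w

        def tokens(t: Tensor) -> Tensor:
            # (N, C, H, W) -> (N, heads, C/heads, H*W): channel tokens
            return ag.reshape(t, (n, hd, ch, sp))

        q, k, v = tokens(self.q(x)), tokens(self.k(x)), tokens(self.v(x))
        scores = ag.matmul(q, ag.transpose(k, (0, 1, 3, 2)))  # (N, heads, C/h, C/h)
        scores = ag.mul(scores, 1.0 / np.sqrt(sp))
        attn = ag.softmax(scores, axis=-1)  # rows sum to 1 over key channels
        self.last_attention = attn.data
        out = ag.matmul(attn, v)  # (N, heads, C/h, H*W)
        out = ag.reshape(out, (n, c, h, w))
        return self.proj(out)

    def params(self):
        return self.q.params() + self.k.params() + self.v.params() + self.proj.params()


class _SRABlock:
    def __init__(self, width: int, heads: int, ffn_expand: int, rng):
        self.attn = _SpectralAttention(width, heads, rng)
        self.ffn1 = Conv2d(width, ffn_expand * width, 3, rng)
        self.ffn2 = Conv2d(ffn_expand * width, width, 3, rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = ag.add(x, self.attn(x))  # attention sublayer, residual
        y = self.ffn2(ag.gelu(self.ffn1(x)))  # conv feed-forward, residual
        return ag.add(x, y)

    def params(self):
        return self.attn.params() + self.ffn1.params() + self.ffn2.params()


class ReconstructionModel:
    """Image-to-image operator RGB (H, W, 3) -> spectral (H, W, 4), unit scale."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.init_seed)
        w = config.width
        self.stem = Conv2d(3, w, 3, rng)
        self.blocks: list = []
        for _ in range(config.depth):
            if config.variant == "srcnet":
                self.blocks.append(_SRCBlock(w, config.growth, rng))
            else:
                self.blocks.append(_SRABlock(w, config.heads, config.ffn_expand, rng))
        self.head = Conv2d(w, 4, 3, rng)
        if config.param_budget is not None:
            n = count_parameters(self)
            if not 0.5 * config.param_budget <= n <= 1.5 * config.param_budget:
                raise ValueError(
                    f"built model has {n} parameters, outside +/-50% of "
                    f"budget {config.param_budget}")

    def params(self) -> List[Tensor]:
        ps = self.stem.params()
        for b in self.blocks:
            ps += b.params()
        return ps + self.head.params()

    def forward(self, x: Tensor) -> Tensor:
        """x: (N, 3, H, W) float32 in [0, 1] -> (N, 4, H, W), unclamped."""
        h = self.stem(x) if self.config.variant == "sranet" else ag.relu(self.stem(x))
        for b in self.blocks:
            h = b(h)
        return self.head(h)

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    def state_dict(self) -> List[np.ndarray]:
        return [p.data.copy() for p in self.params()]

    def load_state(self, state: List[np.ndarray]) -> None:
        for p, s in zip(self.params(), state):
            if p.data.shape != s.shape:
                raise ValueError("state shape mismatch")
            p.data = s.astype(np.float32).copy()


def build_srcnet(config: Optional[ModelConfig] = None) -> ReconstructionModel:
    config = config or default_config("srcnet")
    if config.variant != "srcnet":
        raise ValueError("config.variant must be 'srcnet'")
    return ReconstructionModel(config)


def build_sranet(config: Optional[ModelConfig] = None) -> ReconstructionModel:
    config = config or default_config("sranet")
    if config.variant != "sranet":
        raise ValueError("config.variant must be 'sranet'")
    return ReconstructionModel(config)


def build_model(config: ModelConfig) -> ReconstructionModel:
    return build_srcnet(config) if config.variant == "srcnet" else build_sranet(config)


def count_parameters(model: ReconstructionModel) -> int:
    """Exact count of trainable scalars."""
    return int(sum(p.data.size for p in model.params()))


def reconstruct(model: ReconstructionModel, rgb: RGBImage) -> SpectralImage:
    """Run the model on one RGB image; output clamped to [0, 1]."""
    if rgb.value_scale != "unit":
        raise ValueError("reconstruct expects a unit-scale RGBImage")
    x = np.ascontiguousarray(rgb.pixels.transpose(2, 0, 1)[None], dtype=np.float32)
    y = model.forward(Tensor(x)).data[0].transpose(1, 2, 0)
    return SpectralImage(np.clip(y, 0.0, 1.0).astype(np.float64), "unit", rgb.id)


def reconstruct_batch(model: ReconstructionModel, rgbs: List[RGBImage]) -> List[SpectralImage]:
    return [reconstruct(model, r) for r in rgbs]


def save_checkpoint(model: ReconstructionModel, path: str) -> None:
    """Weights as .npz plus a JSON sidecar with the ModelConfig."""
    arrays = {f"p{i}": a for i, a in enumerate(model.state_dict())}
    np.savez(path if path.endswith(".npz") else path + ".npz", **arrays)
    with open(os.path.splitext(path)[0] + ".json", "w") as fh:
        json.dump(asdict(model.config), fh, indent=2)


def load_checkpoint(path: str) -> ReconstructionModel:
    stem = os.path.splitext(path)[0]
    with open(stem + ".json") as fh:
        config = ModelConfig(**json.load(fh))
    model = build_model(config)
    with np.load(stem + ".npz") as npz:
        model.load_state([npz[f"p{i}"] for i in range(len(npz.files))])
    return model


class Adam:
    """Adam optimizer over a parameter list."""

    def __init__(self, params: List[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
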