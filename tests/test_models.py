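import numpy as np
import pytest

import vegsr
from vegsr.nn.autograd import Tensor
from vegsr.nn.models import (
    Conv2d,
    ModelConfig,
    build_model,
    build_srcnet,
    build_sranet,
    count_parameters,
    default_config,
    load_checkpoint,
    reconstruct,
    save_checkpoint,
)
from vegsr.types import RGBImage


class TestShapes:
    @pytest.mark.parametrize("variant", ["srcnet", "sranet"])
    @pytest.mark.parametrize("hw", [(16, 16), (37, 41)])
    def test_output_shape(self, variant, hw, rng):
        cfg = (ModelConfig("srcnet", width=8, depth=2, growth=2) if variant == "srcnet"
               else ModelConfig("sranet", width=8, depth=2, heads=2))
        m = build_model(cfg)
        x = rng.random((1, 3) + hw).astype(np.float32)
        assert m.forward(Tensor(x)).shape == (1, 4) + hw

    def test_reconstruct_contract(self, tiny_model, scene):
        out = reconstruct(tiny_model, scene.rgb)
        assert out.pixels.shape == scene.rgb.pixels.shape[:2] + (4,)
        assert out.value_scale == "unit"
        assert out.pixels.min() >= 0.0 and out.pixels.max() <= 1.0

    def test_reconstruct_deterministic(self, tiny_model, scene):
        a = reconstruct(tiny_model, scene.rgb)
        b = reconstruct(tiny_model, scene.rgb)
        assert np.array_equal(a.pixels, b.pixels)

    def test_byte_scale_input_rejected(self, tiny_model):
        img = RGBImage(np.zeros((16, 16, 3), dtype=np.uint8), "byte")
        with pytest.raises(ValueError):
            reconstruct(tiny_model, img)


class TestParameterCounts:
    def test_single_conv_hand_count(self):
        conv = Conv2d(3, 4, 3, np.random.default_rng(0))
        assert sum(p.data.size for p in conv.params()) == 3 * 4 * 9 + 4  # 112

    def test_srcnet_budget(self):
        n = count_parameters(build_srcnet())
        assert 150_000 <= n <= 450_000  # soft budget around 0.30 M

    def test_sranet_budget(self):
        n = count_parameters(build_sranet())
        assert 15_000 <= n <= 45_000  # soft budget around 0.03 M

    def test_count_invariant_to_input_size(self, tiny_model, rng):
        n0 = count_parameters(tiny_model)
        tiny_model.forward(Tensor(rng.random((1, 3, 24, 24)).astype(np.float32)))
        assert count_parameters(tiny_model) == n0

    def test_param_budget_enforced(self):
        with pytest.raises(ValueError, match="budget"):
            build_srcnet(ModelConfig("srcnet", width=32, depth=6, growth=3,
                                     param_budget=1_000_000))

    def test_analytic_count_zero_depth_equivalent(self):
        # depth-1 minimal config: stem + one block + head, counted by hand
        cfg = ModelConfig("srcnet", width=4, depth=1, growth=1)
        m = build_srcnet(cfg)
        stem = 3 * 4 * 9 + 4
        block = (4 * 4 * 9 + 4) + (8 * 4 * 1 + 4)
        head = 4 * 4 * 9 + 4
        assert count_parameters(m) == stem + block + head


class TestAttention:
    def test_rows_sum_to_one(self, rng):
        m = build_sranet(ModelConfig("sranet", width=8, depth=1, heads=2))
        m.forward(Tensor(rng.random((1, 3, 16, 16)).astype(np.float32)))
        attn = m.blocks[0].attn.last_attention
        assert attn.shape == (1, 2, 4, 4)
        assert np.allclose(attn.sum(axis=-1), 1.0, atol=1e-5)


class TestEquivariance:
    def test_srcnet_translation_equivariance_interior(self, tiny_model, rng):
        """Shifting the input shifts the reconstruction, away from borders."""
        x = rng.random((40, 40, 3))
        d = 4
        a = reconstruct(tiny_model, RGBImage(x, "unit")).pixels
        b = reconstruct(tiny_model, RGBImage(np.roll(x, d, axis=1), "unit")).pixels
        margin = 10
        inner_a = a[margin:-margin, margin:-margin - d]
        inner_b = b[margin:-margin, margin + d:-margin]
        assert np.allclose(inner_a, inner_b, atol=1e-5)

    def test_sranet_translation_equivariance_approx(self, rng):
        m = build_sranet(ModelConfig("sranet", width=8, depth=1, heads=1))
        x = rng.random((48, 48, 3))
        d = 3
        a = reconstruct(m, RGBImage(x, "unit")).pixels
        b = reconstruct(m, RGBImage(np.roll(x, d, axis=1), "unit")).pixels
        margin = 12
        inner_a = a[margin:-margin, margin:-margin - d]
        inner_b = b[margin:-margin, margin + d:-margin]
        # attention pools over all positions, so equivariance is only
        # approximate: boundary rows perturb the channel statistics, and the
        # perturbation spreads globally; it must stay small, not vanish
        diff = np.abs(inner_a - inner_b)
        assert diff.mean() < 0.01
        assert diff.max() < 0.15


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path, tiny_model, scene):
        p = str(tmp_path / "ckpt.npz")
        save_checkpoint(tiny_model, p)
        back = load_checkpoint(p)
        assert back.config == tiny_model.config
        a = reconstruct(tiny_model, scene.rgb).pixels
        b = reconstruct(back, scene.rgb).pixels
        assert np.array_equal(a, b)


class TestConfigValidation:
    def test_variant_mismatch(self):
        with pytest.raises(ValueError):
            build_srcnet(default_config("sranet"))
        with pytest.raises(ValueError):
            build_sranet(default_config("srcnet"))

    def test_invalid_dimensions(self):
        with pytest.raises(ValueError):
            ModelConfig("srcnet", width=2)
        with pytest.raises(ValueError):
            ModelConfig("sranet", width=8, heads=3)
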