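import numpy as np
import pytest
from skimage.metrics import structural_similarity as sk_ssim

from vegsr import metrics
from vegsr.types import BinaryMask


class TestMseAndPsnr:
    def test_identity_capped(self, rng):
        x = rng.random((8, 8))
        assert metrics.mse(x, x) == 0.0
        assert metrics.psnr(x, x) == 100.0

    def test_constant_offset_hand_value(self):
        x = np.zeros((16, 16))
        y = np.full((16, 16), 10.0)
        assert metrics.mse(x, y) == 100.0
        assert metrics.psnr(x, y, max_value=255) == pytest.approx(28.13, abs=0.005)

    def test_translation_invariance(self, rng):
        x, y = rng.random((6, 6)), rng.random((6, 6))
        assert metrics.mse(x + 5, y + 5) == pytest.approx(metrics.mse(x, y), rel=1e-12)

    def test_monotone_in_mse(self):
        x = np.zeros((8, 8))
        assert metrics.psnr(x, x + 0.1) > metrics.psnr(x, x + 0.2)


class TestSsim:
    def test_identity(self, rng):
        x = rng.random((20, 20))
        assert metrics.ssim(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_constant_images_closed_form(self):
        a, b = 0.3, 0.7
        c1 = 0.01**2
        expected = (2 * a * b + c1) / (a**2 + b**2 + c1)
        got = metrics.ssim(np.full((15, 15), a), np.full((15, 15), b))
        assert got == pytest.approx(expected, rel=1e-9)

    def test_symmetry(self, rng):
        x, y = rng.random((16, 16)), rng.random((16, 16))
        assert metrics.ssim(x, y) == pytest.approx(metrics.ssim(y, x), rel=1e-12)

    def test_matches_reference_implementation(self, rng):
        """Independent cross-check against scikit-image's SSIM on a large
        image, where the slightly different border handling washes out."""
        x, y = rng.random((96, 96)), rng.random((96, 96))
        ref = sk_ssim(x, y, win_size=11, gaussian_weights=True, sigma=1.5,
                      use_sample_covariance=False, data_range=1.0)
        assert metrics.ssim(x, y) == pytest.approx(ref, abs=5e-3)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError, match="window"):
            metrics.ssim(np.zeros((8, 8)), np.zeros((8, 8)))


class TestMrae:
    def test_identity_and_scaling(self, rng):
        y = 0.1 + 0.9 * rng.random((10, 10))
        assert metrics.mrae(y, y) == 0.0
        assert metrics.mrae(1.2 * y, y) == pytest.approx(0.2, rel=1e-9)

    def test_two_pixel_hand_value(self):
        y = np.array([0.5, 1.0])
        x = np.array([0.6, 0.8])
        assert metrics.mrae(x, y) == pytest.approx(0.2, rel=1e-12)

    def test_asymmetric_in_arguments(self):
        x = np.full((4, 4), 0.5)
        y = np.full((4, 4), 1.0)
        assert metrics.mrae(x, y) != metrics.mrae(y, x)

    def test_denominator_floor(self):
        x = np.full((4, 4), 1.0)
        y = np.zeros((4, 4))
        assert metrics.mrae(x, y) == pytest.approx(255.0)


class TestSegmentationScores:
    def test_perfect_prediction(self, rng):
        m = BinaryMask((rng.random((9, 9)) > 0.5).astype(np.uint8))
        rep = metrics.confusion_and_miou(m, m)
        assert rep.miou == rep.pa == rep.mpa == 1.0

    def test_all_vegetation_vs_half(self):
        gt = BinaryMask(np.array([[1, 1], [0, 0]], dtype=np.uint8))
        pred = BinaryMask(np.ones((2, 2), dtype=np.uint8))
        rep = metrics.confusion_and_miou(pred, gt)
        assert rep.iou_vegetation == pytest.approx(0.5)
        assert rep.iou_background == 0.0
        assert rep.miou == pytest.approx(0.25)
        assert rep.pa == pytest.approx(0.5)

    def test_swap_symmetry_of_miou(self, rng):
        a = BinaryMask((rng.random((12, 12)) > 0.4).astype(np.uint8))
        b = BinaryMask((rng.random((12, 12)) > 0.6).astype(np.uint8))
        assert (metrics.confusion_and_miou(a, b).miou
                == pytest.approx(metrics.confusion_and_miou(b, a).miou, rel=1e-12))

    def test_absent_class_convention(self):
        z = BinaryMask(np.zeros((5, 5), dtype=np.uint8))
        rep = metrics.confusion_and_miou(z, z)
        assert rep.iou_vegetation == 1.0 and rep.miou == 1.0

    def test_confusion_columns_sum_to_100(self, rng):
        a = BinaryMask((rng.random((20, 20)) > 0.3).astype(np.uint8))
        b = BinaryMask((rng.random((20, 20)) > 0.7).astype(np.uint8))
        rep = metrics.confusion_and_miou(a, b)
        assert np.allclose(rep.confusion.sum(axis=0), [100.0, 100.0])

    def test_aggregate_is_mean_of_per_image_scores(self, rng):
        pairs = [((rng.random((8, 8)) > 0.5).astype(np.uint8),
                  (rng.random((8, 8)) > 0.5).astype(np.uint8)) for _ in range(4)]
        reports = [metrics.confusion_and_miou(BinaryMask(p), BinaryMask(g)) for p, g in pairs]
        agg = metrics.aggregate(reports)
        assert agg.miou == pytest.approx(np.mean([r.miou for r in reports]))
        assert agg.n_images == 4


class TestBruteForceOracles:
    """Every metric must match a per-pixel scalar loop to 1e-9 on 8x8 inputs."""

    def test_mse_mrae_loops(self, rng):
        x, y = rng.random((8, 8)), 0.1 + 0.8 * rng.random((8, 8))
        acc_mse, acc_mrae = 0.0, 0.0
        for i in range(8):
            for j in range(8):
                acc_mse += (x[i, j] - y[i, j]) ** 2
                acc_mrae += abs(x[i, j] - y[i, j]) / max(y[i, j], 1 / 255)
        assert metrics.mse(x, y) == pytest.approx(acc_mse / 64, abs=1e-9)
        assert metrics.mrae(x, y) == pytest.approx(acc_mrae / 64, abs=1e-9)

    def test_confusion_loop(self, rng):
        p = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        g = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        counts = np.zeros((2, 2))
        for i in range(8):
            for j in range(8):
                counts[p[i, j], g[i, j]] += 1
        rep = metrics.confusion_and_miou(BinaryMask(p), BinaryMask(g))
        assert np.array_equal(rep.counts, counts)
        iou_veg = counts[1, 1] / (counts[1, :].sum() + counts[:, 1].sum() - counts[1, 1])
        iou_back = counts[0, 0] / (counts[0, :].sum() + counts[:, 0].sum() - counts[0, 0])
        assert rep.miou == pytest.approx((iou_veg + iou_back) / 2, abs=1e-9)

    def test_ssim_windowed_loop(self, rng):
        """Brute-force local-statistics loop on a 13x13 image (one interior
        3x3 block of valid windows) reproduces the vectorized SSIM."""
        x, y = rng.random((13, 13)), rng.random((13, 13))
        k1 = np.exp(-(np.arange(-5, 6) ** 2) / (2 * 1.5**2))
        k1 /= k1.sum()
        w = np.outer(k1, k1)
        c1, c2 = 0.01**2, 0.03**2
        vals = []
        for ci in range(5, 8):
            for cj in range(5, 8):
                wx = x[ci - 5:ci + 6, cj - 5:cj + 6]
                wy = y[ci - 5:ci + 6, cj - 5:cj + 6]
                mx, my = (w * wx).sum(), (w * wy).sum()
                vx = (w * wx * wx).sum() - mx**2
                vy = (w * wy * wy).sum() - my**2
                vxy = (w * wx * wy).sum() - mx * my
                vals.append(((2 * mx * my + c1) * (2 * vxy + c2))
                            / ((mx**2 + my**2 + c1) * (vx + vy + c2)))
        assert metrics.ssim(x, y) == pytest.approx(np.mean(vals), abs=1e-9)
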