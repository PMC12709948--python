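import dataclasses

import numpy as np
import pytest

import vegsr
from vegsr import metrics, training
from vegsr.nn.models import ModelConfig, build_model
from vegsr.training import EpochRecord, TrainConfig, select_checkpoint, train
from vegsr.types import SpectralImage


def _small_data(n_train=6, n_test=2, seed=0, **ranges):
    opts = {"height": 32, "width": 32, "strong_noise_px": 0.0}
    opts.update(ranges)
    samples = vegsr.generate_samples(n_train + n_test, opts, seed=seed)
    return {"train": samples[:n_train], "test": samples[n_train:]}


def _small_model(seed=0):
    return build_model(ModelConfig("srcnet", width=8, depth=2, growth=2, init_seed=seed))


class TestLoss:
    def test_identical_images_give_zero(self, scene):
        assert training.loss(scene.spectral_clean, scene.spectral_clean) == pytest.approx(0.0, abs=1e-12)

    def test_decomposes_into_metric_terms(self, rng):
        """loss == MRAE + (1 - SSIM) exactly, both computed by the metrics
        module on the same pair."""
        x = SpectralImage(rng.random((24, 24, 4)), "unit")
        y = SpectralImage(rng.random((24, 24, 4)), "unit")
        s, _ = metrics.ssim_multiband(x.pixels, y.pixels)
        expected = metrics.mrae(x.pixels, y.pixels) + (1.0 - s)
        assert training.loss(x, y) == pytest.approx(expected, abs=1e-9)

    def test_nonnegative(self, rng):
        x = SpectralImage(rng.random((16, 16, 4)), "unit")
        y = SpectralImage(rng.random((16, 16, 4)), "unit")
        assert training.loss(x, y) >= 0.0

    def test_shape_mismatch_rejected(self, rng):
        x = SpectralImage(rng.random((16, 16, 4)), "unit")
        y = SpectralImage(rng.random((20, 20, 4)), "unit")
        with pytest.raises(ValueError):
            training.loss(x, y)

    def test_differentiable_loss_matches_metrics(self, rng):
        """The float32 training loss agrees with the float64 evaluation path."""
        from vegsr.nn.autograd import Tensor

        x = rng.random((1, 4, 24, 24)).astype(np.float32)
        y = rng.random((1, 4, 24, 24)).astype(np.float32)
        lt = float(training.loss_tensor(Tensor(x), y).data)
        le = training.loss(SpectralImage(x[0].transpose(1, 2, 0).astype(np.float64), "unit"),
                           SpectralImage(y[0].transpose(1, 2, 0).astype(np.float64), "unit"))
        assert lt == pytest.approx(le, abs=1e-4)


class TestTrainLoop:
    def test_history_records_and_identity(self):
        data = _small_data()
        cfg = TrainConfig(epochs=2, batch_size=4, crop_size=24, seed=3)
        _, hist = train(_small_model(), data, cfg)
        assert len(hist) == 2
        for r in hist:
            assert r.loss == pytest.approx(r.mrae + (1.0 - r.ssim), abs=1e-9)
            assert r.seg_miou is not None

    def test_deterministic_under_seed(self):
        cfg = TrainConfig(epochs=2, batch_size=4, crop_size=24, seed=7)
        _, h1 = train(_small_model(seed=1), _small_data(), cfg)
        _, h2 = train(_small_model(seed=1), _small_data(), cfg)
        assert [(r.loss, r.mrae, r.ssim, r.seg_miou) for r in h1] \
            == [(r.loss, r.mrae, r.ssim, r.seg_miou) for r in h2]

    def test_loss_decreases_with_training(self):
        data = _small_data(n_train=8, n_test=2)
        cfg = TrainConfig(epochs=6, batch_size=4, crop_size=24, seed=0,
                          eval_segmentation_every=0)
        _, hist = train(_small_model(), data, cfg)
        assert hist[-1].loss < hist[0].loss

    def test_no_training_pairs_rejected(self):
        with pytest.raises(ValueError):
            train(_small_model(), {"train": [], "test": []}, TrainConfig(epochs=1))

    def test_overfit_oracle_constant_pair(self):
        """Capacity sanity check: a model driven onto one constant scene
        reconstructs it with small MRAE."""
        sample = vegsr.generate_scene(vegsr.SceneSpec(
            height=32, width=32, target_veg_fraction=0.0, film_fraction=0.0,
            pixel_noise_sd=0.0, seed=2))
        data = {"train": [sample] * 16, "test": [sample]}
        cfg = TrainConfig(epochs=50, batch_size=4, crop_size=24, seed=0,
                          learning_rate=3e-3,  # small problem, drive hard
                          eval_segmentation_every=0, flip_augment=False)
        _, hist = train(_small_model(), data, cfg)
        assert hist[-1].mrae < 0.05


class TestSelectCheckpoint:
    @staticmethod
    def _rec(epoch, loss=1.0, miou=None):
        return EpochRecord(epoch, loss, 0.0, 0.0, 0.0, miou)

    def test_segmentation_argmax(self):
        hist = [self._rec(1, miou=0.5), self._rec(2, miou=0.8), self._rec(3, miou=0.7)]
        assert select_checkpoint(hist, "segmentation") == 2

    def test_reconstruction_argmin(self):
        hist = [self._rec(1, loss=0.9), self._rec(2, loss=0.4), self._rec(3, loss=0.5)]
        assert select_checkpoint(hist, "reconstruction") == 2

    def test_ties_go_to_earliest(self):
        hist = [self._rec(1, loss=0.5, miou=0.5), self._rec(2, loss=0.5, miou=0.5)]
        assert select_checkpoint(hist, "reconstruction") == 1
        assert select_checkpoint(hist, "segmentation") == 1

    def test_missing_criterion_rejected(self):
        with pytest.raises(ValueError):
            select_checkpoint([self._rec(1)], "segmentation")
        with pytest.raises(ValueError):
            select_checkpoint([self._rec(1)], "f1")
        with pytest.raises(ValueError):
            select_checkpoint([], "reconstruction")


class TestCheckpointAgreementWithoutNoise:
    def test_clean_data_checkpoints_agree(self):
        """Without band misalignment the reconstruction-best and
        segmentation-best checkpoints give similar downstream MIoU."""
        data = _small_data(n_train=16, n_test=4, seed=5)
        cfg = TrainConfig(epochs=6, batch_size=8, crop_size=24, seed=1)
        _, hist = train(_small_model(), data, cfg)
        e_rec = select_checkpoint(hist, "reconstruction")
        e_seg = select_checkpoint(hist, "segmentation")
        miou = {r.epoch: r.seg_miou for r in hist}
        assert abs(miou[e_rec] - miou[e_seg]) <= 0.10
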