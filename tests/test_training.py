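"""Splits, losses, augmentations and the segmentation training contract."""

import math
from dataclasses import replace

import numpy as np
import pytest

from spikelet.annotations import Point2D, PointAnnotationSet, ScaleCalibration
from spikelet.masks import make_binary_mask
from spikelet.synthetic import SpikeSynthParams, generate_spike_image
from spikelet.training import (
    AugmentationPipeline,
    AugmentationSpec,
    Sample,
    SegmentationModel,
    TrainConfig,
    _batch_loss_and_grad,
    build_augmentation_pipeline,
    load_checkpoint,
    loss_bce,
    loss_kldiv,
    predict_mask,
    save_checkpoint,
    split_dataset,
    train_segmentation_model,
)


class TestSplitDataset:
    def test_sizes_and_partition(self):
        ids = [f"i{k}" for k in range(10)]
        tr, va, te = split_dataset(ids, (0.6, 0.2, 0.2), seed=3)
        assert (len(tr), len(va), len(te)) == (6, 2, 2)
        assert sorted(tr + va + te) == sorted(ids)

    def test_deterministic_in_seed(self):
        ids = [f"i{k}" for k in range(25)]
        assert split_dataset(ids, seed=11) == split_dataset(ids, seed=11)
        assert split_dataset(ids, seed=11) != split_dataset(ids, seed=12)

    def test_full_dataset_rounding(self):
        # 1,745 images at 60/20/20
        ids = [str(k) for k in range(1745)]
        tr, va, te = split_dataset(ids)
        assert (len(tr), len(va), len(te)) == (1047, 349, 349)

    def test_too_few_images_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(["a", "b"])


def brute_force_bce(z, t):
    total = 0.0
    for zi, ti in zip(z.ravel(), t.ravel()):
        p = 1.0 / (1.0 + math.exp(-zi))
        total += -(ti * math.log(p) + (1 - ti) * math.log(1 - p))
    return total / z.size


def brute_force_kl(logp, t):
    total = 0.0
    for lp, ti in zip(logp.ravel(), t.ravel()):
        if ti > 0:
            total += ti * (math.log(ti) - lp)
    return total


class TestLosses:
    def test_zero_logits_give_ln2(self):
        z = np.zeros((4, 4))
        t = np.array([[1, 0]] * 8).reshape(4, 4).astype(float)
        assert loss_bce(z, t) == pytest.approx(math.log(2), rel=1e-12)

    def test_confident_correct_logits_drive_loss_to_zero(self):
        t = (np.arange(16).reshape(4, 4) % 3 == 0).astype(float)
        z = np.where(t > 0, 40.0, -40.0)
        assert loss_bce(z, t) < 1e-12

    def test_bce_matches_per_pixel_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            z = rng.normal(0, 2, size=(4, 4))
            t = (rng.random((4, 4)) > 0.5).astype(float)
            assert loss_bce(z, t) == pytest.approx(brute_force_bce(z, t), abs=1e-9)

    def test_bce_rejects_non_binary_target(self):
        with pytest.raises(ValueError, match="0 and 1"):
            loss_bce(np.zeros((2, 2)), np.full((2, 2), 0.3))

    def test_kl_of_identical_distributions_is_zero(self):
        rng = np.random.default_rng(1)
        t = rng.random((4, 4))
        t /= t.sum()
        assert loss_kldiv(np.log(t), t) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_prediction_vs_one_hot_is_ln_n(self):
        n = 16
        t = np.zeros((4, 4))
        t[2, 1] = 1.0
        logp = np.full((4, 4), -math.log(n))
        assert loss_kldiv(logp, t) == pytest.approx(math.log(n), rel=1e-12)

    def test_kl_matches_brute_force_sum(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            t = rng.random((4, 4))
            t /= t.sum()
            q = rng.random((4, 4)) + 1e-3
            logp = np.log(q / q.sum())
            assert loss_kldiv(logp, t) == pytest.approx(brute_force_kl(logp, t), abs=1e-9)

    def test_kl_rejects_unnormalized_target(self):
        with pytest.raises(ValueError, match="sum to 1"):
            loss_kldiv(np.zeros((2, 2)), np.full((2, 2), 0.5))


class TestAugmentationPipeline:
    def _image(self, h=16, w=16, seed=0):
        rng = np.random.default_rng(seed)
        return rng.random((h, w, 3))

    def test_all_probabilities_zero_is_identity_at_same_size(self):
        spec = AugmentationSpec.identity((16, 16))
        img = self._image()
        tgt = (self._image(seed=1)[:, :, 0] > 0.5).astype(float)
        pts = np.array([[3.0, 4.0]])
        out_img, out_tgt, out_pts = AugmentationPipeline(spec, 0)(img, tgt, pts)
        assert np.allclose(out_img, img)
        assert np.array_equal(out_tgt, tgt)
        assert np.allclose(out_pts, pts)

    def test_horizontal_flip_moves_points_and_mask_consistently(self):
        spec = replace(AugmentationSpec.identity((16, 16)), hflip_p=1.0)
        img = self._image()
        tgt = np.zeros((16, 16))
        tgt[5, 3] = 1.0
        pts = np.array([[3.0, 5.0]])
        out_img, out_tgt, out_pts = AugmentationPipeline(spec, 0)(img, tgt, pts)
        assert out_pts[0, 0] == 15 - 3 and out_pts[0, 1] == 5
        assert out_tgt[5, 15 - 3] == 1.0
        assert np.allclose(out_img, img[:, ::-1])

    def test_rotation_keeps_points_aligned_with_warped_mask(self):
        # rasterize-then-rotate must agree with rotate-then-rasterize
        # within one pixel of raster tolerance
        spec = replace(AugmentationSpec.identity((64, 64)), rotate_p=1.0)
        ann = PointAnnotationSet(
            "r", (64, 64), [Point2D(40.0, 22.0)], ScaleCalibration(8.0)
        )
        tgt = np.zeros((64, 64))
        tgt[22, 40] = 1.0
        pipe = AugmentationPipeline(spec, seed=5)
        _, out_tgt, out_pts = pipe(self._image(64, 64), tgt, ann.xy_array())
        r, c = np.unravel_index(np.argmax(out_tgt), out_tgt.shape)
        assert math.hypot(c - out_pts[0, 0], r - out_pts[0, 1]) <= 1.0

    def test_same_seed_same_draws(self):
        spec = AugmentationSpec(resize_to=(16, 16))
        img = self._image()
        a = AugmentationPipeline(spec, 7)
        b = AugmentationPipeline(spec, 7)
        for _ in range(4):
            ia, _, _ = a(img)
            ib, _, _ = b(img)
            assert np.array_equal(ia, ib)

    def test_shape_mismatch_rejected(self):
        pipe = build_augmentation_pipeline(AugmentationSpec.identity((16, 16)))
        with pytest.raises(ValueError, match="shape"):
            pipe(self._image(16, 16), np.zeros((8, 8)))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            AugmentationSpec(hflip_p=1.5)
        with pytest.raises(ValueError):
            AugmentationSpec(resize_to=(30, 16))


class TestTrainConfig:
    def test_loss_must_match_scheme(self):
        with pytest.raises(ValueError, match="incompatible"):
            TrainConfig(target_scheme="binary", loss="kldiv")

    def test_scheme_defaults(self):
        assert TrainConfig(target_scheme="binary").loss == "bce"
        assert TrainConfig(target_scheme="gaussian").loss == "kldiv"

    def test_yaml_round_trip(self):
        import yaml

        cfg = TrainConfig(target_scheme="gaussian", encoder_name="unet-tiny", epochs=3)
        back = TrainConfig.from_dict(yaml.safe_load(yaml.safe_dump(cfg.to_dict())))
        assert back == cfg


def tiny_samples(n=4, seed=0, size=(64, 32)):
    params = SpikeSynthParams(
        image_size=size, px_per_mm=2.0, n_spikelets=3, spacing_mm=4.0,
        curvature_amplitude_mm=1.0,
    )
    out = []
    for k in range(n):
        img, ann = generate_spike_image(replace(params, seed=seed + k))
        ann.image_id = f"t{k}"
        out.append(Sample(image_id=f"t{k}", image=img, annotations=ann))
    return out


def tiny_config(scheme="binary", epochs=1, seed=0):
    return TrainConfig(
        target_scheme=scheme, encoder_name="unet-micro", epochs=epochs,
        batch_size=2, learning_rate=1e-3, seed=seed,
        augmentation=AugmentationSpec.identity((64, 32)),
    )


class TestModelGradients:
    def test_analytic_gradients_match_finite_differences(self):
        cfg = tiny_config()
        model = SegmentationModel(replace(cfg, augmentation=AugmentationSpec.identity((8, 8))))
        rng = np.random.default_rng(1)
        x = rng.random((1, 3, 8, 8))
        t = (rng.random((1, 1, 8, 8)) > 0.7).astype(float)
        z = model.forward(x)
        _, dz = _batch_loss_and_grad(z, t, "binary")
        model.backward(dz)
        grads = [g.copy() for g in model.gradients()]
        params = model.parameters()
        eps = 1e-6
        for pi in (0, 7, 16):
            flat, gflat = params[pi].reshape(-1), grads[pi].reshape(-1)
            for idx in (0, flat.size - 1):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp, _ = _batch_loss_and_grad(model.forward(x), t, "binary")
                flat[idx] = orig - eps
                lm, _ = _batch_loss_and_grad(model.forward(x), t, "binary")
                flat[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert gflat[idx] == pytest.approx(num, abs=1e-6, rel=1e-4)


class TestTrainingContract:
    def test_one_epoch_smoke(self):
        samples = tiny_samples(4)
        model, hist = train_segmentation_model(samples[:2], samples[2:], tiny_config())
        assert len(hist.train_loss) == len(hist.val_loss) == len(hist.val_f1) == 1
        assert hist.best_epoch == 0

    def test_identical_seed_identical_history(self):
        samples = tiny_samples(4)
        cfg = tiny_config(epochs=2, seed=5)
        _, h1 = train_segmentation_model(samples[:2], samples[2:], cfg)
        _, h2 = train_segmentation_model(samples[:2], samples[2:], cfg)
        assert h1.train_loss == h2.train_loss
        assert h1.val_loss == h2.val_loss
        assert h1.val_f1 == h2.val_f1

    def test_empty_split_rejected(self):
        samples = tiny_samples(2)
        with pytest.raises(ValueError, match="non-empty"):
            train_segmentation_model(samples, [], tiny_config())

    @pytest.mark.parametrize("scheme", ["binary", "gaussian"])
    def test_prediction_codomain_and_determinism(self, scheme):
        samples = tiny_samples(4)
        model, _ = train_segmentation_model(
            samples[:2], samples[2:], tiny_config(scheme=scheme)
        )
        pred1 = predict_mask(model, samples[0].image)
        pred2 = predict_mask(model, samples[0].image)
        assert np.array_equal(pred1, pred2)
        assert pred1.shape == samples[0].image.shape[:2]
        if scheme == "binary":
            assert pred1.min() >= 0.0 and pred1.max() <= 1.0
        else:
            assert pred1.min() >= 0.0
            assert pred1.sum() == pytest.approx(1.0, abs=1e-9)

    def test_checkpoint_round_trip(self, tmp_path):
        samples = tiny_samples(4)
        model, _ = train_segmentation_model(samples[:2], samples[2:], tiny_config())
        f = tmp_path / "ckpt.npz"
        save_checkpoint(model, f)
        back = load_checkpoint(f)
        assert back.config == model.config
        assert np.array_equal(
            predict_mask(back, samples[0].image), predict_mask(model, samples[0].image)
        )

    def test_overfit_single_image_recovers_its_own_annotations(self):
        # trained to convergence on one image, the model must decode its
        # own training centers back at F1 = 1 within the 2 mm radius
        from spikelet.evaluation import detection_metrics, match_centers
        from spikelet.extraction import extract_centers_binary

        sample = tiny_samples(1, seed=3)[0]
        cfg = tiny_config(epochs=60, seed=2)
        cfg = replace(cfg, batch_size=1, learning_rate=3e-3, encoder_name="unet-tiny")
        model, hist = train_segmentation_model([sample], [sample], cfg)
        assert max(hist.val_f1) == 1.0
        pred = predict_mask(model, sample.image)
        centers = extract_centers_binary(pred, cfg.extraction, sample.annotations.scale)
        m = match_centers(centers, sample.annotations.points, 2.0, sample.annotations.scale)
        assert detection_metrics(m).f1 == 1.0
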