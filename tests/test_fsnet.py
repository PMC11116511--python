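"""Segmentation stage: Dice loss arithmetic, architecture, training."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import sdetnet as sd
from sdetnet.fsnet import (SegTrainConfig, _batched_dice_loss_grad,
                           augment_pair, build_fsnet, predict_slices)


class TestDiceLoss:
    def test_perfect_overlap_is_slightly_negative(self):
        y = np.ones((10, 10))
        # 1 - 2(100 + 1e-3)/(200 + 1e-3)
        assert sd.dice_loss(y, y.astype(float)) == pytest.approx(-5.0e-6,
                                                                 abs=1e-7)

    def test_total_miss(self):
        y = np.zeros((10, 10))
        y.flat[:4] = 1
        assert sd.dice_loss(y, np.zeros((10, 10))) == pytest.approx(0.9995,
                                                                    abs=1e-4)

    def test_empty_empty_is_minus_one(self):
        z = np.zeros((4, 4))
        assert sd.dice_loss(z, z) == -1.0

    def test_empty_empty_as_metric_is_zero_with_warning(self):
        z = np.zeros((4, 4))
        with pytest.warns(UserWarning):
            assert sd.dice_loss(z, z, mode="metric") == 0.0

    def test_shape_and_range_validation(self):
        with pytest.raises(ValueError):
            sd.dice_loss(np.zeros((2, 2)), np.zeros((3, 3)))
        with pytest.raises(ValueError):
            sd.dice_loss(np.zeros((2, 2)), np.full((2, 2), 1.5))
        with pytest.raises(ValueError):
            sd.dice_loss(np.full((2, 2), 0.3), np.zeros((2, 2)))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(hnp.arrays(np.int8, (6, 6), elements=st.integers(0, 1)),
           hnp.arrays(np.float64, (6, 6),
                      elements=st.floats(0, 1, allow_nan=False)))
    def test_range_for_nonempty_truth(self, y, p):
        y = y.astype(float)
        if y.sum() == 0:
            y.flat[0] = 1.0
        loss = sd.dice_loss(y, p)
        assert -1e-3 < loss <= 1.0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(hnp.arrays(np.int8, (5, 5), elements=st.integers(0, 1)),
           hnp.arrays(np.int8, (5, 5), elements=st.integers(0, 1)))
    def test_symmetric_for_binary_inputs(self, a, b):
        a, b = a.astype(float), b.astype(float)
        assert sd.dice_loss(a, b) == pytest.approx(sd.dice_loss(b, a))

    def test_monotone_in_true_positive_pixel(self):
        y = np.zeros((4, 4))
        y[1, 1] = 1
        p = np.full((4, 4), 0.2)
        losses = []
        for v in (0.1, 0.5, 0.9):
            q = p.copy()
            q[1, 1] = v
            losses.append(sd.dice_loss(y, q))
        assert losses[0] > losses[1] > losses[2]

    def test_batch_aggregation_matches_manual_sums(self, rng):
        y = (rng.random((3, 1, 8, 8)) > 0.7).astype(np.float32)
        p = rng.random((3, 1, 8, 8)).astype(np.float32)
        loss, _ = _batched_dice_loss_grad(y, p, aggregation="batch")
        s = (y.astype(float) * p.astype(float)).sum() + 1e-3
        t = y.sum() + p.sum() + 1e-3
        assert loss == pytest.approx(1 - 2 * s / t)

    def test_per_slice_aggregation_matches_public_op(self, rng):
        y = (rng.random((3, 1, 8, 8)) > 0.7).astype(np.float32)
        p = rng.random((3, 1, 8, 8)).astype(np.float32)
        loss, _ = _batched_dice_loss_grad(y, p, aggregation="per_slice")
        manual = np.mean([sd.dice_loss(y[i, 0], p[i, 0]) for i in range(3)])
        assert loss == pytest.approx(manual)


class TestArchitecture:
    def test_output_shape_and_range(self, rng):
        model = build_fsnet(sd.SegModelConfig(backbone="tiny",
                                              input_size=(64, 64)))
        x = rng.random((2, 1, 64, 64)).astype(np.float32)
        p = model.forward(x)
        assert p.shape == (2, 1, 64, 64)
        assert 0 < p.min() and p.max() < 1

    def test_five_decoder_levels_give_five_upsampling_stages(self):
        model = build_fsnet(sd.SegModelConfig(backbone="vgg16-like",
                                              decoder_levels=5,
                                              base_channels=4,
                                              input_size=(64, 64)))
        assert model.n_upsample_stages == 5

    def test_zero_output_layer_gives_half_everywhere(self, rng):
        model = build_fsnet(sd.SegModelConfig(backbone="tiny",
                                              input_size=(32, 32)))
        model.out_conv.params["W"][...] = 0.0
        model.out_conv.params["b"][...] = 0.0
        p = model.forward(rng.random((1, 1, 32, 32)).astype(np.float32))
        assert np.allclose(p, 0.5)

    def test_indivisible_input_rejected(self):
        with pytest.raises(ValueError):
            sd.SegModelConfig(backbone="tiny", input_size=(30, 30))

    def test_pretrained_flag_rejected(self):
        with pytest.raises(ValueError, match="pretrained"):
            sd.SegModelConfig(backbone="vgg16-like", use_pretrained=True,
                              input_size=(64, 64))


class TestAugmentation:
    def test_rotation_keeps_pair_aligned(self, rng):
        cfg = SegTrainConfig(blur_strength=0.0, brightness_frac=0.0)
        mask = np.zeros((32, 32), dtype=np.float32)
        mask[10:20, 12:22] = 1.0
        image = mask.copy()
        for _ in range(5):
            im, mk = augment_pair(image, mask, rng, cfg)
            assert set(np.unique(mk)) <= {0.0, 1.0}
            inter = ((im > 0.5) & (mk > 0.5)).sum()
            union = ((im > 0.5) | (mk > 0.5)).sum()
            assert inter / union > 0.9  # identical rotation on both

    def test_intensity_ops_leave_mask_untouched(self, rng):
        cfg = SegTrainConfig(rotation_deg=0.0)
        image = rng.random((16, 16)).astype(np.float32)
        mask = (rng.random((16, 16)) > 0.5).astype(np.float32)
        im, mk = augment_pair(image, mask, rng, cfg)
        assert np.array_equal(mk, mask)
        assert not np.array_equal(im, image)


def _toy_batches(rng, n=20, size=32):
    spec = sd.PhantomSpec.tiny()
    vol, msk = sd.generate_phantom(spec, sex=0, instance_seed=1)
    idx = rng.choice(spec.grid_size, size=n)
    imgs = vol.data[idx]
    msks = msk.data[idx].astype(np.float32)
    return sd.SliceBatch(imgs, msks), sd.SliceBatch(imgs[:4], msks[:4])


class TestTraining:
    def test_smoke_history_and_loss_trend(self, rng):
        train, val = _toy_batches(rng)
        cfg = sd.SegModelConfig(backbone="tiny", input_size=(32, 32))
        improved = 0
        for seed in (0, 1, 2):
            model = build_fsnet(cfg, seed=seed)
            _, hist = sd.train_fsnet(
                model, train, val,
                SegTrainConfig(epochs=3, batch_size=8, seed=seed))
            assert len(hist["train_loss"]) == 3
            if hist["train_loss"][-1] <= hist["train_loss"][0]:
                improved += 1
        assert improved >= 2

    def test_lr_recorded_and_never_below_floor(self, rng):
        train, val = _toy_batches(rng, n=8)
        model = build_fsnet(sd.SegModelConfig(backbone="tiny",
                                              input_size=(32, 32)))
        _, hist = sd.train_fsnet(
            model, train, val,
            SegTrainConfig(epochs=6, batch_size=8, plateau_patience=1,
                           initial_lr=1e-3, lr_floor=5e-4))
        assert all(lr >= 5e-4 for lr in hist["lr"])
        assert hist["lr"][0] == 1e-3

    def test_empty_sets_rejected(self, rng):
        train, val = _toy_batches(rng, n=4)
        model = build_fsnet(sd.SegModelConfig(backbone="tiny",
                                              input_size=(32, 32)))
        empty = sd.SliceBatch(np.zeros((0, 32, 32)), np.zeros((0, 32, 32)))
        with pytest.raises(ValueError):
            sd.train_fsnet(model, empty, val, SegTrainConfig(epochs=1))


class TestPrediction:
    def test_uniform_half_probability_marks_everything(self, tiny_spec, rng):
        model = build_fsnet(sd.SegModelConfig(backbone="tiny",
                                              input_size=(32, 32)))
        model.out_conv.params["W"][...] = 0.0
        model.out_conv.params["b"][...] = 0.0
        vol, _ = sd.generate_phantom(tiny_spec, 0, 1)
        probs, mask = predict_slices(model, vol)
        assert np.allclose(probs, 0.5)
        assert mask.data.all()  # >= 0.5 convention includes the boundary

    def test_strongly_negative_bias_gives_empty_mask(self, tiny_spec):
        model = build_fsnet(sd.SegModelConfig(backbone="tiny",
                                              input_size=(32, 32)))
        model.out_conv.params["W"][...] = 0.0
        model.out_conv.params["b"][...] = -10.0
        vol, _ = sd.generate_phantom(tiny_spec, 0, 1)
        _, mask = predict_slices(model, vol)
        assert mask.volume_voxels() == 0

    def test_shape_mismatch_needs_resampling(self, tiny_spec):
        model = build_fsnet(sd.SegModelConfig(backbone="tiny",
                                              input_size=(64, 64)))
        vol, _ = sd.generate_phantom(tiny_spec, 0, 1)
        with pytest.raises(ValueError, match="resampling"):
            predict_slices(model, vol)
        probs, mask = predict_slices(model, vol, resample=True)
        assert probs.shape == vol.shape

    def test_overfit_single_phantom(self):
        """A tiny model memorizing one clean phantom reaches F1 >= 0.8."""
        spec = sd.PhantomSpec.tiny(confounder_count=0, noise_sd=0.0)
        vol, msk = sd.generate_phantom(spec, sex=0, instance_seed=2)
        batch = sd.SliceBatch(vol.data, msk.data.astype(np.float32))
        model = build_fsnet(sd.SegModelConfig(backbone="tiny",
                                              input_size=(32, 32)), seed=0)
        cfg = SegTrainConfig(epochs=40, batch_size=16, augment=False, seed=0)
        model, _ = sd.train_fsnet(model, batch, batch, cfg)
        _, pred = predict_slices(model, vol)
        assert sd.seg_metrics(msk, pred).f1 >= 0.8
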