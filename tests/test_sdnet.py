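"""3D classifier: BCE arithmetic, attention gating, training behavior."""

import numpy as np
import pytest

import sdetnet as sd
from sdetnet.sdnet import AGAM, SDTrainConfig, build_sdnet, predict_sex


class TestBCE:
    def test_perfect_prediction(self):
        assert sd.bce_loss([1.0], [1.0 - 1e-12]) == pytest.approx(0.0, abs=1e-6)

    def test_ln2_at_half(self):
        assert sd.bce_loss([1], [0.5]) == pytest.approx(np.log(2))

    def test_two_sample_mean(self):
        expected = -(np.log(0.9) + np.log(0.9)) / 2
        assert sd.bce_loss([1, 0], [0.9, 0.1]) == pytest.approx(expected)
        assert expected == pytest.approx(0.1054, abs=1e-4)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sd.bce_loss([], [])

    def test_clipping_keeps_loss_finite(self):
        assert np.isfinite(sd.bce_loss([1, 0], [0.0, 1.0]))


class TestAGAM:
    def test_zero_weights_gate_at_half(self, rng):
        ag = AGAM(4, rng=rng, bias=False)
        for layer in ag.layers():
            for k in layer.params:
                layer.params[k][...] = 0.0
        f = rng.random((1, 4, 6, 6, 6)).astype(np.float32)
        s = rng.random((1, 1, 12, 12, 12)).astype(np.float32)
        out = sd.agam_forward(f, s, ag)
        assert np.allclose(out, 0.5 * f)

    def test_single_voxel_gating(self, rng):
        ag = AGAM(2, rng=rng)
        f = np.zeros((1, 2, 4, 4, 4), dtype=np.float32)
        f[0, 0, 1, 2, 3] = 5.0
        s = np.zeros((1, 1, 4, 4, 4), dtype=np.float32)
        out = ag.forward(f, s)
        att = ag._f_att  # cached during forward
        assert out[0, 0, 1, 2, 3] == pytest.approx(
            5.0 * att[0, 0, 1, 2, 3], rel=1e-5)
        assert np.allclose(out[0, 1], 0.0)

    def test_attenuation_over_random_draws(self):
        for i in range(100):
            r = np.random.default_rng(1000 + i)
            ag = AGAM(3, rng=r)
            f = r.normal(size=(1, 3, 5, 5, 5)).astype(np.float32)
            s = r.random((1, 1, 9, 9, 9)).astype(np.float32)
            out = ag.forward(f, s)
            assert np.all(np.abs(out) <= np.abs(f) + 1e-6)

    def test_resample_identity_when_grids_match(self, rng):
        a = rng.random((5, 6, 7))
        assert sd.resample_trilinear(a, (5, 6, 7)) is a

    def test_resample_corners_align(self):
        a = np.zeros((3, 3, 3))
        a[0, 0, 0], a[2, 2, 2] = 1.0, 2.0
        b = sd.resample_trilinear(a, (5, 5, 5))
        assert b[0, 0, 0] == pytest.approx(1.0)
        assert b[4, 4, 4] == pytest.approx(2.0)

    def test_mask_sensitivity(self, rng):
        ag = AGAM(3, rng=rng)
        f = rng.random((1, 3, 6, 6, 6)).astype(np.float32)
        s = rng.random((1, 1, 6, 6, 6)).astype(np.float32)
        out1 = ag.forward(f, s)
        out2 = ag.forward(f, np.ascontiguousarray(s[:, :, ::-1]))
        assert not np.allclose(out1, out2)

    def test_channel_mismatch_rejected(self, rng):
        ag = AGAM(3, rng=rng)
        with pytest.raises(ValueError):
            ag.forward(rng.random((1, 4, 4, 4, 4)).astype(np.float32),
                       rng.random((1, 1, 4, 4, 4)).astype(np.float32))


class TestArchitecture:
    def test_scalar_probability_output(self, rng):
        model = build_sdnet(sd.SDNetConfig(channels=(4, 8), use_agam=True,
                                           input_channels=2))
        x = rng.random((2, 2, 16, 16, 16)).astype(np.float32)
        s = rng.random((2, 1, 16, 16, 16)).astype(np.float32)
        p = model.forward(x, s)
        assert p.shape == (2,)
        assert np.all((0 < p) & (p < 1))

    def test_default_channel_progression(self):
        assert sd.SDNetConfig().channels == (16, 32, 64, 128)

    def test_non_increasing_channels_rejected(self):
        with pytest.raises(ValueError):
            sd.SDNetConfig(channels=(16, 16))

    def test_agam_off_ignores_mask(self, rng):
        model = build_sdnet(sd.SDNetConfig(channels=(4, 8), use_agam=False,
                                           input_channels=1))
        x = rng.random((1, 1, 8, 8, 8)).astype(np.float32)
        p1 = model.forward(x, rng.random((1, 1, 8, 8, 8)).astype(np.float32))
        p2 = model.forward(x, None)
        assert p1 == pytest.approx(p2)

    def test_too_small_input_rejected(self, rng):
        model = build_sdnet(sd.SDNetConfig(channels=(4, 8, 16),
                                           use_agam=False, input_channels=1))
        with pytest.raises(ValueError, match="too small"):
            model.forward(rng.random((1, 1, 4, 4, 4)).astype(np.float32))

    def test_zero_head_gives_half(self, rng):
        model = build_sdnet(sd.SDNetConfig(channels=(4, 8), use_agam=False,
                                           input_channels=1))
        model.head.params["W"][...] = 0.0
        model.head.params["b"][...] = 0.0
        p = model.forward(rng.random((1, 1, 8, 8, 8)).astype(np.float32))
        assert p[0] == pytest.approx(0.5)


def _labeled_rois(n, spec, crop=(16, 16, 16)):
    rois = []
    for i in range(n):
        sex = i % 2
        vol, mask = sd.generate_phantom(spec, sex, instance_seed=i)
        rois.append(sd.extract_roi(vol, mask, crop, label=sex))
    return rois


class TestTraining:
    def test_smoke_history(self, tiny_spec):
        rois = _labeled_rois(8, tiny_spec)
        model = build_sdnet(sd.SDNetConfig(channels=(2, 4), use_agam=True,
                                           input_channels=2))
        model, hist = sd.train_sdnet(model, rois[:6], rois[6:],
                                     SDTrainConfig(epochs=3, seed=0))
        assert len(hist["train_loss"]) == 3
        assert all(np.isfinite(hist["train_loss"]))

    def test_lr_floor_respected(self, tiny_spec):
        rois = _labeled_rois(4, tiny_spec)
        model = build_sdnet(sd.SDNetConfig(channels=(2, 4), use_agam=False,
                                           input_channels=2))
        model, hist = sd.train_sdnet(
            model, rois[:2], rois[2:],
            SDTrainConfig(epochs=8, plateau_patience=1, initial_lr=1e-4,
                          lr_floor=5e-5, seed=0))
        assert all(lr >= 5e-5 for lr in hist["lr"])

    def test_overfits_four_phantoms(self):
        """Capacity check: memorize 4 strongly dimorphic subjects."""
        spec = sd.PhantomSpec.tiny(dimorphism_factor=2.0, noise_sd=0.0,
                                   confounder_count=0)
        rois = _labeled_rois(4, spec)
        model = build_sdnet(sd.SDNetConfig(channels=(2, 4), use_agam=True,
                                           input_channels=2), seed=0)
        model, _ = sd.train_sdnet(model, rois, rois,
                                  SDTrainConfig(epochs=40, initial_lr=3e-3,
                                                plateau_patience=40, seed=0))
        preds = [predict_sex(model, r) >= 0.5 for r in rois]
        assert preds == [bool(r.label) for r in rois]

    def test_unlabeled_roi_rejected(self, tiny_spec):
        rois = _labeled_rois(2, tiny_spec)
        rois[0].label = None
        model = build_sdnet(sd.SDNetConfig(channels=(2, 4), input_channels=2))
        with pytest.raises(ValueError):
            sd.train_sdnet(model, rois, rois, SDTrainConfig(epochs=1))
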