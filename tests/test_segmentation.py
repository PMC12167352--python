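"""UNet segmentation: loss, metrics, augmentation, training machinery."""

import numpy as np
import pytest

from perfdsa.segmentation import (
    RMSProp,
    ReduceLROnPlateau,
    TrainConfig,
    UNet,
    UNetConfig,
    augment,
    combined_loss,
    displacement_bound,
    evaluate,
    predict_mask,
    train,
)
from perfdsa.segmentation.metrics import (
    bce_loss,
    combined_loss_grad_wrt_logits,
    dice_loss,
)
from perfdsa.segmentation.unet import Conv3x3, InstanceNorm, _sigmoid


class TestCombinedLoss:
    def test_perfect_binary_prediction(self):
        g = np.zeros((4, 4))
        g[1:3, 1:3] = 1.0  # S = 4 foreground pixels
        loss = combined_loss(g, g)
        # CE term ~ 0; Dice term = 1 - 2S/(2S+1) with unit smoothing
        assert loss == pytest.approx(1 - 8 / 9, abs=1e-6)

    def test_hand_computed_half_probabilities(self):
        g = np.array([[1.0, 0.0], [0.0, 0.0]])
        p = np.full((2, 2), 0.5)
        # CE = ln 2 everywhere; Dice = 1 - (2*0.5)/(2 + 1 + 1)
        assert bce_loss(p, g) == pytest.approx(np.log(2))
        assert dice_loss(p, g) == pytest.approx(1 - 1 / 4)
        assert combined_loss(p, g) == pytest.approx(np.log(2) + 0.75)

    def test_nonnegative(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            p = rng.random((3, 3))
            g = (rng.random((3, 3)) > 0.5).astype(float)
            assert combined_loss(p, g) >= 0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            combined_loss(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_decreases_toward_reference(self):
        rng = np.random.default_rng(1)
        g = (rng.random((6, 6)) > 0.6).astype(float)
        start = np.full((6, 6), 0.5)
        target = np.clip(g, 1e-4, 1 - 1e-4)
        losses = [
            combined_loss(start + a * (target - start), g)
            for a in np.linspace(0, 1, 5)
        ]
        assert all(l1 < l0 for l0, l1 in zip(losses, losses[1:]))

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(2)
        z = rng.normal(size=(5, 5))
        g = (rng.random((5, 5)) > 0.5).astype(float)
        ana = combined_loss_grad_wrt_logits(_sigmoid(z), g)
        num = np.zeros_like(z)
        eps = 1e-6
        for i in range(5):
            for j in range(5):
                zp, zm = z.copy(), z.copy()
                zp[i, j] += eps
                zm[i, j] -= eps
                num[i, j] = (combined_loss(_sigmoid(zp), g) - combined_loss(_sigmoid(zm), g)) / (2 * eps)
        np.testing.assert_allclose(ana, num, atol=1e-8)


class TestEvaluate:
    def test_perfect_prediction(self):
        m = np.zeros((4, 4))
        m[0:2, 0:2] = 1
        s = evaluate(m, m)
        assert (s.dice, s.sensitivity, s.specificity, s.on_target) == (1.0, 1.0, 1.0, True)

    def test_disjoint_masks(self):
        a = np.zeros((4, 4)); a[0, 0] = 1
        b = np.zeros((4, 4)); b[3, 3] = 1
        s = evaluate(a, b)
        assert s.dice == 0.0 and not s.on_target

    def test_half_coverage_counting(self):
        g = np.zeros((4, 4)); g[0, :4] = 1        # |G| = 4
        p = np.zeros((4, 4)); p[0, :2] = 1        # covers half, no FP
        s = evaluate(p, g)
        assert s.dice == pytest.approx(2 / 3)
        assert s.sensitivity == 0.5
        assert s.specificity == 1.0

    def test_both_empty_is_perfect(self):
        s = evaluate(np.zeros((3, 3)), np.zeros((3, 3)))
        assert s.dice == 1.0

    def test_dice_symmetric_and_bounded(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = (rng.random((5, 5)) > rng.random()).astype(int)
            b = (rng.random((5, 5)) > rng.random()).astype(int)
            s_ab, s_ba = evaluate(a, b), evaluate(b, a)
            assert s_ab.dice == s_ba.dice
            assert 0.0 <= s_ab.dice <= 1.0


class TestAugment:
    def test_disabled_transforms_identity(self):
        rng = np.random.default_rng(0)
        img = rng.random((16, 16))
        msk = (rng.random((16, 16)) > 0.8).astype(np.uint8)
        out_i, out_m = augment(img, msk, rng, prob=0.0)
        np.testing.assert_array_equal(out_i, img)
        np.testing.assert_array_equal(out_m, msk)

    def test_horizontal_flip_is_involution(self):
        rng = np.random.default_rng(1)
        img = rng.random((8, 8))
        msk = (img > 0.5).astype(np.uint8)

        class AlwaysFlip:
            def random(self):
                return 0.0
            def uniform(self, a, b):
                return 0.0

        r = AlwaysFlip()
        i1, m1 = augment(img, msk, r, prob=1.0, translate_frac=0, scale_frac=0, rotate_deg=0)
        i2, m2 = augment(i1, m1, r, prob=1.0, translate_frac=0, scale_frac=0, rotate_deg=0)
        np.testing.assert_array_equal(i2, img)
        np.testing.assert_array_equal(m2, msk)

    def test_mask_stays_binary(self):
        rng = np.random.default_rng(2)
        img = rng.random((32, 32))
        msk = np.zeros((32, 32), dtype=np.uint8)
        msk[10:20, 12:18] = 1
        for _ in range(5):
            _, m = augment(img, msk, rng, prob=1.0)
            assert set(np.unique(m)) <= {0, 1}

    def test_displacement_within_analytic_bound(self):
        h = w = 64
        bound = displacement_bound(h, w, rotate_deg=10, scale_frac=0.05, translate_frac=0.05)
        rng = np.random.default_rng(3)
        msk = np.zeros((h, w), dtype=np.uint8)
        msk[20:24, 40:44] = 1
        c0 = np.array([21.5, 41.5])
        for _ in range(10):
            _, m = augment(np.zeros((h, w)), msk, rng, prob=1.0, hflip=False)
            if m.sum() == 0:
                continue
            c1 = np.argwhere(m).mean(axis=0)
            assert np.linalg.norm(c1 - c0) <= bound + 1.5  # + pixel quantization


class TestOptimAndScheduler:
    def test_rmsprop_reduces_quadratic(self):
        w = np.array([5.0, -3.0])
        opt = RMSProp([w], lr=0.1)
        for _ in range(200):
            opt.step([2 * w])
        assert np.abs(w).max() < 0.5

    def test_plateau_halves_lr_once_after_patience(self):
        w = np.zeros(1)
        opt = RMSProp([w], lr=1e-3)
        sched = ReduceLROnPlateau(opt, patience=10, factor=0.5)
        for _ in range(11):
            sched.step(1.0)  # constant loss
        assert opt.lr == pytest.approx(5e-4)

    def test_plateau_no_reduction_while_improving(self):
        w = np.zeros(1)
        opt = RMSProp([w], lr=1e-3)
        sched = ReduceLROnPlateau(opt, patience=10, factor=0.5)
        for i in range(30):
            sched.step(1.0 / (i + 1))
        assert opt.lr == 1e-3


SMALL_NET = UNetConfig(base_channels=4, max_channels=8)


class TestUNet:
    def test_predict_mask_shape_and_dtype(self):
        model = UNet(SMALL_NET, seed=0)
        mask = predict_mask(model, np.zeros((16, 16)))
        assert mask.shape == (16, 16)
        assert mask.dtype == np.uint8

    def test_predict_mask_non_power_of_two_dims(self):
        model = UNet(SMALL_NET, seed=0)
        for shape in [(17, 23), (30, 14)]:
            assert predict_mask(model, np.random.default_rng(0).random(shape)).shape == shape

    def test_threshold_extremes(self):
        model = UNet(SMALL_NET, seed=0)
        img = np.random.default_rng(1).random((8, 8))
        assert np.all(predict_mask(model, img, threshold=0.0) == 1)
        assert np.all(predict_mask(model, img, threshold=1.0 + 1e-9) == 0)

    def test_conv_gradients_match_finite_differences(self):
        rng = np.random.default_rng(4)
        conv = Conv3x3(2, 3, rng)
        conv.W = conv.W.astype(np.float64)
        conv.b = conv.b.astype(np.float64)
        conv.params = [conv.W, conv.b]
        conv.grads = [np.zeros_like(conv.W), np.zeros_like(conv.b)]
        x = rng.normal(size=(2, 5, 5))
        R = rng.normal(size=(3, 5, 5))  # loss = sum(y * R)
        conv.forward(x)
        dx = conv.backward(R)
        dW = conv.grads[0].copy()
        flat = conv.W.reshape(-1)
        idxs = rng.choice(flat.size, 10, replace=False)
        for idx in idxs:
            eps, old = 1e-6, flat[idx]
            flat[idx] = old + eps
            lp = float((conv.forward(x) * R).sum())
            flat[idx] = old - eps
            lm = float((conv.forward(x) * R).sum())
            flat[idx] = old
            assert (lp - lm) / (2 * eps) == pytest.approx(dW.reshape(-1)[idx], abs=1e-6)
        xf = x.reshape(-1)
        for idx in rng.choice(xf.size, 10, replace=False):
            eps, old = 1e-6, xf[idx]
            xf[idx] = old + eps
            lp = float((conv.forward(x) * R).sum())
            xf[idx] = old - eps
            lm = float((conv.forward(x) * R).sum())
            xf[idx] = old
            assert (lp - lm) / (2 * eps) == pytest.approx(dx.reshape(-1)[idx], abs=1e-5)

    def test_instance_norm_gradients(self):
        rng = np.random.default_rng(5)
        layer = InstanceNorm(2)
        layer.gamma[:] = rng.normal(1, 0.2, 2)
        x = rng.normal(size=(2, 4, 4))
        R = rng.normal(size=(2, 4, 4))
        layer.forward(x)
        dx = layer.backward(R)
        xf = x.reshape(-1)
        for idx in rng.choice(xf.size, 8, replace=False):
            eps, old = 1e-6, xf[idx]
            xf[idx] = old + eps
            lp = float((layer.forward(x) * R).sum())
            xf[idx] = old - eps
            lm = float((layer.forward(x) * R).sum())
            xf[idx] = old
            assert (lp - lm) / (2 * eps) == pytest.approx(dx.reshape(-1)[idx], abs=1e-5)


class TestTraining:
    def _tiny_pairs(self, n, seed=0, size=32):
        rng = np.random.default_rng(seed)
        pairs = []
        for _ in range(n):
            img = np.ones((size, size), dtype=np.float32)
            r0, c0 = rng.integers(4, size - 12, 2)
            img[r0:r0 + 8, c0:c0 + 4] = 0.4
            img += rng.normal(0, 0.01, img.shape).astype(np.float32)
            msk = np.zeros((size, size), dtype=np.uint8)
            msk[r0:r0 + 8, c0:c0 + 4] = 1
            pairs.append((img, msk))
        return pairs

    def test_smoke_two_epochs_history(self):
        pairs = self._tiny_pairs(2)
        cfg = TrainConfig(learning_rate=1e-3, max_epochs=2, seed=0, augment_enabled=False)
        _, hist = train(pairs[:1], pairs[1:], SMALL_NET, cfg)
        assert len(hist) == 2
        assert all(np.isfinite(e["train_loss"]) for e in hist.epochs)

    def test_loss_decreases_on_phantom_set(self):
        pairs = self._tiny_pairs(12, seed=1)
        cfg = TrainConfig(learning_rate=1e-3, max_epochs=5, seed=0)
        _, hist = train(pairs[:10], pairs[10:], SMALL_NET, cfg)
        losses = [e["train_loss"] for e in hist.epochs]
        assert min(losses[1:]) < losses[0]

    def test_training_reproducible_with_fixed_seed(self):
        pairs = self._tiny_pairs(4, seed=2)
        cfg = TrainConfig(learning_rate=1e-3, max_epochs=2, seed=7)
        _, h1 = train(pairs[:3], pairs[3:], SMALL_NET, cfg)
        _, h2 = train(pairs[:3], pairs[3:], SMALL_NET, cfg)
        assert h1.epochs == h2.epochs

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train([], [], SMALL_NET, TrainConfig())

    def test_model_save_load_roundtrip(self, tmp_path):
        from perfdsa.segmentation import load_model, save_model

        model = UNet(SMALL_NET, seed=3)
        img = np.random.default_rng(6).random((16, 16))
        save_model(model, tmp_path / "m.npz")
        re = load_model(tmp_path / "m.npz")
        np.testing.assert_array_equal(re.predict_proba(img), model.predict_proba(img))


class TestTrainConfigValidation:
    def test_probability_bounds(self):
        with pytest.raises(ValueError):
            TrainConfig(augment_prob=1.5)

    def test_patience_positive(self):
        with pytest.raises(ValueError):
            TrainConfig(plateau_patience=0)
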