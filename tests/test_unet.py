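"""U-Net architecture contracts, gradient correctness, training behavior."""

import numpy as np
import pytest

from ivusseg import NetConfig, TrainConfig, UNet, augment, make_split, predict, train
from ivusseg.phantom import SimConfig, generate_sequences
from ivusseg.unet.layers import softmax_cross_entropy
from ivusseg.unet.model import NetConfigError
from ivusseg.unet.training import evaluate_loss, frames_from_sequences


class TestArchitecture:
    def test_output_shape_and_softmax_partition(self):
        net = UNet(NetConfig(depth=4, base_filters=16), rng_seed=0)
        mask, probs = predict(net, np.random.default_rng(0).random((64, 64)))
        assert mask.labels.shape == (64, 64)
        assert probs.shape == (5, 64, 64)
        np.testing.assert_allclose(probs.sum(axis=0), 1.0, atol=1e-5)

    def test_skip_connection_count(self):
        for depth in (2, 3, 4):
            assert UNet(NetConfig(depth=depth, base_filters=4)).n_skip_connections == depth - 1

    def test_parameter_count_matches_hand_count(self):
        """Layer-by-layer analytic count for depth=2, base=4 (3x3 convs + bias)."""
        enc0 = (1 * 9 + 1) * 4 + (4 * 9 + 1) * 4  # 40 + 148
        enc1 = (4 * 9 + 1) * 8 + (8 * 9 + 1) * 8  # 296 + 584
        dec0 = ((8 + 4) * 9 + 1) * 4 + (4 * 9 + 1) * 4  # 436 + 148
        head = (4 + 1) * 5  # 25
        expected = enc0 + enc1 + dec0 + head  # 1677
        assert UNet(NetConfig(depth=2, base_filters=4)).parameter_count() == expected

    def test_filter_doubling_per_level(self):
        net = UNet(NetConfig(depth=3, base_filters=16))
        assert [b.c2.cout for b in net.enc] == [16, 32, 64]
        assert [b.c2.cout for b in net.dec] == [32, 16]

    def test_indivisible_input_raises(self):
        net = UNet(NetConfig(depth=4, base_filters=4))
        with pytest.raises(NetConfigError):
            net.forward(np.zeros((1, 1, 36, 36), dtype=np.float32))

    def test_argmax_ties_break_to_lower_class(self):
        # all-equal logits -> softmax ties -> class 0 everywhere
        net = UNet(NetConfig(depth=2, base_filters=4))
        for layer in net.conv_layers:
            layer.w[:] = 0
            layer.b[:] = 0
        mask, _ = predict(net, np.zeros((16, 16)))
        assert (mask.labels == 0).all()


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Central-difference check of analytic gradients on a tiny net."""
        net = UNet(NetConfig(depth=2, base_filters=2, dropout_rate=0.0), rng_seed=3)
        rng = np.random.default_rng(5)
        x = rng.random((1, 1, 8, 8)).astype(np.float32)
        y = rng.integers(0, 5, (1, 8, 8))

        def loss_value():
            return softmax_cross_entropy(net.forward(x, train=False), y)[0]

        logits = net.forward(x, train=True)
        _, dlogits, _ = softmax_cross_entropy(logits, y)
        net.backward(dlogits)
        eps = 3e-3  # balances float32 round-off against curvature error
        checked = 0
        for layer in (net.enc[0].c1, net.enc[1].c2, net.dec[0].c1, net.head):
            grads = layer.dw
            flat = np.argsort(np.abs(grads).ravel())[-3:]  # largest-gradient entries
            for idx in flat:
                i, j = np.unravel_index(idx, grads.shape)
                orig = layer.w[i, j]
                layer.w[i, j] = orig + eps
                lp = loss_value()
                layer.w[i, j] = orig - eps
                lm = loss_value()
                layer.w[i, j] = orig
                fd = (lp - lm) / (2 * eps)
                assert fd == pytest.approx(grads[i, j], rel=0.08, abs=1e-4)
                checked += 1
        assert checked == 12


class TestAugment:
    def make_pair(self, rng, size=16):
        return rng.random((size, size)), rng.integers(0, 5, (size, size))

    def test_class_counts_preserved(self, rng):
        f, m = self.make_pair(rng)
        for _ in range(10):
            f2, m2 = augment(f, m, rng)
            np.testing.assert_array_equal(
                np.bincount(m.ravel(), minlength=5), np.bincount(m2.ravel(), minlength=5)
            )
            assert f2.shape == f.shape

    def test_same_transform_applied_to_both(self, rng):
        # frame encodes pixel identity; mask must move identically
        size = 8
        ident = np.arange(size * size, dtype=float).reshape(size, size)
        m = (np.arange(size * size) % 5).reshape(size, size)
        f2, m2 = augment(ident, m, rng)
        np.testing.assert_array_equal(m2.ravel(), m.ravel()[f2.ravel().astype(int)])

    def test_horizontal_flip_is_involution(self):
        f = np.arange(16.0).reshape(4, 4)
        np.testing.assert_array_equal(f[:, ::-1][:, ::-1], f)

    def test_class_set_never_grows(self, rng):
        f = rng.random((8, 8))
        m = np.zeros((8, 8), dtype=np.uint8)
        m[2:4, 2:4] = 3
        _, m2 = augment(f, m, rng)
        assert set(np.unique(m2)) <= set(np.unique(m))

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            augment(np.zeros((8, 8)), np.zeros((4, 4), dtype=int), rng)


@pytest.fixture(scope="module")
def sequences():
    cfg = SimConfig(n_patients=6, frames_per_patient=5, image_size=64, pixel_spacing=0.08, rng_seed=31)
    return generate_sequences(cfg)


class TestSplit:
    def test_patient_disjoint(self, sequences, rng):
        plan = make_split(sequences, test_n_patients=2, rng=rng)
        assert len(plan.train_patients) == 4 and len(plan.test_patients) == 2
        assert not set(plan.train_patients) & set(plan.test_patients)

    def test_validation_count_is_20_percent(self, sequences, rng):
        plan = make_split(sequences, test_n_patients=2, rng=rng)
        n_train_frames = 4 * 5
        assert len(plan.validation_frames) == round(0.2 * n_train_frames)
        assert {p for p, _ in plan.validation_frames} <= set(plan.train_patients)

    def test_same_seed_same_split(self, sequences):
        a = make_split(sequences, 2, np.random.default_rng(9))
        b = make_split(sequences, 2, np.random.default_rng(9))
        assert a == b

    def test_too_few_patients_raises(self, sequences, rng):
        with pytest.raises(ValueError):
            make_split(sequences, test_n_patients=6, rng=rng)


class TestTraining:
    def test_overfits_two_frames(self):
        """200 steps on 2 frames must collapse the loss to < 10% of initial."""
        rng = np.random.default_rng(41)
        cfg = SimConfig(n_patients=1, frames_per_patient=2, image_size=32, pixel_spacing=0.16, rng_seed=41)
        seqs = generate_sequences(cfg)
        pairs = frames_from_sequences(seqs)
        net = UNet(NetConfig(depth=2, base_filters=8), rng_seed=41)
        initial = evaluate_loss(net, pairs)
        tc = TrainConfig(max_epochs=200, augment=False, rng_seed=41, early_stop_patience=200)
        train(net, pairs, tc)
        assert evaluate_loss(net, pairs) < 0.1 * initial

    def test_history_and_checkpoint_contract(self):
        cfg = SimConfig(n_patients=2, frames_per_patient=3, image_size=32, pixel_spacing=0.16, rng_seed=43)
        pairs = frames_from_sequences(generate_sequences(cfg))
        net = UNet(NetConfig(depth=2, base_filters=4), rng_seed=43)
        tc = TrainConfig(max_epochs=5, rng_seed=43)
        hist = train(net, pairs[:4], tc, val_pairs=pairs[4:])
        assert len(hist.epochs) <= 5
        assert hist.val_loss[hist.best_epoch] == min(hist.val_loss)
        # restored weights reproduce the best recorded validation loss
        assert evaluate_loss(net, pairs[4:]) == pytest.approx(min(hist.val_loss), rel=1e-5)

    def test_deterministic_under_seed(self):
        cfg = SimConfig(n_patients=1, frames_per_patient=2, image_size=32, pixel_spacing=0.16, rng_seed=47)
        pairs = frames_from_sequences(generate_sequences(cfg))
        nets = []
        for _ in range(2):
            net = UNet(NetConfig(depth=2, base_filters=4), rng_seed=47)
            train(net, pairs, TrainConfig(max_epochs=2, rng_seed=47))
            nets.append(net.get_weights())
        for wa, wb in zip(*nets):
            np.testing.assert_array_equal(wa, wb)

    def test_empty_training_set_raises(self):
        net = UNet(NetConfig(depth=2, base_filters=4))
        with pytest.raises(ValueError):
            train(net, [], TrainConfig())


class TestCheckpointIO:
    def test_save_load_roundtrip(self, tmp_path, rng):
        net = UNet(NetConfig(depth=2, base_filters=4), rng_seed=13)
        p = tmp_path / "ckpt.npz"
        net.save(p)
        back = UNet.load(p)
        x = rng.random((16, 16))
        np.testing.assert_array_equal(net.predict_probs(x), back.predict_probs(x))


def test_perfect_prediction_metrics_invariant_under_augmentation(rng):
    """Any joint flip/rotation of (frame, mask) leaves identity metrics at 1."""
    from ivusseg import LabelMask, aggregate

    cfg = SimConfig(n_patients=1, frames_per_patient=1, image_size=64, pixel_spacing=0.08, rng_seed=53)
    frame, mask, _ = generate_sequences(cfg)[0].frames[0]
    for _ in range(8):
        _, m2 = augment(frame.image, mask.labels, rng)
        rep = aggregate([(LabelMask(m2.copy(), mask.pixel_spacing),) * 2], "pooled")
        assert rep.mean_iou == 1.0 and rep.mean_dice == 1.0
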