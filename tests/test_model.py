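import numpy as np
import pytest

from microres.cgpo import CgpoConfig, cgpo_tiles
from microres.model import (
    Adam, BackboneSpec, CropNet, TrainConfig, fuse, init_position_embeddings,
    label_smoothing_loss, predict, train,
)

TINY = BackboneSpec(channel_schedule=(4, 8))
SMALL_CGPO = CgpoConfig(input_size=32, tile_size=16)


def tiny_model(n_classes=3, seed=0):
    return CropNet(n_classes=n_classes, backbone=TINY, n_tiles=10, seed=seed)


def tile_batch(rng, b=2, n_tiles=10, size=16):
    return rng.uniform(0, 1, size=(b, n_tiles, 3, size, size)).astype(np.float32)


class TestFeatureExtraction:
    def test_each_tile_maps_to_24_dims(self, rng):
        img = rng.integers(0, 256, size=(32, 32, 3), dtype=np.uint8)
        tiles = cgpo_tiles(img, SMALL_CGPO)
        model = tiny_model()
        x = CropNet.tiles_to_array(tiles)[None]
        z = model.extract_features(x)
        assert z.shape == (1, 10, 24)

    def test_weight_sharing_gives_identical_features_for_identical_tiles(self, rng):
        x = tile_batch(rng, b=1)
        x[0, 3] = x[0, 7]
        z = tiny_model().extract_features(x)
        np.testing.assert_allclose(z[0, 3], z[0, 7], rtol=1e-5)

    def test_seeded_init_is_bit_reproducible(self, rng):
        x = tile_batch(rng)
        out1 = tiny_model(seed=5).forward(x)
        out2 = tiny_model(seed=5).forward(x)
        np.testing.assert_array_equal(out1, out2)

    def test_wrong_tile_count_rejected(self, rng):
        x = tile_batch(rng, n_tiles=7)
        with pytest.raises(ValueError):
            tiny_model().extract_features(x)


class TestPositionEmbeddings:
    def test_stated_moments(self):
        p = init_position_embeddings(dim=100, count=10000, seed=0)
        assert abs(p.mean()) < 0.002
        assert abs(p.var() - 0.2) < 0.002

    def test_same_seed_identical(self):
        np.testing.assert_array_equal(init_position_embeddings(seed=3),
                                      init_position_embeddings(seed=3))

    def test_gradient_flows_to_all_embeddings_but_not_tile_zero(self, rng):
        """Only the nine cropped tiles carry embeddings; tile 0 has none."""
        model = tiny_model()
        assert model.pos.value.shape == (9, 24)
        x = tile_batch(rng, b=4)
        logits = model.forward(x, train=True)
        _, dlogits = label_smoothing_loss(logits, np.zeros(4, int), 0.1)
        model.backward(dlogits)
        assert (np.abs(model.pos.grad).sum(axis=1) > 0).all()


class TestFuse:
    def test_zero_embeddings_pass_features_through(self, rng):
        z = rng.normal(size=(10, 24))
        out = fuse(z, np.zeros((9, 24)))
        np.testing.assert_array_equal(out, z.reshape(-1))

    def test_basis_vector_lands_in_its_block(self):
        z = np.zeros((10, 24))
        p = np.zeros((9, 24))
        p[4, 7] = 1.0  # embedding of tile index 5
        out = fuse(z, p)
        assert out[5 * 24 + 7] == 1.0
        assert out.sum() == 1.0

    def test_matches_blockwise_arithmetic_oracle(self, rng):
        z = rng.normal(size=(3, 10, 24))
        p = rng.normal(size=(9, 24))
        expected = np.concatenate(
            [z[:, :1], z[:, 1:] + p[None]], axis=1
        ).reshape(3, 240)
        np.testing.assert_allclose(fuse(z, p), expected)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            fuse(rng.normal(size=(10, 24)), rng.normal(size=(8, 24)))


class TestLabelSmoothingLoss:
    def test_epsilon_zero_is_cross_entropy(self, rng):
        logits = rng.normal(size=(5,))
        loss, _ = label_smoothing_loss(logits, 2, epsilon=0.0)
        log_softmax = logits - np.log(np.exp(logits).sum())
        assert loss == pytest.approx(-log_softmax[2], rel=1e-9)

    @pytest.mark.parametrize("c", [2, 3, 5, 10])
    @pytest.mark.parametrize("eps", [0.0, 0.1, 0.5])
    def test_uniform_logits_give_log_c(self, c, eps):
        loss, _ = label_smoothing_loss(np.zeros(c), 0, epsilon=eps)
        assert loss == pytest.approx(np.log(c), rel=1e-9)

    def test_peaked_logits_hand_value(self):
        # independent evaluation of -sum_k q_k log softmax_k
        logits = np.array([10.0, 0, 0, 0, 0])
        log_p = logits - np.log(np.exp(logits).sum())
        q = np.full(5, 0.1 / 5)
        q[0] += 0.9
        expected = -(q * log_p).sum()
        loss, _ = label_smoothing_loss(logits, 0, epsilon=0.1)
        assert loss == pytest.approx(expected, rel=1e-12)

    def test_strictly_positive_for_positive_epsilon(self):
        loss, _ = label_smoothing_loss(np.array([50.0, 0.0]), 0, epsilon=0.1)
        assert loss > 0

    def test_class_permutation_equivariance(self, rng):
        logits = rng.normal(size=(6,))
        perm = rng.permutation(6)
        a, _ = label_smoothing_loss(logits, 3, epsilon=0.2)
        b, _ = label_smoothing_loss(logits[perm], int(np.where(perm == 3)[0][0]),
                                    epsilon=0.2)
        assert a == pytest.approx(b, rel=1e-12)

    def test_epsilon_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            label_smoothing_loss(np.zeros(3), 0, epsilon=1.0)

    def test_gradient_matches_finite_differences(self, rng):
        logits = rng.normal(size=(4,))
        loss, grad = label_smoothing_loss(logits, 1, epsilon=0.1)
        h = 1e-6
        for k in range(4):
            bumped = logits.copy()
            bumped[k] += h
            loss_k, _ = label_smoothing_loss(bumped, 1, epsilon=0.1)
            assert grad[k] == pytest.approx((loss_k - loss) / h, abs=1e-4)


class TestTraining:
    @staticmethod
    def separable_dataset(rng, n=8, size=32):
        """Left-bright vs right-bright images: linearly trivial classes."""
        data = []
        for i in range(n):
            img = np.full((size, size, 3), 30, np.uint8)
            noise = rng.integers(0, 10, size=(size, size, 3), dtype=np.uint8)
            img = img + noise
            if i % 2 == 0:
                img[:, : size // 2] = 220
            else:
                img[:, size // 2:] = 220
            data.append((img, i % 2))
        return data

    def test_fits_separable_two_class_data(self, rng):
        data = self.separable_dataset(rng)
        cfg = TrainConfig(epochs=20, lr=1e-2, batch_size=4, seed=0,
                          backbone=TINY, cgpo=SMALL_CGPO)
        model, log = train(data, cfg)
        preds = predict(model, [img for img, _ in data], SMALL_CGPO)
        assert (preds == np.array([y for _, y in data])).all()
        assert log[-1]["accuracy"] == 1.0

    def test_zero_epochs_returns_untouched_initialization(self, rng):
        data = self.separable_dataset(rng)
        cfg = TrainConfig(epochs=0, seed=9, backbone=TINY, cgpo=SMALL_CGPO)
        model, log = train(data, cfg)
        assert log == []
        fresh = CropNet(n_classes=2, backbone=TINY, n_tiles=10, seed=9)
        np.testing.assert_array_equal(model.classifier.w.value,
                                      fresh.classifier.w.value)

    def test_same_seed_gives_identical_final_loss(self, rng):
        data = self.separable_dataset(rng)
        cfg = TrainConfig(epochs=3, seed=4, backbone=TINY, cgpo=SMALL_CGPO)
        _, log1 = train(data, cfg)
        _, log2 = train(data, cfg)
        assert log1[-1]["loss"] == log2[-1]["loss"]

    def test_single_class_dataset_rejected(self, rng):
        data = [(rng.integers(0, 256, (32, 32, 3), dtype=np.uint8), 0)
                for _ in range(4)]
        with pytest.raises(ValueError, match="two distinct classes"):
            train(data, TrainConfig(backbone=TINY, cgpo=SMALL_CGPO))

    def test_one_adam_step_decreases_loss(self, rng):
        model = tiny_model()
        x = tile_batch(rng, b=2)
        y = np.array([0, 1])
        opt = Adam(model.params(), lr=1e-3)
        logits = model.forward(x, train=True)
        loss0, dlogits = label_smoothing_loss(logits, y, 0.1)
        opt.zero_grad()
        model.backward(dlogits)
        opt.step()
        loss1, _ = label_smoothing_loss(model.forward(x, train=True), y, 0.1)
        assert loss1 < loss0
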