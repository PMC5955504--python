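"""Architectures, soft Dice loss, training contract, inference."""

import numpy as np
import pytest

from busseg.network import (NetworkConfig, UNet, _propagate_shapes, _val_dice,
                            build_network, predict, soft_dice_loss,
                            train_member, UNetSegmenter)
from busseg.phantom import generate_dataset
from busseg.pipeline import prepare_arrays

TINY = dict(input_size=16, depth=2, filter_exponent_base=1, dropout_rate=0.0)


class TestConfig:
    def test_filter_rule(self):
        cfg = NetworkConfig()
        assert [cfg.filters(l) for l in (1, 3, 5)] == [64, 256, 1024]

    def test_input_divisibility_enforced(self):
        with pytest.raises(ValueError, match="divisible"):
            NetworkConfig(input_size=100)

    def test_crops_only_for_original(self):
        with pytest.raises(ValueError):
            NetworkConfig(crop_per_edge_by_layer=(1, 2, 3, 4))

    def test_wrong_crops_rejected_by_shape_propagation(self):
        with pytest.raises(ValueError, match="disagree"):
            _propagate_shapes(NetworkConfig.original_unet(
                crop_per_edge_by_layer=(88, 40, 16, 8)))

    def test_incompatible_original_input_names_layer(self):
        with pytest.raises(ValueError, match="level"):
            _propagate_shapes(NetworkConfig.original_unet(
                input_size=570, crop_per_edge_by_layer=None))


class TestSoftDiceLoss:
    def test_perfect_overlap_limit(self, rng):
        g = (rng.random((8, 8)) > 0.5).astype(float)
        assert soft_dice_loss(g, g, smooth=1e-9) == pytest.approx(-1.0, abs=1e-6)

    def test_all_zero_prediction_closed_form(self):
        g = np.zeros((6, 6)); g[2:4, 2:4] = 1
        assert soft_dice_loss(np.zeros_like(g), g, smooth=1.0) == pytest.approx(
            -1.0 / (4 + 1))

    def test_matches_brute_force_sums(self, rng):
        p = rng.random((5, 5))
        g = (rng.random((5, 5)) > 0.5).astype(float)
        num = den = 0.0
        for i in range(5):
            for j in range(5):
                num += 2 * p[i, j] * g[i, j]
                den += p[i, j] + g[i, j]
        expected = -(num + 1.0) / (den + 1.0)
        assert soft_dice_loss(p, g, smooth=1.0) == pytest.approx(expected, abs=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            soft_dice_loss(np.zeros((3, 3)), np.zeros((4, 4)))

    def test_consistency_with_dice_metric(self, rng):
        """-soft_dice_loss of a binary prediction ~ the Dice metric."""
        from busseg.metrics import dice
        p = (rng.random((32, 32)) > 0.6).astype(np.uint8)
        g = (rng.random((32, 32)) > 0.6).astype(np.uint8)
        smooth = 1e-9
        assert -soft_dice_loss(p.astype(float), g.astype(float), smooth) == \
            pytest.approx(dice(p, g), abs=1e-6)


class TestBuildAndPredict:
    def test_sigmoid_range_and_inference_determinism(self, rng):
        net = build_network(NetworkConfig.scale_profile("multi_unet", **TINY))
        x = rng.normal(size=(16, 16)).astype(np.float32)
        m1 = predict(net, x)
        m2 = predict(net, x)
        assert m1.pixels.min() >= 0 and m1.pixels.max() <= 1
        assert np.array_equal(m1.pixels, m2.pixels)

    def test_wrong_input_size_rejected(self, rng):
        net = build_network(NetworkConfig.scale_profile("multi_unet", **TINY))
        with pytest.raises(ValueError, match="input"):
            predict(net, rng.normal(size=(32, 32)))

    def test_constant_input_untrained_net_constant_map(self):
        # zero biases + zero input -> every conv output is zero -> sigmoid 0.5
        net = build_network(NetworkConfig.scale_profile("multi_unet", **TINY))
        out = predict(net, np.zeros((16, 16), np.float32))
        assert np.allclose(out.pixels, 0.5)

    def test_doubling_base_doubles_filters(self):
        for b in (1, 2):
            net = build_network(NetworkConfig.scale_profile(
                "multi_unet", input_size=16, depth=2, filter_exponent_base=b))
            assert net.enc[0]["conv1"].cout == 2 ** (b + 1)
            assert net.enc[1]["conv1"].cout == 2 ** (b + 2)

    def test_skip_concatenations_align(self):
        # zero-padded variant: every decoder concat crop is exactly zero
        net = build_network(NetworkConfig.scale_profile("multi_unet"))
        assert all(d["crop"] == 0 for d in net.shapes["decoder"])
        # unpadded variant: crops are positive and consistent
        net_o = build_network(NetworkConfig.scale_profile("original_unet"))
        assert net_o.shapes["crops_by_layer"] == (40, 16, 4)

    def test_save_load_roundtrip(self, rng, tmp_path):
        net = build_network(NetworkConfig.scale_profile("multi_unet", **TINY))
        x = rng.normal(size=(16, 16)).astype(np.float32)
        before = predict(net, x).pixels
        net.save(tmp_path / "m.npz")
        loaded = UNet.load(tmp_path / "m.npz")
        assert np.array_equal(predict(loaded, x).pixels, before)


def _phantom_arrays(n_patients, seed, input_size=64):
    ds = generate_dataset(n_patients, 2, rng_seed=seed)
    X, y, groups, _, _, _ = prepare_arrays(ds, input_size)
    return X, y, groups


class TestTrainMember:
    def test_learning_improves_validation_dice(self):
        X, y, groups = _phantom_arrays(10, seed=31)
        cfg = NetworkConfig.scale_profile("multi_unet", epochs=8, patience=8)
        net = UNet(cfg, rng=np.random.default_rng(0))
        train = list(zip(X[:16], y[:16], groups[:16]))
        val = list(zip(X[16:], y[16:], groups[16:]))
        before = _val_dice(net, X[16:], y[16:])
        hist = train_member(net, train, val, cfg, rng_seed=0)
        assert hist["best_val_dice"] > before

    def test_patient_overlap_rejected(self):
        X, y, groups = _phantom_arrays(4, seed=32)
        cfg = NetworkConfig.scale_profile("multi_unet", epochs=1)
        net = UNet(cfg)
        items = list(zip(X, y, groups))
        with pytest.raises(ValueError, match="share patients"):
            train_member(net, items, items[:2], cfg)

    def test_seeded_training_is_repeatable(self):
        X, y, groups = _phantom_arrays(4, seed=33)
        cfg = NetworkConfig.scale_profile("multi_unet", epochs=2, patience=2)
        losses = []
        for _ in range(2):
            net = UNet(cfg, rng=np.random.default_rng(5))
            hist = train_member(net, list(zip(X[:6], y[:6], groups[:6])),
                                list(zip(X[6:], y[6:], groups[6:])),
                                cfg, rng_seed=5, augment_config=None)
            losses.append(hist["train_loss"][-1])
        assert losses[0] == losses[1]

    def test_empty_training_set_rejected(self):
        cfg = NetworkConfig.scale_profile("multi_unet", epochs=1)
        with pytest.raises(ValueError, match="empty"):
            train_member(UNet(cfg), [], [], cfg)


def test_estimator_sklearn_contract():
    est = UNetSegmenter(config=NetworkConfig.scale_profile("multi_unet"),
                        random_state=3)
    params = est.get_params()
    assert params["random_state"] == 3
    est.set_params(random_state=4)
    assert est.random_state == 4
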