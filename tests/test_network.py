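"""The excitation-augmented CNN: layers, training, extraction."""

import numpy as np
import pytest

from ecnnsvm.network import (EarlyStopper, ECNNConfig, ECNNModel, forward,
                             init_params, loss_and_grads, pointwise_conv_relu,
                             se_excite, se_scale, se_squeeze,
                             softmax_cross_entropy, train_early_stop,
                             extract_features)


class TestPointwiseConv:
    def test_identity_kernel_passes_nonnegative_input(self, rng):
        x = rng.random((2, 5, 3))
        out = pointwise_conv_relu(x, np.eye(3), np.zeros(3))
        assert np.allclose(out, x)

    def test_relu_clamps_negative_bias(self, rng):
        x = rng.random((2, 4, 3))
        out = pointwise_conv_relu(x, np.zeros((2, 3)), np.array([-1.0, -1.0]))
        assert np.all(out == 0.0)

    def test_hand_arithmetic(self):
        x = np.array([[[1.0, 2.0]]])  # 1 sample, 1 position, 2 channels
        out = pointwise_conv_relu(x, np.array([[0.5, 0.5]]), np.zeros(1))
        assert out[0, 0, 0] == pytest.approx(1.5)

    def test_channel_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="channel"):
            pointwise_conv_relu(rng.random((1, 3, 2)), np.ones((4, 3)),
                                np.zeros(4))

    def test_position_count_preserved(self, rng):
        out = pointwise_conv_relu(rng.random((3, 7, 2)), rng.random((5, 2)),
                                  np.zeros(5))
        assert out.shape == (3, 7, 5)


class TestSqueezeExcite:
    def test_squeeze_is_channel_mean(self):
        U = np.array([[[1.0], [2.0], [3.0]]])  # 3 positions, 1 channel
        assert se_squeeze(U)[0, 0] == pytest.approx(2.0)

    def test_squeeze_constant_channel(self, rng):
        U = np.full((2, 6, 4), 3.5)
        assert np.allclose(se_squeeze(U), 3.5)

    def test_squeeze_single_position_is_identity(self, rng):
        U = rng.random((2, 1, 5))
        assert np.allclose(se_squeeze(U), U[:, 0, :])

    def test_excite_zero_weights_give_half(self):
        s = se_excite(np.array([1.0, -2.0]), np.zeros((1, 2)), np.zeros((2, 1)))
        assert np.allclose(s, 0.5)

    def test_excite_hand_value(self):
        s = se_excite(np.array([1.0]), np.array([[1.0]]), np.array([[1.0]]))
        assert s[0] == pytest.approx(0.7310585786300049, abs=1e-9)

    def test_excite_strictly_inside_unit_interval(self, rng):
        for _ in range(20):
            C, r = 6, 2
            z = rng.standard_normal(C) * 50
            W1 = rng.standard_normal((C // r, C)) * 5
            W2 = rng.standard_normal((C, C // r)) * 5
            s = se_excite(z, W1, W2)
            assert np.all(s > 0) and np.all(s < 1)

    def test_scale_identity_and_annihilation(self, rng):
        U = rng.random((2, 4, 3))
        assert np.allclose(se_scale(U, np.ones(3)), U)
        assert np.all(se_scale(U, np.zeros(3)) == 0.0)

    def test_scale_elementwise_product(self):
        U = np.array([[[2.0], [4.0]]])
        out = se_scale(U, np.array([0.5]))
        assert np.allclose(out, [[[1.0], [2.0]]])

    def test_scale_residual_variant(self, rng):
        U = rng.random((1, 3, 2))
        s = rng.random(2)
        assert np.allclose(se_scale(U, s, residual=True), U + U * s)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            se_scale(rng.random((1, 3, 2)), np.ones(3))
        with pytest.raises(ValueError):
            se_excite(np.ones(3), np.ones((1, 2)), np.ones((2, 1)))


class TestForward:
    def _setup(self, tiny_net_config, rng, n=4, F=5):
        params = init_params(F, tiny_net_config, rng)
        x = rng.random((n, F))
        return params, x

    def test_eval_mode_deterministic(self, tiny_net_config, rng):
        params, x = self._setup(tiny_net_config, rng)
        a, _ = forward(x, params, tiny_net_config)
        b, _ = forward(x, params, tiny_net_config)
        assert np.array_equal(a, b)

    def test_batch_shape_contract(self, tiny_net_config, rng):
        params, x = self._setup(tiny_net_config, rng, n=7)
        logits, _ = forward(x, params, tiny_net_config)
        assert logits.shape == (7, 2)

    def test_dropout_mask_matches_rng_replay(self, rng):
        cfg = ECNNConfig(conv1_filters=4, conv2_filters=3, se_ratio=1,
                         fc_hidden=2, dropout1_rate=0.3, dropout2_rate=0.3)
        params = init_params(5, cfg, np.random.default_rng(0))
        x = np.random.default_rng(1).random((2, 5))
        _, cache = forward(x, params, cfg, training=True,
                           rng=np.random.default_rng(99))
        replay = np.random.default_rng(99)
        expected1 = (replay.random((2, 5, 4)) < 0.7) / 0.7
        expected2 = (replay.random((2, 5, 3)) < 0.7) / 0.7
        assert np.array_equal(cache["mask1"], expected1)
        assert np.array_equal(cache["mask2"], expected2)

    def test_se_identity_matches_plain_cnn(self, tiny_net_config, rng):
        """Forcing all channel weights to 1 reproduces the CNN without SE."""
        params, x = self._setup(tiny_net_config, rng)
        from dataclasses import replace
        with_override, _ = forward(x, params, tiny_net_config, se_override=1.0)
        plain_cfg = replace(tiny_net_config, use_se=False)
        plain, _ = forward(x, params, plain_cfg)
        assert np.allclose(with_override, plain, atol=1e-12)

    def test_width_mismatch_rejected(self, tiny_net_config, rng):
        params, _ = self._setup(tiny_net_config, rng, F=5)
        with pytest.raises(ValueError):
            forward(rng.random((2, 9)), params, tiny_net_config)


class TestGradients:
    @pytest.mark.parametrize("use_se,residual", [(True, False), (True, True),
                                                 (False, False)])
    def test_analytic_matches_central_differences(self, use_se, residual):
        """Backprop agrees with finite differences to < 1e-4 relative error."""
        cfg = ECNNConfig(conv1_filters=6, conv2_filters=4, se_ratio=2,
                         fc_hidden=3, dropout1_rate=0.0, dropout2_rate=0.0,
                         use_se=use_se, se_residual=residual)
        rng = np.random.default_rng(3)
        params = init_params(5, cfg, rng)
        x = rng.standard_normal((6, 5))
        y = np.array([0, 1, 1, 0, 1, 0])
        _, analytic = loss_and_grads(params, cfg, x, y)
        eps = 1e-5
        for key in params:
            num = np.zeros_like(params[key])
            it = np.nditer(num, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                params[key][i] += eps
                lp, _ = loss_and_grads(params, cfg, x, y)
                params[key][i] -= 2 * eps
                lm, _ = loss_and_grads(params, cfg, x, y)
                params[key][i] += eps
                num[i] = (lp - lm) / (2 * eps)
            scale = max(np.abs(num).max(), np.abs(analytic[key]).max(), 1e-8)
            assert np.abs(num - analytic[key]).max() / scale < 1e-4, key


class TestEarlyStopping:
    def test_constructed_loss_sequence(self):
        """Losses (1.0, .9, .95, .96, .97) with patience 2 stop after epoch 4
        and restore the epoch-2 snapshot."""
        stopper = EarlyStopper(patience=2)
        stops = []
        for epoch, loss in enumerate([1.0, 0.9, 0.95, 0.96, 0.97], start=1):
            stops.append(stopper.update(epoch, loss, {"epoch": epoch}))
        assert stops == [False, False, False, True, True]
        assert stopper.best_epoch == 2
        assert stopper.best_snapshot == {"epoch": 2}

    def test_strictly_decreasing_never_triggers(self):
        stopper = EarlyStopper(patience=3)
        for epoch in range(1, 11):
            assert not stopper.update(epoch, 1.0 / epoch, epoch)
        assert stopper.best_epoch == 10

    def test_returned_params_achieve_recorded_best_loss(self, rng):
        cfg = ECNNConfig(conv1_filters=8, conv2_filters=4, se_ratio=2,
                         fc_hidden=4, max_epochs=15, patience=3,
                         batch_size=8, seed=0)
        x = rng.random((30, 10))
        y = (rng.random(30) < 0.5).astype(int)
        params, history = train_early_stop(x[:22], y[:22], x[22:], y[22:], cfg)
        logits, _ = forward(x[22:], params, cfg)
        val_loss, _ = softmax_cross_entropy(logits, y[22:])
        best = min(h["val_loss"] for h in history)
        assert val_loss == pytest.approx(best, abs=1e-12)
        assert all(val_loss <= h["val_loss"] + 1e-12 for h in history)

    def test_linearly_separable_toy_reaches_full_accuracy(self):
        rng = np.random.default_rng(5)
        n = 40
        x = np.vstack([rng.normal(-2, 0.3, (n // 2, 2)),
                       rng.normal(2, 0.3, (n // 2, 2))])
        y = np.array([0] * (n // 2) + [1] * (n // 2))
        order = rng.permutation(n)
        x, y = x[order], y[order]
        cfg = ECNNConfig(conv1_filters=8, conv2_filters=4, se_ratio=2,
                         fc_hidden=4, max_epochs=200, patience=200,
                         batch_size=8, seed=1)
        model = ECNNModel(cfg).fit(x[:32], y[:32], x[32:], y[32:])
        assert np.mean(model.predict(x[:32]) == y[:32]) == 1.0

    def test_empty_sets_rejected(self, tiny_net_config, rng):
        x = rng.random((4, 5))
        y = np.array([0, 1, 0, 1])
        with pytest.raises(ValueError):
            train_early_stop(x, y, x[:0], y[:0], tiny_net_config)


class TestExtraction:
    def test_penultimate_width_and_determinism(self, tiny_net_config, rng):
        params = init_params(5, tiny_net_config, rng)
        x = rng.random((6, 5))
        a = extract_features(params, tiny_net_config, x)
        b = extract_features(params, tiny_net_config, x)
        assert a.shape == (6, tiny_net_config.fc_hidden)
        assert np.array_equal(a, b)

    def test_matches_forward_intermediates(self, tiny_net_config, rng):
        params = init_params(5, tiny_net_config, rng)
        x = rng.random((4, 5))
        feats = extract_features(params, tiny_net_config, x)
        _, cache = forward(x, params, tiny_net_config)
        assert np.array_equal(feats, cache["fc1"])

    def test_logit_extraction_option(self, tiny_net_config, rng):
        from dataclasses import replace
        cfg = replace(tiny_net_config, extract_layer="logits")
        params = init_params(5, cfg, rng)
        x = rng.random((4, 5))
        feats = extract_features(params, cfg, x)
        logits, _ = forward(x, params, cfg)
        assert np.array_equal(feats, logits)

    def test_unfitted_model_rejected(self, tiny_net_config, rng):
        with pytest.raises(ValueError, match="not fitted"):
            extract_features(None, tiny_net_config, rng.random((2, 5)))


class TestCheckpoint:
    def test_roundtrip_preserves_outputs(self, tmp_path, rng):
        cfg = ECNNConfig(conv1_filters=8, conv2_filters=4, se_ratio=2,
                         fc_hidden=4, max_epochs=5, patience=5,
                         batch_size=8, seed=2)
        x = rng.random((20, 6))
        y = (rng.random(20) < 0.5).astype(int)
        model = ECNNModel(cfg).fit(x[:15], y[:15], x[15:], y[15:])
        model.save(tmp_path / "m.json")
        loaded = ECNNModel.load(tmp_path / "m.json")
        assert np.array_equal(model.extract(x), loaded.extract(x))
        assert loaded.history == model.history
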