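"""Denoising-autoencoder layer mechanics, greedy pretraining and features."""

import numpy as np
import pytest

from sdaehar import sdae


def manifold_data(n=200, d=10, seed=0):
    """Points on a 2-d linear manifold embedded in d dims, squashed to [0,1]."""
    rng = np.random.default_rng(seed)
    z = rng.uniform(-1, 1, size=(n, 2))
    basis = rng.normal(size=(2, d))
    x = z @ basis
    x = (x - x.min(axis=0)) / (x.max(axis=0) - x.min(axis=0))
    return x


class TestCorruption:
    def test_rate_zero_is_identity(self, rng):
        x = rng.random(50)
        np.testing.assert_array_equal(sdae.corrupt_input(x, 0.0, rng), x)

    def test_rate_one_zeroes_everything(self, rng):
        x = rng.random(50) + 0.1
        assert np.all(sdae.corrupt_input(x, 1.0, rng) == 0.0)

    def test_zero_fraction_within_binomial_interval(self):
        rng = np.random.default_rng(123)
        x = np.ones(10_000)
        out = sdae.corrupt_input(x, 0.4, rng)
        zeros = int((out == 0).sum())
        # 99% binomial interval around n*p: +- 2.576 * sqrt(n p (1-p)) ~ 126
        assert abs(zeros - 4000) < 127

    def test_reproducible_under_seed(self):
        x = np.ones(100)
        a = sdae.corrupt_input(x, 0.4, np.random.default_rng(5))
        b = sdae.corrupt_input(x, 0.4, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)


class TestLayers:
    def test_zero_params_give_half(self):
        p = sdae.LayerParams(
            w_enc=np.zeros((4, 3)), b_enc=np.zeros(3),
            w_dec=np.zeros((3, 4)), b_dec=np.zeros(4),
        )
        np.testing.assert_allclose(sdae.encode_layer(np.ones(4), p), 0.5)
        np.testing.assert_allclose(sdae.decode_layer(np.ones(3), p), 0.5)

    def test_closed_form_sigmoid(self):
        # sigmoid(ln 3) = 3/4
        p = sdae.LayerParams(
            w_enc=np.array([[1.0]]), b_enc=np.zeros(1),
            w_dec=np.array([[1.0]]), b_dec=np.zeros(1),
        )
        np.testing.assert_allclose(sdae.encode_layer(np.array([np.log(3)]), p), 0.75)

    def test_shape_contracts(self, rng):
        p = sdae.init_layer(384, 100, rng)
        h = sdae.encode_layer(rng.random((5, 384)), p)
        assert h.shape == (5, 100)
        r = sdae.decode_layer(h, p)
        assert r.shape == (5, 384)
        assert np.all((h > 0) & (h < 1)) and np.all((r > 0) & (r < 1))

    def test_dimension_mismatch_raises(self, rng):
        p = sdae.init_layer(10, 4, rng)
        with pytest.raises(ValueError):
            sdae.encode_layer(np.ones(9), p)
        with pytest.raises(ValueError):
            sdae.decode_layer(np.ones(5), p)


class TestPretrain:
    def test_reconstruction_improves_over_init(self):
        x = manifold_data()
        cfg = sdae.SDAEConfig(n_hidden=(2,), dropout=0.0, epochs=40, seed=1)
        rng = np.random.default_rng(cfg.seed)
        init = sdae.init_layer(x.shape[1], 2, rng)
        r0 = sdae.decode_layer(sdae.encode_layer(x, init), init)
        mse0 = np.mean((r0 - x) ** 2)
        params, hist = sdae.pretrain_layer(x, cfg, 0)
        r1 = sdae.decode_layer(sdae.encode_layer(x, params), params)
        assert np.mean((r1 - x) ** 2) < mse0
        assert len(hist) == cfg.epochs

    def test_zero_epochs_returns_initialization(self):
        x = manifold_data(n=40)
        cfg = sdae.SDAEConfig(n_hidden=(3,), epochs=0, seed=2)
        params, hist = sdae.pretrain_layer(x, cfg, 0)
        ref = sdae.init_layer(x.shape[1], 3, np.random.default_rng((cfg.seed, 0)))
        np.testing.assert_array_equal(params.w_enc, ref.w_enc)
        assert hist == []

    def test_loss_history_length_equals_epochs(self):
        x = manifold_data(n=64)
        cfg = sdae.SDAEConfig(n_hidden=(4,), batch_size=32, epochs=2, seed=0)
        _, hist = sdae.pretrain_layer(x, cfg, 0)
        assert len(hist) == 2 and all(np.isfinite(hist))


class TestStack:
    def test_single_layer_stack(self):
        x = manifold_data(n=60)
        stack = sdae.build_stack(x, sdae.SDAEConfig(n_hidden=(5,), epochs=2))
        assert len(stack.layers) == 1 and stack.feature_dim == 5

    def test_three_layer_widths_chain(self):
        x = manifold_data(n=60, d=20)
        cfg = sdae.SDAEConfig(n_hidden=(16, 8, 3), epochs=1, seed=0)
        stack = sdae.build_stack(x, cfg)
        dims = [(p.input_dim, p.hidden_dim) for p in stack.layers]
        assert dims == [(20, 16), (16, 8), (8, 3)]
        assert stack.feature_dim == 3

    def test_fine_tune_reduces_unrolled_mse(self):
        x = manifold_data(n=150)
        cfg = sdae.SDAEConfig(n_hidden=(6, 3), dropout=0.1, epochs=15, seed=3)
        stack = sdae.build_stack(x, cfg)
        before = sdae.unrolled_reconstruction_loss(stack, x)
        tuned = sdae.fine_tune_stack(stack, x, cfg)
        after = sdae.unrolled_reconstruction_loss(tuned, x)
        assert after <= before + 1e-6
        # original stack untouched
        assert sdae.unrolled_reconstruction_loss(stack, x) == pytest.approx(before)

    def test_zero_fine_tune_epochs_is_identity(self):
        x = manifold_data(n=40)
        cfg = sdae.SDAEConfig(n_hidden=(4,), epochs=1, fine_tune_epochs=0)
        stack = sdae.build_stack(x, cfg)
        tuned = sdae.fine_tune_stack(stack, x, cfg)
        np.testing.assert_array_equal(stack.layers[0].w_enc, tuned.layers[0].w_enc)


class TestFeatures:
    def test_extraction_deterministic_and_bounded(self):
        x = manifold_data(n=50)
        stack = sdae.build_stack(x, sdae.SDAEConfig(n_hidden=(8, 4), epochs=2))
        f1 = sdae.extract_features(stack, x)
        f2 = sdae.extract_features(stack, x)
        np.testing.assert_array_equal(f1, f2)
        assert f1.shape == (50, 4)
        assert np.all((f1 > 0) & (f1 < 1)) and np.all(np.isfinite(f1))

    def test_concat_widths_sum(self, rng):
        blocks = {f"s{i}": rng.random((7, 30)) for i in range(3)}
        fm = sdae.concat_sensor_features(blocks, labels=np.arange(7))
        assert fm.features.shape == (7, 90)
        assert fm.sensor_widths == {"s0": 30, "s1": 30, "s2": 30}

    def test_concat_row_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            sdae.concat_sensor_features([rng.random((5, 2)), rng.random((4, 2))])

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            sdae.EncoderStack(layers=[], config=sdae.SDAEConfig(n_hidden=(2,)))


class TestPersistence:
    def test_stack_round_trip(self, tmp_path):
        x = manifold_data(n=40)
        stacks = {
            "acc": sdae.build_stack(x, sdae.SDAEConfig(n_hidden=(5, 2), epochs=1)),
            "gyro": sdae.build_stack(x, sdae.SDAEConfig(n_hidden=(3,), epochs=1, seed=9)),
        }
        path = tmp_path / "stacks.h5"
        sdae.save_stack(path, stacks)
        loaded = sdae.load_stack(path)
        assert set(loaded) == {"acc", "gyro"}
        for name in stacks:
            np.testing.assert_array_equal(
                sdae.extract_features(loaded[name], x),
                sdae.extract_features(stacks[name], x),
            )
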