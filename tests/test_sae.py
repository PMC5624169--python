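"""Stacked autoencoder: forward maps, objective, gradients, training."""

import json

import numpy as np
import pytest
from scipy.special import expit
from sklearn.base import clone

from pdvoice.sae import (
    AutoencoderParams,
    SAEConfig,
    SAEModel,
    StackedAutoencoder,
    decode,
    encode,
    loss,
    stack_train,
    train_autoencoder,
    transform,
)


def random_params(d0, d1, seed=0, scale=0.5):
    rng = np.random.default_rng(seed)
    return AutoencoderParams(
        W1=rng.normal(0, scale, (d0, d1)),
        b1=rng.normal(0, 0.1, d1),
        W2=rng.normal(0, scale, (d1, d0)),
        b2=rng.normal(0, 0.1, d0),
    )


def numeric_gradient(params, X, l2_eps, h=1e-6):
    """Central finite differences of the batch objective, parameter by parameter."""
    from pdvoice.sae import _ae_loss_and_grads

    out = {}
    for name in ("W1", "b1", "W2", "b2"):
        arr = getattr(params, name)
        grad = np.empty_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = arr[idx]
            arr[idx] = orig + h
            up, _ = _ae_loss_and_grads(params, X, l2_eps)
            arr[idx] = orig - h
            down, _ = _ae_loss_and_grads(params, X, l2_eps)
            arr[idx] = orig
            grad[idx] = (up - down) / (2 * h)
        out[name] = grad
    return out


class TestForwardMaps:
    def test_zero_params_give_half(self):
        p = AutoencoderParams(W1=np.zeros((4, 3)), b1=np.zeros(3), W2=np.zeros((3, 4)), b2=np.zeros(4))
        np.testing.assert_allclose(encode(p, np.array([1.0, -2.0, 3.0, 0.5])), 0.5)
        np.testing.assert_allclose(decode(p, np.array([0.2, 0.8, 0.1])), 0.5)

    def test_saturation(self):
        p = AutoencoderParams(
            W1=np.zeros((2, 2)), b1=np.array([0.0, 30.0]), W2=np.zeros((2, 2)), b2=np.zeros(2)
        )
        x1 = encode(p, np.zeros(2))
        assert x1[0] == pytest.approx(0.5)
        assert x1[1] == pytest.approx(1.0, abs=1e-9)

    def test_matches_hand_rolled_matrix_product(self):
        p = random_params(6, 4, seed=3)
        x0 = np.random.default_rng(4).normal(size=6)
        expected = 1.0 / (1.0 + np.exp(-(p.W1.T @ x0 + p.b1)))
        np.testing.assert_allclose(encode(p, x0), expected, atol=1e-12)
        x1 = expected
        expected2 = 1.0 / (1.0 + np.exp(-(p.W2.T @ x1 + p.b2)))
        np.testing.assert_allclose(decode(p, x1), expected2, atol=1e-12)

    def test_roundtrip_shape_contract(self):
        p = random_params(5, 2)
        x0 = np.random.default_rng(0).uniform(size=5)
        assert decode(p, encode(p, x0)).shape == (5,)

    def test_dimension_mismatch_raises(self):
        p = random_params(5, 2)
        with pytest.raises(ValueError, match="dim"):
            encode(p, np.zeros(4))
        with pytest.raises(ValueError, match="dim"):
            decode(p, np.zeros(5))


class TestLoss:
    def test_perfect_reconstruction_without_decay_is_zero(self):
        p = random_params(3, 2)
        x = np.array([0.1, 0.5, 0.9])
        assert loss(p, x, x, 0.0) == 0.0

    def test_zero_eps_equals_reconstruction_error(self):
        p = random_params(3, 2)
        x0, x2 = np.array([0.1, 0.5, 0.9]), np.array([0.2, 0.4, 0.8])
        assert loss(p, x0, x2, 0.0) == pytest.approx(np.mean((x0 - x2) ** 2), rel=1e-15)

    def test_hand_computed_value(self):
        p = AutoencoderParams(
            W1=np.array([[1.0, 2.0], [3.0, 4.0]]),
            b1=np.zeros(2),
            W2=np.array([[1.0, 0.0], [0.0, 1.0]]),
            b2=np.zeros(2),
        )
        x0, x2 = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        # Lr = 1; ||W1||^2 = 30, ||W2||^2 = 2; eps = 0.1 -> 1 + 0.05*32
        assert loss(p, x0, x2, 0.1) == pytest.approx(1.0 + 0.05 * 32.0, rel=1e-12)


class TestGradients:
    def test_backprop_matches_central_differences(self):
        from pdvoice.sae import _ae_loss_and_grads

        rng = np.random.default_rng(0)
        X = rng.uniform(0, 1, (5, 4))
        p = random_params(4, 3, seed=1)
        _, analytic = _ae_loss_and_grads(p, X, l2_eps=1e-3)
        numeric = numeric_gradient(p, X, l2_eps=1e-3)
        for name in analytic:
            a, n = analytic[name], numeric[name]
            rel = np.abs(a - n) / np.maximum(1e-8, np.abs(a) + np.abs(n))
            assert rel.max() < 1e-6, name


class TestTraining:
    def test_descends_on_constant_target(self):
        data = np.tile(np.random.default_rng(0).uniform(0, 1, 6), (50, 1))
        params = train_autoencoder(data, 2, SAEConfig(layer_sizes=(2,), epochs_pretrain=50, seed=0))
        assert params.loss_history[-1] < params.loss_history[0]

    def test_loss_non_increasing_within_tolerance(self):
        data = np.random.default_rng(1).uniform(0, 1, (80, 10))
        params = train_autoencoder(data, 4, SAEConfig(layer_sizes=(4,), epochs_pretrain=100, seed=1))
        history = np.array(params.loss_history)
        rel_change = (history[1:] - history[:-1]) / history[:-1]
        assert rel_change.max() <= 0.01  # <= 1% transient increase per epoch

    def test_same_seed_is_bitwise_identical(self):
        data = np.random.default_rng(2).uniform(0, 1, (40, 8))
        cfg = SAEConfig(layer_sizes=(5, 3), epochs_pretrain=20, epochs_finetune=20, seed=7)
        m1, m2 = stack_train(data, cfg), stack_train(data, cfg)
        for s1, s2 in zip(m1.stages, m2.stages):
            np.testing.assert_array_equal(s1.W1, s2.W1)
            np.testing.assert_array_equal(s1.W2, s2.W2)
            np.testing.assert_array_equal(s1.b1, s2.b1)
            np.testing.assert_array_equal(s1.b2, s2.b2)

    def test_stacking_contract(self):
        data = np.random.default_rng(3).uniform(0, 1, (60, 26))
        cfg = SAEConfig(layer_sizes=(9, 7), epochs_pretrain=5, epochs_finetune=5, seed=0)
        model = stack_train(data, cfg)
        assert model.stages[0].input_dim == 26
        assert model.stages[1].input_dim == 9
        assert model.output_dim == 7
        assert transform(model, data).shape == (60, 7)

    def test_single_stage_equals_plain_autoencoder(self):
        data = np.random.default_rng(4).uniform(0, 1, (30, 6))
        cfg = SAEConfig(layer_sizes=(3,), epochs_pretrain=15, finetune="none", seed=5)
        model = stack_train(data, cfg, scale=False)
        direct = train_autoencoder(data, 3, cfg)
        np.testing.assert_array_equal(model.stages[0].W1, direct.W1)

    def test_supervised_finetune_runs_and_requires_labels(self):
        data = np.random.default_rng(5).uniform(0, 1, (40, 6))
        labels = (np.arange(40) % 2).astype(int)
        cfg = SAEConfig(layer_sizes=(3,), epochs_pretrain=10, epochs_finetune=10,
                        finetune="supervised", seed=0)
        model = stack_train(data, cfg, labels=labels)
        assert model.fine_tuned
        with pytest.raises(ValueError, match="labels"):
            stack_train(data, cfg)


@pytest.fixture(scope="module")
def model_and_data():
    data = np.random.default_rng(6).uniform(0, 1, (50, 22))
    cfg = SAEConfig(layer_sizes=(10, 8), epochs_pretrain=10, epochs_finetune=10, seed=1)
    return stack_train(data, cfg), data


class TestTransform:
    def test_output_in_unit_interval(self, model_and_data):
        model, data = model_and_data
        z = transform(model, data)
        assert z.min() > 0.0 and z.max() < 1.0

    def test_row_order_equivariance(self, model_and_data):
        model, data = model_and_data
        perm = np.random.default_rng(7).permutation(data.shape[0])
        np.testing.assert_allclose(transform(model, data)[perm], transform(model, data[perm]))

    def test_width_follows_config_for_all_grid_cells(self):
        data = np.random.default_rng(8).uniform(0, 1, (30, 22))
        for l1 in (10, 9, 8):
            for l2 in (8, 7, 6):
                cfg = SAEConfig(layer_sizes=(l1, l2), epochs_pretrain=2, epochs_finetune=2, seed=0)
                assert transform(stack_train(data, cfg), data).shape == (30, l2)

    def test_wrong_width_rejected(self, model_and_data):
        model, _ = model_and_data
        with pytest.raises(ValueError, match="columns"):
            transform(model, np.zeros((3, 5)))


class TestSerialization:
    def test_bit_exact_round_trip(self):
        data = np.random.default_rng(9).uniform(0, 1, (40, 12))
        cfg = SAEConfig(layer_sizes=(6, 4), epochs_pretrain=10, epochs_finetune=10, seed=2)
        model = stack_train(data, cfg)
        restored = SAEModel.from_dict(json.loads(json.dumps(model.to_dict())))
        for s1, s2 in zip(model.stages, restored.stages):
            np.testing.assert_array_equal(s1.W1, s2.W1)
            np.testing.assert_array_equal(s1.b2, s2.b2)
        np.testing.assert_array_equal(model.scaler_min, restored.scaler_min)
        np.testing.assert_array_equal(transform(model, data), transform(restored, data))


class TestSklearnInterface:
    def test_fit_transform_and_params(self):
        X = np.random.default_rng(10).normal(size=(40, 8))
        est = StackedAutoencoder(layer_sizes=(4, 3), epochs_pretrain=5, epochs_finetune=5,
                                 random_state=1)
        z = est.fit_transform(X)
        assert z.shape == (40, 3)
        assert est.n_features_in_ == 8
        cloned = clone(est)
        assert cloned.get_params()["layer_sizes"] == (4, 3)
        z2 = cloned.fit(X).transform(X)
        np.testing.assert_array_equal(z, z2)
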