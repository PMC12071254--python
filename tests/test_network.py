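"""Meta-network: attention algebra, exact gradients, training behaviour."""

import numpy as np
import pytest

from emdeepsd import (
    MetaNetwork,
    NetworkConfig,
    TrainedNetwork,
    auc_mann_whitney,
    self_attention,
    train_network,
)
from emdeepsd.network import _sigmoid


def dense_attention_oracle(Q, K, V):
    """Direct dense evaluation of softmax(QK^T/sqrt(d_k))V."""
    d_k = Q.shape[1]
    S = (Q @ K.T) / np.sqrt(d_k)
    A = np.exp(S)
    A = A / A.sum(axis=1, keepdims=True)
    return A @ V


class TestSelfAttention:
    def test_single_timestep_passthrough(self, rng):
        V = rng.standard_normal((1, 4))
        out = self_attention(rng.standard_normal((1, 4)),
                             rng.standard_normal((1, 4)), V)
        np.testing.assert_allclose(out, V, atol=1e-12)

    def test_zero_query_averages_values(self, rng):
        K = rng.standard_normal((5, 4))
        V = rng.standard_normal((5, 4))
        out = self_attention(np.zeros((5, 4)), K, V)
        np.testing.assert_allclose(out, np.tile(V.mean(axis=0), (5, 1)),
                                   atol=1e-12)

    def test_matches_dense_oracle(self, rng):
        Q, K, V = (rng.standard_normal((3, 4)) for _ in range(3))
        np.testing.assert_allclose(self_attention(Q, K, V),
                                   dense_attention_oracle(Q, K, V), atol=1e-6)

    def test_zero_dk_rejected(self):
        with pytest.raises(ValueError, match="d_k"):
            self_attention(np.zeros((2, 0)), np.zeros((2, 0)), np.zeros((2, 0)))

    def test_rows_are_convex_combinations(self, rng):
        Q, K = rng.standard_normal((4, 3)), rng.standard_normal((4, 3))
        V = rng.uniform(1.0, 2.0, (4, 3))
        out = self_attention(Q, K, V)
        assert (out >= V.min(axis=0) - 1e-12).all()
        assert (out <= V.max(axis=0) + 1e-12).all()


class TestForward:
    def test_zero_parameters_give_half(self):
        cfg = NetworkConfig(hidden_units=6, seed=0)
        net = MetaNetwork(cfg)
        for k in net.params:
            net.params[k][:] = 0.0
        X = np.random.RandomState(0).standard_normal((4, 5, 1))
        np.testing.assert_allclose(net.forward_batch(X), 0.5, atol=1e-12)

    def test_output_strictly_in_unit_interval(self, rng):
        net = MetaNetwork(NetworkConfig(hidden_units=8, seed=1))
        p = net.forward_batch(rng.standard_normal((10, 7, 1)))
        assert ((p > 0) & (p < 1)).all()

    def test_gate_closed_form_with_zero_weights(self):
        # zero weight matrices with bias b: every gate activation is a
        # constant sigma(b) / tanh(b), so the first hidden state has the
        # closed form o * tanh(f*c0 + i*g) = sigma(bo)*tanh(sigma(bi)*tanh(bg))
        h = 3
        cfg = NetworkConfig(lstm_layers=1, hidden_units=h, seed=0,
                            use_attention=False)
        net = MetaNetwork(cfg)
        net.params["lstm0_W"][:] = 0.0
        bi, bf, bg, bo = 0.3, -0.4, 0.7, 0.3  # per-gate constant biases
        net.params["lstm0_b"][:] = np.concatenate(
            [np.full(h, bi), np.full(h, bf), np.full(h, bg), np.full(h, bo)]
        )
        h_seq, _ = net._lstm_forward(np.zeros((1, 1, 1)), 0)
        expected = _sigmoid(np.array(bo)) * np.tanh(
            _sigmoid(np.array(bi)) * np.tanh(bg)
        )
        np.testing.assert_allclose(h_seq[0, 0], expected, atol=1e-12)

    def test_manifest_length_mismatch_names_expectation(self):
        net = train_network(
            np.random.RandomState(0).uniform(size=(30, 4)),
            np.r_[np.ones(15), np.zeros(15)],
            NetworkConfig(hidden_units=4, epochs=2, seed=0),
            columns=["a", "b", "c", "d"],
        )
        with pytest.raises(ValueError, match="manifest"):
            net.predict(np.zeros((2, 7)))
        with pytest.raises(ValueError, match="manifest"):
            net.predict(np.zeros((2, 4)), columns=["a", "b", "d", "c"])


class TestGradients:
    def test_backprop_matches_finite_differences(self, rng):
        cfg = NetworkConfig(lstm_layers=2, hidden_units=4, seed=3)
        net = MetaNetwork(cfg, input_dim=1)
        X = rng.standard_normal((5, 3, 1))
        y = np.array([0.0, 1.0, 1.0, 0.0, 1.0])
        p, cache = net.forward_batch(X, cache=True)
        grads = net.backward_batch(y, p, cache)
        eps = 1e-5
        for name, param in net.params.items():
            num = np.zeros_like(param)
            it = np.nditer(param, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = param[idx]
                param[idx] = orig + eps
                lp = net.loss(net.forward_batch(X), y)
                param[idx] = orig - eps
                lm = net.loss(net.forward_batch(X), y)
                param[idx] = orig
                num[idx] = (lp - lm) / (2 * eps)
            np.testing.assert_allclose(grads[name], num, atol=1e-7,
                                       err_msg=name)


@pytest.fixture(scope="module")
def separable_meta():
    rng = np.random.RandomState(1)
    n = 60
    base = np.r_[np.ones((n, 15)), np.zeros((n, 15))] * 0.5 + 0.25
    X = np.clip(base + 0.15 * rng.standard_normal((2 * n, 15)), 0, 1)
    y = np.r_[np.ones(n), np.zeros(n)]
    return X, y


class TestTraining:
    def test_separable_meta_features_learned(self, separable_meta):
        X, y = separable_meta
        net = train_network(X, y, NetworkConfig(seed=0))
        assert auc_mann_whitney(y.astype(int), net.predict(X)) >= 0.95
        assert net.final_loss < net.first_epoch_loss

    def test_training_is_deterministic(self, separable_meta):
        X, y = separable_meta
        a = train_network(X, y, NetworkConfig(seed=4, epochs=10))
        b = train_network(X, y, NetworkConfig(seed=4, epochs=10))
        assert abs(a.final_loss - b.final_loss) < 1e-6
        np.testing.assert_allclose(a.predict(X), b.predict(X), atol=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            train_network(np.zeros((10, 3)), np.ones(10),
                          NetworkConfig(hidden_units=3))

    def test_prediction_applies_stored_normalisation(self, separable_meta):
        X, y = separable_meta
        net = train_network(X, y, NetworkConfig(seed=0, epochs=5))
        assert net.feature_mean.shape == (15,)
        p1 = net.predict(X[:3])
        p2 = np.array([net.predict(row[None, :])[0] for row in X[:3]])
        np.testing.assert_allclose(p1, p2, atol=1e-12)


class TestPoolingIdentity:
    def test_single_timestep_without_attention_is_logistic_on_lstm(self, rng):
        # with one timestep and attention bypassed the head reduces to
        # logistic regression on the final LSTM hidden state, which we
        # recompute here from the raw gate equations as the oracle
        cfg = NetworkConfig(lstm_layers=1, hidden_units=4, seed=2,
                            use_attention=False)
        net = MetaNetwork(cfg)
        x = rng.standard_normal((1, 1, 1))
        W, b = net.params["lstm0_W"], net.params["lstm0_b"]
        h = cfg.hidden_units
        z = np.concatenate([x[0, 0], np.zeros(h)]) @ W + b
        i, f = _sigmoid(z[:h]), _sigmoid(z[h : 2 * h])
        g, o = np.tanh(z[2 * h : 3 * h]), _sigmoid(z[3 * h :])
        hidden = o * np.tanh(i * g)
        expected = _sigmoid(
            hidden @ net.params["dense_w"] + net.params["dense_b"][0]
        )
        np.testing.assert_allclose(net.forward_batch(x)[0], expected,
                                   atol=1e-12)
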