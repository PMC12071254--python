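"""Meta-network: stacked LSTM, self-attention, pooling, sigmoid head.

The base-learner probabilities for a sample form a short sequence (one
timestep per model, in the recorded subsequence-major, algorithm-minor
column order, feature dimension 1). The network runs this sequence
through two LSTM layers, a scaled dot-product self-attention layer
(Q, K, V from three learned linear maps of the LSTM output,
softmax(QK^T / sqrt(d_k)) V), global average pooling over timesteps, and
a dense layer with sigmoid activation that emits the cancer probability.

Implemented self-contained in NumPy: forward pass, reverse-mode
gradients (backpropagation through time for the LSTM layers and an
explicit softmax-attention backward), and an Adam optimiser. Gradients
are exact and checked against finite differences in the test suite.
Training minimises binary cross-entropy; per-feature z-score statistics
are frozen from the training data and reapplied at prediction time.
Everything is seeded, so training is bit-reproducible on one machine.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class NetworkConfig:
    """Architecture and training hyperparameters.

    Defaults follow the stacked-LSTM design: 2 layers, 20 hidden units
    for the 15-column SSA stack (use 10 for the 10-column EMD stack),
    Adam at learning rate 1e-3, 50 epochs, batch size 64.
    """

    lstm_layers: int = 2
    hidden_units: int = 20
    learning_rate: float = 0.001
    epochs: int = 50
    batch_size: int = 64
    seed: int = 0
    use_attention: bool = True

    def __post_init__(self) -> None:
        if self.hidden_units <= 0:
            raise ValueError("hidden_units must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lstm_layers < 1:
            raise ValueError("need at least one LSTM layer")


class MetaNetwork:
    """The LSTM + self-attention classifier over meta-feature sequences.

    Parameters live in ``self.params`` (a flat dict of arrays). LSTM gate
    order within the stacked weight matrices is (i, f, g, o).
    """

    def __init__(self, config: NetworkConfig, input_dim: int = 1):
        self.config = config
        self.input_dim = input_dim
        h = config.hidden_units
        rng = np.random.RandomState(config.seed)
        self.params: dict[str, np.ndarray] = {}
        in_dim = input_dim
        for layer in range(config.lstm_layers):
            fan_in = in_dim + h
            scale = np.sqrt(6.0 / (fan_in + 4 * h))
            self.params[f"lstm{layer}_W"] = rng.uniform(
                -scale, scale, size=(fan_in, 4 * h)
            )
            b = np.zeros(4 * h)
            b[h : 2 * h] = 1.0  # forget-gate bias starts open
            self.params[f"lstm{layer}_b"] = b
            in_dim = h
        if config.use_attention:
            scale = np.sqrt(6.0 / (2 * h))
            for name in ("Wq", "Wk", "Wv"):
                self.params[name] = rng.uniform(-scale, scale, size=(h, h))
        scale = np.sqrt(6.0 / (h + 1))
        self.params["dense_w"] = rng.uniform(-scale, scale, size=h)
        self.params["dense_b"] = np.zeros(1)

    # -- forward -----------------------------------------------------------

    def _lstm_forward(self, x: np.ndarray, layer: int):
        """x: (B, T, D) -> h_seq (B, T, H) plus caches for backprop."""
        B, T, D = x.shape
        h = self.config.hidden_units
        W = self.params[f"lstm{layer}_W"]
        b = self.params[f"lstm{layer}_b"]
        h_t = np.zeros((B, h))
        c_t = np.zeros((B, h))
        h_seq = np.empty((B, T, h))
        caches = []
        for t in range(T):
            x_t = x[:, t, :]
            z = np.concatenate([x_t, h_t], axis=1) @ W + b
            i = _sigmoid(z[:, :h])
            f = _sigmoid(z[:, h : 2 * h])
            g = np.tanh(z[:, 2 * h : 3 * h])
            o = _sigmoid(z[:, 3 * h :])
            c_new = f * c_t + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            caches.append((x_t, h_t, c_t, i, f, g, o, tanh_c))
            h_t, c_t = h_new, c_new
            h_seq[:, t, :] = h_t
        return h_seq, caches

    def _attention_forward(self, H: np.ndarray):
        """Scaled dot-product self-attention over timesteps."""
        h = self.config.hidden_units
        Q = H @ self.params["Wq"]
        K = H @ self.params["Wk"]
        V = H @ self.params["Wv"]
        S = Q @ K.transpose(0, 2, 1) / np.sqrt(h)
        S = S - S.max(axis=-1, keepdims=True)
        A = np.exp(S)
        A = A / A.sum(axis=-1, keepdims=True)
        O = A @ V
        return O, (H, Q, K, V, A)

    def forward_batch(self, X_seq: np.ndarray, cache: bool = False):
        """X_seq: (B, T, D) normalised input -> probabilities (B,)."""
        h_in = X_seq
        lstm_caches = []
        for layer in range(self.config.lstm_layers):
            h_in, caches = self._lstm_forward(h_in, layer)
            lstm_caches.append(caches)
        H = h_in
        if self.config.use_attention:
            O, attn_cache = self._attention_forward(H)
        else:
            O, attn_cache = H, None
        z = O.mean(axis=1)  # global average pooling over timesteps
        logit = z @ self.params["dense_w"] + self.params["dense_b"][0]
        p = _sigmoid(logit)
        if cache:
            return p, (X_seq, lstm_caches, H, O, attn_cache, z, logit)
        return p

    # -- backward ----------------------------------------------------------

    def _lstm_backward(self, dH_seq: np.ndarray, caches, layer: int, grads):
        B, T, h = dH_seq.shape
        W = self.params[f"lstm{layer}_W"]
        in_dim = W.shape[0] - h
        dW = np.zeros_like(W)
        db = np.zeros(4 * h)
        dX = np.empty((B, T, in_dim))
        dh_next = np.zeros((B, h))
        dc_next = np.zeros((B, h))
        for t in range(T - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, tanh_c = caches[t]
            dh = dH_seq[:, t, :] + dh_next
            do = dh * tanh_c
            dc = dh * o * (1 - tanh_c**2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g**2),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            inp = np.concatenate([x_t, h_prev], axis=1)
            dW += inp.T @ dz
            db += dz.sum(axis=0)
            dinp = dz @ W.T
            dX[:, t, :] = dinp[:, :in_dim]
            dh_next = dinp[:, in_dim:]
            dc_next = dc * f
        grads[f"lstm{layer}_W"] = dW
        grads[f"lstm{layer}_b"] = db
        return dX

    def backward_batch(self, y: np.ndarray, p: np.ndarray, cache):
        """Gradients of mean binary cross-entropy w.r.t. all parameters."""
        X_seq, lstm_caches, H, O, attn_cache, z, logit = cache
        B, T, h = H.shape
        grads: dict[str, np.ndarray] = {}
        dlogit = (p - y) / B
        grads["dense_w"] = z.T @ dlogit
        grads["dense_b"] = np.array([dlogit.sum()])
        dz = dlogit[:, None] * self.params["dense_w"][None, :]
        dO = np.repeat(dz[:, None, :] / T, T, axis=1)
        if self.config.use_attention:
            _, Q, K, V, A = attn_cache
            dV = A.transpose(0, 2, 1) @ dO
            dA = dO @ V.transpose(0, 2, 1)
            dS = A * (dA - (dA * A).sum(axis=-1, keepdims=True)) / np.sqrt(h)
            dQ = dS @ K
            dK = dS.transpose(0, 2, 1) @ Q
            Hf = H.reshape(-1, h)
            grads["Wq"] = Hf.T @ dQ.reshape(-1, h)
            grads["Wk"] = Hf.T @ dK.reshape(-1, h)
            grads["Wv"] = Hf.T @ dV.reshape(-1, h)
            dH = (
                dQ @ self.params["Wq"].T
                + dK @ self.params["Wk"].T
                + dV @ self.params["Wv"].T
            )
        else:
            dH = dO
        dX = dH
        for layer in range(self.config.lstm_layers - 1, -1, -1):
            dX = self._lstm_backward(dX, lstm_caches[layer], layer, grads)
        return grads

    def loss(self, p: np.ndarray, y: np.ndarray) -> float:
        eps = 1e-12
        return float(
            -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
        )


@dataclass
class TrainedNetwork:
    """A trained meta-network with its column manifest and normalisation."""

    network: MetaNetwork
    manifest: list[str]
    feature_mean: np.ndarray
    feature_std: np.ndarray
    final_loss: float = float("nan")
    first_epoch_loss: float = float("nan")

    def _prepare(self, X: np.ndarray, columns: Sequence[str] | None) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.manifest):
            raise ValueError(
                f"expected {len(self.manifest)} meta-features in manifest order "
                f"{self.manifest}, got {X.shape[1]}"
            )
        if columns is not None and list(columns) != self.manifest:
            raise ValueError(
                "meta-feature columns do not match the training manifest; "
                f"expected {self.manifest}"
            )
        Xn = (X - self.feature_mean) / self.feature_std
        return Xn[:, :, None]  # one feature per timestep

    def predict(self, X: np.ndarray, columns: Sequence[str] | None = None) -> np.ndarray:
        """Cancer probabilities for rows of meta-features."""
        return self.network.forward_batch(self._prepare(X, columns))


def forward(net: TrainedNetwork, meta_row: np.ndarray) -> float:
    """Probability for a single meta-feature row."""
    return float(net.predict(np.atleast_2d(meta_row))[0])


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g**2
            m_hat = self.m[k] / (1 - b1**self.t)
            v_hat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * m_hat / (np.sqrt(v_hat) + eps)


def train_network(
    meta_X: np.ndarray,
    y: np.ndarray,
    config: NetworkConfig,
    columns: Sequence[str] | None = None,
) -> TrainedNetwork:
    """Train the meta-network with Adam on binary cross-entropy.

    Features are z-scored with training-set statistics (stored on the
    returned object); batches are shuffled with the configured seed.
    """
    X = np.asarray(meta_X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("meta_X must be 2-D (samples x models)")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("both classes must be present in y")
    n, t_len = X.shape
    manifest = list(columns) if columns is not None else [
        f"m{i}" for i in range(t_len)
    ]
    if len(manifest) != t_len:
        raise ValueError("columns length must match meta_X width")
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std = np.where(std < 1e-12, 1.0, std)
    Xn = ((X - mean) / std)[:, :, None]
    net = MetaNetwork(config, input_dim=1)
    opt = _Adam(net.params, config.learning_rate)
    rng = np.random.RandomState(config.seed)
    first_epoch_loss = float("nan")
    last_loss = float("nan")
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            p, cache = net.forward_batch(Xn[idx], cache=True)
            losses.append(net.loss(p, y[idx]) * idx.size)
            grads = net.backward_batch(y[idx], p, cache)
            opt.step(net.params, grads)
        epoch_loss = float(np.sum(losses) / n)
        if epoch == 0:
            first_epoch_loss = epoch_loss
        last_loss = epoch_loss
    return TrainedNetwork(
        network=net,
        manifest=manifest,
        feature_mean=mean,
        feature_std=std,
        final_loss=last_loss,
        first_epoch_loss=first_epoch_loss,
    )


def self_attention(Q: np.ndarray, K: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Standalone scaled dot-product attention softmax(QK^T/sqrt(d_k))V."""
    Q, K, V = (np.asarray(m, dtype=float) for m in (Q, K, V))
    d_k = Q.shape[-1]
    if d_k == 0:
        raise ValueError("d_k must be positive")
    S = Q @ K.T / np.sqrt(d_k)
    S = S - S.max(axis=-1, keepdims=True)
    A = np.exp(S)
    A = A / A.sum(axis=-1, keepdims=True)
    return A @ V
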