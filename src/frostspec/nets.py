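"""Small spectral deep-learning regressors in plain numpy.

Two fixed architectures over a 1-D band axis:

* ``CNNRegressor`` — three same-padded convolution layers (ReLU) over the
  spectrum treated as a (bands × 1) image, one max-pooling layer, dropout,
  and a fully connected scalar output; Adam optimizer.
* ``LSTMRegressor`` — the band axis consumed as a sequence of scalars by a
  single LSTM layer (tanh), dropout on the final hidden state, and a dense
  scalar output; Adam optimizer.

Inputs are row-wise L2-normalized and the response is standardized
internally; both models are deterministic given their seed. Gradients are
hand-derived and verified against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np


def l2_normalize_rows(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return X / norms


class Adam:
    """Adam over a dict of parameter arrays."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k in params:
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


# ---------------------------------------------------------------------------
# 1-D convolution helpers (stride 1, same padding)

def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """x (n, C_in, L), W (C_out, C_in, k) -> out (n, C_out, L)."""
    k = W.shape[2]
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    L = x.shape[2]
    cols = np.stack([xp[:, :, i : i + L] for i in range(k)], axis=-1)  # (n, C_in, L, k)
    out = np.einsum("nclk,ock->nol", cols, W, optimize=True) + b[None, :, None]
    return out, cols


def _conv_backward(gout: np.ndarray, cols: np.ndarray, W: np.ndarray, L: int):
    k = W.shape[2]
    pad = k // 2
    gW = np.einsum("nclk,nol->ock", cols, gout, optimize=True)
    gb = gout.sum(axis=(0, 2))
    gcols = np.einsum("nol,ock->nclk", gout, W, optimize=True)
    n, C_in = gcols.shape[0], gcols.shape[1]
    gxp = np.zeros((n, C_in, L + 2 * pad))
    for i in range(k):
        gxp[:, :, i : i + L] += gcols[:, :, :, i]
    gx = gxp[:, :, pad : pad + L]
    return gx, gW, gb


def _maxpool_forward(x: np.ndarray, size: int):
    """Non-overlapping max pooling along the last axis; trailing remainder dropped."""
    n, C, L = x.shape
    if size <= 1 or L < size:
        return x, None
    L2 = L // size
    xr = x[:, :, : L2 * size].reshape(n, C, L2, size)
    arg = xr.argmax(axis=3)
    out = xr.max(axis=3)
    return out, (arg, L, size)


def _maxpool_backward(gout: np.ndarray, cache, x_shape):
    if cache is None:
        return gout
    arg, L, size = cache
    n, C, L2 = gout.shape
    # scatter gradients to argmax positions
    gx = np.zeros((n, C, L))
    ii, cc = np.meshgrid(np.arange(n), np.arange(C), indexing="ij")
    for l2 in range(L2):
        gx[ii, cc, l2 * size + arg[:, :, l2]] += gout[:, :, l2]
    return gx


class _BaseNet:
    def __init__(self, learning_rate: float, batch_size: int, epochs: int,
                 dropout: float, seed: int):
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.dropout = dropout
        self.seed = seed
        self.params: dict[str, np.ndarray] = {}
        self.loss_history_: list[float] = []
        self._y_mean = 0.0
        self._y_sd = 1.0
        self.n_features_: int | None = None

    def _standardize_y(self, y: np.ndarray) -> np.ndarray:
        self._y_mean = float(np.mean(y))
        self._y_sd = float(np.std(y)) or 1.0
        return (y - self._y_mean) / self._y_sd

    def fit(self, X: np.ndarray, y: np.ndarray):
        X = l2_normalize_rows(X)
        y = self._standardize_y(np.asarray(y, dtype=float).ravel())
        n = X.shape[0]
        self.n_features_ = X.shape[1]
        rng = np.random.default_rng(self.seed)
        self._init_params(X.shape[1], rng)
        opt = Adam(self.params, lr=self.learning_rate)
        batch = min(self.batch_size, n)
        for _ in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for s in range(0, n, batch):
                idx = order[s : s + batch]
                loss, grads = self._loss_and_grads(X[idx], y[idx], rng)
                opt.step(self.params, grads)
                epoch_loss += loss * idx.size
            self.loss_history_.append(epoch_loss / n)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.n_features_ is not None and X.shape[1] != self.n_features_:
            raise ValueError(
                f"expected {self.n_features_} bands, got {X.shape[1]}"
            )
        X = l2_normalize_rows(X)
        out = self._forward_inference(X)
        return out * self._y_sd + self._y_mean

    # subclass hooks -------------------------------------------------------
    def _init_params(self, n_features: int, rng) -> None:  # pragma: no cover
        raise NotImplementedError

    def _loss_and_grads(self, X, y, rng):  # pragma: no cover
        raise NotImplementedError

    def _forward_inference(self, X):  # pragma: no cover
        raise NotImplementedError


class CNNRegressor(_BaseNet):
    """Three ReLU convolution layers + max pool + dropout + dense output."""

    def __init__(self, channels=(16, 32, 64), kernel_size: int = 3, pool_size: int = 2,
                 learning_rate: float = 1e-3, batch_size: int = 64, epochs: int = 400,
                 dropout: float = 0.5, seed: int = 0):
        super().__init__(learning_rate, batch_size, epochs, dropout, seed)
        self.channels = tuple(channels)
        self.kernel_size = kernel_size
        self.pool_size = pool_size

    def _init_params(self, n_features: int, rng) -> None:
        k = self.kernel_size
        chans = (1,) + self.channels
        p = {}
        for i in range(3):
            fan_in = chans[i] * k
            p[f"W{i}"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(chans[i + 1], chans[i], k))
            p[f"b{i}"] = np.zeros(chans[i + 1])
        L_pool = n_features // self.pool_size if n_features >= self.pool_size else n_features
        flat = self.channels[-1] * L_pool
        p["Wd"] = rng.normal(0.0, np.sqrt(1.0 / flat), size=flat)
        p["bd"] = np.zeros(1)
        self.params = p

    def _forward(self, X: np.ndarray, drop_mask: np.ndarray | None):
        x = X[:, None, :]  # (n, 1, L)
        caches = []
        for i in range(3):
            z, cols = _conv_forward(x, self.params[f"W{i}"], self.params[f"b{i}"])
            a = np.maximum(z, 0.0)
            caches.append((x.shape[2], cols, z))
            x = a
        pooled, pcache = _maxpool_forward(x, self.pool_size)
        flat = pooled.reshape(pooled.shape[0], -1)
        if drop_mask is not None:
            flat = flat * drop_mask
        yhat = flat @ self.params["Wd"] + self.params["bd"][0]
        return yhat, (caches, x.shape, pcache, pooled.shape, flat)

    def _loss_and_grads(self, X, y, rng):
        drop_mask = None
        if self.dropout > 0:
            keep = 1.0 - self.dropout
            flat_dim = self.params["Wd"].size
            drop_mask = (rng.random((X.shape[0], flat_dim)) < keep) / keep
        yhat, (caches, relu_shape, pcache, pooled_shape, flat) = self._forward(X, drop_mask)
        n = X.shape[0]
        resid = yhat - y
        loss = 0.5 * float(np.mean(resid**2))
        grads = {}
        gyhat = resid / n
        grads["Wd"] = flat.T @ gyhat
        grads["bd"] = np.array([gyhat.sum()])
        gflat = np.outer(gyhat, self.params["Wd"])
        if drop_mask is not None:
            gflat = gflat * drop_mask
        gpooled = gflat.reshape(pooled_shape)
        gx = _maxpool_backward(gpooled, pcache, relu_shape)
        for i in reversed(range(3)):
            L, cols, z = caches[i]
            gz = gx * (z > 0)
            gx, gW, gb = _conv_backward(gz, cols, self.params[f"W{i}"], L)
            grads[f"W{i}"] = gW
            grads[f"b{i}"] = gb
        gx = gx[:, 0, :]  # gradient w.r.t. the input spectrum (unused)
        return loss, grads

    def _forward_inference(self, X):
        yhat, _ = self._forward(X, None)
        return yhat


class LSTMRegressor(_BaseNet):
    """Single LSTM layer over the band sequence + dropout + dense output."""

    def __init__(self, hidden_units: int = 20, learning_rate: float = 1e-3,
                 batch_size: int = 64, epochs: int = 40, dropout: float = 0.5,
                 seed: int = 0):
        super().__init__(learning_rate, batch_size, epochs, dropout, seed)
        self.hidden_units = hidden_units

    def _init_params(self, n_features: int, rng) -> None:
        H = self.hidden_units
        s = np.sqrt(1.0 / H)
        self.params = {
            "Wx": rng.normal(0.0, s, size=(1, 4 * H)),
            "Wh": rng.normal(0.0, s, size=(H, 4 * H)),
            "b": np.zeros(4 * H),
            "Wd": rng.normal(0.0, s, size=H),
            "bd": np.zeros(1),
        }
        # forget-gate bias at 1 helps gradient flow over long band sequences
        self.params["b"][H : 2 * H] = 1.0

    def _forward(self, X: np.ndarray, drop_mask: np.ndarray | None, keep_cache: bool):
        n, T = X.shape
        H = self.hidden_units
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        h = np.zeros((n, H))
        c = np.zeros((n, H))
        cache = [] if keep_cache else None
        for t in range(T):
            x_t = X[:, t : t + 1]
            z = x_t @ Wx + h @ Wh + b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            o = _sigmoid(z[:, 2 * H : 3 * H])
            g = np.tanh(z[:, 3 * H :])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            if keep_cache:
                cache.append((x_t, h, c, i, f, o, g, tanh_c))
            h, c = h_new, c_new
        h_out = h * drop_mask if drop_mask is not None else h
        yhat = h_out @ self.params["Wd"] + self.params["bd"][0]
        return yhat, h, h_out, cache

    def _loss_and_grads(self, X, y, rng):
        n, T = X.shape
        H = self.hidden_units
        drop_mask = None
        if self.dropout > 0:
            keep = 1.0 - self.dropout
            drop_mask = (rng.random((n, H)) < keep) / keep
        yhat, h_last, h_out, cache = self._forward(X, drop_mask, keep_cache=True)
        resid = yhat - y
        loss = 0.5 * float(np.mean(resid**2))
        gyhat = resid / n
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        grads["Wd"] = h_out.T @ gyhat
        grads["bd"] = np.array([gyhat.sum()])
        gh = np.outer(gyhat, self.params["Wd"])
        if drop_mask is not None:
            gh = gh * drop_mask
        gc = np.zeros((n, H))
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        for t in reversed(range(T)):
            x_t, h_prev, c_prev, i, f, o, g, tanh_c = cache[t]
            go = gh * tanh_c
            gc = gc + gh * o * (1 - tanh_c**2)
            gi = gc * g
            gf = gc * c_prev
            gg = gc * i
            gz = np.concatenate(
                [gi * i * (1 - i), gf * f * (1 - f), go * o * (1 - o), gg * (1 - g**2)],
                axis=1,
            )
            grads["Wx"] += x_t.T @ gz
            grads["Wh"] += h_prev.T @ gz
            grads["b"] += gz.sum(axis=0)
            gh = gz @ Wh.T
            gc = gc * f
        return loss, grads

    def _forward_inference(self, X):
        yhat, _, _, _ = self._forward(X, None, keep_cache=False)
        return yhat
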