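"""Minimal NumPy neural-network layers used by the classifier.

Implements exactly what the architecture needs — batch normalisation,
2D convolution with stride and SAME (ceil) padding, leaky rectifier,
dense output and the Adam optimiser — with explicit forward/backward
passes.  Arrays are NHWC float32; gradients flow back to the input so
saliency maps can be computed with the same machinery.
"""

from __future__ import annotations

import numpy as np


class Layer:
    params: list
    grads: list

    def __init__(self):
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class BatchNorm(Layer):
    """Channel-wise batch normalisation (NHWC or NC input)."""

    def __init__(self, channels: int, momentum: float = 0.99, eps: float = 1e-3):
        super().__init__()
        self.gamma = np.ones(channels, np.float32)
        self.beta = np.zeros(channels, np.float32)
        self.moving_mean = np.zeros(channels, np.float32)
        self.moving_var = np.ones(channels, np.float32)
        self.momentum = momentum
        self.eps = eps
        self.calibrating = False
        self._calib_n = 0
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]

    def forward(self, x, train):
        x = x.astype(np.float32)
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            if self.calibrating:
                # simple running average: exact dataset statistics are
                # needed for inference when the batch count is small
                n = self._calib_n
                self.moving_mean[...] = (n * self.moving_mean + mean) / (n + 1)
                self.moving_var[...] = (n * self.moving_var + var) / (n + 1)
                self._calib_n += 1
            else:
                self.moving_mean *= self.momentum
                self.moving_mean += (1 - self.momentum) * mean
                self.moving_var *= self.momentum
                self.moving_var += (1 - self.momentum) * var
        else:
            mean, var = self.moving_mean, self.moving_var
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._inv
        self._train = train
        return self.gamma * self._xhat + self.beta

    def backward(self, dy):
        axes = tuple(range(dy.ndim - 1))
        self.grads[0][...] = (dy * self._xhat).sum(axis=axes)
        self.grads[1][...] = dy.sum(axis=axes)
        if not self._train:
            return dy * self.gamma * self._inv
        n = dy.size // dy.shape[-1]
        dxhat = dy * self.gamma
        return (
            self._inv
            / n
            * (
                n * dxhat
                - dxhat.sum(axis=axes)
                - self._xhat * (dxhat * self._xhat).sum(axis=axes)
            )
        ).astype(np.float32)


def _same_pad(size: int, stride: int, kernel: int) -> tuple[int, int]:
    out = -(-size // stride)  # ceil
    pad = max((out - 1) * stride + kernel - size, 0)
    return pad // 2, pad - pad // 2


class Conv2D(Layer):
    """Strided 2D convolution, SAME padding with ceil output size."""

    def __init__(self, c_in, c_out, kernel=(4, 4), stride=(2, 2), rng=None):
        super().__init__()
        rng = np.random.default_rng() if rng is None else rng
        kh, kw = kernel
        fan_in, fan_out = kh * kw * c_in, kh * kw * c_out
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        self.W = rng.uniform(-limit, limit, size=(kh, kw, c_in, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, np.float32)
        self.stride = stride
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def out_shape(self, h, w):
        return -(-h // self.stride[0]), -(-w // self.stride[1])

    def forward(self, x, train):
        kh, kw, _, _ = self.W.shape
        sh, sw = self.stride
        n, h, w, c = x.shape
        ph = _same_pad(h, sh, kh)
        pw = _same_pad(w, sw, kw)
        xp = np.pad(x, ((0, 0), ph, pw, (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
        patches = win[:, ::sh, ::sw]  # (n, ho, wo, c, kh, kw)
        self._patches = patches
        self._xshape = x.shape
        self._pad = (ph, pw)
        return (
            np.einsum("nhwckl,klcf->nhwf", patches, self.W, optimize=True) + self.b
        ).astype(np.float32)

    def backward(self, dy):
        kh, kw, _, _ = self.W.shape
        sh, sw = self.stride
        n, h, w, c = self._xshape
        ph, pw = self._pad
        self.grads[0][...] = np.einsum(
            "nhwckl,nhwf->klcf", self._patches, dy, optimize=True
        )
        self.grads[1][...] = dy.sum(axis=(0, 1, 2))
        ho, wo = dy.shape[1], dy.shape[2]
        dxp = np.zeros((n, h + ph[0] + ph[1], w + pw[0] + pw[1], c), np.float32)
        for i in range(kh):
            for j in range(kw):
                dxp[:, i : i + sh * ho : sh, j : j + sw * wo : sw, :] += np.einsum(
                    "nhwf,cf->nhwc", dy, self.W[i, j], optimize=True
                )
        return dxp[:, ph[0] : ph[0] + h, pw[0] : pw[0] + w, :]


class LeakyReLU(Layer):
    def __init__(self, alpha=0.2):
        super().__init__()
        self.alpha = alpha

    def forward(self, x, train):
        self._mask = x >= 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, dy):
        return np.where(self._mask, dy, self.alpha * dy)


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, d_in, d_out, rng=None):
        super().__init__()
        rng = np.random.default_rng() if rng is None else rng
        limit = np.sqrt(6.0 / (d_in + d_out))
        self.W = rng.uniform(-limit, limit, size=(d_in, d_out)).astype(np.float32)
        self.b = np.zeros(d_out, np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.W.T


class Sequential:
    """A feed-forward stack ending in a single logit."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def parameters(self):
        out = []
        for layer in self.layers:
            out.extend(zip(layer.params, layer.grads))
        return out

    def n_params(self) -> int:
        return sum(p.size for layer in self.layers for p in layer.params)

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params):
                state[f"layer{i}_param{j}"] = p
            if isinstance(layer, BatchNorm):
                state[f"layer{i}_moving_mean"] = layer.moving_mean
                state[f"layer{i}_moving_var"] = layer.moving_var
        return state

    def load_state_dict(self, state):
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params):
                p[...] = state[f"layer{i}_param{j}"]
            if isinstance(layer, BatchNorm):
                layer.moving_mean[...] = state[f"layer{i}_moving_mean"]
                layer.moving_var[...] = state[f"layer{i}_moving_var"]


class Adam:
    """Adaptive-moment gradient descent (Keras-default hyperparameters)."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    z = z.ravel()
    p = sigmoid(z)
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    dz = ((p - y) / len(y)).astype(np.float32)
    return loss, dz.reshape(-1, 1)
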