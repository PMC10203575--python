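"""Minimal 1-D convolutional layers with manual backpropagation.

All layers operate on float32 arrays of shape (batch, length, channels)
and cache whatever the backward pass needs on the instance.  ``params()``
yields (weight, gradient) pairs for the optimizer; layers without
trainable weights yield nothing.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


def _sliding_windows(x: np.ndarray, kernel: int) -> np.ndarray:
    """Zero-copy (B, L_out, kernel, C) view over a padded (B, L, C) array."""
    b, l, c = x.shape
    sb, sl, sc = x.strides
    l_out = l - kernel + 1
    return np.lib.stride_tricks.as_strided(
        x, shape=(b, l_out, kernel, c), strides=(sb, sl, sl, sc), writeable=False
    )


class Layer:
    def params(self):
        return ()

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv1D(Layer):
    """Same-padded 1-D convolution implemented as im2col + matmul."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        fan_in = kernel * c_in
        # He initialisation, suited to the ReLU nonlinearities around it
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, c_out)).astype(F32)
        self.b = np.zeros(c_out, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        yield self.W, self.dW
        yield self.b, self.db

    def forward(self, x, training):
        b, l, _ = x.shape
        self._shape = (b, l)
        if self.kernel == 1:
            cols = x.reshape(b * l, self.c_in)
        else:
            pad_l = (self.kernel - 1) // 2
            pad_r = self.kernel - 1 - pad_l
            xp = np.pad(x, ((0, 0), (pad_l, pad_r), (0, 0)))
            cols = _sliding_windows(xp, self.kernel).reshape(b * l, self.kernel * self.c_in)
        self._cols = cols
        y = cols @ self.W
        y += self.b
        return y.reshape(b, l, self.c_out)

    def backward(self, dy):
        b, l = self._shape
        dyf = dy.reshape(b * l, self.c_out)
        self.dW[...] = self._cols.T @ dyf
        self.db[...] = dyf.sum(axis=0)
        if self.kernel == 1:
            return (dyf @ self.W.T).reshape(b, l, self.c_in)
        dcols = (dyf @ self.W.T).reshape(b, l, self.kernel, self.c_in)
        pad_l = (self.kernel - 1) // 2
        dxp = np.zeros((b, l + self.kernel - 1, self.c_in), dtype=F32)
        for k in range(self.kernel):
            dxp[:, k : k + l] += dcols[:, :, k]
        return dxp[:, pad_l : pad_l + l]


class BatchNorm1D(Layer):
    """Per-channel batch normalisation over (batch, length)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=F32)
        self.beta = np.zeros(channels, dtype=F32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=F32)
        self.running_var = np.ones(channels, dtype=F32)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        yield self.gamma, self.dgamma
        yield self.beta, self.dbeta

    def forward(self, x, training):
        self._training = training
        if training:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mean).astype(F32)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(F32)
            inv_std = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean) * inv_std
            self._xhat = xhat
            self._inv_std = inv_std.astype(F32)
            self._n = x.shape[0] * x.shape[1]
            return (self.gamma * xhat + self.beta).astype(F32)
        # inference: a single fused affine map per channel
        inv_std = 1.0 / np.sqrt(self.running_var + self.eps)
        scale = (self.gamma * inv_std).astype(F32)
        self._eval_scale = scale
        y = x * scale
        y += self.beta - self.running_mean * scale
        return y

    def backward(self, dy):
        if not self._training:
            # gamma/beta gradients are not needed outside training
            return dy * self._eval_scale
        xhat, inv_std = self._xhat, self._inv_std
        self.dgamma[...] = (dy * xhat).sum(axis=(0, 1))
        self.dbeta[...] = dy.sum(axis=(0, 1))
        n = self._n
        # standard batch-norm gradient with batch statistics
        dxhat = dy * self.gamma
        return (
            inv_std
            / n
            * (n * dxhat - dxhat.sum(axis=(0, 1)) - xhat * (dxhat * xhat).sum(axis=(0, 1)))
        ).astype(F32)


class ReLU(Layer):
    """Rectifier applied in place; upstream layers hand over fresh buffers."""

    def forward(self, x, training):
        self._mask = x > 0
        np.maximum(x, F32(0.0), out=x)
        return x

    def backward(self, dy):
        return dy * self._mask


class AvgPool1D(Layer):
    """Non-overlapping average pooling; a trailing odd position is dropped."""

    def __init__(self, stride: int = 2):
        self.stride = stride

    def forward(self, x, training):
        b, l, c = x.shape
        s = self.stride
        l_out = l // s
        self._in_len = l
        return x[:, : l_out * s].reshape(b, l_out, s, c).mean(axis=2)

    def backward(self, dy):
        b, l_out, c = dy.shape
        s = self.stride
        dx = np.zeros((b, self._in_len, c), dtype=F32)
        dx[:, : l_out * s] = np.repeat(dy / s, s, axis=1)
        return dx


class Flatten(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)).astype(F32)
        self.b = np.zeros(n_out, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        yield self.W, self.dW
        yield self.b, self.db

    def forward(self, x, training):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        return dy @ self.W.T
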