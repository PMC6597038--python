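"""Minimal seeded feed-forward network: 1-D convolutions along the
sequence axis, dense layers, dropout, softmax cross-entropy, Adam.

Sized for desk-scale move-predictor training on encoded puzzle states.
All randomness (init, shuffling, dropout) flows from one generator, so
training is bit-reproducible given a seed.  Arrays are float64 N x L x C
(batch, sequence position, channels) until flattened.
"""

from __future__ import annotations

import numpy as np


def _he_init(rng, shape, fan_in):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Layer:
    params: list  # [(weight array, grad array), ...]

    def forward(self, x, train): ...
    def backward(self, grad): ...


class Conv1D(Layer):
    """Same-padded 1-D convolution with optional stride-subsampling."""

    def __init__(self, rng, in_ch, out_ch, kernel, stride=1):
        self.kernel, self.stride = kernel, stride
        self.W = _he_init(rng, (kernel, in_ch, out_ch), kernel * in_ch)
        self.b = np.zeros(out_ch)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.params = [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x, train=False):
        K = self.kernel
        pad = K // 2
        self._xpad = np.pad(x, ((0, 0), (pad, K - 1 - pad), (0, 0)))
        N, L, _ = x.shape
        out = np.zeros((N, L, self.W.shape[2]))
        for k in range(K):
            out += self._xpad[:, k : k + L, :] @ self.W[k]
        out += self.b
        self._L = L
        if self.stride > 1:
            out = out[:, :: self.stride, :]
        return out

    def backward(self, grad):
        K, L = self.kernel, self._L
        if self.stride > 1:
            full = np.zeros((grad.shape[0], L, grad.shape[2]))
            full[:, :: self.stride, :] = grad
            grad = full
        pad = K // 2
        dxpad = np.zeros_like(self._xpad)
        self.dW[...] = 0.0
        for k in range(K):
            seg = self._xpad[:, k : k + L, :]
            self.dW[k] = np.einsum("nlc,nlo->co", seg, grad)
            dxpad[:, k : k + L, :] += grad @ self.W[k].T
        self.db[...] = grad.sum(axis=(0, 1))
        return dxpad[:, pad : pad + L, :]


class MeanPool1D(Layer):
    """Non-overlapping average pooling along the sequence axis."""

    params: list = []

    def __init__(self, size):
        self.size = size

    def forward(self, x, train=False):
        if self.size == 1:
            return x
        N, L, C = x.shape
        self._L = L
        trim = (L // self.size) * self.size
        self._trim = trim
        return x[:, :trim, :].reshape(N, -1, self.size, C).mean(axis=2)

    def backward(self, grad):
        if self.size == 1:
            return grad
        N, Lp, C = grad.shape
        out = np.zeros((N, self._L, C))
        expanded = np.repeat(grad / self.size, self.size, axis=1)
        out[:, : self._trim, :] = expanded
        return out


class Activation(Layer):
    params: list = []

    def __init__(self, kind):
        if kind not in ("relu", "sigmoid"):
            raise ValueError(f"unknown activation {kind!r}")
        self.kind = kind

    def forward(self, x, train=False):
        if self.kind == "relu":
            self._mask = x > 0
            return x * self._mask
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -50, 50)))
        return self._y

    def backward(self, grad):
        if self.kind == "relu":
            return grad * self._mask
        return grad * self._y * (1.0 - self._y)


class Flatten(Layer):
    params: list = []

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, rng, n_in, n_out):
        self.W = _he_init(rng, (n_in, n_out), n_in)
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.params = [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T


class Dropout(Layer):
    params: list = []

    def __init__(self, rng, rate):
        self.rng, self.rate = rng, rate

    def forward(self, x, train=False):
        if not train or self.rate <= 0:
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        if self.rate <= 0:
            return grad
        return grad * self._mask


class Network:
    def __init__(self, layers):
        self.layers = layers

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    def get_weights(self):
        return [w.copy() for layer in self.layers for (w, _) in layer.params]

    def set_weights(self, weights):
        pairs = [p for layer in self.layers for p in layer.params]
        for (w, _), new in zip(pairs, weights):
            w[...] = new


def softmax(logits, axis=-1):
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_xent(logits, labels):
    """Mean cross-entropy and its gradient w.r.t. logits.

    labels: integer class indices, shape (N,).
    """
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.log(p[np.arange(n), labels] + 1e-12).mean()
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(w) for (w, _) in params]
        self.v = [np.zeros_like(w) for (w, _) in params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, (w, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            w -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
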