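"""Minimal NumPy neural-network layers with manual backpropagation.

Implements exactly the pieces the inverse model needs — 1D convolution and
transposed convolution (stride 1, kernel 3, "same" padding), batch
normalization, ReLU, fully connected layers, mean-squared-error loss, and
the Adam optimizer — in float32, with im2col-based convolutions so the heavy
lifting happens in BLAS matmuls. Parameter initialization follows the
Kaiming-uniform scheme. All randomness flows through an explicit
``numpy.random.Generator`` so training is reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv1d",
    "ConvTranspose1d",
    "BatchNorm1d",
    "ReLU",
    "Flatten",
    "Linear",
    "Sequential",
    "Adam",
    "mse_loss",
]


class Layer:
    params: dict
    grads: dict

    def __init__(self):
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def state(self) -> dict:
        return dict(self.params)

    def load_state(self, state: dict) -> None:
        for k in self.params:
            self.params[k] = np.asarray(state[k], dtype=np.float32)


def _kaiming_uniform(rng, shape, fan_in):
    bound = np.sqrt(1.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, C, L) -> (B, C*k, L) sliding windows with zero 'same' padding."""
    b, c, l = x.shape
    pad = (k - 1) // 2
    xp = np.zeros((b, c, l + 2 * pad), dtype=x.dtype)
    xp[:, :, pad:pad + l] = x
    windows = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)
    # (B, C, L, k) -> (B, C, k, L) -> (B, C*k, L)
    return np.ascontiguousarray(windows.transpose(0, 1, 3, 2)).reshape(b, c * k, l)


def _col2im(cols: np.ndarray, c: int, k: int, l: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`."""
    b = cols.shape[0]
    pad = (k - 1) // 2
    cols = cols.reshape(b, c, k, l)
    xp = np.zeros((b, c, l + 2 * pad), dtype=cols.dtype)
    for j in range(k):
        xp[:, :, j:j + l] += cols[:, :, j, :]
    return xp[:, :, pad:pad + l]


class Conv1d(Layer):
    """1D convolution, stride 1, odd kernel, zero padding preserving length."""

    def __init__(self, in_channels, out_channels, kernel_size, rng):
        super().__init__()
        self.cin, self.cout, self.k = in_channels, out_channels, kernel_size
        fan_in = in_channels * kernel_size
        self.params = {
            "w": _kaiming_uniform(rng, (out_channels, in_channels * kernel_size), fan_in),
            "b": _kaiming_uniform(rng, (out_channels,), fan_in),
        }

    def forward(self, x, training):
        self._cols = _im2col(x, self.k)
        self._l = x.shape[2]
        return self.params["w"] @ self._cols + self.params["b"][:, None]

    def backward(self, grad):
        b, cout, l = grad.shape
        g2 = np.ascontiguousarray(grad.transpose(1, 0, 2)).reshape(cout, b * l)
        c2 = np.ascontiguousarray(self._cols.transpose(1, 0, 2)).reshape(-1, b * l)
        self.grads["w"] = g2 @ c2.T
        self.grads["b"] = grad.sum(axis=(0, 2))
        dcols = self.params["w"].T @ grad
        return _col2im(dcols, self.cin, self.k, self._l)


class ConvTranspose1d(Conv1d):
    """1D transposed convolution, stride 1, kernel 3, padding 1.

    With unit stride and symmetric padding, the transposed convolution is the
    convolution with the kernel flipped along its tap axis; it is stored and
    executed in convolution layout here.
    """


class BatchNorm1d(Layer):
    def __init__(self, channels, momentum=0.1, eps=1e-5):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.params = {
            "gamma": np.ones(channels, dtype=np.float32),
            "beta": np.zeros(channels, dtype=np.float32),
        }
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x, training):
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        self._inv_std = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        self._xhat = (x - mean[:, None]) * self._inv_std[:, None]
        return self.params["gamma"][:, None] * self._xhat + self.params["beta"][:, None]

    def backward(self, grad):
        self.grads["gamma"] = (grad * self._xhat).sum(axis=(0, 2))
        self.grads["beta"] = grad.sum(axis=(0, 2))
        m = grad.shape[0] * grad.shape[2]
        g = grad * self.params["gamma"][:, None]
        dxhat_sum = g.sum(axis=(0, 2))
        dxhat_dot = (g * self._xhat).sum(axis=(0, 2))
        return (self._inv_std[:, None] / m) * (
            m * g
            - dxhat_sum[:, None]
            - self._xhat * dxhat_dot[:, None]
        )

    def state(self):
        return dict(self.params) | {
            "running_mean": self.running_mean,
            "running_var": self.running_var,
        }

    def load_state(self, state):
        super().load_state(state)
        self.running_mean = np.asarray(state["running_mean"], dtype=np.float32)
        self.running_var = np.asarray(state["running_var"], dtype=np.float32)


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Flatten(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Linear(Layer):
    def __init__(self, in_features, out_features, rng):
        super().__init__()
        self.params = {
            "w": _kaiming_uniform(rng, (in_features, out_features), in_features),
            "b": _kaiming_uniform(rng, (out_features,), in_features),
        }

    def forward(self, x, training):
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, grad):
        self.grads["w"] = self._x.T @ grad
        self.grads["b"] = grad.sum(axis=0)
        return grad @ self.params["w"].T


class Sequential:
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def __call__(self, x):
        return self.forward(np.asarray(x, dtype=np.float32), training=False)

    def n_parameters(self) -> int:
        return sum(p.size for layer in self.layers for p in layer.params.values())

    def state(self) -> dict:
        out = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.state().items():
                out[f"layer{i}.{k}"] = v
        return out

    def load_state(self, state: dict) -> None:
        for i, layer in enumerate(self.layers):
            sub = {
                k.split(".", 1)[1]: v
                for k, v in state.items()
                if k.startswith(f"layer{i}.")
            }
            if sub:
                layer.load_state(sub)


class Adam:
    def __init__(self, model: Sequential, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.model = model
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [
            {k: np.zeros_like(v) for k, v in layer.params.items()}
            for layer in model.layers
        ]
        self._v = [
            {k: np.zeros_like(v) for k, v in layer.params.items()}
            for layer in model.layers
        ]

    def step(self):
        self.t += 1
        corr1 = 1.0 - self.b1 ** self.t
        inv_sqrt_corr2 = 1.0 / np.sqrt(1.0 - self.b2 ** self.t)
        lr_t = np.float32(self.lr / corr1)
        for layer, m, v in zip(self.model.layers, self._m, self._v):
            for k, p in layer.params.items():
                g = layer.grads[k]
                m[k] *= self.b1
                m[k] += np.float32(1 - self.b1) * g
                v[k] *= self.b2
                v[k] += np.float32(1 - self.b2) * (g * g)
                denom = np.sqrt(v[k])
                denom *= np.float32(inv_sqrt_corr2)
                denom += np.float32(self.eps)
                np.divide(m[k], denom, out=denom)
                denom *= lr_t
                p -= denom


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient with respect to ``pred``."""
    diff = pred - target
    return float(np.mean(diff**2)), (2.0 / diff.size) * diff
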