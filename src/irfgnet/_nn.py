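"""Minimal NumPy neural-network layers with reverse-mode gradients.

Just enough machinery for the package's 1D CNN: Conv1D (same padding, via
im2col + GEMM), BatchNorm over (batch, length) per channel, ReLU, MaxPool,
Flatten, Dense, inverted Dropout, and an Adam optimizer. float32
throughout; all randomness flows through a caller-supplied Generator, so
runs are bit-reproducible on a fixed seed in single-threaded BLAS.
"""

from __future__ import annotations

import numpy as np

F = np.float32


class Layer:
    train_mode: bool = True

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[tuple[str, np.ndarray, np.ndarray]]:
        """(name, value, gradient) triples; empty for stateless layers."""
        return []

    def state(self) -> dict[str, np.ndarray]:
        """Non-trainable buffers to persist (e.g. batch-norm running stats)."""
        return {}


class Conv1D(Layer):
    """Cross-correlation with 'same' zero padding, odd kernel, stride 1."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd")
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        fan_in = c_in * kernel
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, fan_in)).astype(F)
        self.b = np.zeros(c_out, dtype=F)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, L = x.shape
        p = self.kernel // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        # (n, c, L, k) windows -> (n*L, c*k) columns
        win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=2)
        cols = win.transpose(0, 2, 1, 3).reshape(n * L, c * self.kernel).astype(F, copy=True)
        self._cols, self._shape = cols, (n, c, L)
        out = cols @ self.W.T + self.b
        return out.reshape(n, L, self.c_out).transpose(0, 2, 1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, L = self._shape
        g = grad.transpose(0, 2, 1).reshape(n * L, self.c_out).astype(F)
        self.dW[...] = g.T @ self._cols
        self.db[...] = g.sum(axis=0)
        dcols = (g @ self.W).reshape(n, L, c, self.kernel)
        p = self.kernel // 2
        dxp = np.zeros((n, c, L + 2 * p), dtype=F)
        for k in range(self.kernel):
            dxp[:, :, k : k + L] += dcols[:, :, :, k].transpose(0, 2, 1)
        return dxp[:, :, p : p + L]

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]


class BatchNorm1D(Layer):
    """Per-channel normalization over the batch and length axes."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=F)
        self.beta = np.zeros(c, dtype=F)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=F)
        self.running_var = np.ones(c, dtype=F)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.train_mode:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        self._invstd = (1.0 / np.sqrt(var + self.eps)).astype(F)
        self._xhat = ((x - mean[None, :, None]) * self._invstd[None, :, None]).astype(F)
        return self.gamma[None, :, None] * self._xhat + self.beta[None, :, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, L = grad.shape
        m = n * L
        self.dbeta[...] = grad.sum(axis=(0, 2))
        self.dgamma[...] = (grad * self._xhat).sum(axis=(0, 2))
        if not self.train_mode:
            return grad * (self.gamma * self._invstd)[None, :, None]
        coeff = (self.gamma * self._invstd / m)[None, :, None]
        return coeff * (
            m * grad
            - self.dbeta[None, :, None]
            - self._xhat * self.dgamma[None, :, None]
        )

    def params(self):
        return [("gamma", self.gamma, self.dgamma), ("beta", self.beta, self.dbeta)]

    def state(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, F(0))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, F(0))


class MaxPool1D(Layer):
    def __init__(self, pool: int):
        if pool < 1:
            raise ValueError("pool size must be >= 1")
        self.pool = pool

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, L = x.shape
        if L % self.pool:
            raise ValueError(f"length {L} not divisible by pool {self.pool}")
        xr = x.reshape(n, c, L // self.pool, self.pool)
        self._arg = xr.argmax(axis=3)
        self._shape = x.shape
        return xr.max(axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, L = self._shape
        dx = np.zeros((n, c, L // self.pool, self.pool), dtype=F)
        np.put_along_axis(dx, self._arg[..., None], grad[..., None].astype(F), axis=3)
        return dx.reshape(n, c, L)


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_out, n_in)).astype(F)
        self.b = np.zeros(n_out, dtype=F)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x.astype(F)
        return self._x @ self.W.T + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = grad.astype(F)
        self.dW[...] = g.T @ self._x
        self.db[...] = g.sum(axis=0)
        return g @ self.W

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate, self.rng = rate, rng

    def forward(self, x: np.ndarray) -> np.ndarray:
        if not self.train_mode or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(F) / F(keep)
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self._mask is None else grad * self._mask


class Adam:
    def __init__(self, layers: list[Layer], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.layers, self.lr, self.beta1, self.beta2, self.eps = layers, lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for lay in layers for _, p, _ in lay.params()]
        self.v = [np.zeros_like(p) for lay in layers for _, p, _ in lay.params()]

    def step(self) -> None:
        self.t += 1
        i = 0
        bc1 = 1.0 - self.beta1**self.t
        bc2 = 1.0 - self.beta2**self.t
        for lay in self.layers:
            for _, p, g in lay.params():
                self.m[i] += (1 - self.beta1) * (g - self.m[i])
                self.v[i] += (1 - self.beta2) * (g * g - self.v[i])
                p -= self.lr * (self.m[i] / bc1) / (np.sqrt(self.v[i] / bc2) + self.eps)
                i += 1


def set_train_mode(layers: list[Layer], train: bool) -> None:
    for lay in layers:
        lay.train_mode = train


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out
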