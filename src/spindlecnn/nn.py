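"""Minimal 1-D CNN engine: layers, backprop and AdamW, in pure numpy.

This is a deliberately small, fully deterministic substrate for the spindle
classifier: convolution is lowered to matrix multiplication (im2col), every
layer implements an explicit ``backward``, and the optimizer is AdamW with
decoupled weight decay. Determinism is inherited from numpy — identical
seeds and data give bit-identical parameters, which the transfer-learning
contracts (frozen layers bitwise unchanged) rely on.

Gradient correctness of every layer is validated against central finite
differences in the test suite.

Internally all activations are channels-last, (batch, length, channels), so
the im2col gather is the only data copy per convolution; convert once at the
network boundary. All computation is float32; convolution kernels must have
odd length so "same" padding keeps the temporal grid aligned.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "Conv1d", "BatchNorm1d", "ReLU", "AvgPool1d", "Flatten",
    "Linear", "Network", "softmax", "softmax_cross_entropy", "AdamW",
]

_DT = np.float32


class Layer:
    """Base layer: parameter dict, gradient dict, freeze flag.

    ``frozen`` layers are excluded from optimization; a frozen BatchNorm
    additionally stops updating its running statistics, so a frozen block is
    bitwise inert through any amount of training.
    """

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}
        self.frozen: bool = False

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def state(self) -> dict[str, np.ndarray]:
        return {**self.params, **self.buffers}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = state[k].astype(_DT).copy()
        for k in self.buffers:
            self.buffers[k] = state[k].astype(_DT).copy()


class Conv1d(Layer):
    """Stride-1 "same" convolution; weight (out_ch, in_ch, k), odd k.

    Activations are (batch, length, channels); the convolution is one im2col
    gather plus one sgemm.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd for same padding")
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        fan_in = in_ch * kernel
        # He initialization, appropriate for ReLU nonlinearities
        self.params["weight"] = (
            rng.standard_normal((out_ch, in_ch, kernel)) * np.sqrt(2.0 / fan_in)
        ).astype(_DT)
        self.params["bias"] = np.zeros(out_ch, dtype=_DT)

    def _w2(self) -> np.ndarray:
        # (out, in, k) -> (in*k? no: (k, in) flat) matching im2col (c, k) order
        return self.params["weight"].transpose(1, 2, 0).reshape(
            self.in_ch * self.kernel, self.out_ch
        )

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, length, c = x.shape
        k, p = self.kernel, self.kernel // 2
        xp = np.pad(x, ((0, 0), (p, p), (0, 0)))
        view = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)
        # view is (n, L, c, k); flattening (c, k) matches the weight layout
        cols = view.reshape(n * length, c * k)
        y = cols @ self._w2() + self.params["bias"]
        self._cache = (cols, x.shape)
        return y.reshape(n, length, self.out_ch)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, (n, length, c) = self._cache
        k, p = self.kernel, self.kernel // 2
        dy_flat = dy.reshape(n * length, self.out_ch)
        dw2 = cols.T @ dy_flat  # (c*k, out)
        self.grads["weight"] = np.ascontiguousarray(
            dw2.reshape(c, k, self.out_ch).transpose(2, 0, 1)
        )
        self.grads["bias"] = dy_flat.sum(axis=0)
        # dx: correlate dy with the flipped kernel (transposed convolution)
        dyp = np.pad(dy, ((0, 0), (k - 1, k - 1), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(dyp, k, axis=1)
        win = win[:, p : p + length]  # (n, L, out, k) on the input grid
        wflip = self.params["weight"][:, :, ::-1]  # (out, in, k)
        m = np.ascontiguousarray(wflip.transpose(0, 2, 1)).reshape(
            self.out_ch * k, c
        )
        dx = win.reshape(n * length, self.out_ch * k) @ m
        return dx.reshape(n, length, c)


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (batch, length).

    Training uses batch statistics and maintains exponential running
    estimates (momentum 0.1, unbiased variance); evaluation — and any frozen
    layer — normalizes with the running statistics.
    """

    def __init__(self, n_ch: int, eps: float = 1e-5, momentum: float = 0.1) -> None:
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params["gamma"] = np.ones(n_ch, dtype=_DT)
        self.params["beta"] = np.zeros(n_ch, dtype=_DT)
        self.buffers["running_mean"] = np.zeros(n_ch, dtype=_DT)
        self.buffers["running_var"] = np.ones(n_ch, dtype=_DT)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        use_batch = training and not self.frozen
        if use_batch:
            mu = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            m = x.shape[0] * x.shape[1]
            unbiased = var * m / max(m - 1, 1)
            self.buffers["running_mean"] = (
                (1 - self.momentum) * self.buffers["running_mean"]
                + self.momentum * mu
            ).astype(_DT)
            self.buffers["running_var"] = (
                (1 - self.momentum) * self.buffers["running_var"]
                + self.momentum * unbiased
            ).astype(_DT)
        else:
            mu = self.buffers["running_mean"]
            var = self.buffers["running_var"]
        ivar = (1.0 / np.sqrt(var + self.eps)).astype(_DT)
        xhat = (x - mu) * ivar
        self._cache = (xhat, ivar, use_batch)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, ivar, used_batch = self._cache
        self.grads["gamma"] = (dy * xhat).sum(axis=(0, 1))
        self.grads["beta"] = dy.sum(axis=(0, 1))
        g = self.params["gamma"]
        if not used_batch:
            return dy * (g * ivar)
        m = dy.shape[0] * dy.shape[1]
        dxhat = dy * g
        s1 = dxhat.sum(axis=(0, 1))
        s2 = (dxhat * xhat).sum(axis=(0, 1))
        return (ivar / m) * (m * dxhat - s1 - xhat * s2)


class ReLU(Layer):
    """max(x, 0): negatives are zeroed, positives pass unchanged."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, np.float32(0))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class AvgPool1d(Layer):
    """Average pooling along time, size = stride = 2; length must be even."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, length, c = x.shape
        if length % 2:
            raise ValueError(f"AvgPool1d(2) needs even length, got {length}")
        return x.reshape(n, length // 2, 2, c).mean(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.repeat(dy / 2.0, 2, axis=1)


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Linear(Layer):
    """Affine map; weight (out, in), He-initialized."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params["weight"] = (
            rng.standard_normal((n_out, n_in)) * np.sqrt(2.0 / n_in)
        ).astype(_DT)
        self.params["bias"] = np.zeros(n_out, dtype=_DT)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return x @ self.params["weight"].T + self.params["bias"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["weight"] = dy.T @ self._x
        self.grads["bias"] = dy.sum(axis=0)
        return dy @ self.params["weight"]


class Network:
    """Ordered sequence of named layers with joint forward/backward.

    ``forward`` takes (batch, in_channels, length) — the public convention —
    and converts once to the internal channels-last layout.
    """

    def __init__(self, layers: list[tuple[str, Layer]]) -> None:
        self.layers = layers

    def __iter__(self):
        return iter(self.layers)

    def __getitem__(self, name: str) -> Layer:
        for n, layer in self.layers:
            if n == name:
                return layer
        raise KeyError(name)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = np.ascontiguousarray(
            np.asarray(x, dtype=_DT).transpose(0, 2, 1)
        )
        for _, layer in self.layers:
            out = layer.forward(out, training)
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray | None:
        """Backpropagate; returns the input gradient in the public layout.

        Gradients are not propagated below the earliest layer with trainable
        parameters (pure speed optimization: those gradients would be
        discarded); in that case None is returned.
        """
        trainable_idx = [
            i for i, (_, layer) in enumerate(self.layers)
            if layer.params and not layer.frozen
        ]
        stop = min(trainable_idx) if trainable_idx else 0
        for i in range(len(self.layers) - 1, stop - 1, -1):
            dy = self.layers[i][1].backward(dy)
        if stop > 0:
            return None
        # back to the public (batch, channels, length) convention
        return dy.transpose(0, 2, 1)

    def state(self) -> dict[str, np.ndarray]:
        """Flat ``layer.param`` → array mapping (parameters + buffers)."""
        out = {}
        for name, layer in self.layers:
            for k, v in layer.state().items():
                out[f"{name}.{k}"] = v
        return out

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for name, layer in self.layers:
            sub = {
                k.split(".", 1)[1]: v
                for k, v in state.items()
                if k.startswith(name + ".")
            }
            layer.load_state(sub)

    def trainable_params(self):
        """Yields (qualified name, layer, param key) for unfrozen layers."""
        for name, layer in self.layers:
            if layer.frozen:
                continue
            for k in layer.params:
                yield f"{name}.{k}", layer, k


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. logits."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = -np.mean(np.log(p[np.arange(n), labels] + 1e-12))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(_DT)


class AdamW:
    """Adam with decoupled weight decay.

    Weight decay is applied multiplicatively to matrix/tensor weights only;
    biases and normalization parameters are exempt, the common convention.
    """

    def __init__(self, network: Network, lr: float, weight_decay: float = 0.01,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        self.network = network
        self.lr = lr
        self.weight_decay = weight_decay
        self.betas = betas
        self.eps = eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for qname, layer, key in self.network.trainable_params():
            g = layer.grads[key].astype(np.float64)
            p = layer.params[key].astype(np.float64)
            m = self.m.setdefault(qname, np.zeros_like(p))
            v = self.v.setdefault(qname, np.zeros_like(p))
            m[:] = b1 * m + (1 - b1) * g
            v[:] = b2 * v + (1 - b2) * g * g
            if self.weight_decay and p.ndim > 1:
                p -= self.lr * self.weight_decay * p
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            layer.params[key] = p.astype(_DT)
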