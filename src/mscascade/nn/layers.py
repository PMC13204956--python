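"""Minimal NumPy neural-network layers with hand-written backpropagation.

Only what the normalizer-free 1D classifier needs: 1D convolution,
ReLU, max-pooling, batch normalization (for the ablation variant only),
dropout, multi-head self-attention, global average pooling and a linear
head.  Layers cache what their backward pass needs during forward; a
full forward must precede each backward.  All arithmetic is float32.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv1d",
    "ReLU",
    "MaxPool1d",
    "BatchNorm1d",
    "Dropout",
    "GlobalAvgPool",
    "Linear",
    "MHSA",
    "Sequential",
]

F32 = np.float32


class Param:
    """A learnable tensor and its gradient accumulator."""

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.ascontiguousarray(value, dtype=F32)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1d(Layer):
    """1D convolution with 'same'-style zero padding (pad = kernel // 2)."""

    def __init__(self, cin: int, cout: int, kernel: int, stride: int = 1, rng: np.random.Generator | None = None, name: str = "conv") -> None:
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (cin * kernel))
        self.w = Param(rng.normal(0.0, std, size=(cout, cin, kernel)), f"{name}.w")
        self.b = Param(np.zeros(cout), f"{name}.b")
        self.stride = stride
        self.pad = kernel // 2
        self.kernel = kernel

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = x.astype(F32, copy=False)
        b, c, l = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        windows = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=2)
        cols = windows[:, :, :: self.stride, :]  # (B, Cin, Lout, K)
        self._cols = cols
        self._in_len = l
        y = np.einsum("bclk,ock->bol", cols, self.w.value, optimize=True)
        return y + self.b.value[None, :, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = grad.astype(F32, copy=False)
        self.w.grad += np.einsum("bol,bclk->ock", grad, self._cols, optimize=True)
        self.b.grad += grad.sum(axis=(0, 2))
        dcols = np.einsum("bol,ock->bclk", grad, self.w.value, optimize=True)
        b, cin, lout, k = dcols.shape
        dxp = np.zeros((b, cin, self._in_len + 2 * self.pad), dtype=F32)
        s = self.stride
        for j in range(k):
            dxp[:, :, j : j + lout * s : s] += dcols[:, :, :, j]
        return dxp[:, :, self.pad : self.pad + self._in_len]

    def out_len(self, l: int) -> int:
        return (l + 2 * self.pad - self.kernel) // self.stride + 1


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, 0.0)


class MaxPool1d(Layer):
    """Non-overlapping max pooling (kernel = stride); trailing samples dropped."""

    def __init__(self, stride: int = 4) -> None:
        self.stride = stride

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        b, c, l = x.shape
        lo = l // self.stride
        xr = x[:, :, : lo * self.stride].reshape(b, c, lo, self.stride)
        self._arg = xr.argmax(axis=3)
        self._shape = (b, c, l, lo)
        return xr.max(axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b, c, l, lo = self._shape
        dxr = np.zeros((b, c, lo, self.stride), dtype=F32)
        np.put_along_axis(dxr, self._arg[..., None], grad[..., None].astype(F32), axis=3)
        dx = np.zeros((b, c, l), dtype=F32)
        dx[:, :, : lo * self.stride] = dxr.reshape(b, c, lo * self.stride)
        return dx


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (batch, time).

    Used only by the conv–BN ablation variant; the proposed model is
    normalizer-free by construction.  Training mode uses batch statistics
    and updates running estimates; eval mode uses the running estimates —
    the train/inference mismatch this introduces under distribution shift
    is exactly what the normalizer-free design avoids.
    """

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5, name: str = "bn") -> None:
        self.gamma = Param(np.ones(c), f"{name}.gamma")
        self.beta = Param(np.zeros(c), f"{name}.beta")
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)
        self.momentum = momentum
        self.eps = eps

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean.astype(F32)
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var.astype(F32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv[None, :, None]
        self._xhat, self._inv, self._training = xhat, inv, training
        self._n = x.shape[0] * x.shape[2]
        return self.gamma.value[None, :, None] * xhat + self.beta.value[None, :, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.gamma.grad += (grad * self._xhat).sum(axis=(0, 2))
        self.beta.grad += grad.sum(axis=(0, 2))
        gxh = grad * self.gamma.value[None, :, None]
        if not self._training:
            return gxh * self._inv[None, :, None]
        n = self._n
        sum_g = gxh.sum(axis=(0, 2), keepdims=True)
        sum_gx = (gxh * self._xhat).sum(axis=(0, 2), keepdims=True)
        return (self._inv[None, :, None] / n) * (n * gxh - sum_g - self._xhat * sum_gx)


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator) -> None:
        self.p = p
        self.rng = rng

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(F32) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self._mask is None else grad * self._mask


class GlobalAvgPool(Layer):
    """(B, C, T) -> (B, C) mean over time."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._t = x.shape[2]
        return x.mean(axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.repeat(grad[:, :, None], self._t, axis=2) / self._t


class Linear(Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None, name: str = "linear") -> None:
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / cin)
        self.w = Param(rng.normal(0.0, std, size=(cout, cin)), f"{name}.w")
        self.b = Param(np.zeros(cout), f"{name}.b")

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x.astype(F32, copy=False)
        return self._x @ self.w.value.T + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = grad.astype(F32, copy=False)
        self.w.grad += grad.T @ self._x
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value


class MHSA(Layer):
    """Multi-head self-attention over the temporal axis of (B, C, T).

    Channels are projected tokenwise to the embedding dimension; no
    positional encoding is used (microstate trajectories carry their own
    slow temporal structure, and the downstream head is permutation-
    sensitive only through the convolutional features).  The head-averaged
    attention matrix of the last forward pass is kept for interpretability.
    """

    def __init__(self, cin: int, embed: int, heads: int, rng: np.random.Generator | None = None, name: str = "mhsa") -> None:
        if embed % heads:
            raise ValueError("embedding dimension must be divisible by the head count")
        rng = rng or np.random.default_rng(0)
        self.heads, self.embed, self.dh = heads, embed, embed // heads
        std_in = np.sqrt(2.0 / cin)
        std_e = np.sqrt(1.0 / embed)
        self.win = Param(rng.normal(0, std_in, (embed, cin)), f"{name}.win")
        self.bin = Param(np.zeros(embed), f"{name}.bin")
        self.wq = Param(rng.normal(0, std_e, (embed, embed)), f"{name}.wq")
        self.wk = Param(rng.normal(0, std_e, (embed, embed)), f"{name}.wk")
        self.wv = Param(rng.normal(0, std_e, (embed, embed)), f"{name}.wv")
        self.wo = Param(rng.normal(0, std_e, (embed, embed)), f"{name}.wo")
        self.bq = Param(np.zeros(embed), f"{name}.bq")
        self.bk = Param(np.zeros(embed), f"{name}.bk")
        self.bv = Param(np.zeros(embed), f"{name}.bv")
        self.bo = Param(np.zeros(embed), f"{name}.bo")
        self.last_attention: np.ndarray | None = None  # (B, H, T, T)

    def params(self) -> list[Param]:
        return [self.win, self.bin, self.wq, self.wk, self.wv, self.wo,
                self.bq, self.bk, self.bv, self.bo]

    def _split(self, x: np.ndarray) -> np.ndarray:
        b, t, _ = x.shape
        return x.reshape(b, t, self.heads, self.dh).transpose(0, 2, 1, 3)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._xt = x.transpose(0, 2, 1).astype(F32, copy=False)  # (B, T, C)
        xe = self._xt @ self.win.value.T + self.bin.value  # (B, T, E)
        self._xe = xe
        q = self._split(xe @ self.wq.value.T + self.bq.value)
        k = self._split(xe @ self.wk.value.T + self.bk.value)
        v = self._split(xe @ self.wv.value.T + self.bv.value)
        scale = 1.0 / np.sqrt(self.dh)
        s = (q @ k.transpose(0, 1, 3, 2)) * scale
        s -= s.max(axis=-1, keepdims=True)
        e = np.exp(s)
        a = e / e.sum(axis=-1, keepdims=True)
        o = a @ v
        b_, h, t, dh = o.shape
        oc = o.transpose(0, 2, 1, 3).reshape(b_, t, self.embed)
        y = oc @ self.wo.value.T + self.bo.value
        self._cache = (q, k, v, a, oc, scale)
        self.last_attention = a
        return y.transpose(0, 2, 1)  # (B, E, T)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        q, k, v, a, oc, scale = self._cache
        gy = grad.transpose(0, 2, 1).astype(F32, copy=False)  # (B, T, E)
        self.wo.grad += np.einsum("bte,btf->ef", gy, oc, optimize=True)
        self.bo.grad += gy.sum(axis=(0, 1))
        doc = gy @ self.wo.value  # (B, T, E)
        do = self._split(doc)  # (B, H, T, dh)
        da = do @ v.transpose(0, 1, 3, 2)
        dv = a.transpose(0, 1, 3, 2) @ do
        ds = a * (da - (da * a).sum(axis=-1, keepdims=True))
        dq = (ds @ k) * scale
        dk = (ds.transpose(0, 1, 3, 2) @ q) * scale

        def merge(z: np.ndarray) -> np.ndarray:
            b_, h, t, dh = z.shape
            return z.transpose(0, 2, 1, 3).reshape(b_, t, self.embed)

        dq, dk, dv = merge(dq), merge(dk), merge(dv)
        xe = self._xe
        dxe = np.zeros_like(xe)
        for d, w, bp in ((dq, self.wq, self.bq), (dk, self.wk, self.bk), (dv, self.wv, self.bv)):
            w.grad += np.einsum("bte,btf->ef", d, xe, optimize=True)
            bp.grad += d.sum(axis=(0, 1))
            dxe += d @ w.value
        self.win.grad += np.einsum("bte,btc->ec", dxe, self._xt, optimize=True)
        self.bin.grad += dxe.sum(axis=(0, 1))
        dxt = dxe @ self.win.value
        return dxt.transpose(0, 2, 1)

    def pooled_attention(self) -> np.ndarray:
        """Head- and query-averaged attention, one distribution per sample."""
        if self.last_attention is None:
            raise RuntimeError("no forward pass recorded")
        return self.last_attention.mean(axis=(1, 2))


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad
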