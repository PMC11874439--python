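"""Minimal 3D convolutional network primitives in NumPy.

Layers operate on (batch, channels, D, H, W) tensors, cache what backward
needs, and accumulate parameter gradients in-place. Convolutions are 3x3x3,
stride 1, same padding, implemented by im2col; pooling is 2x max. This is
deliberately small: the scorers built on top use desk-scale widths and grids,
where explicit NumPy matmuls are fast enough on one CPU core.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(value, gradient) pairs; gradients are zeroed by the optimizer."""
        return []


class Conv3d(Layer):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, k: int = 3):
        self.k = k
        self.c_in = c_in
        self.c_out = c_out
        fan_in = c_in * k**3
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, fan_in))
        self.b = np.zeros(c_out)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._shape: tuple | None = None

    def forward(self, x):
        k, p = self.k, self.k // 2
        bsz, c, d, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
        cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(
            bsz, d * h * w, c * k**3
        )
        self._cols = cols
        self._shape = (bsz, c, d, h, w)
        out = cols @ self.w.T + self.b
        return out.reshape(bsz, d, h, w, self.c_out).transpose(0, 4, 1, 2, 3)

    def backward(self, gout):
        k, p = self.k, self.k // 2
        bsz, c, d, h, w = self._shape
        g = gout.transpose(0, 2, 3, 4, 1).reshape(bsz, d * h * w, self.c_out)
        self.gw += np.einsum("bno,bnk->ok", g, self._cols)
        self.gb += g.sum(axis=(0, 1))
        gcols = (g @ self.w).reshape(bsz, d, h, w, c, k, k, k)
        gcols = gcols.transpose(0, 4, 1, 2, 3, 5, 6, 7)
        gx = np.zeros((bsz, c, d + 2 * p, h + 2 * p, w + 2 * p))
        for a in range(k):
            for bb in range(k):
                for cc in range(k):
                    gx[:, :, a : a + d, bb : bb + h, cc : cc + w] += gcols[
                        ..., a, bb, cc
                    ]
        self._cols = None
        return gx[:, :, p : p + d, p : p + h, p : p + w]

    def parameters(self):
        return [(self.w, self.gw), (self.b, self.gb)]


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gout):
        return gout * self._mask


class MaxPool3d(Layer):
    """2x2x2 max pooling, stride 2 (odd trailing voxels are dropped)."""

    def forward(self, x):
        bsz, c, d, h, w = x.shape
        d2, h2, w2 = d // 2, h // 2, w // 2
        xt = x[:, :, : 2 * d2, : 2 * h2, : 2 * w2]
        r = xt.reshape(bsz, c, d2, 2, h2, 2, w2, 2)
        out = r.max(axis=(3, 5, 7))
        self._x = xt
        self._out = out
        self._orig_shape = x.shape
        return out

    def backward(self, gout):
        bsz, c, d, h, w = self._x.shape
        d2, h2, w2 = d // 2, h // 2, w // 2
        up = np.repeat(
            np.repeat(np.repeat(self._out, 2, axis=2), 2, axis=3), 2, axis=4
        )
        gup = np.repeat(
            np.repeat(np.repeat(gout, 2, axis=2), 2, axis=3), 2, axis=4
        )
        mask = self._x == up
        # split gradient between tied maxima to keep the total flow exact
        counts = (
            mask.reshape(bsz, c, d2, 2, h2, 2, w2, 2)
            .sum(axis=(3, 5, 7), keepdims=True)
            .reshape(bsz, c, d2, 1, h2, 1, w2, 1)
        )
        counts = np.repeat(
            np.repeat(np.repeat(counts, 2, axis=3), 2, axis=5), 2, axis=7
        ).reshape(self._x.shape)
        gx_part = gup * mask / counts
        gx = np.zeros(self._orig_shape)
        gx[:, :, :d, :h, :w] = gx_part
        return gx


class GlobalAvgPool(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, gout):
        bsz, c, d, h, w = self._shape
        return np.broadcast_to(
            gout[:, :, None, None, None], self._shape
        ) / float(d * h * w)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_out, n_in))
        self.b = np.zeros(n_out)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def forward(self, x):
        self._x = x
        return x @ self.w.T + self.b

    def backward(self, gout):
        self.gw += gout.T @ self._x
        self.gb += gout.sum(axis=0)
        return gout @ self.w

    def parameters(self):
        return [(self.w, self.gw), (self.b, self.gb)]


class DenseBlock(Layer):
    """Densely connected convolutions: conv i sees the concatenation of the
    block input and all previous conv outputs; the block emits the full
    concatenation."""

    def __init__(
        self, c_in: int, growth: int, n_convs: int, rng: np.random.Generator
    ):
        self.convs: list[Conv3d] = []
        self.relus: list[ReLU] = []
        c = c_in
        for _ in range(n_convs):
            self.convs.append(Conv3d(c, growth, rng))
            self.relus.append(ReLU())
            c += growth
        self.c_out = c

    def forward(self, x):
        feats = [x]
        for conv, relu in zip(self.convs, self.relus):
            inp = np.concatenate(feats, axis=1)
            feats.append(relu.forward(conv.forward(inp)))
        self._channel_sizes = [f.shape[1] for f in feats]
        return np.concatenate(feats, axis=1)

    def backward(self, gout):
        sizes = self._channel_sizes
        splits = np.cumsum(sizes)[:-1]
        gfeats = list(np.split(gout, splits, axis=1))
        for i in reversed(range(len(self.convs))):
            g = self.relus[i].backward(gfeats[i + 1])
            gin = self.convs[i].backward(g)  # grad w.r.t. concat(feats[:i+1])
            in_splits = np.cumsum(sizes[: i + 1])[:-1]
            for k, piece in enumerate(np.split(gin, in_splits, axis=1)):
                gfeats[k] = gfeats[k] + piece
        return gfeats[0]

    def parameters(self):
        return [p for conv in self.convs for p in conv.parameters()]


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, gout):
        for layer in reversed(self.layers):
            gout = layer.backward(gout)
        return gout

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]


class SGD:
    """SGD with momentum and global gradient-norm clipping (an oversized early
    step can silence every ReLU in a small network; clipping prevents it)."""

    def __init__(self, params, lr: float = 0.01, momentum: float = 0.9,
                 clip_norm: float = 5.0):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.clip_norm = clip_norm
        self.velocity = [np.zeros_like(w) for w, _ in params]

    def step(self):
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g**2).sum()) for _, g in self.params))
            if total > self.clip_norm:
                scale = self.clip_norm / total
                for _, g in self.params:
                    g *= scale
        for (w, g), v in zip(self.params, self.velocity):
            v *= self.momentum
            v -= self.lr * g
            w += v
            g[...] = 0.0

    def zero_grad(self):
        for _, g in self.params:
            g[...] = 0.0


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=axis, keepdims=True))


ROT90_OPS = [
    (k, axes)
    for axes in ((0, 1), (0, 2), (1, 2))
    for k in range(4)
]


def random_grid_rotation(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One of the 24 proper cube rotations applied to the spatial axes of a
    (channels, D, H, W) grid (composed from two random axis rotations)."""
    out = values
    for _ in range(2):
        k, axes = ROT90_OPS[int(rng.integers(len(ROT90_OPS)))]
        out = np.rot90(out, k=k, axes=(axes[0] + 1, axes[1] + 1))
    return np.ascontiguousarray(out)
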