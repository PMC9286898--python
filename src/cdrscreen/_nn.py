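"""A small, deterministic CNN stack on numpy.

Implements exactly the pieces the image classifier needs: 2-D convolution
(im2col), ReLU, max pooling, channel-concatenated parallel branches for
inception blocks, global average pooling, dense layers, softmax
cross-entropy, and SGD with momentum.  Everything is float32 and driven by an
explicit :class:`numpy.random.Generator`, so training runs are bit-reproducible
for a fixed seed and thread-free by construction.

This is deliberately minimal: no autograd graph, just forward/backward pairs
per layer, which keeps desk-scale training (thousands of ~64x32 grayscale
images) fast on one CPU.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Layer:
    """Base layer: forward caches what backward needs; params/grads in lists."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def walk(self):
        yield self


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Conv2D(Layer):
    """Same/valid 2-D convolution via im2col; stride >= 1, He-initialized."""

    def __init__(self, cin: int, cout: int, ksize: int, rng: np.random.Generator,
                 stride: int = 1, pad: int | None = None):
        super().__init__()
        self.cin, self.cout, self.k, self.stride = cin, cout, ksize, stride
        self.pad = (ksize - 1) // 2 if pad is None else pad
        fan_in = cin * ksize * ksize
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, cout))
        self.w = w.astype(F32)
        self.b = np.zeros(cout, dtype=F32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def _cols(self, x: np.ndarray) -> tuple[np.ndarray, tuple[int, ...]]:
        n, c, h, w = x.shape
        p, k, s = self.pad, self.k, self.stride
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        if ho < 1 or wo < 1:
            raise ValueError(
                f"input {h}x{w} too small for conv k={k}, stride={s}, pad={p}; "
                f"minimum input is {k - 2 * p}x{k - 2 * p}"
            )
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]  # (n, c, ho, wo, k, k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
        return np.ascontiguousarray(cols, dtype=F32), (n, c, h, w, ho, wo)

    def forward(self, x):
        cols, shape = self._cols(x)
        self._cols_cache, self._shape = cols, shape
        n, _, _, _, ho, wo = shape
        out = cols @ self.w + self.b
        return out.reshape(n, ho, wo, self.cout).transpose(0, 3, 1, 2)

    def backward(self, grad):
        n, c, h, w, ho, wo = self._shape
        go = grad.transpose(0, 2, 3, 1).reshape(n * ho * wo, self.cout)
        go = np.ascontiguousarray(go, dtype=F32)
        self.grads[0][...] = self._cols_cache.T @ go
        self.grads[1][...] = go.sum(axis=0)
        dcols = go @ self.w.T  # (n*ho*wo, c*k*k)
        dcols = dcols.reshape(n, ho, wo, c, self.k, self.k)
        p, s = self.pad, self.stride
        gxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=F32)
        for i in range(self.k):
            for j in range(self.k):
                gxp[:, :, i:i + ho * s:s, j:j + wo * s:s] += dcols[
                    :, :, :, :, i, j
                ].transpose(0, 3, 1, 2)
        return gxp[:, :, p:p + h, p:p + w]


class MaxPool2D(Layer):
    """Max pooling with arbitrary kernel/stride/pad (pad uses -inf)."""

    def __init__(self, ksize: int = 2, stride: int | None = None, pad: int = 0):
        super().__init__()
        self.k = ksize
        self.stride = stride if stride is not None else ksize
        self.pad = pad

    def forward(self, x):
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        self._fast = s == k and p == 0
        if self._fast:
            ho, wo = h // k, w // k
            if ho < 1 or wo < 1:
                raise ValueError(
                    f"input {h}x{w} too small for pool k={k}, stride={s}"
                )
            win = (
                x[:, :, :ho * k, :wo * k]
                .reshape(n, c, ho, k, wo, k)
                .transpose(0, 1, 2, 4, 3, 5)
                .reshape(n, c, ho, wo, k * k)
            )
            idx = win.argmax(axis=-1)
            out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
            self._cache = (idx, (n, c, h, w, h, w, ho, wo))
            return np.ascontiguousarray(out, dtype=F32)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)),
                    constant_values=-np.inf) if p else x
        hp, wp = h + 2 * p, w + 2 * p
        ho = (hp - k) // s + 1
        wo = (wp - k) // s + 1
        if ho < 1 or wo < 1:
            raise ValueError(
                f"input {h}x{w} too small for pool k={k}, stride={s}, pad={p}"
            )
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s].reshape(n, c, ho, wo, k * k)
        idx = win.argmax(axis=-1)
        out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, (n, c, h, w, hp, wp, ho, wo))
        return np.ascontiguousarray(out, dtype=F32)

    def backward(self, grad):
        idx, (n, c, h, w, hp, wp, ho, wo) = self._cache
        k, s, p = self.k, self.stride, self.pad
        if self._fast:
            # non-overlapping windows: scatter into the window axis directly
            gwin = np.zeros((n, c, ho, wo, k * k), dtype=F32)
            np.put_along_axis(gwin, idx[..., None], grad[..., None], axis=-1)
            gx = np.zeros((n, c, h, w), dtype=F32)
            gx[:, :, :ho * k, :wo * k] = (
                gwin.reshape(n, c, ho, wo, k, k)
                .transpose(0, 1, 2, 4, 3, 5)
                .reshape(n, c, ho * k, wo * k)
            )
            return gx
        di, dj = idx // k, idx % k
        oi = np.arange(ho)[None, None, :, None] * s
        oj = np.arange(wo)[None, None, None, :] * s
        rows = (oi + di).ravel()
        cols = (oj + dj).ravel()
        nn = np.repeat(np.arange(n), c * ho * wo)
        cc = np.tile(np.repeat(np.arange(c), ho * wo), n)
        lin = ((nn * c + cc) * hp + rows) * wp + cols
        flat = np.bincount(lin, weights=grad.ravel().astype(np.float64),
                           minlength=n * c * hp * wp)
        gxp = flat.reshape(n, c, hp, wp).astype(F32)
        return gxp[:, :, p:p + h, p:p + w] if p else gxp


class GlobalAvgPool(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        n, c, h, w = self._shape
        return np.broadcast_to(
            grad[:, :, None, None] / (h * w), self._shape
        ).astype(F32)


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, din: int, dout: int, rng: np.random.Generator):
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / din), size=(din, dout))
        self.w = w.astype(F32)
        self.b = np.zeros(dout, dtype=F32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x):
        self._x = np.ascontiguousarray(x, dtype=F32)
        return self._x @ self.w + self.b

    def backward(self, grad):
        grad = np.ascontiguousarray(grad, dtype=F32)
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.w.T


class Branches(Layer):
    """Parallel layer chains whose channel outputs are concatenated (inception)."""

    def __init__(self, branches: list[list[Layer]]):
        super().__init__()
        self.branches = branches

    def walk(self):
        yield self
        for branch in self.branches:
            for layer in branch:
                yield from layer.walk()

    def forward(self, x):
        outs = []
        for branch in self.branches:
            h = x
            for layer in branch:
                h = layer.forward(h)
            outs.append(h)
        self._widths = [o.shape[1] for o in outs]
        return np.concatenate(outs, axis=1)

    def backward(self, grad):
        gx = None
        start = 0
        for branch, width in zip(self.branches, self._widths):
            g = grad[:, start:start + width]
            start += width
            for layer in reversed(branch):
                g = layer.backward(g)
            gx = g if gx is None else gx + g
        return gx


class Network:
    """An ordered stack of layers ending in a 2-class logit head."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = np.ascontiguousarray(x, dtype=F32)
        for layer in self.layers:
            h = layer.forward(h)
        return h

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def all_layers(self):
        for layer in self.layers:
            yield from layer.walk()

    def parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        out = []
        for layer in self.all_layers():
            out.extend(zip(layer.params, layer.grads))
        return out

    def n_parameters(self) -> int:
        return sum(p.size for p, _ in self.parameters())

    def state_arrays(self) -> list[np.ndarray]:
        return [p for p, _ in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.state_arrays()
        if len(arrays) != len(params):
            raise ValueError(
                f"checkpoint has {len(arrays)} arrays, network needs {len(params)}"
            )
        for p, a in zip(params, arrays):
            if p.shape != a.shape:
                raise ValueError(f"shape mismatch: {p.shape} vs {a.shape}")
            p[...] = a.astype(F32)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean 2-class cross-entropy and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    probs = softmax(logits.astype(np.float64))
    eps = 1e-12
    loss = -np.log(probs[np.arange(n), y] + eps).mean()
    grad = probs
    grad[np.arange(n), y] -= 1.0
    return float(loss), (grad / n).astype(F32)


class SGDMomentum:
    """Classical momentum: v <- m v - lr g; p <- p + v."""

    def __init__(self, net: Network, lr: float, momentum: float = 0.9):
        self.lr = lr
        self.momentum = momentum
        self.pairs = net.parameters()
        self.velocity = [np.zeros_like(p) for p, _ in self.pairs]

    def step(self) -> None:
        for (p, g), v in zip(self.pairs, self.velocity):
            v *= self.momentum
            v -= self.lr * g
            p += v
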