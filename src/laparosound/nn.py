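"""Compact convolutional network and optimizers, implemented on numpy.

The classifier backbone is deliberately small and dependency-free: three
3x3 stride-2 convolution blocks with ReLU, mean-pooling over the time axis
(the mel axis is kept, since band position carries the class signal),
and a linear softmax head — about 10k parameters for 96x64 log-mel input.
Adam and RMSprop are provided, with deterministic behavior for a fixed
seed: initialization and minibatch shuffling are the only stochastic parts
and both draw from one generator.
"""

from __future__ import annotations

import numpy as np


class Conv2d:
    """3x3 convolution with stride and zero padding.

    Patch extraction and gradient scatter are done with nine strided slices
    (one per kernel offset) so both directions reduce to BLAS tensordots.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 k: int = 3, stride: int = 2, pad: int = 1):
        scale = np.sqrt(2.0 / (c_in * k * k))  # He initialization
        self.w = (rng.standard_normal((c_out, c_in, k, k)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k, self.stride, self.pad = k, stride, pad
        self.c_in, self.c_out = c_in, c_out

    def _out_hw(self, h: int, w: int) -> tuple[int, int]:
        return ((h + 2 * self.pad - self.k) // self.stride + 1,
                (w + 2 * self.pad - self.k) // self.stride + 1)

    def _patches(self, xp: np.ndarray, oh: int, ow: int) -> np.ndarray:
        b, c = xp.shape[:2]
        s = self.stride
        out = np.empty((b, c, self.k, self.k, oh, ow), dtype=xp.dtype)
        for kh in range(self.k):
            for kw in range(self.k):
                out[:, :, kh, kw] = xp[:, :, kh:kh + s * (oh - 1) + 1:s,
                                       kw:kw + s * (ow - 1) + 1:s]
        return out

    def forward(self, x: np.ndarray):
        b, _, h, w = x.shape
        oh, ow = self._out_hw(h, w)
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)))
        patches = self._patches(xp, oh, ow)          # (B, C, k, k, OH, OW)
        out = np.tensordot(patches, self.w, axes=([1, 2, 3], [1, 2, 3]))
        out = np.moveaxis(out, 3, 1) + self.b[None, :, None, None]
        return np.ascontiguousarray(out), (patches, x.shape)

    def backward(self, dout: np.ndarray, cache):
        patches, x_shape = cache
        b, _, h, w = x_shape
        oh, ow = dout.shape[2], dout.shape[3]
        s = self.stride
        self.dw = np.tensordot(dout, patches, axes=([0, 2, 3], [0, 4, 5]))
        self.db = dout.sum(axis=(0, 2, 3))
        # (B, OH, OW, C, k, k) gradient of every extracted patch
        dpatch = np.tensordot(dout, self.w, axes=([1], [0]))
        dxp = np.zeros((b, self.c_in, h + 2 * self.pad, w + 2 * self.pad),
                       dtype=dout.dtype)
        for kh in range(self.k):
            for kw in range(self.k):
                dxp[:, :, kh:kh + s * (oh - 1) + 1:s,
                    kw:kw + s * (ow - 1) + 1:s] += np.moveaxis(
                        dpatch[:, :, :, :, kh, kw], 3, 1)
        if self.pad:
            return dxp[:, :, self.pad:-self.pad, self.pad:-self.pad]
        return dxp

    @property
    def params(self):
        return [self.w, self.b]

    @property
    def grads(self):
        return [self.dw, self.db]


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = (rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)
                  ).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    def forward(self, x: np.ndarray):
        return x @ self.w + self.b, x

    def backward(self, dout: np.ndarray, cache):
        x = cache
        self.dw = x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.w.T

    @property
    def params(self):
        return [self.w, self.b]

    @property
    def grads(self):
        return [self.dw, self.db]


class CompactCNN:
    """Three conv blocks + time pooling + linear softmax head.

    Input patches are (96, 64); stride-2 blocks reduce them to (12, 8) maps
    with ``channels[-1]`` features, which are averaged over time and fed to
    the classification layer.
    """

    def __init__(self, n_classes: int = 5, channels: tuple[int, ...] = (8, 16, 32),
                 input_shape: tuple[int, int] = (96, 64), seed: int = 0):
        rng = np.random.default_rng(seed)
        self.input_shape = tuple(input_shape)
        self.n_classes = n_classes
        self.convs = []
        c_prev = 1
        for c in channels:
            self.convs.append(Conv2d(c_prev, c, rng))
            c_prev = c
        t, f = input_shape
        for _ in channels:
            t = (t + 2 - 3) // 2 + 1
            f = (f + 2 - 3) // 2 + 1
        self.head = Dense(channels[-1] * f, n_classes, rng)
        self._pooled_shape = (channels[-1], t, f)

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray):
        """x: (B, 96, 64) -> logits (B, n_classes) plus backprop caches."""
        if x.shape[1:] != self.input_shape:
            raise ValueError(f"expected patches of shape {self.input_shape}, "
                             f"got {x.shape[1:]}")
        h = np.ascontiguousarray(x[:, None, :, :], dtype=np.float32)
        caches = []
        for conv in self.convs:
            h, cc = conv.forward(h)
            mask = h > 0
            h = h * mask
            caches.append((cc, mask))
        t_dim = h.shape[2]
        pooled = h.mean(axis=2)                    # (B, C, F): time pooling
        flat = pooled.reshape(h.shape[0], -1)
        logits, dcache = self.head.forward(flat)
        return logits, (caches, dcache, h.shape, t_dim)

    def backward(self, dlogits: np.ndarray, cache):
        caches, dcache, h_shape, t_dim = cache
        dflat = self.head.backward(dlogits, dcache)
        dpooled = dflat.reshape(h_shape[0], h_shape[1], h_shape[3])
        dh = np.repeat(dpooled[:, :, None, :], t_dim, axis=2) / t_dim
        for conv, (cc, mask) in zip(reversed(self.convs), reversed(caches)):
            dh = conv.backward(dh * mask, cc)

    # -- inference ----------------------------------------------------------
    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = []
        for i in range(0, x.shape[0], batch_size):
            logits, _ = self.forward(x[i:i + batch_size])
            out.append(softmax(logits))
        return np.concatenate(out)

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        return self.predict_proba(x, batch_size).argmax(axis=1)

    # -- parameter plumbing -------------------------------------------------
    @property
    def layers(self):
        return [*self.convs, self.head]

    def get_params(self) -> list[np.ndarray]:
        return [p.copy() for layer in self.layers for p in layer.params]

    def set_params(self, params: list[np.ndarray]) -> None:
        flat = [p for layer in self.layers for p in layer.params]
        if len(flat) != len(params):
            raise ValueError("parameter list length mismatch")
        for dst, src in zip(flat, params):
            dst[...] = src

    @property
    def n_parameters(self) -> int:
        return sum(p.size for layer in self.layers for p in layer.params)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and gradient w.r.t. logits."""
    p = softmax(logits)
    n = y.shape[0]
    loss = -float(np.mean(np.log(np.maximum(p[np.arange(n), y], 1e-300))))
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


class Adam:
    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m: list[np.ndarray] | None = None
        self.v: list[np.ndarray] | None = None
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if self.m is None:
            self.m = [np.zeros_like(p) for p in params]
            self.v = [np.zeros_like(p) for p in params]
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class RMSprop:
    def __init__(self, lr: float, rho: float = 0.9, eps: float = 1e-8):
        self.lr, self.rho, self.eps = lr, rho, eps
        self.v: list[np.ndarray] | None = None

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if self.v is None:
            self.v = [np.zeros_like(p) for p in params]
        for p, g, v in zip(params, grads, self.v):
            v[...] = self.rho * v + (1 - self.rho) * g * g
            p -= self.lr * g / (np.sqrt(v) + self.eps)


OPTIMIZERS = {"ADAM": Adam, "RMSprop": RMSprop}
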