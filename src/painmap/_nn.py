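"""Compact numpy neural-network engine with manual backpropagation.

Implements exactly the pieces the two decoders need: grouped 3-D
convolution, batch normalization, ReLU, global average pooling, linear
layers, GIN message passing, class-weighted cross-entropy, and SGD with
momentum and weight decay. Layers follow a forward/backward protocol and
expose their parameters for the optimizer; everything is deterministic
given a seeded ``numpy.random.Generator``.

Convolution expands the grouped kernel block-diagonally (the group
structure saves no meaningful FLOPs at the volume sizes this package
targets) and accumulates one dense GEMM per kernel offset, which avoids
materializing a full im2col tensor and keeps single-CPU training fast.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param", "Layer", "Conv3d", "BatchNorm3d", "ReLU", "GlobalAvgPool3d",
    "Linear", "Sequential", "GinLayer", "weighted_cross_entropy", "SGD",
    "softmax",
]


DTYPE = np.float32  # single precision: training here is memory-bound


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())


class Conv3d(Layer):
    """Grouped 3-D convolution (no bias; batch norm follows it).

    Forward, weight gradient and input gradient are all computed by
    per-kernel-offset dense GEMMs on strided slices of the padded input;
    the input gradient is scattered back offset by offset.
    ``input_grad=False`` lets a network's first layer skip the input
    gradient entirely.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, stride: int = 1,
                 padding: int = 1, groups: int = 1,
                 rng: np.random.Generator | None = None,
                 input_grad: bool = True):
        if in_ch % groups or out_ch % groups:
            raise ValueError("in_ch and out_ch must be divisible by groups")
        rng = rng or np.random.default_rng(0)
        fan_in = (in_ch // groups) * kernel**3
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.w = Param(rng.normal(0.0, scale,
                                  (out_ch, in_ch // groups, kernel, kernel, kernel)))
        self.stride, self.padding, self.groups = stride, padding, groups
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        self.input_grad = input_grad  # first layers may skip the input gradient

    def params(self):
        return [self.w]

    def _out_size(self, d: int) -> int:
        return (d + 2 * self.padding - self.kernel) // self.stride + 1

    def _offsets(self):
        k = self.kernel
        return [(a, b, c) for a in range(k) for b in range(k) for c in range(k)]

    def _slice(self, xp, j, do, ho, wo):
        a, b, cc = self._offsets()[j]
        s = self.stride
        n, c = xp.shape[:2]
        view = xp[:, :, a:a + s * do:s, b:b + s * ho:s, cc:cc + s * wo:s]
        return view.reshape(n, c, do * ho * wo)

    def _dense_w(self) -> np.ndarray:
        """Block-diagonal dense (in_ch, k^3, out_ch) view of the grouped kernel."""
        k, g = self.kernel, self.groups
        cig, cog = self.in_ch // g, self.out_ch // g
        dense = np.zeros((self.in_ch, k**3, self.out_ch), dtype=DTYPE)
        wk = self.w.value.reshape(self.out_ch, cig, k**3)
        for gi in range(g):
            dense[gi * cig:(gi + 1) * cig, :, gi * cog:(gi + 1) * cog] = \
                wk[gi * cog:(gi + 1) * cog].transpose(1, 2, 0)
        return dense

    def forward(self, x, train=True):
        n, c, d, h, w = x.shape
        if c != self.in_ch:
            raise ValueError(f"expected {self.in_ch} channels, got {c}")
        k, s, p = self.kernel, self.stride, self.padding
        do, ho, wo = self._out_size(d), self._out_size(h), self._out_size(w)
        if do < 1 or ho < 1 or wo < 1:
            raise ValueError(
                f"spatial shape {(d, h, w)} too small for kernel {k} stride {s}; "
                f"minimum input extent is {max(1, k - 2 * p)}")
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        self._xshape, self._xp = x.shape, xp
        pp = do * ho * wo
        # per-offset dense accumulation: the group structure saves no
        # meaningful FLOPs at this scale, so the grouped kernel is expanded
        # block-diagonally and each kernel offset contributes one GEMM
        wd = self._dense_w()  # (c, K, o)
        out = np.zeros((n, pp, self.out_ch), dtype=DTYPE)
        for j in range(k**3):
            out += np.tensordot(self._slice(xp, j, do, ho, wo), wd[:, j, :],
                                axes=([1], [0]))
        self._out_shape = (do, ho, wo)
        return np.ascontiguousarray(np.moveaxis(out, 1, 2)).reshape(
            n, self.out_ch, do, ho, wo)

    def backward(self, grad):
        n = grad.shape[0]
        k, s, p, g = self.kernel, self.stride, self.padding, self.groups
        do, ho, wo = self._out_shape
        _, _, d, h, w = self._xshape
        cig, cog = self.in_ch // g, self.out_ch // g
        xp = self._xp
        gp = np.ascontiguousarray(
            np.moveaxis(grad.reshape(n, self.out_ch, -1), 1, 2))  # (n, p, o)
        wd = self._dense_w()
        dw_dense = np.empty((self.in_ch, k**3, self.out_ch), dtype=DTYPE)
        gxp = np.zeros(xp.shape, dtype=DTYPE) if self.input_grad else None
        for j in range(k**3):
            sl = self._slice(xp, j, do, ho, wo)
            dw_dense[:, j, :] = np.tensordot(sl, gp, axes=([0, 2], [0, 1]))
            if gxp is not None:
                gsl = np.tensordot(gp, wd[:, j, :], axes=([2], [1]))  # (n,p,c)
                a, b, cc = self._offsets()[j]
                gxp[:, :, a:a + s * do:s, b:b + s * ho:s, cc:cc + s * wo:s] += \
                    np.moveaxis(gsl, 2, 1).reshape(n, self.in_ch, do, ho, wo)
        wg = self.w.grad.reshape(self.out_ch, cig, k**3)
        for gi in range(g):
            blk = dw_dense[gi * cig:(gi + 1) * cig, :, gi * cog:(gi + 1) * cog]
            wg[gi * cog:(gi + 1) * cog] += blk.transpose(2, 0, 1)
        if gxp is None:
            return None
        return gxp[:, :, p:p + d, p:p + h, p:p + w]


class BatchNorm3d(Layer):
    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(ch))
        self.beta = Param(np.zeros(ch))
        self.running_mean = np.zeros(ch, dtype=DTYPE)
        self.running_var = np.ones(ch, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=True):
        axes = (0, 2, 3, 4)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        shp = (1, -1, 1, 1, 1)
        self._xhat = (x - mean.reshape(shp)) / np.sqrt(var.reshape(shp) + self.eps)
        self._std = np.sqrt(var + self.eps)
        self._train = train
        return self.gamma.value.reshape(shp) * self._xhat + self.beta.value.reshape(shp)

    def backward(self, grad):
        shp = (1, -1, 1, 1, 1)
        axes = (0, 2, 3, 4)
        m = grad.shape[0] * grad.shape[2] * grad.shape[3] * grad.shape[4]
        self.gamma.grad += (grad * self._xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        gx_hat = grad * self.gamma.value.reshape(shp)
        if not self._train:
            return gx_hat / self._std.reshape(shp)
        t1 = gx_hat - gx_hat.mean(axis=axes).reshape(shp)
        t2 = self._xhat * (gx_hat * self._xhat).mean(axis=axes).reshape(shp)
        return (t1 - t2) / self._std.reshape(shp)


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class GlobalAvgPool3d(Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, grad):
        n, c, d, h, w = self._shape
        g = grad[:, :, None, None, None] / (d * h * w)
        return np.broadcast_to(g, self._shape).copy()


class Linear(Layer):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / in_f)
        self.w = Param(rng.normal(0.0, scale, (out_f, in_f)))
        self.b = Param(np.zeros(out_f))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=True):
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, grad):
        # supports (..., in_f) inputs by flattening leading axes
        gf = grad.reshape(-1, grad.shape[-1])
        xf = self._x.reshape(-1, self._x.shape[-1])
        self.w.grad += gf.T @ xf
        self.b.grad += gf.sum(axis=0)
        return (gf @ self.w.value).reshape(self._x.shape)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train=True):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad


class GinLayer(Layer):
    """Graph Isomorphism Network layer: h' = MLP((1 + eps) h + A h).

    ``A`` is a batch of (R, R) adjacency matrices; node features are
    (N, R, F). ``eps`` may be fixed or learnable.
    """

    def __init__(self, in_f: int, out_f: int, hidden: int | None = None,
                 eps: float = 0.0, learn_eps: bool = False,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        hidden = hidden or out_f
        self.lin1 = Linear(in_f, hidden, rng)
        self.relu = ReLU()
        self.lin2 = Linear(hidden, out_f, rng)
        self.learn_eps = learn_eps
        self.eps = Param(np.array(float(eps))) if learn_eps else float(eps)

    def params(self):
        ps = self.lin1.params() + self.lin2.params()
        if self.learn_eps:
            ps.append(self.eps)
        return ps

    def _eps_value(self) -> float:
        return float(self.eps.value) if self.learn_eps else self.eps

    def aggregate(self, x: np.ndarray, adj: np.ndarray) -> np.ndarray:
        """(1 + eps) h_v + sum over neighbours, before the MLP."""
        return (1.0 + self._eps_value()) * x + adj @ x

    def forward(self, inputs, train=True):
        x, adj = inputs
        self._x, self._adj = x, adj
        agg = self.aggregate(x, adj)
        h = self.lin2.forward(self.relu.forward(self.lin1.forward(agg, train), train),
                              train)
        return h

    def backward(self, grad):
        g = self.lin1.backward(self.relu.backward(self.lin2.backward(grad)))
        if self.learn_eps:
            self.eps.grad += float((g * self._x).sum())
        # adjacency is symmetric, but transpose kept for generality
        gx = (1.0 + self._eps_value()) * g + np.swapaxes(self._adj, -1, -2) @ g
        return gx


def softmax(scores: np.ndarray) -> np.ndarray:
    z = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def weighted_cross_entropy(scores: np.ndarray, labels: np.ndarray,
                           class_weights: np.ndarray) -> tuple[float, np.ndarray]:
    """Class-weighted cross-entropy; returns (loss, dL/dscores)."""
    n = len(labels)
    p = softmax(scores)
    w = class_weights[labels]
    logp = np.log(np.clip(p[np.arange(n), labels], 1e-12, None))
    wsum = w.sum()
    loss = float(-(w * logp).sum() / wsum)
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    grad *= (w / wsum)[:, None]
    return loss, grad


class SGD:
    """Stochastic gradient descent with classical momentum and weight decay."""

    def __init__(self, params: list[Param], lr: float, momentum: float = 0.9,
                 weight_decay: float = 5.0e-4):
        self.params = params
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self._v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        for p, v in zip(self.params, self._v):
            g = p.grad + self.weight_decay * p.value
            v *= self.momentum
            v += g
            p.value -= self.lr * v
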