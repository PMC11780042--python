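"""Minimal reverse-mode automatic differentiation on numpy arrays.

Provides the small set of operations needed by the encoder–decoder
networks in this package: elementwise arithmetic with broadcasting,
reductions, activations, 2D convolution (same padding), 2×2 max pooling,
stride-2 transposed convolution, channel concatenation, batch
normalization and a channel softmax.  All ops operate on float32 NCHW
tensors and register a backward closure; `Tensor.backward()` runs a
topological sweep.

The engine is intentionally small rather than general: every op here is
exercised by finite-difference gradient checks in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "conv_transpose2x", "maxpool2x2", "softmax_channels", "batchnorm2d"]


def _as_f32(x):
    a = np.asarray(x, dtype=np.float32)
    return a


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = _as_f32(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):  # pragma: no cover - debug aid
        return f"Tensor(shape={self.data.shape}, grad={'yes' if self.requires_grad else 'no'})"

    def _accum(self, g):
        if self.grad is None:
            # copies only if g is non-contiguous, not float32, or aliases data
            self.grad = np.ascontiguousarray(g, dtype=np.float32)
            if self.grad is g and g.base is not None:
                self.grad = g.copy()
        else:
            self.grad += g

    def backward(self):
        """Backpropagate from this (scalar or any-shape) tensor with seed 1."""
        topo: list[Tensor] = []
        seen = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if node._parents:
                node.grad = None  # free intermediate gradients as we go

    # ------------------------------------------------------------------
    # elementwise arithmetic (broadcasting-aware)
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g, a=self):
            if a.requires_grad:
                a._accum(-g)

        return Tensor(-self.data, parents=(self,), backward=bwd)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data

        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data / other.data

        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g, a=self, axis=axis, keepdims=keepdims):
            if not a.requires_grad:
                return
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accum(np.broadcast_to(gg, a.data.shape).astype(np.float32))

        return Tensor(out_data, parents=(self,), backward=bwd)

    def mean(self):
        n = self.data.size
        return self.sum() * (1.0 / n)

    def reshape(self, *shape):
        out_data = self.data.reshape(*shape)

        def bwd(g, a=self):
            if a.requires_grad:
                a._accum(g.reshape(a.data.shape))

        return Tensor(out_data, parents=(self,), backward=bwd)

    # activations -------------------------------------------------------
    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask

        def bwd(g, a=self, mask=mask):
            if a.requires_grad:
                a._accum(g * mask)

        return Tensor(out_data, parents=(self,), backward=bwd)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g, a=self, y=out_data):
            if a.requires_grad:
                a._accum(g * y * (1.0 - y))

        return Tensor(out_data, parents=(self,), backward=bwd)

    def log(self):
        out_data = np.log(self.data)

        def bwd(g, a=self):
            if a.requires_grad:
                a._accum(g / a.data)

        return Tensor(out_data, parents=(self,), backward=bwd)

    def square(self):
        return self * self


def _unbroadcast(g, shape):
    """Sum gradient `g` down to `shape` (inverse of numpy broadcasting)."""
    g = np.asarray(g)
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g.astype(np.float32)


# ----------------------------------------------------------------------
def concat(tensors, axis=1):
    """Concatenate along an axis (channel axis by default)."""
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g, ts=tuple(tensors), splits=splits, axis=axis):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(ts, parts):
            if t.requires_grad:
                t._accum(p)

    return Tensor(out_data, parents=tuple(tensors), backward=bwd)


def _im2col(xp, kh, kw):
    # xp: padded (N, C, Hp, Wp) -> (N*Ho*Wo, C*kh*kw)
    v = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    n, c, ho, wo = v.shape[:4]
    cols = v.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
    return np.ascontiguousarray(cols), (n, ho, wo)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """2D convolution (cross-correlation), stride 1, 'same' zero padding.

    x: (N, C, H, W); w: (F, C, kh, kw) with odd kh, kw; b: (F,) or None.
    """
    n, c, h, wd = x.data.shape
    f, c2, kh, kw = w.data.shape
    assert c == c2, "channel mismatch"
    if kh == 1 and kw == 1:
        return _conv1x1(x, w, b)
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    cols, (n_, ho, wo) = _im2col(xp, kh, kw)
    wmat = w.data.reshape(f, c * kh * kw).T  # (Ckk, F)
    out = cols @ wmat  # (N*H*W, F)
    del cols  # recomputed in backward; holding it for every conv is too costly
    if b is not None:
        out = out + b.data[None, :]
    out_data = out.reshape(n, ho, wo, f).transpose(0, 3, 1, 2)

    parents = (x, w) if b is None else (x, w, b)

    def bwd(g, x=x, w=w, b=b, wmat=wmat, dims=(n, c, h, wd, f, kh, kw, ph, pw)):
        n, c, h, wd, f, kh, kw, ph, pw = dims
        gflat = g.transpose(0, 2, 3, 1).reshape(-1, f)  # (N*H*W, F)
        if w.requires_grad:
            xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
            cols, _ = _im2col(xp, kh, kw)
            dw = (cols.T @ gflat).T.reshape(f, c, kh, kw)
            w._accum(dw)
        if b is not None and b.requires_grad:
            b._accum(gflat.sum(axis=0))
        if x.requires_grad:
            # dx is the correlation of g with spatially flipped kernels
            # (stride 1, same padding, odd kernel), done as one GEMM
            wflip = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (C, F, kh, kw)
            gp = np.pad(g, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
            gcols, _ = _im2col(gp, kh, kw)
            dx = (gcols @ wflip.reshape(c, f * kh * kw).T).reshape(n, h, wd, c)
            x._accum(dx.transpose(0, 3, 1, 2))

    return Tensor(out_data, parents=parents, backward=bwd)


def _conv1x1(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    n, c, h, wd = x.data.shape
    f = w.data.shape[0]
    wmat = w.data.reshape(f, c)
    out = np.einsum("nchw,fc->nfhw", x.data, wmat, optimize=True)
    if b is not None:
        out += b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)

    def bwd(g, x=x, w=w, b=b, wmat=wmat, f=f, c=c):
        if w.requires_grad:
            dw = np.einsum("nfhw,nchw->fc", g, x.data, optimize=True)
            w._accum(dw.reshape(f, c, 1, 1))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            x._accum(np.einsum("nfhw,fc->nchw", g, wmat, optimize=True))

    return Tensor(out, parents=parents, backward=bwd)


def conv_transpose2x(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Transposed convolution with a 2x2 kernel and stride 2 (exact).

    x: (N, C, H, W); w: (C, F, 2, 2); output (N, F, 2H, 2W).
    Output pixel (2i+a, 2j+d) receives sum_c x[c,i,j] * w[c,f,a,d].
    """
    n, c, h, wd = x.data.shape
    c2, f = w.data.shape[:2]
    assert c == c2
    out = np.einsum("ncij,cfab->nfiajb", x.data, w.data, optimize=True)
    out_data = out.reshape(n, f, 2 * h, 2 * wd)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)

    def bwd(g, x=x, w=w, b=b, dims=(n, c, h, wd, f)):
        n, c, h, wd, f = dims
        g6 = g.reshape(n, f, h, 2, wd, 2)
        if x.requires_grad:
            dx = np.einsum("nfiajb,cfab->ncij", g6, w.data, optimize=True)
            x._accum(dx)
        if w.requires_grad:
            dw = np.einsum("nfiajb,ncij->cfab", g6, x.data, optimize=True)
            w._accum(dw)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))

    return Tensor(out_data, parents=parents, backward=bwd)


def maxpool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2; H and W must be even."""
    n, c, h, w = x.data.shape
    assert h % 2 == 0 and w % 2 == 0, "maxpool2x2 requires even spatial dims"
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
    idx = xr.argmax(axis=-1)
    out_data = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def bwd(g, x=x, idx=idx, dims=(n, c, h, w)):
        if not x.requires_grad:
            return
        n, c, h, w = dims
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(dxr, idx[..., None], g[..., None], axis=-1)
        dx = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        x._accum(dx)

    return Tensor(out_data, parents=(x,), backward=bwd)


def softmax_channels(x: Tensor) -> Tensor:
    """Softmax over axis 1 (class channels) of an NCHW tensor."""
    z = x.data - x.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)

    def bwd(g, x=x, p=p):
        if x.requires_grad:
            dot = (g * p).sum(axis=1, keepdims=True)
            x._accum(p * (g - dot))

    return Tensor(p, parents=(x,), backward=bwd)


def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor, running_mean, running_var,
                training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Batch normalization over (N, H, W) per channel.

    `running_mean`/`running_var` are plain float32 arrays updated in place
    when `training` is true.
    """
    n, c, h, w = x.data.shape
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= (1.0 - momentum)
        running_mean += momentum * mu
        running_var *= (1.0 - momentum)
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * inv[None, :, None, None]
    out_data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def bwd(g, x=x, gamma=gamma, beta=beta, xhat=xhat, inv=inv, training=training):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gi = g * gamma.data[None, :, None, None]
            if training:
                m = g.shape[0] * g.shape[2] * g.shape[3]
                mean_gi = gi.mean(axis=(0, 2, 3), keepdims=True)
                mean_gixh = (gi * xhat).mean(axis=(0, 2, 3), keepdims=True)
                dx = inv[None, :, None, None] * (gi - mean_gi - xhat * mean_gixh)
            else:
                dx = gi * inv[None, :, None, None]
            x._accum(dx)

    return Tensor(out_data, parents=(x, gamma, beta), backward=bwd)
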