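"""Minimal reverse-mode automatic differentiation on numpy arrays.

The fusion network and its training losses need a differentiable compute
graph, so this module provides one: a :class:`Tensor` wrapping a numpy array
with broadcast arithmetic, matmul, reductions, shape ops, the activations
used by the encoder/decoder blocks, stride-1 convolution, 2x2 stride-2
transposed convolution, depthwise convolution, average pooling and bilinear
upsampling.  Gradients are accumulated by :meth:`Tensor.backward`.

Scalars passed as python floats keep the array dtype, so float32 networks
and float64 gradient checks coexist.
"""

from __future__ import annotations

import contextlib

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "is_grad_enabled",
    "manual_seed",
    "get_rng",
    "as_tensor",
    "concat",
    "softmax",
    "conv2d",
    "depthwise_conv2d",
    "conv_transpose2x2",
    "avg_pool2d",
    "upsample_bilinear",
    "dropout",
]

_GRAD_ENABLED = True
_RNG = np.random.default_rng(0)


def manual_seed(seed: int) -> None:
    """Reset the global RNG used for dropout and parameter init."""
    global _RNG
    _RNG = np.random.default_rng(int(seed))


def get_rng() -> np.random.Generator:
    return _RNG


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


@contextlib.contextmanager
def no_grad():
    """Context manager that disables graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # remove leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype}, grad={self.requires_grad})"

    def _accum(self, g: np.ndarray) -> None:
        fresh = False
        if g.dtype != self.data.dtype:
            g = g.astype(self.data.dtype)
            fresh = True
        if self.grad is None:
            # grad must be a private buffer: closures may hand the same
            # array to several parents
            self.grad = g if fresh else g.copy()
        else:
            np.add(self.grad, g, out=self.grad)

    def backward(self, grad=None) -> None:
        """Backpropagate from this tensor through the recorded graph."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            # free graph references as we go
            if node is not self:
                node._parents = ()
                node._backward = None


def as_tensor(x, dtype=None) -> Tensor:
    if isinstance(x, Tensor):
        if dtype is not None and x.data.dtype != dtype:
            return Tensor(x.data.astype(dtype), _parents=(x,) if (_GRAD_ENABLED and x.requires_grad) else (),
                          requires_grad=x.requires_grad,
                          _backward=(lambda g, x=x: x._accum(g.astype(x.data.dtype)))
                          if (_GRAD_ENABLED and x.requires_grad) else None)
        return x
    arr = np.asarray(x, dtype=dtype)
    return Tensor(arr)


def _needs_graph(*tensors: Tensor) -> bool:
    return _GRAD_ENABLED and any(t.requires_grad for t in tensors)


def _make(data, parents, backward):
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        return Tensor(data, requires_grad=True, _parents=tuple(parents), _backward=backward)
    return Tensor(data)


# -- elementwise binary ops -----------------------------------------------

def _binary(a, b, fwd, da, db):
    a, b = as_tensor(a), as_tensor(b)
    out_data = fwd(a.data, b.data)

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(da(g, a.data, b.data, out_data), a.data.shape).astype(a.data.dtype))
        if b.requires_grad:
            b._accum(_unbroadcast(db(g, a.data, b.data, out_data), b.data.shape).astype(b.data.dtype))

    return _make(out_data, (a, b), backward)


def _add(a, b):
    return _binary(a, b, lambda x, y: x + y, lambda g, x, y, o: g, lambda g, x, y, o: g)


def _sub(a, b):
    return _binary(a, b, lambda x, y: x - y, lambda g, x, y, o: g, lambda g, x, y, o: -g)


def _mul(a, b):
    return _binary(a, b, lambda x, y: x * y, lambda g, x, y, o: g * y, lambda g, x, y, o: g * x)


def _div(a, b):
    return _binary(a, b, lambda x, y: x / y, lambda g, x, y, o: g / y,
                   lambda g, x, y, o: -g * x / (y * y))


def _matmul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accum(_unbroadcast(ga, a.data.shape).astype(a.data.dtype))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accum(_unbroadcast(gb, b.data.shape).astype(b.data.dtype))

    return _make(out_data, (a, b), backward)


# -- elementwise unary ops ------------------------------------------------

def _unary(x, fwd, dfn):
    x = as_tensor(x)
    out_data = fwd(x.data)

    def backward(g):
        if x.requires_grad:
            x._accum((g * dfn(x.data, out_data)).astype(x.data.dtype))

    return _make(out_data, (x,), backward)


_SQRT2_OVER_PI = 0.7978845608028654


class _OpsMixin:
    """Operator methods attached to Tensor below (keeps the class readable)."""


def _attach_ops():
    T = Tensor
    T.__add__ = lambda self, o: _add(self, o)
    T.__radd__ = lambda self, o: _add(o, self)
    T.__sub__ = lambda self, o: _sub(self, o)
    T.__rsub__ = lambda self, o: _sub(o, self)
    T.__mul__ = lambda self, o: _mul(self, o)
    T.__rmul__ = lambda self, o: _mul(o, self)
    T.__truediv__ = lambda self, o: _div(self, o)
    T.__rtruediv__ = lambda self, o: _div(o, self)
    T.__neg__ = lambda self: _mul(self, -1.0)
    T.__matmul__ = lambda self, o: _matmul(self, o)

    T.exp = lambda self: _unary(self, np.exp, lambda x, o: o)
    T.log = lambda self: _unary(self, np.log, lambda x, o: 1.0 / x)
    T.sqrt = lambda self: _unary(self, np.sqrt, lambda x, o: 0.5 / o)
    T.tanh = lambda self: _unary(self, np.tanh, lambda x, o: 1.0 - o * o)
    T.sigmoid = lambda self: _unary(
        self, lambda x: 1.0 / (1.0 + np.exp(-x)), lambda x, o: o * (1.0 - o))
    T.relu = lambda self: _unary(self, lambda x: np.maximum(x, 0.0), lambda x, o: (x > 0).astype(x.dtype))
    T.relu6 = lambda self: _unary(
        self, lambda x: np.clip(x, 0.0, 6.0), lambda x, o: ((x > 0) & (x < 6)).astype(x.dtype))
    T.elu = lambda self: _unary(
        self, lambda x: np.where(x > 0, x, np.expm1(np.minimum(x, 0.0))),
        lambda x, o: np.where(x > 0, 1.0, o + 1.0))

    def _gelu(self):
        x = self
        xd = x.data
        t = np.tanh(_SQRT2_OVER_PI * (xd + 0.044715 * xd ** 3))
        out = 0.5 * xd * (1.0 + t)

        def backward(g):
            if x.requires_grad:
                dt = (1.0 - t * t) * _SQRT2_OVER_PI * (1.0 + 3 * 0.044715 * xd * xd)
                x._accum(g * (0.5 * (1.0 + t) + 0.5 * xd * dt))

        return _make(out, (x,), backward)

    T.gelu = _gelu
    T.arctan = lambda self: _unary(self, np.arctan, lambda x, o: 1.0 / (1.0 + x * x))

    def _pow(self, p):
        p = float(p)
        return _unary(self, lambda x: x ** p, lambda x, o: p * x ** (p - 1))

    T.__pow__ = _pow

    def smooth_abs(self, eps=1e-12):
        eps = float(eps)
        return _unary(self, lambda x: np.sqrt(x * x + eps), lambda x, o: x / o)

    T.smooth_abs = smooth_abs

    def _sum(self, axis=None, keepdims=False):
        x = self
        out_data = x.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not x.requires_grad:
                return
            if axis is None:
                x._accum(np.broadcast_to(g, x.data.shape).astype(x.data.dtype))
                return
            gg = g
            if not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                axes = tuple(a % x.data.ndim for a in axes)
                for a in sorted(axes):
                    gg = np.expand_dims(gg, a)
            x._accum(np.broadcast_to(gg, x.data.shape).astype(x.data.dtype))

        return _make(out_data, (x,), backward)

    T.sum = _sum

    def _mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return _sum(self, axis=axis, keepdims=keepdims) * (1.0 / float(n))

    T.mean = _mean

    def _reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        x = self
        out_data = x.data.reshape(shape)

        def backward(g):
            if x.requires_grad:
                x._accum(g.reshape(x.data.shape))

        return _make(out_data, (x,), backward)

    T.reshape = _reshape

    def _transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        x = self
        out_data = x.data.transpose(axes)
        inv = np.argsort(axes)

        def backward(g):
            if x.requires_grad:
                x._accum(g.transpose(inv))

        return _make(out_data, (x,), backward)

    T.transpose = _transpose

    def _getitem(self, idx):
        x = self
        out_data = x.data[idx]

        def backward(g):
            if x.requires_grad:
                buf = np.zeros_like(x.data)
                np.add.at(buf, idx, g)
                x._accum(buf)

        return _make(out_data, (x,), backward)

    T.__getitem__ = _getitem


_attach_ops()


def concat(tensors, axis=0):
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return _make(out_data, tuple(tensors), backward)


def softmax(x: Tensor, axis=-1) -> Tensor:
    x = as_tensor(x)
    m = Tensor(x.data.max(axis=axis, keepdims=True))  # detached shift for stability
    e = (x - m).exp()
    return e / e.sum(axis=axis, keepdims=True)


def dropout(x: Tensor, p: float, training: bool) -> Tensor:
    """Inverted dropout driven by the module-global RNG."""
    if not training or p <= 0.0:
        return as_tensor(x)
    x = as_tensor(x)
    keep = (_RNG.random(x.data.shape) >= p).astype(x.data.dtype) / (1.0 - p)
    return x * Tensor(keep)


# -- spatial ops ----------------------------------------------------------

_IM2COL_LIMIT = 3 * 10 ** 8  # bytes; above this fall back to the shift method


def _conv2d_shift(x, w, b, parents, padding):
    """Shift-and-GEMM convolution; no im2col buffer, used for large maps."""
    xd, wd = x.data, w.data
    N, C, H, W = xd.shape
    O, _, kh, kw = wd.shape
    p = padding
    xp = np.pad(xd, ((0, 0), (0, 0), (p, p), (p, p))) if p else xd
    Ho, Wo = H + 2 * p - kh + 1, W + 2 * p - kw + 1
    out = np.zeros((N, Ho, Wo, O), dtype=xd.dtype)
    for i in range(kh):
        for j in range(kw):
            out += np.tensordot(xp[:, :, i:i + Ho, j:j + Wo], wd[:, :, i, j], axes=([1], [1]))
    out = np.ascontiguousarray(out.transpose(0, 3, 1, 2))
    if b is not None:
        out += b.data.reshape(1, -1, 1, 1)

    def backward(g):
        if w.requires_grad:
            dW = np.empty_like(wd)
            for i in range(kh):
                for j in range(kw):
                    dW[:, :, i, j] = np.tensordot(
                        g, xp[:, :, i:i + Ho, j:j + Wo], axes=([0, 2, 3], [0, 2, 3]))
            w._accum(dW)
        if x.requires_grad:
            dxp = np.zeros((N, C, H + 2 * p, W + 2 * p), dtype=xd.dtype)
            for i in range(kh):
                for j in range(kw):
                    gi = np.tensordot(g, wd[:, :, i, j], axes=([1], [0]))  # N,Ho,Wo,C
                    dxp[:, :, i:i + Ho, j:j + Wo] += gi.transpose(0, 3, 1, 2)
            x._accum(dxp[:, :, p:p + H, p:p + W] if p else dxp)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))

    return _make(out, tuple(parents), backward)


def conv2d(x, w, b=None, padding: int = 0) -> Tensor:
    """Stride-1 2-D convolution (cross-correlation), NCHW x OCkk -> NOHW.

    Small/medium maps go through a single im2col GEMM (the patch matrix is
    kept for the backward pass); very large maps use a shift-and-GEMM path
    that avoids the im2col buffer.
    """
    x, w = as_tensor(x), as_tensor(w)
    parents = [x, w]
    if b is not None:
        b = as_tensor(b)
        parents.append(b)
    xd, wd = x.data, w.data
    N, C, H, W = xd.shape
    O, C2, kh, kw = wd.shape
    if C2 != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight {C2}")
    p = int(padding)
    Ho, Wo = H + 2 * p - kh + 1, W + 2 * p - kw + 1

    if kh == 1 and kw == 1 and p == 0:  # pointwise: plain GEMM
        xs2d = np.ascontiguousarray(xd.transpose(0, 2, 3, 1)).reshape(N * H * W, C)
        wm1 = wd.reshape(O, C)
        out = np.ascontiguousarray(
            (xs2d @ wm1.T).reshape(N, H, W, O).transpose(0, 3, 1, 2))
        if b is not None:
            out += b.data.reshape(1, -1, 1, 1)

        def backward1(g):
            g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(N * H * W, O)
            if w.requires_grad:
                w._accum((g2.T @ xs2d).reshape(O, C, 1, 1))
            if x.requires_grad:
                x._accum(np.ascontiguousarray(
                    (g2 @ wm1).reshape(N, H, W, C).transpose(0, 3, 1, 2)))
            if b is not None and b.requires_grad:
                b._accum(g.sum(axis=(0, 2, 3)))

        return _make(out, tuple(parents), backward1)

    cols_bytes = N * Ho * Wo * C * kh * kw * xd.itemsize
    if cols_bytes > _IM2COL_LIMIT:
        return _conv2d_shift(x, w, b, parents, p)

    def _im2col():
        xs = np.ascontiguousarray(xd.transpose(0, 2, 3, 1))  # NHWC
        if p:
            xs = np.pad(xs, ((0, 0), (p, p), (p, p), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xs, (kh, kw), axis=(1, 2))
        # window layout is already (..., C, kh, kw)
        return np.ascontiguousarray(win).reshape(N * Ho * Wo, C * kh * kw)

    wm = wd.reshape(O, C * kh * kw)
    out2d = _im2col() @ wm.T
    out = np.ascontiguousarray(
        out2d.reshape(N, Ho, Wo, O).transpose(0, 3, 1, 2))
    del out2d
    if b is not None:
        out += b.data.reshape(1, -1, 1, 1)

    def backward(g):
        g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(N * Ho * Wo, O)
        if w.requires_grad:
            # the patch matrix is recomputed rather than cached: the graph
            # already retains x, and the buffer is 9x the activation size
            w._accum((g2.T @ _im2col()).reshape(O, C, kh, kw))
        if x.requires_grad:
            dcols = (g2 @ wm).reshape(N, Ho, Wo, C, kh, kw)
            dxs = np.zeros((N, H + 2 * p, W + 2 * p, C), dtype=xd.dtype)
            for i in range(kh):
                for j in range(kw):
                    dxs[:, i:i + Ho, j:j + Wo, :] += dcols[:, :, :, :, i, j]
            if p:
                dxs = dxs[:, p:p + H, p:p + W, :]
            x._accum(np.ascontiguousarray(dxs.transpose(0, 3, 1, 2)))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))

    return _make(out, tuple(parents), backward)


def depthwise_conv2d(x, w, padding: int = 0) -> Tensor:
    """Per-channel 2-D convolution with a (C, kh, kw) kernel stack."""
    x, w = as_tensor(x), as_tensor(w)
    xd, wd = x.data, w.data
    N, C, H, W = xd.shape
    C2, kh, kw = wd.shape
    if C2 not in (C, 1):
        raise ValueError("depthwise kernel channel mismatch")
    p = int(padding)
    xp = np.pad(xd, ((0, 0), (0, 0), (p, p), (p, p))) if p else xd
    Ho, Wo = H + 2 * p - kh + 1, W + 2 * p - kw + 1
    out = np.zeros((N, C, Ho, Wo), dtype=xd.dtype)
    for i in range(kh):
        for j in range(kw):
            out += xp[:, :, i:i + Ho, j:j + Wo] * wd[:, i, j].reshape(1, -1, 1, 1)

    def backward(g):
        if w.requires_grad:
            dW = np.empty_like(wd)
            for i in range(kh):
                for j in range(kw):
                    s = (g * xp[:, :, i:i + Ho, j:j + Wo]).sum(axis=(0, 2, 3))
                    dW[:, i, j] = s if C2 == C else s.sum()
            w._accum(dW)
        if x.requires_grad:
            dxp = np.zeros((N, C, H + 2 * p, W + 2 * p), dtype=xd.dtype)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + Ho, j:j + Wo] += g * wd[:, i, j].reshape(1, -1, 1, 1)
            x._accum(dxp[:, :, p:p + H, p:p + W] if p else dxp)

    return _make(out, (x, w), backward)


def conv_transpose2x2(x, w, b=None) -> Tensor:
    """2x2 stride-2 transposed convolution (exact 2x upsampling), w: (C, O, 2, 2)."""
    x, w = as_tensor(x), as_tensor(w)
    parents = [x, w]
    if b is not None:
        b = as_tensor(b)
        parents.append(b)
    xd, wd = x.data, w.data
    N, C, H, W = xd.shape
    C2, O, _, _ = wd.shape
    if C2 != C:
        raise ValueError("conv_transpose2x2 channel mismatch")
    t = np.tensordot(xd, wd, axes=([1], [0]))  # N,H,W,O,2,2
    out = np.ascontiguousarray(
        t.transpose(0, 3, 1, 4, 2, 5).reshape(N, O, 2 * H, 2 * W))
    if b is not None:
        out += b.data.reshape(1, -1, 1, 1)

    def backward(g):
        G = g.reshape(N, O, H, 2, W, 2).transpose(0, 2, 4, 1, 3, 5)  # N,H,W,O,2,2
        if x.requires_grad:
            dx = np.tensordot(G, wd, axes=([3, 4, 5], [1, 2, 3]))  # N,H,W,C
            x._accum(np.ascontiguousarray(dx.transpose(0, 3, 1, 2)))
        if w.requires_grad:
            dW = np.tensordot(xd, G, axes=([0, 2, 3], [0, 1, 2]))  # C,O,2,2
            w._accum(dW)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))

    return _make(out, tuple(parents), backward)


def avg_pool2d(x, factor) -> Tensor:
    """Non-overlapping average pooling by an integer factor (or (fh, fw))."""
    x = as_tensor(x)
    fh, fw = (factor, factor) if np.isscalar(factor) else factor
    N, C, H, W = x.data.shape
    if H % fh or W % fw:
        raise ValueError(f"avg_pool2d: {H}x{W} not divisible by {fh}x{fw}")
    out = x.data.reshape(N, C, H // fh, fh, W // fw, fw).mean(axis=(3, 5))

    def backward(g):
        if x.requires_grad:
            gg = np.broadcast_to(
                g[:, :, :, None, :, None] / (fh * fw), (N, C, H // fh, fh, W // fw, fw))
            x._accum(gg.reshape(N, C, H, W).astype(x.data.dtype))

    return _make(out, (x,), backward)


def _bilinear_index(n_in: int, factor: int):
    pos = (np.arange(n_in * factor) + 0.5) / factor - 0.5
    i0 = np.floor(pos).astype(np.int64)
    frac = pos - i0
    i0c = np.clip(i0, 0, n_in - 1)
    i1c = np.clip(i0 + 1, 0, n_in - 1)
    return i0c, i1c, frac


def upsample_bilinear(x, factor) -> Tensor:
    """Bilinear upsampling by an integer factor (half-pixel convention)."""
    x = as_tensor(x)
    fh, fw = (factor, factor) if np.isscalar(factor) else factor
    N, C, H, W = x.data.shape
    y0, y1, wy = _bilinear_index(H, fh)
    x0, x1, wx = _bilinear_index(W, fw)
    wy = wy.astype(x.data.dtype)[None, None, :, None]
    wx = wx.astype(x.data.dtype)[None, None, None, :]
    xd = x.data
    top = xd[:, :, y0][:, :, :, x0] * (1 - wx) + xd[:, :, y0][:, :, :, x1] * wx
    bot = xd[:, :, y1][:, :, :, x0] * (1 - wx) + xd[:, :, y1][:, :, :, x1] * wx
    out = top * (1 - wy) + bot * wy

    def backward(g):
        if not x.requires_grad:
            return
        buf = np.zeros_like(xd)
        for yi, wyi in ((y0, (1 - wy)), (y1, wy)):
            for xi, wxi in ((x0, (1 - wx)), (x1, wx)):
                contrib = g * wyi * wxi
                # scatter-add along both spatial axes
                tmp = np.zeros((N, C, H, g.shape[3]), dtype=xd.dtype)
                np.add.at(tmp, (slice(None), slice(None), yi), contrib)
                np.add.at(buf.transpose(0, 1, 3, 2), (slice(None), slice(None), xi),
                          tmp.transpose(0, 1, 3, 2))
        x._accum(buf)

    return _make(out.astype(xd.dtype), (x,), backward)
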