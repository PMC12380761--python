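"""Reverse-mode automatic differentiation over numpy arrays.

The package's networks are small enough that a plain numpy tape is
practical on one CPU: every operation records its parents and a closure
that accumulates gradients.  All arithmetic is float32.

A second execution mode runs the *same* forward code on :class:`ShapeProbe`
objects that carry only a shape.  Inside a :func:`profile` context the
convolution entry point adds its multiply-accumulate count to the active
counter, which is how the structural FLOPs audit traces a model without
doing any arithmetic.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np

_F32 = np.float32


# ---------------------------------------------------------------------------
# shape probing / FLOPs profiling

class ShapeProbe:
    """Stand-in for a Tensor that carries only a shape through forward code."""

    __slots__ = ("shape",)

    def __init__(self, shape: Sequence[int]):
        self.shape = tuple(int(s) for s in shape)

    @property
    def ndim(self) -> int:
        return len(self.shape)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        n = int(np.prod(self.shape))
        shape = list(shape)
        if -1 in shape:
            i = shape.index(-1)
            rest = int(np.prod([s for s in shape if s != -1]))
            shape[i] = n // rest
        assert int(np.prod(shape)) == n, (self.shape, shape)
        return ShapeProbe(shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return ShapeProbe(tuple(self.shape[a] for a in axes))

    def __getitem__(self, idx):
        return getitem(self, idx)

    def __repr__(self):  # pragma: no cover
        return f"ShapeProbe{self.shape}"


class _Profile:
    def __init__(self):
        self.macs = 0

    @property
    def flops(self) -> int:
        """Total FLOPs under the 2-FLOPs-per-multiply-accumulate convention."""
        return 2 * self.macs


_ACTIVE_PROFILE: list[_Profile] = []


@contextlib.contextmanager
def profile():
    """Context manager collecting conv/linear MACs of shape-probed forwards."""
    p = _Profile()
    _ACTIVE_PROFILE.append(p)
    try:
        yield p
    finally:
        _ACTIVE_PROFILE.pop()


def _count_macs(n: int) -> None:
    if _ACTIVE_PROFILE:
        _ACTIVE_PROFILE[-1].macs += int(n)


def is_probe(x) -> bool:
    return isinstance(x, ShapeProbe)


# ---------------------------------------------------------------------------
# tensor core

class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=_F32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- basic introspection ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- autograd -----------------------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        self._accumulate(np.asarray(grad, dtype=_F32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- operator sugar -----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(astensor(other), -1.0))

    def __rsub__(self, other):
        return add(astensor(other), mul(self, -1.0))

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(astensor(other), self)

    def __pow__(self, p):
        return power(self, p)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def reshape(self, *shape):
        return reshape(self, *shape)

    def transpose(self, *axes):
        return transpose(self, *axes)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents: Iterable[Tensor], backward) -> Tensor:
    parents = tuple(p for p in parents if isinstance(p, Tensor))
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = parents
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient g down to `shape` (inverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


# ---------------------------------------------------------------------------
# elementwise arithmetic

def add(a, b) -> Tensor:
    if is_probe(a) or is_probe(b):
        sa = a.shape if hasattr(a, "shape") else ()
        sb = b.shape if hasattr(b, "shape") else ()
        return ShapeProbe(np.broadcast_shapes(sa, sb))
    a, b = astensor(a), astensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    if is_probe(a) or is_probe(b):
        sa = a.shape if hasattr(a, "shape") else ()
        sb = b.shape if hasattr(b, "shape") else ()
        return ShapeProbe(np.broadcast_shapes(sa, sb))
    a, b = astensor(a), astensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    return _make(out_data, (a, b), backward)


def div(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out_data = a.data / b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g / b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g * a.data / (b.data ** 2), b.shape))

    return _make(out_data, (a, b), backward)


def power(a, p: float) -> Tensor:
    a = astensor(a)
    out_data = a.data ** p

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * p * a.data ** (p - 1))

    return _make(out_data, (a,), backward)


def sqrt(a) -> Tensor:
    return power(a, 0.5)


def exp(a) -> Tensor:
    a = astensor(a)
    out_data = np.exp(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * out_data)

    return _make(out_data, (a,), backward)


def log(a) -> Tensor:
    a = astensor(a)
    out_data = np.log(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g / a.data)

    return _make(out_data, (a,), backward)


def arctan(a) -> Tensor:
    a = astensor(a)
    out_data = np.arctan(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g / (1.0 + a.data ** 2))

    return _make(out_data, (a,), backward)


def maximum(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out_data = np.maximum(a.data, b.data)
    mask = (a.data >= b.data).astype(_F32)

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * mask, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * (1.0 - mask), b.shape))

    return _make(out_data, (a, b), backward)


def minimum(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out_data = np.minimum(a.data, b.data)
    mask = (a.data <= b.data).astype(_F32)

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * mask, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * (1.0 - mask), b.shape))

    return _make(out_data, (a, b), backward)


def clip(a, lo=None, hi=None) -> Tensor:
    a = astensor(a)
    out_data = np.clip(a.data, lo, hi)
    mask = np.ones_like(a.data)
    if lo is not None:
        mask *= (a.data >= lo)
    if hi is not None:
        mask *= (a.data <= hi)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * mask)

    return _make(out_data, (a,), backward)


# ---------------------------------------------------------------------------
# activations

def relu(a) -> Tensor:
    if is_probe(a):
        return ShapeProbe(a.shape)
    a = astensor(a)
    out_data = np.maximum(a.data, 0.0)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * (a.data > 0))

    return _make(out_data, (a,), backward)


def sigmoid(a) -> Tensor:
    if is_probe(a):
        return ShapeProbe(a.shape)
    a = astensor(a)
    out_data = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60, 60)))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), backward)


def silu(a) -> Tensor:
    if is_probe(a):
        return ShapeProbe(a.shape)
    a = astensor(a)
    s = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60, 60)))
    out_data = a.data * s

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * (s + a.data * s * (1.0 - s)))

    return _make(out_data, (a,), backward)


# ---------------------------------------------------------------------------
# reductions / shaping

def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = astensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if not a.requires_grad:
            return
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.shape).astype(_F32))
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.shape).astype(_F32))

    return _make(out_data, (a,), backward)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    if is_probe(a):
        return ShapeProbe(np.mean(np.zeros(a.shape, dtype=np.int8),
                                  axis=axis, keepdims=keepdims).shape)
    a = astensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))])
    return mul(tsum(a, axis, keepdims), 1.0 / float(n))


def tmax(a, axis: int, keepdims: bool = False) -> Tensor:
    if is_probe(a):
        return ShapeProbe(np.zeros(a.shape, dtype=np.int8).max(
            axis=axis, keepdims=keepdims).shape)
    a = astensor(a)
    out_data = a.data.max(axis=axis, keepdims=True)
    mask = (a.data == out_data)
    # ties share gradient equally
    mask = mask / mask.sum(axis=axis, keepdims=True)
    res = out_data if keepdims else np.squeeze(out_data, axis=axis)

    def backward(g):
        if a.requires_grad:
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate((g * mask).astype(_F32))

    return _make(res, (a,), backward)


def reshape(a, *shape) -> Tensor:
    if is_probe(a):
        return a.reshape(*shape)
    a = astensor(a)
    if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
        shape = tuple(shape[0])
    out_data = a.data.reshape(shape)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.reshape(a.shape))

    return _make(out_data, (a,), backward)


def transpose(a, *axes) -> Tensor:
    if is_probe(a):
        return a.transpose(*axes)
    a = astensor(a)
    if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
        axes = tuple(axes[0])
    out_data = a.data.transpose(axes)
    inv = np.argsort(axes)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.transpose(inv))

    return _make(out_data, (a,), backward)


def getitem(a, idx) -> Tensor:
    if is_probe(a):
        return ShapeProbe(np.empty(a.shape, dtype=np.bool_)[idx].shape)
    a = astensor(a)
    out_data = a.data[idx]

    def backward(g):
        if a.requires_grad:
            ga = np.zeros_like(a.data)
            np.add.at(ga, idx, g)
            a._accumulate(ga)

    return _make(out_data, (a,), backward)


def concat(tensors: Sequence, axis: int = 1) -> Tensor:
    if any(is_probe(t) for t in tensors):
        shapes = [t.shape for t in tensors]
        out = list(shapes[0])
        out[axis] = sum(s[axis] for s in shapes)
        return ShapeProbe(out)
    tensors = [astensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        for t, gp in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(gp)

    return _make(out_data, tuple(tensors), backward)


def gather(a, indices: np.ndarray, axis: int) -> Tensor:
    """take_along_axis with gradient scatter-add."""
    a = astensor(a)
    idx = np.asarray(indices)
    out_data = np.take_along_axis(a.data, idx, axis=axis)

    def backward(g):
        if a.requires_grad:
            ga = np.zeros_like(a.data)
            mesh = list(np.meshgrid(*[np.arange(s) for s in idx.shape],
                                    indexing="ij"))
            mesh[axis] = idx
            np.add.at(ga, tuple(mesh), g)
            a._accumulate(ga)

    return _make(out_data, (a,), backward)


def log_softmax(a, axis: int = -1) -> Tensor:
    a = astensor(a)
    m = a.data.max(axis=axis, keepdims=True)
    z = a.data - m
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out_data = z - lse
    sm = np.exp(out_data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g - sm * g.sum(axis=axis, keepdims=True))

    return _make(out_data, (a,), backward)


def softmax(a, axis: int = -1) -> Tensor:
    return exp(log_softmax(a, axis))


def bce_with_logits(logits, targets) -> Tensor:
    """Elementwise binary cross-entropy on logits (numerically stable);
    `targets` is a constant array in [0, 1]."""
    a = astensor(logits)
    t = np.asarray(targets, dtype=_F32)
    x = a.data
    out_data = np.maximum(x, 0) - x * t + np.log1p(np.exp(-np.abs(x)))
    sig = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * (sig - t))

    return _make(out_data, (a,), backward)


# ---------------------------------------------------------------------------
# spatial ops

def _conv_out(h, p, k, s):
    return (h + 2 * p - k) // s + 1


def conv2d(x, w, b=None, stride: int = 1, padding: int = 0,
           groups: int = 1) -> Tensor:
    """Grouped 2-D cross-correlation, NCHW layout, weight (Cout, Cin/g, KH, KW)."""
    if is_probe(x):
        n, c, h, ww = x.shape
        cout, cg, kh, kw = w.shape if not isinstance(w, Tensor) else w.data.shape
        oh = _conv_out(h, padding, kh, stride)
        ow = _conv_out(ww, padding, kw, stride)
        _count_macs(n * oh * ow * cout * cg * kh * kw)
        return ShapeProbe((n, cout, oh, ow))
    x, w = astensor(x), astensor(w)
    n, c, h, wid = x.shape
    cout, cg, kh, kw = w.shape
    g = groups
    assert c == cg * g, f"channel mismatch: {c} vs {cg}*{g}"
    assert cout % g == 0
    og = cout // g
    s = stride
    oh = _conv_out(h, padding, kh, s)
    ow = _conv_out(wid, padding, kw, s)
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    depthwise = (g == c and cg == 1 and og == 1)

    if depthwise:
        wk = w.data[:, 0]                      # (C, KH, KW)
        out = np.zeros((n, c, oh, ow), dtype=_F32)
        for i in range(kh):
            for j in range(kw):
                xs = xp[:, :, i:i + s * oh:s, j:j + s * ow:s]
                out += xs * wk[None, :, i, j, None, None]
    elif g == 1:
        # im2col + single GEMM
        cols = np.empty((kh * kw, c, n, oh, ow), dtype=_F32)
        for i in range(kh):
            for j in range(kw):
                cols[i * kw + j] = np.moveaxis(
                    xp[:, :, i:i + s * oh:s, j:j + s * ow:s], 0, 1)
        col = cols.reshape(kh * kw * c, n * oh * ow)
        wf = w.data.transpose(2, 3, 1, 0).reshape(kh * kw * c, cout)
        out = (wf.T @ col).reshape(cout, n, oh, ow).transpose(1, 0, 2, 3)
        out = np.ascontiguousarray(out)
    else:
        xpg = xp.reshape(n, g, cg, xp.shape[2], xp.shape[3])
        wg = w.data.reshape(g, og, cg, kh, kw)
        acc = np.zeros((g, n * oh * ow, og), dtype=_F32)
        for i in range(kh):
            for j in range(kw):
                xs = xpg[:, :, :, i:i + s * oh:s, j:j + s * ow:s]
                xs_r = np.moveaxis(xs, 1, 0).reshape(g, n, cg, oh * ow)
                xs_r = np.moveaxis(xs_r, 2, 3).reshape(g, n * oh * ow, cg)
                acc += np.matmul(xs_r, wg[:, :, :, i, j].transpose(0, 2, 1))
        out = acc.reshape(g, n, oh, ow, og)
        out = np.moveaxis(out, (1, 0, 4), (0, 1, 2)).reshape(n, cout, oh, ow)
        out = np.ascontiguousarray(out)

    bt = astensor(b) if b is not None else None
    if bt is not None:
        out = out + bt.data.reshape(1, cout, 1, 1)

    def backward(gr):
        hp, wp = xp.shape[2], xp.shape[3]
        if depthwise:
            wk = w.data[:, 0]
            if w.requires_grad:
                gw = np.zeros_like(w.data)
                for i in range(kh):
                    for j in range(kw):
                        xs = xp[:, :, i:i + s * oh:s, j:j + s * ow:s]
                        gw[:, 0, i, j] = (gr * xs).sum(axis=(0, 2, 3))
                w._accumulate(gw)
            if x.requires_grad:
                gxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        gxp[:, :, i:i + s * oh:s, j:j + s * ow:s] += \
                            gr * wk[None, :, i, j, None, None]
                if padding:
                    gxp = gxp[:, :, padding:-padding, padding:-padding]
                x._accumulate(gxp)
        elif g == 1:
            gr_f = gr.transpose(1, 0, 2, 3).reshape(cout, n * oh * ow)
            if w.requires_grad:
                cols = np.empty((kh * kw, c, n, oh, ow), dtype=_F32)
                for i in range(kh):
                    for j in range(kw):
                        cols[i * kw + j] = np.moveaxis(
                            xp[:, :, i:i + s * oh:s, j:j + s * ow:s], 0, 1)
                col = cols.reshape(kh * kw * c, n * oh * ow)
                gwf = gr_f @ col.T                     # (cout, khkw*c)
                gw = gwf.reshape(cout, kh, kw, c).transpose(0, 3, 1, 2)
                w._accumulate(np.ascontiguousarray(gw))
            if x.requires_grad:
                wf = w.data.transpose(2, 3, 1, 0).reshape(kh * kw * c, cout)
                gcol = (wf @ gr_f).reshape(kh * kw, c, n, oh, ow)
                gxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        gxp[:, :, i:i + s * oh:s, j:j + s * ow:s] += \
                            np.moveaxis(gcol[i * kw + j], 1, 0)
                if padding:
                    gxp = gxp[:, :, padding:-padding, padding:-padding]
                x._accumulate(gxp)
        else:
            xpg = xp.reshape(n, g, cg, hp, wp)
            wg = w.data.reshape(g, og, cg, kh, kw)
            gr_g = gr.reshape(n, g, og, oh, ow)
            gr_r = np.moveaxis(gr_g, 1, 0).reshape(g, n, og, oh * ow)
            gr_r = np.moveaxis(gr_r, 2, 3).reshape(g, n * oh * ow, og)
            if w.requires_grad:
                gw = np.zeros_like(wg)
                for i in range(kh):
                    for j in range(kw):
                        xs = xpg[:, :, :, i:i + s * oh:s, j:j + s * ow:s]
                        xs_r = np.moveaxis(xs, 1, 0).reshape(g, n, cg,
                                                             oh * ow)
                        xs_r = np.moveaxis(xs_r, 2, 3).reshape(
                            g, n * oh * ow, cg)
                        gw[:, :, :, i, j] = np.matmul(
                            gr_r.transpose(0, 2, 1), xs_r)
                w._accumulate(gw.reshape(w.shape))
            if x.requires_grad:
                gxp = np.zeros((n, g, cg, hp, wp), dtype=_F32)
                for i in range(kh):
                    for j in range(kw):
                        gxs = np.matmul(gr_r, wg[:, :, :, i, j])
                        gxs = gxs.reshape(g, n, oh * ow, cg)
                        gxs = np.moveaxis(gxs, 3, 2).reshape(g, n, cg, oh, ow)
                        gxp[:, :, :, i:i + s * oh:s, j:j + s * ow:s] += \
                            np.moveaxis(gxs, 0, 1)
                gxp = gxp.reshape(n, c, hp, wp)
                if padding:
                    gxp = gxp[:, :, padding:-padding, padding:-padding]
                x._accumulate(gxp)
        if bt is not None and bt.requires_grad:
            bt._accumulate(gr.sum(axis=(0, 2, 3)))

    parents = (x, w) if bt is None else (x, w, bt)
    return _make(out, parents, backward)


def max_pool2d(x, kernel: int, stride: int = 1, padding: int | None = None) -> Tensor:
    if padding is None:
        padding = kernel // 2
    if is_probe(x):
        n, c, h, w = x.shape
        return ShapeProbe((n, c, _conv_out(h, padding, kernel, stride),
                           _conv_out(w, padding, kernel, stride)))
    x = astensor(x)
    n, c, h, w = x.shape
    s = stride
    oh = _conv_out(h, padding, kernel, s)
    ow = _conv_out(w, padding, kernel, s)
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                constant_values=-np.inf)
    stacked = np.stack([
        xp[:, :, i:i + s * oh:s, j:j + s * ow:s]
        for i in range(kernel) for j in range(kernel)], axis=0)
    arg = stacked.argmax(axis=0)
    out = np.take_along_axis(stacked, arg[None], axis=0)[0]

    def backward(g):
        if not x.requires_grad:
            return
        gxp = np.zeros_like(xp)
        k = 0
        for i in range(kernel):
            for j in range(kernel):
                mask = (arg == k)
                view = gxp[:, :, i:i + s * oh:s, j:j + s * ow:s]
                view += g * mask
                k += 1
        if padding:
            gxp = gxp[:, :, padding:-padding, padding:-padding]
        x._accumulate(gxp.astype(_F32))

    return _make(out.astype(_F32), (x,), backward)


def upsample_nearest(x, scale: int = 2) -> Tensor:
    if is_probe(x):
        n, c, h, w = x.shape
        return ShapeProbe((n, c, h * scale, w * scale))
    x = astensor(x)
    out_data = x.data.repeat(scale, axis=2).repeat(scale, axis=3)

    def backward(g):
        if x.requires_grad:
            n, c, h, w = x.shape
            g = g.reshape(n, c, h, scale, w, scale).sum(axis=(3, 5))
            x._accumulate(g)

    return _make(out_data, (x,), backward)


def batch_norm(x, gamma, beta, running_mean, running_var, training: bool,
               momentum: float = 0.03, eps: float = 1e-3) -> Tensor:
    """Per-channel batch normalization for NCHW tensors.

    `running_mean`/`running_var` are plain numpy buffers mutated in place
    during training, matching the usual exponential-moving-average scheme.
    """
    if is_probe(x):
        return ShapeProbe(x.shape)
    x = astensor(x)
    gamma, beta = astensor(gamma), astensor(beta)
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean += momentum * (mu - running_mean)
        running_var += momentum * (var - running_var)
    else:
        mu, var = running_mean, running_var
    ivstd = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * ivstd[None, :, None, None]
    out_data = gamma.data[None, :, None, None] * xhat + \
        beta.data[None, :, None, None]

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gs = gamma.data[None, :, None, None]
            if training:
                m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
                dxhat = g * gs
                term1 = dxhat
                term2 = dxhat.mean(axis=(0, 2, 3), keepdims=True)
                term3 = xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
                gx = (term1 - term2 - term3) * ivstd[None, :, None, None]
                del m
            else:
                gx = g * gs * ivstd[None, :, None, None]
            x._accumulate(gx.astype(_F32))

    return _make(out_data, (x, gamma, beta), backward)
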