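"""Reverse-mode automatic differentiation over NumPy arrays.

A small tape-based tensor engine providing exactly the operations the
segmentation models need: elementwise arithmetic, matrix products, 2D
convolution and pooling, shape manipulation, and the reductions required
for softmax and normalisation layers.  Gradients are accumulated by
walking the recorded graph in reverse topological order.

All arrays follow NumPy broadcasting; gradients of broadcast operands are
summed back to the operand's shape.  Convolutions use NCHW layout with
stride 1, which is all the encoder--decoder backbone requires.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """An n-d array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward

    # -- properties ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    # -- autodiff driver ----------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient "
                                 "requires a scalar output")
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad)

        # iterative topological sort
        topo, visited, stack = [], set(), [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in visited:
                    stack.append((p, False))

        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, g: np.ndarray):
        # gradients are never mutated in place, so storing a reference is safe
        if self.grad is None:
            self.grad = np.asarray(g)
        else:
            self.grad = self.grad + g

    # -- operator sugar -----------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        if isinstance(other, Tensor):
            return add(self, mul(other, -1.0))
        return add(self, -other if isinstance(other, (int, float)) else -np.asarray(other))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, power(other, -1.0))
        if isinstance(other, (int, float)):
            return mul(self, 1.0 / other)
        return mul(self, 1.0 / np.asarray(other))

    def __rtruediv__(self, other):
        return mul(power(self, -1.0), other)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    # -- method sugar --------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, axes):
        return transpose(self, axes)

    def exp(self):
        return exp(self)

    def log(self):
        return log(self)

    def relu(self):
        return relu(self)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _make(data, parents, backward) -> Tensor:
    req = any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req,
                  _parents=parents if req else (),
                  _backward=backward if req else None)


# ---------------------------------------------------------------------
# elementwise
# ---------------------------------------------------------------------

def add(a, b) -> Tensor:
    if not isinstance(a, Tensor):
        a, b = b, a
    if isinstance(b, (int, float)):  # scalar path: avoids dtype promotion
        out_data = a.data + b

        def backward_scalar(g):
            if a.requires_grad:
                a._accumulate(g)

        return _make(out_data, (a,), backward_scalar)
    a, b = astensor(a), astensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    if not isinstance(a, Tensor):
        a, b = b, a
    if isinstance(b, (int, float)):  # scalar path: avoids dtype promotion
        out_data = a.data * b

        def backward_scalar(g):
            if a.requires_grad:
                a._accumulate(g * b)

        return _make(out_data, (a,), backward_scalar)
    a, b = astensor(a), astensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    return _make(out_data, (a, b), backward)


def power(a, exponent: float) -> Tensor:
    a = astensor(a)
    out_data = a.data ** exponent

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * exponent * a.data ** (exponent - 1.0))

    return _make(out_data, (a,), backward)


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


def sqrt(a) -> Tensor:
    return power(a, 0.5)


def relu(a) -> Tensor:
    a = astensor(a)
    mask = a.data > 0
    out_data = a.data * mask

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * mask)

    return _make(out_data, (a,), backward)


def clip(a, lo: float, hi: float) -> Tensor:
    """Clamp values to [lo, hi]; gradient passes only inside the range."""
    a = astensor(a)
    out_data = np.clip(a.data, lo, hi)
    mask = (a.data >= lo) & (a.data <= hi)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * mask)

    return _make(out_data, (a,), backward)


# ---------------------------------------------------------------------
# linear algebra
# ---------------------------------------------------------------------

def matmul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accumulate(_unbroadcast(ga, a.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accumulate(_unbroadcast(gb, b.shape))

    return _make(out_data, (a, b), backward)


def edge_message(m, q, transpose: bool = False) -> Tensor:
    """Contract an edge-matrix field with a label distribution.

    ``m``: (..., K, K), ``q``: (..., K).  With ``transpose=False`` returns
    ``out_a = sum_b m[a, b] q_b`` (the sender sits on the matrix columns);
    with ``transpose=True`` returns ``out_b = sum_a m[a, b] q_a``.
    A fused primitive because this runs twice per direction per mean-field
    iteration.
    """
    m, q = astensor(m), astensor(q)
    if transpose:
        out_data = np.einsum("...ab,...a->...b", m.data, q.data)
    else:
        out_data = np.einsum("...ab,...b->...a", m.data, q.data)

    def backward(g):
        if m.requires_grad:
            if transpose:
                m._accumulate(np.einsum("...a,...b->...ab", q.data, g))
            else:
                m._accumulate(np.einsum("...a,...b->...ab", g, q.data))
        if q.requires_grad:
            if transpose:
                q._accumulate(np.einsum("...ab,...b->...a", m.data, g))
            else:
                q._accumulate(np.einsum("...ab,...a->...b", m.data, g))

    return _make(out_data, (m, q), backward)


# ---------------------------------------------------------------------
# reductions
# ---------------------------------------------------------------------

def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = astensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if not a.requires_grad:
            return
        g = np.asarray(g)
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.shape).copy())
            return
        if not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            axes = tuple(ax % a.ndim for ax in axes)
            g = np.expand_dims(g, tuple(sorted(axes)))
        a._accumulate(np.broadcast_to(g, a.shape).copy())

    return _make(out_data, (a,), backward)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = astensor(a)
    if axis is None:
        n = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = 1
        for ax in axes:
            n *= a.shape[ax % a.ndim]
    return tsum(a, axis=axis, keepdims=keepdims) * (1.0 / n)


# ---------------------------------------------------------------------
# shape manipulation
# ---------------------------------------------------------------------

def reshape(a, shape) -> Tensor:
    a = astensor(a)
    in_shape = a.shape
    out_data = a.data.reshape(shape)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.reshape(in_shape))

    return _make(out_data, (a,), backward)


def transpose(a, axes) -> Tensor:
    a = astensor(a)
    out_data = a.data.transpose(axes)
    inv = np.argsort(axes)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.transpose(inv))

    return _make(out_data, (a,), backward)


def getitem(a, idx) -> Tensor:
    a = astensor(a)
    out_data = a.data[idx]
    parts = idx if isinstance(idx, tuple) else (idx,)
    basic = all(isinstance(p, (slice, int)) or p is Ellipsis for p in parts)

    def backward(g):
        if a.requires_grad:
            full = np.zeros(a.shape, dtype=g.dtype)
            if basic:  # no index can repeat: plain assignment is safe and fast
                full[idx] = g
            else:
                np.add.at(full, idx, g)
            a._accumulate(full)

    return _make(out_data, (a,), backward)


def pad(a, pad_width) -> Tensor:
    """Zero-pad; ``pad_width`` is a per-axis (before, after) sequence."""
    a = astensor(a)
    out_data = np.pad(a.data, pad_width)
    slices = tuple(slice(b, b + s) for (b, _), s in zip(pad_width, a.shape))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g[slices])

    return _make(out_data, (a,), backward)


def concat(tensors, axis: int) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return _make(out_data, tuple(tensors), backward)


# ---------------------------------------------------------------------
# image ops (NHWC, stride 1)
# ---------------------------------------------------------------------

def conv2d(x, weight, bias=None, padding: int = 1) -> Tensor:
    """2D cross-correlation, stride 1.  x: (N,H,W,C); weight: (k,k,C,O).

    Implemented as a single GEMM over the zero-padded input against the
    kernel taps stacked along the output axis, followed by shifted
    accumulation -- this avoids materialising im2col patch copies, which
    dominate the runtime of small convolutions.
    """
    x, weight = astensor(x), astensor(weight)
    bias = astensor(bias) if bias is not None else None
    k, _, c_in, c_out = weight.shape
    p = padding
    xpad = np.pad(x.data, ((0, 0), (p, p), (p, p), (0, 0)))
    n, hp, wp, _ = xpad.shape
    oh, ow = hp - k + 1, wp - k + 1
    flat = xpad.reshape(-1, c_in)
    wcat = weight.data.reshape(k * k, c_in, c_out) \
        .transpose(1, 0, 2).reshape(c_in, k * k * c_out)
    z = (flat @ wcat).reshape(n, hp, wp, k * k, c_out)
    if bias is not None:
        out = np.broadcast_to(bias.data, (n, oh, ow, c_out)).copy()
    else:
        out = np.zeros((n, oh, ow, c_out), dtype=z.dtype)
    tap = 0
    for di in range(k):
        for dj in range(k):
            out += z[:, di:di + oh, dj:dj + ow, tap]
            tap += 1

    def backward(g):
        g2 = np.ascontiguousarray(g).reshape(-1, c_out)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g2.sum(axis=0))
        if weight.requires_grad:
            dw = np.empty((k * k, c_in, c_out), dtype=g.dtype)
            tap = 0
            for di in range(k):
                for dj in range(k):
                    xv = xpad[:, di:di + oh, dj:dj + ow, :].reshape(-1, c_in)
                    dw[tap] = xv.T @ g2
                    tap += 1
            weight._accumulate(dw.reshape(weight.shape))
        if x.requires_grad:
            wcat2 = weight.data.reshape(k * k, c_in, c_out) \
                .transpose(2, 0, 1).reshape(c_out, k * k * c_in)
            taps = (g2 @ wcat2).reshape(n, oh, ow, k * k, c_in)
            dxpad = np.zeros((n, hp, wp, c_in), dtype=g.dtype)
            tap = 0
            for di in range(k):
                for dj in range(k):
                    dxpad[:, di:di + oh, dj:dj + ow, :] += taps[:, :, :, tap]
                    tap += 1
            x._accumulate(dxpad[:, p:hp - p, p:wp - p, :] if p else dxpad)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return _make(out, parents, backward)


def instance_norm2d(x, gamma, beta, eps: float = 1e-5) -> Tensor:
    """Fused per-sample, per-channel spatial normalisation (NHWC).

    Equivalent to composing mean/variance primitives but with a single
    hand-derived backward pass, which matters because normalisation sits
    after every convolution.
    """
    x, gamma, beta = astensor(x), astensor(gamma), astensor(beta)
    mu = x.data.mean(axis=(1, 2), keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=(1, 2), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out_data = xhat * gamma.data + beta.data

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 1, 2)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 1, 2)))
        if x.requires_grad:
            dxhat = g * gamma.data
            m1 = dxhat.mean(axis=(1, 2), keepdims=True)
            m2 = (dxhat * xhat).mean(axis=(1, 2), keepdims=True)
            x._accumulate(inv * (dxhat - m1 - xhat * m2))

    return _make(out_data, (x, gamma, beta), backward)


def avg_pool2d(x) -> Tensor:
    """2x2 average pooling with stride 2 (NHWC)."""
    x = astensor(x)
    n, h, w, c = x.shape
    if h % 2 or w % 2:
        raise ValueError("avg_pool2d requires even spatial dimensions")
    out_data = x.data.reshape(n, h // 2, 2, w // 2, 2, c).mean(axis=(2, 4))

    def backward(g):
        if x.requires_grad:
            gx = np.repeat(np.repeat(g, 2, axis=1), 2, axis=2) * 0.25
            x._accumulate(gx)

    return _make(out_data, (x,), backward)


def upsample_nearest2(x) -> Tensor:
    """Nearest-neighbour 2x upsampling of an NHWC tensor."""
    x = astensor(x)
    out_data = np.repeat(np.repeat(x.data, 2, axis=1), 2, axis=2)

    def backward(g):
        if x.requires_grad:
            n, h, w, c = g.shape
            gx = g.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))
            x._accumulate(gx)

    return _make(out_data, (x,), backward)


# ---------------------------------------------------------------------
# composed helpers
# ---------------------------------------------------------------------

def softmax(x, axis: int = -1) -> Tensor:
    """Fused, max-shifted softmax along ``axis``."""
    x = astensor(x)
    e = np.exp(x.data - x.data.max(axis=axis, keepdims=True))
    y = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if x.requires_grad:
            x._accumulate(y * (g - (g * y).sum(axis=axis, keepdims=True)))

    return _make(y, (x,), backward)


def log_softmax(x, axis: int = -1) -> Tensor:
    """Fused, max-shifted log-softmax along ``axis``."""
    x = astensor(x)
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out = shifted - lse

    def backward(g):
        if x.requires_grad:
            x._accumulate(g - np.exp(out) * g.sum(axis=axis, keepdims=True))

    return _make(out, (x,), backward)
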