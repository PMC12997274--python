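"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine sufficient for training the message-passing
quantile network: dense layers, tanh/relu nonlinearities, gather /
segment-sum for graph message passing, and the fused asymmetric Huber
primitive used by the quantile loss.  Gradients are accumulated by
topological traversal of the recorded graph.

Every public function accepts either a :class:`Tensor` or a plain
``numpy`` array; with arrays it computes the forward value only, so the
loss functions in :mod:`dp5q.losses` can be written once and used both
for training (differentiably) and for plain evaluation.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add",
    "mul",
    "matmul",
    "tanh",
    "relu",
    "gather",
    "segment_sum",
    "quantile_huber",
    "huber_value",
    "mean",
    "total_sum",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over axes that were broadcast from `shape`."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient tape."""

    __slots__ = ("v", "grad", "_parents", "_bw", "requires_grad")

    def __init__(self, value, requires_grad: bool = False, _parents=(), _bw=None):
        self.v = np.asarray(value, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._bw = _bw

    @property
    def shape(self):
        return self.v.shape

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.v.shape}, requires_grad={self.requires_grad})"

    # --- operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return _slice(self, idx)

    # --- backward -------------------------------------------------------
    def backward(self):
        if self.v.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
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
        self.grad = np.ones_like(self.v)
        for node in reversed(topo):
            if node._bw is not None and node.grad is not None:
                node._bw(node.grad)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _is_tensor(*xs) -> bool:
    return any(isinstance(x, Tensor) for x in xs)


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = np.zeros_like(t.v)
    t.grad += g


# --------------------------------------------------------------------------
# primitives
# --------------------------------------------------------------------------

def add(a, b):
    if not _is_tensor(a, b):
        return np.add(a, b)
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.v + b.v, _parents=(a, b))

    def bw(g):
        _accum(a, _unbroadcast(g, a.v.shape))
        _accum(b, _unbroadcast(g, b.v.shape))

    out._bw = bw
    return out


def mul(a, b):
    if not _is_tensor(a, b):
        return np.multiply(a, b)
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.v * b.v, _parents=(a, b))

    def bw(g):
        _accum(a, _unbroadcast(g * b.v, a.v.shape))
        _accum(b, _unbroadcast(g * a.v, b.v.shape))

    out._bw = bw
    return out


def matmul(a, b):
    if not _is_tensor(a, b):
        return np.matmul(a, b)
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.v @ b.v, _parents=(a, b))

    def bw(g):
        _accum(a, g @ b.v.T)
        _accum(b, a.v.T @ g)

    out._bw = bw
    return out


def tanh(a):
    if not _is_tensor(a):
        return np.tanh(a)
    tv = np.tanh(a.v)
    out = Tensor(tv, _parents=(a,))

    # capture the value array, not the Tensor: a closure holding `out`
    # would create a reference cycle and delay freeing the tape
    def bw(g):
        _accum(a, g * (1.0 - tv**2))

    out._bw = bw
    return out


def relu(a):
    if not _is_tensor(a):
        return np.maximum(a, 0.0)
    out = Tensor(np.maximum(a.v, 0.0), _parents=(a,))

    def bw(g):
        _accum(a, g * (a.v > 0.0))

    out._bw = bw
    return out


def _slice(a, idx):
    if not _is_tensor(a):
        return np.asarray(a)[idx]
    out = Tensor(a.v[idx], _parents=(a,))

    def bw(g):
        if a.requires_grad:
            full = np.zeros_like(a.v)
            np.add.at(full, idx, g)
            _accum(a, full)

    out._bw = bw
    return out


def gather(a, rows):
    """Select rows of a 2-D tensor; gradient scatters back."""
    rows = np.asarray(rows)
    if not _is_tensor(a):
        return np.asarray(a)[rows]
    out = Tensor(a.v[rows], _parents=(a,))

    def bw(g):
        if a.requires_grad:
            full = np.zeros_like(a.v)
            np.add.at(full, rows, g)
            _accum(a, full)

    out._bw = bw
    return out


def segment_sum(a, starts, n_segments: int):
    """Sum contiguous row blocks of `a`.

    `starts[k]` is the first row of segment `k`; rows must already be
    grouped by segment (the featuriser sorts edges by destination so the
    per-node message aggregation is a single ``reduceat``).  Empty
    segments are allowed and yield zero rows.
    """
    starts = np.asarray(starts)

    def fwd(v):
        n = v.shape[0]
        out = np.zeros((n_segments,) + v.shape[1:], dtype=np.float64)
        if n == 0:
            return out
        # trailing segments starting at n are empty; reduceat rejects
        # index == len, so only the leading starts are reduced
        head = starts[starts < n]
        if head.size:
            out[: head.size] = np.add.reduceat(v, head, axis=0)
            # reduceat yields v[start] for zero-length segments: zero them
            empty = np.flatnonzero(np.diff(np.append(head, n)) == 0)
            if empty.size:
                out[empty] = 0.0
        return out

    if not _is_tensor(a):
        return fwd(np.asarray(a))
    out = Tensor(fwd(a.v), _parents=(a,))
    lengths = np.diff(np.append(starts, a.v.shape[0]))
    seg_of_row = np.repeat(np.arange(n_segments), lengths)

    def bw(g):
        _accum(a, g[seg_of_row])

    out._bw = bw
    return out


def huber_value(r, delta: float):
    """Smoothed absolute error: r^2/(2*delta) inside |r| <= delta, |r| - delta/2 outside."""
    r = np.asarray(r, dtype=np.float64)
    a = np.abs(r)
    return np.where(a <= delta, r * r / (2.0 * delta), a - delta / 2.0)


def quantile_huber(residual, tau, delta: float):
    """Fused asymmetric Huber term: ``w(r) * huber(r)``.

    `residual` is observed minus predicted; the weight is ``tau`` for
    under-prediction (positive residual) and ``1 - tau`` for
    over-prediction.  The derivative w.r.t. the residual,
    ``w(r) * clip(r/delta, -1, 1)``, is continuous at zero because the
    Huber slope vanishes there.
    """
    tau = np.asarray(tau, dtype=np.float64)

    def weight(rv):
        return np.where(rv > 0, tau, 1.0 - tau)

    if not _is_tensor(residual):
        rv = np.asarray(residual, dtype=np.float64)
        return weight(rv) * huber_value(rv, delta)

    r = residual
    w = weight(r.v)
    out = Tensor(w * huber_value(r.v, delta), _parents=(r,))

    def bw(g):
        _accum(r, g * w * np.clip(r.v / delta, -1.0, 1.0))

    out._bw = bw
    return out


def total_sum(a, axis=None):
    if not _is_tensor(a):
        return np.sum(a, axis=axis)
    out = Tensor(np.sum(a.v, axis=axis, keepdims=False), _parents=(a,))

    def bw(g):
        if axis is None:
            _accum(a, np.broadcast_to(g, a.v.shape).copy())
        else:
            _accum(a, np.broadcast_to(np.expand_dims(g, axis), a.v.shape).copy())

    out._bw = bw
    return out


def mean(a, axis=None):
    if not _is_tensor(a):
        return np.mean(a, axis=axis)
    n = a.v.size if axis is None else a.v.shape[axis]
    return mul(total_sum(a, axis=axis), 1.0 / n)
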