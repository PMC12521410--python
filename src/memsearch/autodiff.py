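"""A small reverse-mode automatic differentiation core on numpy arrays.

Just enough machinery for the recurrent models in this package: broadcasting
elementwise arithmetic, matmul, tanh/sigmoid/exp/log, softmax/log-softmax,
concatenation, slicing/gather, reductions, and elementwise min/clip (for the
clipped policy-gradient surrogate).  Gradients are accumulated by a
topological-order backward sweep from a scalar root.

Arrays are float64 throughout; determinism follows from numpy's.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np

Array = np.ndarray


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Array | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[Array], tuple[Array, ...]] | None = None

    # -- construction helpers -------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- autograd plumbing ----------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar root")
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._backward(node.grad)):
                if g is None or not parent.requires_grad:
                    continue  # constant leaves need no gradient
                if parent.grad is None:
                    parent.grad = g.copy()
                else:
                    parent.grad += g

    # -- operators -------------------------------------------------------
    def __add__(self, other):
        return add(self, as_tensor(other))

    __radd__ = __add__

    def __sub__(self, other):
        return add(self, neg(as_tensor(other)))

    def __rsub__(self, other):
        return add(as_tensor(other), neg(self))

    def __neg__(self):
        return neg(self)

    def __mul__(self, other):
        return mul(self, as_tensor(other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return mul(self, power(other, -1.0))

    def __matmul__(self, other):
        return matmul(self, as_tensor(other))

    def __getitem__(self, key):
        return getitem(self, key)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


_grad_enabled = True


class no_grad:
    """Context manager suppressing graph construction (cheap rollouts)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _make(data: Array, parents: tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(data)
    if _grad_enabled and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = parents
        out._backward = backward
    return out


# -- elementwise ---------------------------------------------------------


def add(a: Tensor, b: Tensor) -> Tensor:
    data = a.data + b.data
    return _make(
        data,
        (a, b),
        lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)),
    )


def neg(a: Tensor) -> Tensor:
    return _make(-a.data, (a,), lambda g: (-g,))


def mul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data * b.data
    return _make(
        data,
        (a, b),
        lambda g: (
            _unbroadcast(g * b.data, a.shape),
            _unbroadcast(g * a.data, b.shape),
        ),
    )


def power(a: Tensor, p: float) -> Tensor:
    data = a.data**p
    return _make(data, (a,), lambda g: (g * p * a.data ** (p - 1.0),))


def tanh(a: Tensor) -> Tensor:
    data = np.tanh(a.data)
    return _make(data, (a,), lambda g: (g * (1.0 - data * data),))


def sigmoid(a: Tensor) -> Tensor:
    data = 1.0 / (1.0 + np.exp(-a.data))
    return _make(data, (a,), lambda g: (g * data * (1.0 - data),))


def exp(a: Tensor) -> Tensor:
    data = np.exp(a.data)
    return _make(data, (a,), lambda g: (g * data,))


def log(a: Tensor) -> Tensor:
    return _make(np.log(a.data), (a,), lambda g: (g / a.data,))


def minimum(a: Tensor, b: Tensor) -> Tensor:
    data = np.minimum(a.data, b.data)
    mask = a.data <= b.data
    return _make(
        data,
        (a, b),
        lambda g: (
            _unbroadcast(g * mask, a.shape),
            _unbroadcast(g * ~mask, b.shape),
        ),
    )


def clip(a: Tensor, lo: float, hi: float) -> Tensor:
    data = np.clip(a.data, lo, hi)
    inside = (a.data >= lo) & (a.data <= hi)
    return _make(data, (a,), lambda g: (g * inside,))


# -- linear algebra ------------------------------------------------------


def matmul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data @ b.data

    def backward(g: Array):
        if a.ndim == 1 and b.ndim == 2:
            return g @ b.data.T, np.outer(a.data, g)
        if a.ndim == 2 and b.ndim == 1:
            return np.outer(g, b.data), a.data.T @ g
        return g @ b.data.swapaxes(-1, -2), a.data.swapaxes(-1, -2) @ g

    return _make(data, (a, b), backward)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g: Array):
        return tuple(np.split(g, splits, axis=axis))

    return _make(data, tuple(tensors), backward)


def getitem(a: Tensor, key) -> Tensor:
    data = a.data[key]

    def backward(g: Array):
        out = np.zeros_like(a.data)
        np.add.at(out, key, g)
        return (out,)

    return _make(data, (a,), backward)


def gather_rows(a: Tensor, idx: Array) -> Tensor:
    """Select a[i, idx[i]] for each row i -> shape (B,)."""
    rows = np.arange(a.shape[0])
    return getitem(a, (rows, np.asarray(idx)))


def reshape(a: Tensor, shape: tuple[int, ...]) -> Tensor:
    return _make(a.data.reshape(shape), (a,), lambda g: (g.reshape(a.shape),))


def transpose(a: Tensor) -> Tensor:
    return _make(a.data.T, (a,), lambda g: (g.T,))


def stack_cols(tensors: list[Tensor]) -> Tensor:
    """Stack a list of (B,) tensors into (B, L)."""
    cols = [reshape(t, (t.shape[0], 1)) for t in tensors]
    return concat(cols, axis=1)


def scatter_set_cols(base: Tensor, idx: Array, vals: Tensor) -> Tensor:
    """out[i, idx[i, j]] = vals[i, j]; other entries copied from ``base``.

    Used to overwrite studied items' logits with pointer (context-match)
    scores while leaving off-list logits to the output embeddings.  Columns
    within a row must be distinct.
    """
    idx = np.asarray(idx)
    rows = np.arange(base.shape[0])[:, None]
    data = base.data.copy()
    data[rows, idx] = vals.data

    def backward(g: Array):
        g_base = g.copy()
        g_base[rows, idx] = 0.0
        return g_base, g[rows, idx]

    return _make(data, (base, vals), backward)


def scatter_add_cols(base: Tensor, idx: Array, vals: Tensor) -> Tensor:
    """base[i, idx[i, j]] += vals[i, j] (fresh output; idx is constant).

    Used to add pointer scores over studied positions onto full-vocabulary
    logits.  Columns hit twice in one row accumulate.
    """
    idx = np.asarray(idx)
    rows = np.arange(base.shape[0])[:, None]
    data = base.data.copy()
    np.add.at(data, (rows, idx), vals.data)

    def backward(g: Array):
        return g, g[rows, idx]

    return _make(data, (base, vals), backward)


# -- reductions ----------------------------------------------------------


def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g: Array):
        if axis is None:
            return (np.broadcast_to(g, a.shape).copy(),)
        g2 = g if keepdims else np.expand_dims(g, axis)
        return (np.broadcast_to(g2, a.shape).copy(),)

    return _make(data, (a,), backward)


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    n = a.data.size if axis is None else a.data.shape[axis]
    return tsum(a, axis=axis, keepdims=keepdims) * (1.0 / n)


# -- softmax family ------------------------------------------------------


def log_softmax(a: Tensor, axis: int = -1) -> Tensor:
    m = a.data.max(axis=axis, keepdims=True)
    shifted = a.data - m
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    data = shifted - lse
    sm = np.exp(data)

    def backward(g: Array):
        return (g - sm * g.sum(axis=axis, keepdims=True),)

    return _make(data, (a,), backward)


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    return exp(log_softmax(a, axis=axis))


# -- parameters ----------------------------------------------------------


def parameter(data: Array) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


def zero_grads(params: Iterable[Tensor]) -> None:
    for p in params:
        p.grad = None
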