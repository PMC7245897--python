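"""A small reverse-mode automatic-differentiation engine over numpy arrays.

Just enough machinery to train the recurrent networks in this package on a
CPU: broadcasting elementwise arithmetic, matrix products, the usual
saturating nonlinearities, reductions, concatenation/stacking, gather
operations for label indexing, and two batched contractions against constant
memory banks (used by the knowledge-base attention, whose memory vectors are
fixed embeddings and receive no gradient).

Gradients are accumulated by a topological-order sweep over the recorded
operation graph.  Everything is float64; the models here are small enough
that precision is worth more than speed.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence

import numpy as np

Array = np.ndarray


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum a gradient down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Optional[Callable[[Array], None]] = None,
    ) -> None:
        self.data = np.asarray(data, dtype=float)
        self.grad: Optional[Array] = None
        self.requires_grad = requires_grad
        self._parents = _parents
        self._backward = _backward

    # -- helpers ----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, g: Array) -> None:
        g = _unbroadcast(np.asarray(g, dtype=float), self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = _op(
            np.add(self.data, other.data),
            (self, other),
            lambda g: (self._accumulate(g), other._accumulate(g)),
        )
        return out

    __radd__ = __add__

    def __neg__(self):
        return _op(-self.data, (self,), lambda g: self._accumulate(-g))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        return _op(
            self.data * other.data,
            (self, other),
            lambda g: (
                self._accumulate(g * other.data),
                other._accumulate(g * self.data),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return _op(
            self.data / other.data,
            (self, other),
            lambda g: (
                self._accumulate(g / other.data),
                other._accumulate(-g * self.data / other.data**2),
            ),
        )

    def __matmul__(self, other):
        other = as_tensor(other)
        a, b = self.data, other.data

        def backward(g: Array) -> None:
            if a.ndim == 1 and b.ndim == 2:
                self._accumulate(g @ b.T)
                other._accumulate(np.outer(a, g))
            elif a.ndim == 2 and b.ndim == 2:
                self._accumulate(g @ b.T)
                other._accumulate(a.T @ g)
            elif a.ndim == 2 and b.ndim == 1:
                self._accumulate(np.outer(g, b))
                other._accumulate(a.T @ g)
            elif a.ndim == 1 and b.ndim == 1:
                self._accumulate(g * b)
                other._accumulate(g * a)
            else:  # pragma: no cover - not used
                raise NotImplementedError

        return _op(a @ b, (self, other), backward)

    # -- shape ------------------------------------------------------------
    def reshape(self, *shape):
        orig = self.data.shape
        return _op(
            self.data.reshape(*shape),
            (self,),
            lambda g: self._accumulate(g.reshape(orig)),
        )

    def __getitem__(self, idx):
        def backward(g: Array) -> None:
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        return _op(self.data[idx], (self,), backward)

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g: Array) -> None:
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape))
            else:
                g2 = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g2, self.data.shape))

        return _op(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- autograd ---------------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        order: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            order.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(order):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _op(data: Array, parents: tuple[Tensor, ...], backward) -> Tensor:
    track = any(p.requires_grad or p._parents for p in parents)
    return Tensor(
        data,
        _parents=tuple(p for p in parents) if track else (),
        _backward=backward if track else None,
    )


# ---------------------------------------------------------------------------
# functions
# ---------------------------------------------------------------------------

def tanh(x: Tensor) -> Tensor:
    y = np.tanh(x.data)
    return _op(y, (x,), lambda g: x._accumulate(g * (1.0 - y**2)))


def sigmoid(x: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))
    return _op(y, (x,), lambda g: x._accumulate(g * y * (1.0 - y)))


def exp(x: Tensor) -> Tensor:
    y = np.exp(x.data)
    return _op(y, (x,), lambda g: x._accumulate(g * y))


def log(x: Tensor) -> Tensor:
    return _op(np.log(x.data), (x,), lambda g: x._accumulate(g / x.data))


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g: Array) -> None:
        for t, s, e in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(s, e)
            t._accumulate(g[tuple(sl)])

    return _op(
        np.concatenate([t.data for t in tensors], axis=axis),
        tuple(tensors),
        backward,
    )


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]

    def backward(g: Array) -> None:
        for i, t in enumerate(tensors):
            t._accumulate(np.take(g, i, axis=axis))

    return _op(
        np.stack([t.data for t in tensors], axis=axis), tuple(tensors), backward
    )


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax (max-subtraction; shift is a constant)."""
    shift = x.data.max(axis=axis, keepdims=True)
    e = exp(x - Tensor(shift))
    return e / e.sum(axis=axis, keepdims=True)


def logsumexp(x: Tensor, axis: int = -1, keepdims: bool = False) -> Tensor:
    shift = x.data.max(axis=axis, keepdims=True)
    out = log(exp(x - Tensor(shift)).sum(axis=axis, keepdims=True)) + Tensor(shift)
    if not keepdims:
        out = out.reshape(np.squeeze(out.data, axis=axis).shape)
    return out


def take_rows(x: Tensor, idx: Array) -> Tensor:
    """``x[arange(B), idx]`` for a (B, C) tensor; used to gather gold logits."""
    rows = np.arange(x.data.shape[0])

    def backward(g: Array) -> None:
        full = np.zeros_like(x.data)
        np.add.at(full, (rows, idx), g)
        x._accumulate(full)

    return _op(x.data[rows, idx], (x,), backward)


def gather(x: Tensor, idx: tuple[Array, ...]) -> Tensor:
    """Advanced-index gather ``x[idx]`` with scatter-add backward."""

    def backward(g: Array) -> None:
        full = np.zeros_like(x.data)
        np.add.at(full, idx, g)
        x._accumulate(full)

    return _op(x.data[idx], (x,), backward)


def memory_scores(memory: Array, query: Tensor) -> Tensor:
    """Batched dot products against a constant memory bank.

    memory: (B, M, D) constant; query: (B, D) -> scores (B, M).
    """

    def backward(g: Array) -> None:
        query._accumulate(np.einsum("bmd,bm->bd", memory, g))

    return _op(np.einsum("bmd,bd->bm", memory, query.data), (query,), backward)


def memory_combine(weights: Tensor, memory: Array) -> Tensor:
    """Convex combination of constant memory rows.

    weights: (B, M); memory: (B, M, D) constant -> (B, D).
    """

    def backward(g: Array) -> None:
        weights._accumulate(np.einsum("bd,bmd->bm", g, memory))

    return _op(
        np.einsum("bm,bmd->bd", weights.data, memory), (weights,), backward
    )


def cross_entropy(logits: Tensor, labels: Array) -> Tensor:
    """Mean negative log-likelihood of integer ``labels`` under softmax logits."""
    logz = logsumexp(logits, axis=1)
    gold = take_rows(logits, np.asarray(labels))
    return (logz - gold).mean()
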