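"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the operations the condition-prediction model needs:
broadcast arithmetic, (batched) matrix multiplication, softmax /
log-softmax, embedding gather, reductions, reshapes, and concatenation.
Gradients are accumulated by topological traversal of the operation
graph.  All computation is on plain ``numpy.ndarray``s, so runs are
bit-reproducible for a fixed seed on one device.
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional, Sequence

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra > 0:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        backward: Optional[Callable[[np.ndarray], None]] = None,
    ):
        self.data = np.asarray(data)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._parents = tuple(parents)
        self._backward = backward

    # -- graph -------------------------------------------------------------
    def backward(self, grad: Optional[np.ndarray] = None) -> None:
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
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- helpers -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> np.ndarray:
        return self.data

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(_wrap(other), -1.0))

    def __rsub__(self, other):
        return add(_wrap(other), mul(self, -1.0))

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, power(other, -1.0))
        return mul(self, 1.0 / np.asarray(other))

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _make(data, parents, backward, requires) -> Tensor:
    if not requires:
        return Tensor(data)
    return Tensor(data, requires_grad=True, parents=parents, backward=backward)


# ---------------------------------------------------------------------------
# primitive operations
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data + b.data
    req = a.requires_grad or b.requires_grad
    parents = tuple(t for t in (a, b) if t.requires_grad)

    def backward(grad):
        if a.requires_grad:
            a.accumulate(_unbroadcast(grad, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(grad, b.data.shape))

    return _make(out_data, parents, backward, req)


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data * b.data
    req = a.requires_grad or b.requires_grad
    parents = tuple(t for t in (a, b) if t.requires_grad)

    def backward(grad):
        if a.requires_grad:
            a.accumulate(_unbroadcast(grad * b.data, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(grad * a.data, b.data.shape))

    return _make(out_data, parents, backward, req)


def power(a, exponent: float) -> Tensor:
    a = _wrap(a)
    out_data = a.data ** exponent

    def backward(grad):
        a.accumulate(grad * exponent * a.data ** (exponent - 1.0))

    return _make(out_data, (a,), backward, a.requires_grad)


def matmul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = np.matmul(a.data, b.data)
    req = a.requires_grad or b.requires_grad
    parents = tuple(t for t in (a, b) if t.requires_grad)

    def backward(grad):
        if a.requires_grad:
            ga = np.matmul(grad, np.swapaxes(b.data, -1, -2))
            a.accumulate(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.matmul(np.swapaxes(a.data, -1, -2), grad)
            b.accumulate(_unbroadcast(gb, b.data.shape))

    return _make(out_data, parents, backward, req)


def exp(a) -> Tensor:
    a = _wrap(a)
    out_data = np.exp(a.data)

    def backward(grad):
        a.accumulate(grad * out_data)

    return _make(out_data, (a,), backward, a.requires_grad)


def log(a) -> Tensor:
    a = _wrap(a)
    out_data = np.log(a.data)

    def backward(grad):
        a.accumulate(grad / a.data)

    return _make(out_data, (a,), backward, a.requires_grad)


def tanh(a) -> Tensor:
    a = _wrap(a)
    out_data = np.tanh(a.data)

    def backward(grad):
        a.accumulate(grad * (1.0 - out_data**2))

    return _make(out_data, (a,), backward, a.requires_grad)


def relu(a) -> Tensor:
    a = _wrap(a)
    out_data = np.maximum(a.data, 0.0)

    def backward(grad):
        a.accumulate(grad * (a.data > 0))

    return _make(out_data, (a,), backward, a.requires_grad)


def sqrt(a) -> Tensor:
    return power(a, 0.5)


def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _wrap(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(grad):
        g = grad
        if not keepdims and axis is not None:
            g = np.expand_dims(g, axis)
        a.accumulate(np.broadcast_to(g, a.data.shape).copy())

    return _make(out_data, (a,), backward, a.requires_grad)


def tmean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _wrap(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def reshape(a, shape) -> Tensor:
    a = _wrap(a)
    out_data = a.data.reshape(shape)

    def backward(grad):
        a.accumulate(grad.reshape(a.data.shape))

    return _make(out_data, (a,), backward, a.requires_grad)


def transpose(a, axes) -> Tensor:
    a = _wrap(a)
    out_data = a.data.transpose(axes)
    inv = np.argsort(axes)

    def backward(grad):
        a.accumulate(grad.transpose(inv))

    return _make(out_data, (a,), backward, a.requires_grad)


def getitem(a, idx) -> Tensor:
    a = _wrap(a)
    out_data = a.data[idx]

    def backward(grad):
        full = np.zeros_like(a.data)
        np.add.at(full, idx, grad)
        a.accumulate(full)

    return _make(out_data, (a,), backward, a.requires_grad)


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad for t in tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(grad):
        parts = np.split(grad, splits, axis=axis)
        for t, g in zip(tensors, parts):
            if t.requires_grad:
                t.accumulate(g)

    return _make(out_data, tuple(t for t in tensors if t.requires_grad), backward, req)


def embedding(weight: Tensor, ids: np.ndarray) -> Tensor:
    ids = np.asarray(ids)
    out_data = weight.data[ids]

    def backward(grad):
        full = np.zeros_like(weight.data)
        np.add.at(full, ids.reshape(-1), grad.reshape(-1, weight.data.shape[-1]))
        weight.accumulate(full)

    return _make(out_data, (weight,), backward, weight.requires_grad)


def softmax(a, axis: int = -1) -> Tensor:
    a = _wrap(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(grad):
        dot = (grad * out_data).sum(axis=axis, keepdims=True)
        a.accumulate(out_data * (grad - dot))

    return _make(out_data, (a,), backward, a.requires_grad)


def log_softmax(a, axis: int = -1) -> Tensor:
    a = _wrap(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out_data = shifted - lse
    soft = np.exp(out_data)

    def backward(grad):
        a.accumulate(grad - soft * grad.sum(axis=axis, keepdims=True))

    return _make(out_data, (a,), backward, a.requires_grad)
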