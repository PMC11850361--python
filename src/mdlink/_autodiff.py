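"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The model in this package is small (dense graphs of at most a few
thousand nodes), so a compact tape-based engine over dense ``ndarray``
operands is sufficient: each :class:`Tensor` records the operation that
produced it and a closure that accumulates gradients into its parents.
Only the operations the encoders, the recurrent layer and the decoder
need are implemented.

Gradients follow NumPy broadcasting: the backward pass sums a gradient
over any axes that were broadcast in the forward pass.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack_rows"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape``, undoing NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


def _as_array(value) -> np.ndarray:
    return np.asarray(value, dtype=np.float64)


class Tensor:
    """A NumPy array with an attached gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._prev = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = Tensor._lift(other)
        out_data = self.data + other.data

        def backward(grad, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(grad, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(grad, b.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(grad, a=self):
            if a.requires_grad:
                a._accum(-grad)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out_data = self.data * other.data

        def backward(grad, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(grad * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(grad * a.data, b.data.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out_data = self.data / other.data

        def backward(grad, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(grad / b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-grad * a.data / (b.data**2), b.data.shape))

        return self._make(out_data, (self, other), backward)

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out_data = self.data @ other.data

        def backward(grad, a=self, b=other):
            if a.requires_grad:
                a._accum(grad @ b.data.T)
            if b.requires_grad:
                b._accum(a.data.T @ grad)

        return self._make(out_data, (self, other), backward)

    def __getitem__(self, key):
        out_data = self.data[key]

        def backward(grad, a=self, k=key):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, k, grad)
                a._accum(full)

        return self._make(out_data, (self,), backward)

    @property
    def T(self) -> "Tensor":
        def backward(grad, a=self):
            if a.requires_grad:
                a._accum(grad.T)

        return self._make(self.data.T, (self,), backward)

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(grad, a=self, ax=axis, kd=keepdims):
            if not a.requires_grad:
                return
            g = np.asarray(grad)
            if ax is not None and not kd:
                g = np.expand_dims(g, ax)
            a._accum(np.broadcast_to(g, a.data.shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise nonlinearities -------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def backward(grad, a=self, o=out_data):
            if a.requires_grad:
                a._accum(grad * o)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(grad, a=self):
            if a.requires_grad:
                a._accum(grad / a.data)

        return self._make(np.log(self.data), (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(grad, a=self, o=out_data):
            if a.requires_grad:
                a._accum(grad * (1.0 - o**2))

        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 0.5 * (1.0 + np.tanh(0.5 * self.data))  # stable logistic

        def backward(grad, a=self, o=out_data):
            if a.requires_grad:
                a._accum(grad * o * (1.0 - o))

        return self._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(grad, a=self, m=mask):
            if a.requires_grad:
                a._accum(grad * m)

        return self._make(self.data * mask, (self,), backward)

    def leaky_relu(self, slope: float = 0.2):
        pos = self.data > 0
        out_data = np.where(pos, self.data, slope * self.data)

        def backward(grad, a=self, p=pos, s=slope):
            if a.requires_grad:
                a._accum(grad * np.where(p, 1.0, s))

        return self._make(out_data, (self,), backward)

    def square(self):
        return self * self

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes through unclipped entries only."""
        mask = (self.data > lo) & (self.data < hi)
        out_data = np.clip(self.data, lo, hi)

        def backward(grad, a=self, m=mask):
            if a.requires_grad:
                a._accum(grad * m)

        return self._make(out_data, (self,), backward)

    # -- softmax over masked rows ---------------------------------------------

    def masked_row_softmax(self, mask: np.ndarray):
        """Row-wise softmax restricted to ``mask`` (boolean, same shape).

        Entries outside the mask get probability exactly zero; each row
        must contain at least one unmasked entry.
        """
        m = np.asarray(mask, dtype=bool)
        if not m.any(axis=1).all():
            raise ValueError("masked softmax: a row has no admissible entries")
        shifted = np.where(m, self.data, -np.inf)
        shifted = shifted - shifted.max(axis=1, keepdims=True)
        e = np.where(m, np.exp(shifted), 0.0)
        out_data = e / e.sum(axis=1, keepdims=True)

        def backward(grad, a=self, o=out_data):
            if a.requires_grad:
                dot = (grad * o).sum(axis=1, keepdims=True)
                a._accum(o * (grad - dot))

        return self._make(out_data, (self,), backward)

    # -- autograd driver ------------------------------------------------------

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64, copy=True)
        else:
            self.grad += grad

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; recursion overflows on long LSTM tapes
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._prev:
                stack.append((parent, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Concatenate tensors along ``axis`` with gradient routing."""
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    out = Tensor(out_data, requires_grad=any(t.requires_grad for t in tensors))
    if out.requires_grad:
        out._prev = tuple(tensors)

        def backward(grad):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * grad.ndim
                    sl[axis] = slice(lo, hi)
                    t._accum(grad[tuple(sl)])

        out._backward = backward
    return out


def stack_rows(rows: list[Tensor]) -> Tensor:
    """Stack 1×d row tensors into an n×d tensor (for recurrent outputs)."""
    out_data = np.concatenate([r.data.reshape(1, -1) for r in rows], axis=0)
    out = Tensor(out_data, requires_grad=any(r.requires_grad for r in rows))
    if out.requires_grad:
        out._prev = tuple(rows)

        def backward(grad):
            for i, r in enumerate(rows):
                if r.requires_grad:
                    r._accum(grad[i].reshape(r.data.shape))

        out._backward = backward
    return out
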