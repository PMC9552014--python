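"""Minimal reverse-mode automatic differentiation on numpy arrays.

The model in :mod:`mvifmda.model` is a small full-batch network (a handful of
dense matrix products, tanh/ReLU/sigmoid nonlinearities and a softmax over a
few scalars), so a compact tape-based engine suffices.  Every operation
records its parents and a closure that accumulates gradients; calling
:meth:`Tensor.backward` on a scalar loss walks the tape in reverse
topological order.

Gradient correctness is established by central finite differences in the test
suite, for each primitive and for the assembled model loss.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat_cols"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach `grad.shape`."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An array node on the autodiff tape.

    The floating dtype of the input array is preserved (the model trains in
    float32; gradient-check tests use float64).  Python scalars lifted into an
    expression adopt the dtype of the tensor they combine with.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    #: make numpy defer to Tensor.__r*__ in ndarray-op-Tensor expressions
    __array_priority__ = 1000

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if arr.dtype.kind != "f":
            arr = arr.astype(np.float64)
        self.data = arr
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    def _lift(self, x) -> "Tensor":
        if isinstance(x, Tensor):
            return x
        return Tensor(np.asarray(x, dtype=self.data.dtype))

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep with many epochs
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
            if node._backward is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return self._make(self.data / other.data, (self, other), backward)

    def __matmul__(self, other):
        other = self._lift(other)

        def backward(g):
            g = np.atleast_2d(g)
            if self.requires_grad:
                self._accum(
                    _unbroadcast(g @ np.atleast_2d(other.data).T, self.data.shape)
                )
            if other.requires_grad:
                other._accum(
                    _unbroadcast(np.atleast_2d(self.data).T @ g, other.data.shape)
                )

        return self._make(self.data @ other.data, (self, other), backward)

    # ------------------------------------------------------------ elementwise
    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return self._make(self.data * mask, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data**2))

        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def clamp(self, lo: float, hi: float):
        """Clip values; gradient is zero outside [lo, hi] (straight-through inside)."""
        mask = (self.data >= lo) & (self.data <= hi)

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return self._make(np.clip(self.data, lo, hi), (self,), backward)

    # -------------------------------------------------------------- reductions
    def sum(self):
        def backward(g):
            if self.requires_grad:
                self._accum(np.full_like(self.data, float(g)))

        return self._make(self.data.sum(), (self,), backward)

    def mean(self):
        n = self.data.size

        def backward(g):
            if self.requires_grad:
                self._accum(np.full_like(self.data, float(g) / n))

        return self._make(self.data.mean(), (self,), backward)

    # ------------------------------------------------------------- structural
    def T_(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g.T)

        return self._make(self.data.T, (self,), backward)

    def rows(self, start: int, stop: int):
        """Contiguous row slice [start:stop)."""

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[start:stop] = g
                self._accum(full)

        return self._make(self.data[start:stop], (self,), backward)


def concat_cols(a: Tensor, b: Tensor) -> Tensor:
    """Column-wise concatenation [a | b] of two 2-D tensors with equal row counts."""
    if a.data.shape[0] != b.data.shape[0]:
        raise ValueError(
            f"row mismatch in concatenation: {a.data.shape} vs {b.data.shape}"
        )
    na = a.data.shape[1]

    def backward(g):
        if a.requires_grad:
            a._accum(g[:, :na])
        if b.requires_grad:
            b._accum(g[:, na:])

    out = Tensor(np.concatenate([a.data, b.data], axis=1))
    out.requires_grad = a.requires_grad or b.requires_grad
    if out.requires_grad:
        out._parents = (a, b)
        out._backward = backward
    return out
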