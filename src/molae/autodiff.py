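"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Just enough machinery for recurrent sequence autoencoders: elementwise
arithmetic with broadcasting, 2-D matrix products, slicing/concatenation,
pointwise nonlinearities, a masked softmax (for attention over variable-
length sequences) and a fused softmax/cross-entropy head. Gradients are
accumulated by an iterative topological sweep, so graphs with tens of
thousands of nodes (long unrolled RNNs) stay clear of the recursion limit.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum *grad* down to *shape* (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    # -- graph construction ------------------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        return Tensor(data, req, parents if req else (), backward if req else None)

    def __add__(self, other):
        other = self._lift(other)

        def backward(out):
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(out):
            if self.requires_grad:
                self._accum(-out.grad)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def backward(out):
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, scalar: float):
        return self * (1.0 / scalar)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ out.grad)

        return self._make(self.data @ other.data, (self, other), backward)

    __matmul__ = matmul

    def tanh(self) -> "Tensor":
        y = np.tanh(self.data)

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad * (1.0 - out.data**2))

        return self._make(y, (self,), backward)

    def sigmoid(self) -> "Tensor":
        y = 1.0 / (1.0 + np.exp(-self.data))

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad * out.data * (1.0 - out.data))

        return self._make(y, (self,), backward)

    def exp(self) -> "Tensor":
        def backward(out):
            if self.requires_grad:
                self._accum(out.grad * out.data)

        return self._make(np.exp(self.data), (self,), backward)

    def square(self) -> "Tensor":
        def backward(out):
            if self.requires_grad:
                self._accum(out.grad * 2.0 * self.data)

        return self._make(self.data**2, (self,), backward)

    def sum(self) -> "Tensor":
        def backward(out):
            if self.requires_grad:
                self._accum(np.full(self.shape, out.grad))

        return self._make(self.data.sum(), (self,), backward)

    def narrow(self, start: int, stop: int) -> "Tensor":
        """Columns ``start:stop`` of a 2-D tensor."""

        def backward(out):
            if self.requires_grad:
                g = np.zeros_like(self.data)
                g[:, start:stop] = out.grad
                self._accum(g)

        return self._make(self.data[:, start:stop], (self,), backward)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self) -> None:
        """Reverse sweep from this (scalar or any-shaped) tensor."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                stack.append((parent, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node)


def concat(tensors: list[Tensor]) -> Tensor:
    """Concatenate 2-D tensors along axis 1."""
    widths = [t.shape[1] for t in tensors]
    offsets = np.concatenate([[0], np.cumsum(widths)])
    req = any(t.requires_grad for t in tensors)

    def backward(out):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                t._accum(out.grad[:, lo:hi])

    data = np.concatenate([t.data for t in tensors], axis=1)
    return Tensor(data, req, tuple(tensors) if req else (), backward if req else None)


def masked_softmax(scores: Tensor, mask: np.ndarray) -> Tensor:
    """Row-wise softmax of a 2-D score tensor over positions where *mask*
    is 1; masked positions get exactly zero weight. Raises if any row is
    fully masked."""
    if not np.all(mask.any(axis=1)):
        raise ValueError("softmax over a fully masked row")
    shifted = np.where(mask > 0, scores.data, -np.inf)
    shifted = shifted - shifted.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    w = e / e.sum(axis=1, keepdims=True)

    def backward(out):
        if scores.requires_grad:
            dot = (out.grad * w).sum(axis=1, keepdims=True)
            scores._accum(w * (out.grad - dot))

    return Tensor(w, scores.requires_grad, (scores,) if scores.requires_grad else (),
                  backward if scores.requires_grad else None)


def cross_entropy_logits(
    logits: Tensor, targets: np.ndarray, weights: np.ndarray
) -> Tensor:
    """Weighted sum of per-row cross-entropies ``-w_i log softmax(x_i)[t_i]``.

    ``targets`` are class indices, ``weights`` typically a 0/1 PAD mask.
    Returns the weighted *sum*; divide by the weight total for a mean.
    """
    shifted = logits.data - logits.data.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(shifted).sum(axis=1, keepdims=True))
    logp = shifted - logsumexp
    rows = np.arange(len(targets))
    value = -(weights * logp[rows, targets]).sum()

    def backward(out):
        if logits.requires_grad:
            grad = np.exp(logp)
            grad[rows, targets] -= 1.0
            logits._accum(out.grad * grad * weights[:, None])

    return Tensor(value, logits.requires_grad,
                  (logits,) if logits.requires_grad else (),
                  backward if logits.requires_grad else None)


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Plain NumPy softmax (inference paths)."""
    shifted = x - x.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)
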