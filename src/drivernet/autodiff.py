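"""A small reverse-mode automatic-differentiation engine on numpy arrays.

Supports exactly the operations the graph encoder and link-prediction loss
need: dense matmul, broadcast add, elementwise multiply, ReLU, softplus,
row gather (with scatter-add backward), sparse-matrix x dense product
(adjacency aggregation), concatenation, reductions, and an Adam optimizer.

Gradients are accumulated by topological traversal of the expression graph;
correctness is checked against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

__all__ = ["Tensor", "Adam", "spmm", "gather", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the closure needed to backpropagate through it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # ---- graph construction -------------------------------------------------

    def __add__(self, other: "Tensor") -> "Tensor":
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def backward(grad):
            return (
                _unbroadcast(grad, self.data.shape),
                _unbroadcast(grad, other.data.shape),
            )

        out._backward = backward
        return out

    def __mul__(self, other) -> "Tensor":
        if np.isscalar(other):
            out = Tensor(self.data * other, parents=(self,))
            out._backward = lambda grad: (grad * other,)
            return out
        other = _as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def backward(grad):
            return (
                _unbroadcast(grad * other.data, self.data.shape),
                _unbroadcast(grad * self.data, other.data.shape),
            )

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __neg__(self) -> "Tensor":
        return self * -1.0

    def __matmul__(self, other: "Tensor") -> "Tensor":
        other = _as_tensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def backward(grad):
            return grad @ other.data.T, self.data.T @ grad

        out._backward = backward
        return out

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))
        mask = self.data > 0.0
        out._backward = lambda grad: (grad * mask,)
        return out

    def softplus(self) -> "Tensor":
        # log(1 + e^x), computed stably; gradient is the logistic function.
        out = Tensor(
            np.logaddexp(0.0, self.data), parents=(self,)
        )
        sig = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        out._backward = lambda grad: (grad * sig,)
        return out

    def sum(self, axis: int | None = None) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis), parents=(self,))
        shape = self.data.shape

        def backward(grad):
            if axis is None:
                return (np.full(shape, grad),)
            return (np.broadcast_to(np.expand_dims(grad, axis), shape).copy(),)

        out._backward = backward
        return out

    def mean(self) -> "Tensor":
        n = self.data.size
        out = Tensor(self.data.mean(), parents=(self,))
        shape = self.data.shape
        out._backward = lambda grad: (np.full(shape, grad / n),)
        return out

    # ---- backpropagation ----------------------------------------------------

    def backward(self) -> None:
        if self.data.ndim != 0:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: "Tensor") -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(1.0)}
        for t in reversed(topo):
            grad = grads.pop(id(t), None)
            if grad is None:
                continue
            if not t._parents:
                t.grad = grad if t.grad is None else t.grad + grad
                continue
            parent_grads = t._backward(grad)
            for p, g in zip(t._parents, parent_grads):
                if not p.requires_grad or g is None:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + g
                else:
                    grads[id(p)] = g
        # leaves reached with no grad (disconnected) keep grad=None


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def spmm(a: sparse.spmatrix, x: Tensor) -> Tensor:
    """Sparse @ dense with gradient flowing to the dense operand only."""
    a = sparse.csr_matrix(a)
    out = Tensor(a @ x.data, parents=(x,))
    at = a.T.tocsr()
    out._backward = lambda grad: (at @ grad,)
    return out


def gather(x: Tensor, idx: np.ndarray) -> Tensor:
    """Row selection ``x[idx]``; backward scatter-adds into the source rows."""
    idx = np.asarray(idx, dtype=np.intp)
    out = Tensor(x.data[idx], parents=(x,))
    shape = x.data.shape

    def backward(grad):
        g = np.zeros(shape)
        np.add.at(g, idx, grad)
        return (g,)

    out._backward = backward
    return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(grad):
        return tuple(np.split(grad, splits, axis=axis))

    out._backward = backward
    return out


class Adam:
    """Adaptive-moment gradient descent over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
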