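"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the sequence models need: elementwise
arithmetic with broadcasting, matrix multiplication, sigmoid/tanh/relu,
elementwise maximum, column concatenation, means, and fused
softmax-cross-entropy / mean-squared-error losses. Gradients flow only
through tensors created with ``requires_grad=True`` (parameters) or derived
from them; raw data enters as constants.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` to undo numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # -- graph traversal -----------------------------------------------------

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # -- ops -----------------------------------------------------------------

    def __add__(self, other: "Tensor") -> "Tensor":
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        out._backward = bwd
        return out

    def __sub__(self, other: "Tensor") -> "Tensor":
        other = _as_tensor(other)
        out = Tensor(self.data - other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(-g)

        out._backward = bwd
        return out

    def __mul__(self, other) -> "Tensor":
        other = _as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)

        out._backward = bwd
        return out

    def __rmul__(self, other) -> "Tensor":
        return self.__mul__(other)

    def __matmul__(self, other: "Tensor") -> "Tensor":
        other = _as_tensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        out._backward = bwd
        return out

    def mean(self) -> "Tensor":
        out = Tensor(self.data.mean(), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(np.full_like(self.data, g / self.data.size))

        out._backward = bwd
        return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(s, parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accum(g * s * (1.0 - s))

    out._backward = bwd
    return out


def tanh(x: Tensor) -> Tensor:
    t = np.tanh(x.data)
    out = Tensor(t, parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accum(g * (1.0 - t * t))

    out._backward = bwd
    return out


def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accum(g * (x.data > 0))

    out._backward = bwd
    return out


def identity(x: Tensor) -> Tensor:
    return x


def maximum(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise max; ties send the gradient to the first argument."""
    take_a = a.data >= b.data
    out = Tensor(np.where(take_a, a.data, b.data), parents=(a, b))

    def bwd(g):
        if a.requires_grad:
            a._accum(g * take_a)
        if b.requires_grad:
            b._accum(g * ~take_a)

    out._backward = bwd
    return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    out._backward = bwd
    return out


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer labels under softmax(logits)."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = len(labels)
    ll = -np.log(np.clip(probs[np.arange(n), labels], 1e-300, None))
    out = Tensor(ll.mean(), parents=(logits,))

    def bwd(g):
        if logits.requires_grad:
            grad = probs.copy()
            grad[np.arange(n), labels] -= 1.0
            logits._accum(g * grad / n)

    out._backward = bwd
    return out


def softmax_probs(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = Tensor(pred.data - np.asarray(target, dtype=float), parents=(pred,))

    def bwd(g):
        if pred.requires_grad:
            pred._accum(g)

    diff._backward = bwd
    return (diff * diff).mean()


class Adam:
    """Standard Adam on a list of parameter Tensors; deterministic."""

    def __init__(self, params: list[Tensor], lr: float = 0.01,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * p.grad
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * p.grad**2
            mhat = self.m[i] / (1 - self.beta1**self.t)
            vhat = self.v[i] / (1 - self.beta2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
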