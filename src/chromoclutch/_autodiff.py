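"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the force-matching loss needs: broadcast
add/sub/mul, matrix multiplication, tanh, squaring, means/sums, and
contraction against a constant third-order tensor.  Gradients flow to leaf
``Var`` nodes (the network parameters).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Var", "add", "sub", "mul", "matmul", "tanh", "square", "mean_all",
           "contract_bcm"]


class Var:
    """A node in the computation tape."""

    __slots__ = ("value", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, value, parents=(), backward=None, requires_grad=False):
        self.value = np.asarray(value, dtype=float)
        self.grad = None
        self._parents = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in parents
        )

    def backward(self) -> None:
        """Accumulate gradients of this (scalar) node into the leaves."""
        order: list[Var] = []
        seen: set[int] = set()

        def visit(v: "Var") -> None:
            if id(v) in seen or not v.requires_grad:
                return
            seen.add(id(v))
            for p in v._parents:
                visit(p)
            order.append(v)

        visit(self)
        for v in order:
            v.grad = np.zeros_like(v.value)
        self.grad = np.ones_like(self.value)
        for v in reversed(order):
            if v._backward is not None:
                v._backward(v.grad)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _acc(v: Var, g: np.ndarray) -> None:
    if v.requires_grad:
        v.grad += _unbroadcast(g, v.value.shape)


def add(a: Var, b: Var) -> Var:
    out = Var(a.value + b.value, (a, b))
    out._backward = lambda g: (_acc(a, g), _acc(b, g))
    return out


def sub(a: Var, b: Var) -> Var:
    out = Var(a.value - b.value, (a, b))
    out._backward = lambda g: (_acc(a, g), _acc(b, -g))
    return out


def mul(a: Var, b: Var) -> Var:
    out = Var(a.value * b.value, (a, b))
    out._backward = lambda g: (_acc(a, g * b.value), _acc(b, g * a.value))
    return out


def matmul(a: Var, b: Var) -> Var:
    out = Var(a.value @ b.value, (a, b))

    def back(g):
        ga = g @ b.value.T if b.value.ndim == 2 else np.outer(g, b.value)
        if a.value.ndim == 2:
            _acc(a, ga)
        else:
            _acc(a, b.value @ g if g.ndim == 1 else ga)
        if b.value.ndim == 2:
            _acc(b, a.value.T @ g if g.ndim == 2 else np.outer(a.value, g))
        else:
            _acc(b, a.value.T @ g)

    out._backward = back
    return out


def tanh(a: Var) -> Var:
    t = np.tanh(a.value)
    out = Var(t, (a,))
    out._backward = lambda g: _acc(a, g * (1 - t**2))
    return out


def square(a: Var) -> Var:
    out = Var(a.value**2, (a,))
    out._backward = lambda g: _acc(a, 2 * g * a.value)
    return out


def mean_all(a: Var) -> Var:
    out = Var(np.mean(a.value), (a,))
    out._backward = lambda g: _acc(a, np.full_like(a.value, g / a.value.size))
    return out


def contract_bcm(G: np.ndarray, J: Var) -> Var:
    """y[b, c] = sum_m G[b, c, m] * J[b, m] with constant G."""
    out = Var(np.einsum("bcm,bm->bc", G, J.value), (J,))
    out._backward = lambda g: _acc(J, np.einsum("bcm,bc->bm", G, g))
    return out
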