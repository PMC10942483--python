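"""Minimal reverse-mode automatic differentiation over numpy arrays.

The physics residual of the inverse solver needs exact derivatives of small
dense networks with respect to both their inputs (for the PDE operator) and
their parameters (for the optimizer).  Input derivatives are propagated
forward through the layers with exact chain-rule recurrences built from the
primitives below; parameter gradients then come from one reverse sweep over
the resulting graph.  Only the handful of operations the solver composes are
implemented: elementwise arithmetic, matrix products, ``tanh``/``softplus``/
``sigmoid``, and reductions, all with full broadcasting support.

The graph preserves the dtype of its inputs (float32 or float64); training
typically runs in float32 — the norm for this class of model — while
verification paths use float64.  Gradients are accumulated, so one tensor
may feed several downstream nodes.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "tanh", "sigmoid", "softplus", "matmul"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape``, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum away leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were size-1 in the original
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A node in the differentiation graph wrapping a float ndarray."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_vjps")

    def __init__(self, value, requires_grad: bool = False, _parents=(), _vjps=()):
        value = np.asarray(value)
        if value.dtype not in (np.float32, np.float64):
            value = value.astype(np.float64)
        self.value = value
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self.grad: np.ndarray | None = None
        self._parents = _parents
        self._vjps = _vjps

    # -- graph construction helpers -------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @property
    def shape(self):
        return self.value.shape

    # -- arithmetic ------------------------------------------------------
    # Python scalars take a fast path that keeps the array dtype (a wrapped
    # float64 0-d array would silently promote float32 graphs).
    def __add__(self, other):
        if isinstance(other, (int, float)):
            return Tensor(self.value + other, _parents=(self,), _vjps=(lambda g: g,))
        other = self._wrap(other)
        return Tensor(
            self.value + other.value,
            _parents=(self, other),
            _vjps=(
                lambda g: _unbroadcast(g, self.value.shape),
                lambda g: _unbroadcast(g, other.value.shape),
            ),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.value, _parents=(self,), _vjps=(lambda g: -g,))

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return Tensor(self.value - other, _parents=(self,), _vjps=(lambda g: g,))
        other = self._wrap(other)
        return Tensor(
            self.value - other.value,
            _parents=(self, other),
            _vjps=(
                lambda g: _unbroadcast(g, self.value.shape),
                lambda g: _unbroadcast(-g, other.value.shape),
            ),
        )

    def __rsub__(self, other):
        if isinstance(other, (int, float)):
            return Tensor(other - self.value, _parents=(self,), _vjps=(lambda g: -g,))
        return self._wrap(other) - self

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            return Tensor(self.value * other, _parents=(self,),
                          _vjps=(lambda g: g * other,))
        other = self._wrap(other)
        return Tensor(
            self.value * other.value,
            _parents=(self, other),
            _vjps=(
                lambda g: _unbroadcast(g * other.value, self.value.shape),
                lambda g: _unbroadcast(g * self.value, other.value.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        other = self._wrap(other)
        inv = 1.0 / other.value
        return Tensor(
            self.value * inv,
            _parents=(self, other),
            _vjps=(
                lambda g: _unbroadcast(g * inv, self.value.shape),
                lambda g: _unbroadcast(-g * self.value * inv * inv, other.value.shape),
            ),
        )

    def __matmul__(self, other):
        other = self._wrap(other)
        a, b = self.value, other.value

        def vjp_b(g):
            if a.ndim > 2:  # stacked tangents: contract all leading axes
                k, m = a.shape[-1], g.shape[-1]
                return a.reshape(-1, k).T @ g.reshape(-1, m)
            return a.T @ g

        return Tensor(
            a @ b,
            _parents=(self, other),
            _vjps=(lambda g: g @ b.swapaxes(-1, -2), vjp_b),
        )

    def square(self):
        return Tensor(
            self.value * self.value,
            _parents=(self,),
            _vjps=(lambda g: g * (2.0 * self.value),),
        )

    def sum(self, axis=None):
        shape = self.value.shape
        if axis is None:
            return Tensor(
                self.value.sum(),
                _parents=(self,),
                _vjps=(lambda g: np.broadcast_to(g, shape).copy(),),
            )
        return Tensor(
            self.value.sum(axis=axis),
            _parents=(self,),
            _vjps=(lambda g: np.broadcast_to(np.expand_dims(g, axis), shape).copy(),),
        )

    def rows(self, start: int, stop: int):
        """View of rows [start, stop) along axis 0 (zero-padded adjoint)."""
        shape = self.value.shape

        def vjp(g):
            out = np.zeros(shape, dtype=g.dtype)
            out[start:stop] = g
            return out

        return Tensor(self.value[start:stop], _parents=(self,), _vjps=(vjp,))

    def take0(self, index: int):
        """Select one slice along axis 0."""
        shape = self.value.shape

        def vjp(g):
            out = np.zeros(shape, dtype=g.dtype)
            out[index] = g
            return out

        return Tensor(self.value[index], _parents=(self,), _vjps=(vjp,))

    def mean(self):
        n = self.value.size
        shape = self.value.shape
        return Tensor(
            self.value.mean(),
            _parents=(self,),
            _vjps=(lambda g: np.broadcast_to(g / n, shape).copy(),),
        )

    # -- reverse sweep ----------------------------------------------------
    def backward(self, grad=None) -> None:
        """Accumulate gradients of ``self`` into every reachable leaf."""
        if grad is None:
            grad = np.ones_like(self.value)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
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
        self.grad = np.asarray(grad, dtype=self.value.dtype)
        for node in reversed(topo):
            g = node.grad
            if g is None:
                continue
            for parent, vjp in zip(node._parents, node._vjps):
                if not parent.requires_grad:
                    continue
                pg = vjp(g)
                if parent.grad is None:
                    parent.grad = pg
                else:
                    parent.grad = parent.grad + pg

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.value.shape}, requires_grad={self.requires_grad})"


def tanh(x: Tensor) -> Tensor:
    v = np.tanh(x.value)
    return Tensor(v, _parents=(x,), _vjps=(lambda g: g * (1.0 - v * v),))


def sigmoid(x: Tensor) -> Tensor:
    v = 0.5 * (1.0 + np.tanh(0.5 * x.value))  # numerically stable logistic
    return Tensor(v, _parents=(x,), _vjps=(lambda g: g * v * (1.0 - v),))


def softplus(x: Tensor) -> Tensor:
    # log(1 + e^x) written to avoid overflow for large |x|
    v = np.maximum(x.value, 0.0) + np.log1p(np.exp(-np.abs(x.value)))
    s = 0.5 * (1.0 + np.tanh(0.5 * x.value))
    return Tensor(v, _parents=(x,), _vjps=(lambda g: g * s,))


def matmul(a: Tensor, b: Tensor) -> Tensor:
    return a @ b


# -- fused primitives for the tangent recurrences -------------------------
# These collapse the chain-rule updates of the forward-mode derivative
# propagation (tanh' = 1 - a², tanh'' = -2a(1 - a²), with a = tanh(z)) into
# single graph nodes, which matters because the elementwise graph overhead
# dominates the optimizer's per-step cost.

def dtanh_mul(a: Tensor, zu: Tensor) -> Tensor:
    """(1 - a²) · zu — the first-derivative tangent update."""
    av, zuv = a.value, zu.value
    s2 = 1.0 - av * av
    return Tensor(
        s2 * zuv,
        _parents=(a, zu),
        _vjps=(
            lambda g: _unbroadcast(g * (-2.0 * av * zuv), av.shape),
            lambda g: _unbroadcast(g * s2, zuv.shape),
        ),
    )


def d2tanh_comb(a: Tensor, zu: Tensor, zv: Tensor | None) -> Tensor:
    """(1 - a²)·zv − 2a(1 − a²)·zu² — the second-derivative tangent update.

    ``zv`` may be None for the first layer, where the incoming curvature is
    exactly zero.
    """
    av, zuv = a.value, zu.value
    s2 = 1.0 - av * av
    t2 = -2.0 * av * s2
    zu2 = zuv * zuv
    val = t2 * zu2
    if zv is not None:
        val = val + s2 * zv.value

        def vjp_a(g):
            return _unbroadcast(
                g * (-2.0 * av * zv.value + (6.0 * av * av - 2.0) * zu2), av.shape
            )

        return Tensor(
            val,
            _parents=(a, zu, zv),
            _vjps=(
                vjp_a,
                lambda g: _unbroadcast(g * (2.0 * t2 * zuv), zuv.shape),
                lambda g: _unbroadcast(g * s2, zv.value.shape),
            ),
        )
    return Tensor(
        val,
        _parents=(a, zu),
        _vjps=(
            lambda g: _unbroadcast(g * ((6.0 * av * av - 2.0) * zu2), av.shape),
            lambda g: _unbroadcast(g * (2.0 * t2 * zuv), zuv.shape),
        ),
    )
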