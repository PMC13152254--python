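"""Minimal reverse-mode automatic differentiation on numpy arrays.

The model core needs gradients of a learned scalar energy with respect to
its inputs *inside* the forward pass (the symplectic integrator consumes
dH/dq and dH/dp), and then gradients of the training loss through those
gradients. Every vector-Jacobian product below is therefore expressed in
terms of the same differentiable operations, so ``grad`` output tensors
remain valid nodes of the computation graph and second-order
differentiation (double backprop) works without special casing.

Scope is deliberately narrow: float64 only, 1-D/2-D arrays, the handful of
operations the models use. Not a general tensor library.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = ["Tensor", "astensor", "grad"]


class Tensor:
    """A numpy array plus the graph edges needed for reverse-mode AD."""

    __slots__ = ("data", "parents", "vjp", "requires_grad")
    __array_priority__ = 100  # keep numpy from hijacking reflected operators

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        vjp: Callable[["Tensor"], tuple] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.parents = tuple(parents)
        self.vjp = vjp
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in self.parents
        )

    # -- conveniences -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- operator sugar ----------------------------------------------
    def __add__(self, other):
        return add(self, astensor(other))

    def __radd__(self, other):
        return add(astensor(other), self)

    def __sub__(self, other):
        return add(self, neg(astensor(other)))

    def __rsub__(self, other):
        return add(astensor(other), neg(self))

    def __mul__(self, other):
        return mul(self, astensor(other))

    def __rmul__(self, other):
        return mul(astensor(other), self)

    def __truediv__(self, other):
        return mul(self, power(astensor(other), -1.0))

    def __rtruediv__(self, other):
        return mul(astensor(other), power(self, -1.0))

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, astensor(other))

    def __pow__(self, exponent):
        return power(self, float(exponent))

    def __getitem__(self, idx):
        return take(self, idx)

    @property
    def T(self):
        return transpose(self)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------


def _unbroadcast(g: Tensor, shape: tuple) -> Tensor:
    """Sum ``g`` over the axes that numpy broadcasting expanded."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = tsum(g, axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    if g.shape != shape:
        g = reshape(g, shape)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(
        a.data + b.data,
        parents=(a, b),
        vjp=lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)),
    )


def neg(a: Tensor) -> Tensor:
    return Tensor(-a.data, parents=(a,), vjp=lambda g: (neg(g),))


def mul(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(
        a.data * b.data,
        parents=(a, b),
        vjp=lambda g: (
            _unbroadcast(mul(g, b), a.shape),
            _unbroadcast(mul(g, a), b.shape),
        ),
    )


def power(a: Tensor, exponent: float) -> Tensor:
    out = Tensor(
        a.data**exponent,
        parents=(a,),
        vjp=lambda g: (mul(g, mul(Tensor(exponent), power(a, exponent - 1.0))),),
    )
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(
        a.data @ b.data,
        parents=(a, b),
        vjp=lambda g: (matmul(g, transpose(b)), matmul(transpose(a), g)),
    )


def transpose(a: Tensor) -> Tensor:
    return Tensor(a.data.T, parents=(a,), vjp=lambda g: (transpose(g),))


def reshape(a: Tensor, shape: tuple) -> Tensor:
    old = a.shape
    return Tensor(
        a.data.reshape(shape), parents=(a,), vjp=lambda g: (reshape(g, old),)
    )


def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    in_shape = a.shape

    def vjp(g: Tensor):
        if axis is None:
            kept = (1,) * len(in_shape)
        elif keepdims:
            kept = g.shape
        else:
            axes = (axis,) if np.isscalar(axis) else tuple(axis)
            axes = tuple(ax % len(in_shape) for ax in axes)
            kept = tuple(
                1 if i in axes else s for i, s in enumerate(in_shape)
            )
        expanded = mul(reshape(g, kept), Tensor(np.ones(in_shape)))
        return (expanded,)

    return Tensor(a.data.sum(axis=axis, keepdims=keepdims), parents=(a,), vjp=vjp)


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    s = tsum(a, axis=axis, keepdims=keepdims)
    denom = a.size / s.size
    return mul(s, Tensor(1.0 / denom))


def relu(a: Tensor) -> Tensor:
    mask = Tensor((a.data > 0).astype(np.float64))
    return Tensor(
        np.maximum(a.data, 0.0), parents=(a,), vjp=lambda g: (mul(g, mask),)
    )


def tanh(a: Tensor) -> Tensor:
    out = Tensor(np.tanh(a.data), parents=(a,))
    out.vjp = lambda g: (mul(g, add(Tensor(1.0), neg(mul(out, out)))),)
    return out


def sin(a: Tensor) -> Tensor:
    return Tensor(np.sin(a.data), parents=(a,), vjp=lambda g: (mul(g, cos(a)),))


def cos(a: Tensor) -> Tensor:
    return Tensor(
        np.cos(a.data), parents=(a,), vjp=lambda g: (neg(mul(g, sin(a))),)
    )


def exp(a: Tensor) -> Tensor:
    out = Tensor(np.exp(a.data), parents=(a,))
    out.vjp = lambda g: (mul(g, out),)
    return out


def log(a: Tensor) -> Tensor:
    return Tensor(
        np.log(a.data), parents=(a,), vjp=lambda g: (mul(g, power(a, -1.0)),)
    )


def take(a: Tensor, idx) -> Tensor:
    """Constant-index selection (basic or fancy indexing)."""
    shape = a.shape
    return Tensor(
        a.data[idx], parents=(a,), vjp=lambda g: (scatter(g, idx, shape),)
    )


def scatter(g: Tensor, idx, shape: tuple) -> Tensor:
    """Adjoint of ``take``: place ``g`` into zeros of ``shape`` at ``idx``."""

    def forward(data):
        out = np.zeros(shape)
        np.add.at(out, idx, data)
        return out

    return Tensor(forward(g.data), parents=(g,), vjp=lambda gg: (take(gg, idx),))


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.concatenate([[0], np.cumsum(sizes)])

    def vjp(g: Tensor):
        outs = []
        for i in range(len(tensors)):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
            outs.append(take(g, tuple(sl)))
        return tuple(outs)

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        parents=tuple(tensors),
        vjp=vjp,
    )


def spmm(S: sp.spmatrix, x: Tensor) -> Tensor:
    """Multiply a *constant* sparse matrix by a dense tensor: ``S @ x``.

    The adjoint is ``S.T @ g`` which is again an ``spmm``, so the operation
    is linear and arbitrarily re-differentiable.
    """
    S = sp.csr_matrix(S)
    ST = sp.csr_matrix(S.T)
    return Tensor(S @ x.data, parents=(x,), vjp=lambda g: (spmm(ST, g),))


def logsumexp_rows(a: Tensor) -> Tensor:
    """Row-wise log-sum-exp, numerically shifted by the (constant) row max.

    The shift is treated as a constant; the gradient of log-sum-exp is
    invariant to any fixed shift, so this is exact.
    """
    m = Tensor(a.data.max(axis=1, keepdims=True))
    shifted = add(a, neg(m))
    return add(log(tsum(exp(shifted), axis=1, keepdims=True)), m)


def log_softmax(a: Tensor) -> Tensor:
    return add(a, neg(logsumexp_rows(a)))


# ---------------------------------------------------------------------------
# reverse pass
# ---------------------------------------------------------------------------


def _toposort(root: Tensor) -> list[Tensor]:
    order: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            if p.requires_grad and id(p) not in seen:
                stack.append((p, False))
    return order


def grad(output: Tensor, inputs: Iterable[Tensor]) -> list[Tensor]:
    """Gradients of a scalar ``output`` w.r.t. each tensor in ``inputs``.

    Returned gradients are themselves graph nodes, so they can be fed back
    into ``grad`` for higher-order derivatives.
    """
    inputs = list(inputs)
    if output.size != 1:
        raise ValueError("grad expects a scalar output")
    grads: dict[int, Tensor] = {id(output): Tensor(np.ones(output.shape))}
    for node in reversed(_toposort(output)):
        g = grads.pop(id(node), None)
        if g is None or node.vjp is None:
            if g is not None:
                grads[id(node)] = g  # leaf: keep for the caller
            continue
        is_input = any(node is t for t in inputs)
        parent_grads = node.vjp(g)
        for p, pg in zip(node.parents, parent_grads):
            if pg is None or not p.requires_grad:
                continue
            acc = grads.get(id(p))
            grads[id(p)] = pg if acc is None else add(acc, pg)
        if is_input:
            grads[id(node)] = g
    return [grads.get(id(t), Tensor(np.zeros(t.shape))) for t in inputs]
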