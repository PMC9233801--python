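"""Minimal reverse-mode automatic differentiation on numpy arrays.

This engine backs the sequence autoencoder, the latent-space WGAN-GP and the
QSAR predictor.  It supports higher-order differentiation: every vector-Jacobian
product is itself expressed in terms of engine primitives, so gradients can be
differentiated again.  That property is what allows the Wasserstein critic to be
trained through the gradient-penalty term, whose loss contains the gradient of
the critic with respect to its input.

Only the primitives the package needs are implemented (dense algebra, common
nonlinearities, reductions, slicing/concatenation and an embedding lookup); it
is deliberately not a general framework.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "no_grad", "grad", "concat", "stack_rows", "embedding_lookup"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference / plain backward)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _as_array(x):
    if isinstance(x, np.ndarray):
        return x.astype(np.float64) if x.dtype != np.float64 else x
    return np.asarray(x, dtype=np.float64)


class Tensor:
    __slots__ = ("data", "requires_grad", "grad", "_parents", "_vjps")

    def __init__(self, data, requires_grad=False, _parents=(), _vjps=()):
        self.data = _as_array(data)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents = _parents
        self._vjps = _vjps

    # ---- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, vjps):
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            return Tensor(data, requires_grad=True, _parents=parents, _vjps=vjps)
        return Tensor(data)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self):
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # ---- broadcasting support -------------------------------------------------
    def _unbroadcast(self, g, shape):
        """Sum gradient `g` down to `shape` (inverse of numpy broadcasting)."""
        if g.shape == shape:
            return g
        extra = g.ndim - len(shape)
        for _ in range(extra):
            g = g.sum(axis=0)
        for ax, n in enumerate(shape):
            if n == 1 and g.shape[ax] != 1:
                g = g.sum(axis=ax, keepdims=True)
        return g

    # ---- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        sa, sb = self.shape, other.shape
        return Tensor._make(
            self.data + other.data,
            (self, other),
            (lambda g: self._unbroadcast(g, sa), lambda g: self._unbroadcast(g, sb)),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), (lambda g: -g,))

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        sa, sb = self.shape, other.shape
        return Tensor._make(
            self.data * other.data,
            (self, other),
            (
                lambda g: self._unbroadcast(g * other, sa),
                lambda g: self._unbroadcast(g * self, sb),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor(other) * self ** -1.0

    def __pow__(self, p):
        p = float(p)
        return Tensor._make(
            self.data ** p, (self,), (lambda g: g * (p * self ** (p - 1.0)),)
        )

    def __matmul__(self, other):
        assert self.ndim == 2 and other.ndim == 2
        return Tensor._make(
            self.data @ other.data,
            (self, other),
            (lambda g: g @ other.T(), lambda g: self.T() @ g),
        )

    def T(self):
        return Tensor._make(self.data.T, (self,), (lambda g: g.T(),))

    # ---- nonlinearities -------------------------------------------------------
    def exp(self):
        out = Tensor._make(np.exp(self.data), (self,), ())
        out._vjps = (lambda g: g * out,)
        return out

    def log(self):
        return Tensor._make(np.log(self.data), (self,), (lambda g: g / self,))

    def tanh(self):
        out = Tensor._make(np.tanh(self.data), (self,), ())
        out._vjps = (lambda g: g * (1.0 - out * out),)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor._make(s, (self,), ())
        out._vjps = (lambda g: g * (out * (1.0 - out)),)
        return out

    def leaky_relu(self, alpha=0.3):
        # slope mask is constant w.r.t. differentiation (kink measure zero)
        slope = np.where(self.data > 0, 1.0, alpha)
        return Tensor._make(self.data * slope, (self,), (lambda g: g * Tensor(slope),))

    def sqrt(self):
        return self ** 0.5

    # ---- reductions / shaping -------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        shape = self.shape

        def vjp(g):
            gd = g
            if axis is not None and not keepdims:
                gd = gd.reshape(_keepdim_shape(shape, axis))
            return gd * Tensor(np.ones(shape))

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), (vjp,))

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        old = self.shape
        return Tensor._make(
            self.data.reshape(*shape), (self,), (lambda g: g.reshape(*old),)
        )

    def __getitem__(self, idx):
        shape = self.shape
        return Tensor._make(self.data[idx], (self,), (lambda g: _scatter(g, idx, shape),))

    # ---- backward -------------------------------------------------------------
    def backward(self, create_graph=False):
        """Accumulate gradients of `self` (a scalar) into leaf `.grad` arrays."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        leaves = [t for t in _toposort(self) if t.requires_grad and not t._parents]
        gs = grad(self, leaves, create_graph=create_graph)
        for leaf, g in zip(leaves, gs):
            arr = g.data if isinstance(g, Tensor) else g
            leaf.grad = arr if leaf.grad is None else leaf.grad + arr


def _keepdim_shape(shape, axis):
    s = list(shape)
    if isinstance(axis, int):
        axis = (axis,)
    for a in axis:
        s[a] = 1
    return tuple(s)


def _scatter(g, idx, shape):
    """Place gradient `g` into a zero tensor of `shape` at `idx` (inverse of getitem)."""
    def vjp(gg):
        return gg[idx]

    data = np.zeros(shape)
    data[idx] = g.data
    return Tensor._make(data, (g,), (vjp,))


def concat(tensors, axis=0):
    tensors = list(tensors)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def make_vjp(i):
        def vjp(g):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
            return g[tuple(sl)]

        return vjp

    data = np.concatenate([t.data for t in tensors], axis=axis)
    return Tensor._make(data, tuple(tensors), tuple(make_vjp(i) for i in range(len(tensors))))


def stack_rows(tensors):
    """Stack equally-shaped tensors along a new leading axis."""
    def make_vjp(i):
        return lambda g: g[i]

    data = np.stack([t.data for t in tensors], axis=0)
    return Tensor._make(data, tuple(tensors), tuple(make_vjp(i) for i in range(len(tensors))))


def embedding_lookup(table, indices):
    """Row lookup `table[indices]` with scatter-add gradient into the table."""
    indices = np.asarray(indices)
    n_rows = table.shape[0]

    def vjp(g):
        return _scatter_add_rows(g, indices, n_rows)

    return Tensor._make(table.data[indices], (table,), (vjp,))


def _scatter_add_rows(g, indices, n_rows):
    def vjp(gg):
        return embedding_lookup(gg, indices)

    data = np.zeros((n_rows, g.shape[-1]))
    np.add.at(data, indices.reshape(-1), g.data.reshape(-1, g.shape[-1]))
    return Tensor._make(data, (g,), (vjp,))


def _toposort(root):
    order, seen = [], set()
    stack = [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if id(p) not in seen:
                stack.append((p, False))
    return order


def grad(output, inputs, create_graph=False):
    """Gradients of scalar `output` w.r.t. `inputs`, returned as Tensors.

    With ``create_graph=True`` the returned gradients carry their own graph and
    can be differentiated again (used by the WGAN gradient penalty).
    """
    if output.data.size != 1:
        raise ValueError("grad() requires a scalar output")
    order = _toposort(output)
    grads = {id(output): Tensor(np.ones_like(output.data))}
    wanted = {id(t) for t in inputs}
    ctx = no_grad() if not create_graph else _nullcontext()
    with ctx:
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if id(node) in wanted:
                grads[id(node)] = g  # keep for return
            for p, vjp in zip(node._parents, node._vjps):
                if not p.requires_grad:
                    continue
                pg = vjp(g)
                prev = grads.get(id(p))
                grads[id(p)] = pg if prev is None else prev + pg
    out = []
    for t in inputs:
        g = grads.get(id(t))
        out.append(g if g is not None else Tensor(np.zeros_like(t.data)))
    return out


class _nullcontext:
    def __enter__(self):
        return self

    def __exit__(self, *exc):
        return False
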