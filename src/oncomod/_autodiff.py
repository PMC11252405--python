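"""Minimal reverse-mode automatic differentiation over numpy arrays.

The classifier and the mask-learning explainer both need gradients of a
scalar loss with respect to dense parameter matrices and per-edge /
per-feature mask logits.  The computation graphs involved are small (a few
hundred nodes), so a tape-based ``Tensor`` wrapping ``numpy.ndarray`` with
the handful of primitives used by the model is sufficient and keeps the
package dependency-free beyond the scientific Python stack.

Primitives: elementwise arithmetic with broadcasting, ``matmul`` (2-D),
``exp``/``log``/``sigmoid``/``relu``/``pow``, reductions (``sum``/``mean``/
``max``), ``reshape``/``concat``, and the two graph primitives
``gather_rows`` (fancy indexing along axis 0) and ``scatter_sum`` (its
adjoint).  Everything else (layer norm, softmax over edge segments,
max-pooling) is composed from these, so a single finite-difference test of
the primitives covers the whole model.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "gather_rows", "scatter_sum", "segment_max", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` by summing broadcast axes."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with a gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_bwd")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._bwd = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _node(data, parents, bwd) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._parents for p in parents):
            out._parents = tuple(parents)
            out._bwd = bwd
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------
    def _needs_grad(self) -> bool:
        return self.requires_grad or bool(self._parents)

    def __add__(self, other):
        other = Tensor._lift(other)
        out_data = self.data + other.data
        na, nb = self._needs_grad(), other._needs_grad()

        def bwd(g):
            return (
                _unbroadcast(g, self.shape) if na else None,
                _unbroadcast(g, other.shape) if nb else None,
            )

        return Tensor._node(out_data, (self, other), bwd)

    __radd__ = __add__

    def __mul__(self, other):
        other = Tensor._lift(other)
        out_data = self.data * other.data
        na, nb = self._needs_grad(), other._needs_grad()

        def bwd(g):
            return (
                _unbroadcast(g * other.data, self.shape) if na else None,
                _unbroadcast(g * self.data, other.shape) if nb else None,
            )

        return Tensor._node(out_data, (self, other), bwd)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __truediv__(self, other):
        other = Tensor._lift(other)
        return self * other.power(-1.0)

    def __rtruediv__(self, other):
        return Tensor._lift(other) * self.power(-1.0)

    def power(self, exponent: float) -> "Tensor":
        out_data = self.data**exponent

        def bwd(g):
            return (g * exponent * self.data ** (exponent - 1.0),)

        return Tensor._node(out_data, (self,), bwd)

    def __pow__(self, exponent):
        return self.power(float(exponent))

    def sqrt(self):
        return self.power(0.5)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = Tensor._lift(other)
        out_data = self.data @ other.data
        na, nb = self._needs_grad(), other._needs_grad()

        def bwd(g):
            return (
                g @ other.data.T if na else None,
                self.data.T @ g if nb else None,
            )

        return Tensor._node(out_data, (self, other), bwd)

    __matmul__ = matmul

    # -- nonlinearities -------------------------------------------------------
    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def bwd(g):
            return (g * out_data,)

        return Tensor._node(out_data, (self,), bwd)

    def log(self) -> "Tensor":
        out_data = np.log(self.data)

        def bwd(g):
            return (g / self.data,)

        return Tensor._node(out_data, (self,), bwd)

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            return (g * out_data * (1.0 - out_data),)

        return Tensor._node(out_data, (self,), bwd)

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def bwd(g):
            return (g * mask,)

        return Tensor._node(self.data * mask, (self,), bwd)

    # -- reductions / reshaping ----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.shape

        def bwd(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, shape).copy(),)

        return Tensor._node(out_data, (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        """Max along an axis; ties route the gradient to the first argmax."""
        idx = np.argmax(self.data, axis=axis)
        out_data = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis)
        if not keepdims:
            out_data = np.squeeze(out_data, axis)
        shape = self.shape

        def bwd(g):
            g = np.asarray(g)
            if not keepdims:
                g = np.expand_dims(g, axis)
            full = np.zeros(shape)
            np.put_along_axis(full, np.expand_dims(idx, axis), g, axis)
            return (full,)

        return Tensor._node(out_data, (self,), bwd)

    def reshape(self, *shape) -> "Tensor":
        old = self.shape
        out_data = self.data.reshape(*shape)

        def bwd(g):
            return (g.reshape(old),)

        return Tensor._node(out_data, (self,), bwd)

    def __getitem__(self, key) -> "Tensor":
        out_data = self.data[key]
        shape = self.shape

        def bwd(g):
            full = np.zeros(shape)
            np.add.at(full, key, g)
            return (full,)

        return Tensor._node(out_data, (self,), bwd)

    # -- backward pass --------------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            stack = [(t, iter(t._parents))]
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._bwd is None:
                continue
            for parent, pg in zip(node._parents, node._bwd(g)):
                if pg is None:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg

    def zero_grad(self) -> None:
        self.grad = None


# ---------------------------------------------------------------------------
# free functions
# ---------------------------------------------------------------------------

_csr_cache: dict = {}


def _scatter_matrix(index: np.ndarray, n: int):
    """Cached (n x len(index)) CSR with a 1 at (index[e], e): segment-sum operator."""
    import scipy.sparse as sp

    key = (index.tobytes(), n)
    M = _csr_cache.get(key)
    if M is None:
        e = len(index)
        M = sp.csr_matrix((np.ones(e), (index, np.arange(e))), shape=(n, e))
        if len(_csr_cache) > 64:
            _csr_cache.clear()
        _csr_cache[key] = M
    return M


def _segment_sum(values: np.ndarray, index: np.ndarray, n: int) -> np.ndarray:
    tail = values.shape[1:]
    out = _scatter_matrix(index, n) @ values.reshape(len(index), -1)
    return np.ascontiguousarray(out).reshape((n,) + tail)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._node(out_data, tuple(tensors), bwd)


def gather_rows(t: Tensor, index: np.ndarray) -> Tensor:
    """``t[index]`` along axis 0; adjoint scatter-adds."""
    index = np.asarray(index, dtype=np.intp)
    out_data = t.data[index]
    n = t.shape[0]

    def bwd(g):
        return (_segment_sum(g, index, n),)

    return Tensor._node(out_data, (t,), bwd)


def scatter_sum(t: Tensor, index: np.ndarray, n: int) -> Tensor:
    """Sum rows of ``t`` into ``n`` output rows by ``index`` (axis 0)."""
    index = np.asarray(index, dtype=np.intp)
    out_data = _segment_sum(t.data, index, n)

    def bwd(g):
        return (g[index],)

    return Tensor._node(out_data, (t,), bwd)


def segment_max(values: np.ndarray, index: np.ndarray, n: int) -> np.ndarray:
    """Per-segment max of raw values (no gradient; used as a softmax shift)."""
    out = np.full((n,) + values.shape[1:], -np.inf)
    np.maximum.at(out, index, values)
    return out


class Adam:
    """Adaptive-moment optimizer over a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * p.grad
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * p.grad**2
            m_hat = self._m[i] / (1 - self.b1**self.t)
            v_hat = self._v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
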