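"""Minimal reverse-mode automatic differentiation on numpy arrays.

A tape-free, graph-walking autograd: each :class:`Tensor` wraps an
``ndarray`` and remembers its parents plus a closure that propagates the
output gradient back to them.  ``Tensor.backward()`` topologically sorts
the graph and accumulates gradients into ``.grad``.

Only the operations needed by the coordinate-attention LSTM classifier are
implemented (broadcast arithmetic, matmul, sigmoid/tanh/exp/log, reductions,
reshape/transpose/slice/concat/flip, clip).  Gradients are checked against
finite differences in the test suite.
"""

from __future__ import annotations

import contextlib

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(float)
        self.data: np.ndarray = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph plumbing ---------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad = self.grad + grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other)
        a, b = self, other

        def backward(g):
            a._accum(_unbroadcast(g, a.shape))
            b._accum(_unbroadcast(g, b.shape))

        return self._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return self._make(-a.data, (a,), lambda g: a._accum(-g))

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        a, b = self, other

        def backward(g):
            a._accum(_unbroadcast(g * b.data, a.shape))
            b._accum(_unbroadcast(g * a.data, b.shape))

        return self._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        a, b = self, other

        def backward(g):
            a._accum(_unbroadcast(g / b.data, a.shape))
            b._accum(_unbroadcast(-g * a.data / (b.data**2), b.shape))

        return self._make(a.data / b.data, (a, b), backward)

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, exponent: float):
        a = self
        p = float(exponent)

        def backward(g):
            a._accum(g * p * a.data ** (p - 1.0))

        return self._make(a.data**p, (a,), backward)

    def __matmul__(self, other):
        other = _as_tensor(other)
        a, b = self, other

        def backward(g):
            if b.data.ndim >= 2:
                ga = g @ np.swapaxes(b.data, -1, -2)
            else:  # b is a vector
                ga = np.expand_dims(g, -1) * b.data
            if a.data.ndim >= 2:
                gb = np.swapaxes(a.data, -1, -2) @ g
            else:
                gb = np.expand_dims(a.data, -1) * np.expand_dims(g, -2)
            a._accum(_unbroadcast(np.asarray(ga), a.shape))
            b._accum(_unbroadcast(np.asarray(gb), b.shape))

        return self._make(a.data @ b.data, (a, b), backward)

    # -- nonlinearities ---------------------------------------------------

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))

        def backward(g):
            a._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (a,), backward)

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def backward(g):
            a._accum(g * (1.0 - out_data**2))

        return self._make(out_data, (a,), backward)

    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def backward(g):
            a._accum(g * out_data)

        return self._make(out_data, (a,), backward)

    def log(self):
        a = self

        def backward(g):
            a._accum(g / a.data)

        return self._make(np.log(a.data), (a,), backward)

    def silu(self):
        """x * sigmoid(x), the SiLU activation."""
        return self * self.sigmoid()

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only through the unclamped region."""
        a = self
        mask = (a.data >= lo) & (a.data <= hi)

        def backward(g):
            a._accum(g * mask)

        return self._make(np.clip(a.data, lo, hi), (a,), backward)

    # -- reductions -------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def backward(g):
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape).copy())
            else:
                ge = np.expand_dims(g, axis) if not keepdims else g
                a._accum(np.broadcast_to(ge, a.shape).copy())

        return self._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if np.isscalar(axis) else tuple(axis)
            n = int(np.prod([self.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max_const(self, axis=None, keepdims: bool = False) -> np.ndarray:
        """Max of the values as a plain array (used for softmax shifts)."""
        return self.data.max(axis=axis, keepdims=keepdims)

    # -- shape ops --------------------------------------------------------

    def reshape(self, *shape):
        a = self
        old = a.shape

        def backward(g):
            a._accum(g.reshape(old))

        return self._make(a.data.reshape(*shape), (a,), backward)

    def transpose(self, *axes):
        a = self
        if not axes:
            axes = tuple(reversed(range(a.ndim)))
        inv = np.argsort(axes)

        def backward(g):
            a._accum(g.transpose(inv))

        return self._make(a.data.transpose(axes), (a,), backward)

    def __getitem__(self, idx):
        a = self

        def backward(g):
            # in-place scatter-add: avoids allocating a full-size zero array
            # for every slice (the LSTM loop slices one column per timestep)
            if not a.requires_grad:
                return
            if a.grad is None:
                a.grad = np.zeros_like(a.data)
            a.grad[idx] += g

        return self._make(a.data[idx], (a,), backward)

    def flip(self, axis: int):
        a = self

        def backward(g):
            a._accum(np.flip(g, axis=axis))

        return self._make(np.flip(a.data, axis=axis), (a,), backward)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accum(g[tuple(idx)])

    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    proto = tensors[0]
    return proto._make(out_data, tensors, backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax along ``axis`` (shift is non-differentiated,
    which is exact since softmax is shift-invariant)."""
    shifted = x - Tensor(x.max_const(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def parameter(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> Tensor:
    """Uniform(-1/sqrt(fan_in), 1/sqrt(fan_in)) initialised trainable tensor."""
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)
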