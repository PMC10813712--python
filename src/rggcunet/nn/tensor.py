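"""A compact reverse-mode automatic-differentiation engine over numpy arrays.

Tensors wrap ``numpy.ndarray`` values and record, for each produced tensor,
the parent tensors and a closure that maps the output gradient to parent
gradients.  Calling :meth:`Tensor.backward` on a scalar tensor runs the tape
in reverse topological order.  The op set is deliberately small: exactly what
a convolutional encoder-decoder with attention needs (elementwise algebra,
reductions, shape ops, activations).  Convolutions, pooling, normalisation
and resampling live in :mod:`rggcunet.nn.functional`.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were size-1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None,
                 name: str | None = None):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward
        self.name = name

    # ---- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        grad = ", grad" if self.requires_grad else ""
        return f"Tensor(shape={self.shape}, dtype={self.dtype}{grad})"

    # ---- autodiff ------------------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (scalar unless ``grad`` is given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ---- elementwise algebra ------------------------------------------
    def __add__(self, other):
        other = as_tensor(other, self.dtype)
        out_req = self.requires_grad or other.requires_grad

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor(self.data + other.data, out_req, (self, other), bwd if out_req else None)

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other, self.dtype)
        out_req = self.requires_grad or other.requires_grad

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor(self.data * other.data, out_req, (self, other), bwd if out_req else None)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other, self.dtype))

    def __rsub__(self, other):
        return as_tensor(other, self.dtype) + (-self)

    def __truediv__(self, other):
        other = as_tensor(other, self.dtype)
        out_req = self.requires_grad or other.requires_grad
        out = self.data / other.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(-g * out / other.data, other.shape))

        return Tensor(out, out_req, (self, other), bwd if out_req else None)

    def __rtruediv__(self, other):
        return as_tensor(other, self.dtype) / self

    # ---- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)
        req = self.requires_grad

        def bwd(g):
            gg = g
            if not keepdims and axis is not None:
                gg = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(gg, self.shape).copy())

        return Tensor(out, req, (self,), bwd if req else None)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # ---- activations ---------------------------------------------------
    def relu(self):
        mask = self.data > 0
        req = self.requires_grad

        def bwd(g):
            self._accumulate(g * mask)

        return Tensor(self.data * mask, req, (self,), bwd if req else None)

    def sigmoid(self):
        from scipy.special import expit  # numerically stable logistic
        out = expit(self.data)
        req = self.requires_grad

        def bwd(g):
            self._accumulate(g * out * (1.0 - out))

        return Tensor(out, req, (self,), bwd if req else None)

    # ---- shape ops -----------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        req = self.requires_grad

        def bwd(g):
            self._accumulate(g.reshape(self.shape))

        return Tensor(self.data.reshape(shape), req, (self,), bwd if req else None)

    def transpose(self, axes):
        inv = np.argsort(axes)
        req = self.requires_grad

        def bwd(g):
            self._accumulate(np.transpose(g, inv))

        return Tensor(np.transpose(self.data, axes), req, (self,), bwd if req else None)

    def __getitem__(self, idx):
        req = self.requires_grad

        def bwd(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            self._accumulate(full)

        return Tensor(self.data[idx], req, (self,), bwd if req else None)


def as_tensor(x, dtype=None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    arr = np.asarray(x, dtype=dtype)
    return Tensor(arr)


def concat(tensors: list[Tensor], axis: int) -> Tensor:
    """Concatenate tensors along ``axis`` with gradient routing back to parts."""
    tensors = [as_tensor(t) for t in tensors]
    req = any(t.requires_grad for t in tensors)
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor(out, req, tuple(tensors), bwd if req else None)
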