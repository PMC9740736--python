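"""Reverse-mode automatic differentiation on NumPy arrays.

A small tape-based engine providing exactly the operations the segmentation
network needs: broadcast-aware arithmetic, (batched) matrix products, axis
reductions with max-routing, gather/scatter indexing, and the elementwise
nonlinearities.  Gradients are accumulated in ``float64`` throughout, which is
what lets the finite-difference checks in the test suite hold to 1e-4
relative tolerance.

Only :class:`Tensor`, the functional helpers (:func:`concat`, :func:`stack`,
:func:`softmax`, :func:`layer_norm`) and :class:`Adam` are public.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack", "softmax", "layer_norm", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


class Tensor:
    """An n-d array that records the operations applied to it.

    Parameters
    ----------
    data:
        Array-like; stored as ``float64``.
    requires_grad:
        Whether :meth:`backward` should populate ``.grad`` for this node.
    """

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction of derived nodes ------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

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

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        a, b = self, _as_tensor(other)

        def backward(g):
            return _unbroadcast(g, a.shape), _unbroadcast(g, b.shape)

        return Tensor._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._make(-a.data, (a,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        a, b = self, _as_tensor(other)

        def backward(g):
            return (_unbroadcast(g * b.data, a.shape),
                    _unbroadcast(g * a.data, b.shape))

        return Tensor._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, _as_tensor(other)

        def backward(g):
            return (_unbroadcast(g / b.data, a.shape),
                    _unbroadcast(-g * a.data / (b.data ** 2), b.shape))

        return Tensor._make(a.data / b.data, (a, b), backward)

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, p: float):
        a = self

        def backward(g):
            return (g * p * a.data ** (p - 1),)

        return Tensor._make(a.data ** p, (a,), backward)

    def __matmul__(self, other):
        a, b = self, _as_tensor(other)

        def backward(g):
            ad, bd = a.data, b.data
            if ad.ndim == 1:
                ad = ad[None, :]
            if bd.ndim == 1:
                bd = bd[:, None]
            gm = g
            if a.data.ndim == 1:
                gm = gm[..., None, :]
            if b.data.ndim == 1:
                gm = gm[..., :, None]
            ga = gm @ bd.swapaxes(-1, -2)
            gb = ad.swapaxes(-1, -2) @ gm
            if a.data.ndim == 1:
                ga = ga.reshape(ga.shape[:-2] + (ga.shape[-1],))
            if b.data.ndim == 1:
                gb = gb.reshape(gb.shape[:-2] + (gb.shape[-2],))
            return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

        return Tensor._make(a.data @ b.data, (a, b), backward)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, a.shape).copy(),)
            gx = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gx, a.shape).copy(),)

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.size if axis is None else self.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def max(self, axis: int, keepdims: bool = False):
        """Max along ``axis``; the gradient routes to the first arg-max."""
        a = self
        idx = np.argmax(a.data, axis=axis)
        out = np.take_along_axis(a.data, np.expand_dims(idx, axis), axis=axis)

        def backward(g):
            gx = g if keepdims else np.expand_dims(g, axis)
            grad = np.zeros_like(a.data)
            np.put_along_axis(grad, np.expand_dims(idx, axis), gx, axis=axis)
            return (grad,)

        res = out if keepdims else np.squeeze(out, axis=axis)
        return Tensor._make(res, (a,), backward)

    # -- elementwise -------------------------------------------------------
    def relu(self):
        a = self
        mask = a.data > 0
        return Tensor._make(a.data * mask, (a,), lambda g: (g * mask,))

    def exp(self):
        a = self
        out_data = np.exp(a.data)
        return Tensor._make(out_data, (a,), lambda g: (g * out_data,))

    def log(self):
        a = self
        return Tensor._make(np.log(a.data), (a,), lambda g: (g / a.data,))

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)
        return Tensor._make(out_data, (a,), lambda g: (g * 0.5 / out_data,))

    def abs(self):
        a = self
        sign = np.sign(a.data)
        return Tensor._make(np.abs(a.data), (a,), lambda g: (g * sign,))

    def clip_min(self, lo: float):
        a = self
        mask = a.data >= lo
        return Tensor._make(np.maximum(a.data, lo), (a,), lambda g: (g * mask,))

    # -- shape -------------------------------------------------------------
    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return Tensor._make(a.data.reshape(shape), (a,),
                            lambda g: (g.reshape(a.shape),))

    def transpose(self, *axes):
        a = self
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        if not axes:
            axes = tuple(range(a.ndim))[::-1]
        inv = np.argsort(axes)
        return Tensor._make(a.data.transpose(axes), (a,),
                            lambda g: (g.transpose(inv),))

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        a = self

        def backward(g):
            grad = np.zeros_like(a.data)
            np.add.at(grad, idx, g)
            return (grad,)

        return Tensor._make(a.data[idx], (a,), backward)

    def take_rows(self, indices: np.ndarray) -> "Tensor":
        """Gather rows (axis 0) by an arbitrary integer index array."""
        return self[np.asarray(indices)]

    # -- autodiff driver ---------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_ = [(self, False)]
        while stack_:
            node, processed = stack_.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack_.append((node, True))
            for p in node._parents:
                stack_.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg
        # leaves reached through the dict (e.g. self is a leaf)
        # handled above; nothing else to do


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offs = np.cumsum([0] + sizes)

    def backward(g):
        return tuple(np.take(g, range(offs[i], offs[i + 1]), axis=axis)
                     for i in range(len(tensors)))

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tuple(tensors), backward)


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]

    def backward(g):
        parts = np.split(g, len(tensors), axis=axis)
        return tuple(np.squeeze(p, axis=axis) for p in parts)

    return Tensor._make(np.stack([t.data for t in tensors], axis=axis),
                        tuple(tensors), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize the last axis to zero mean / unit variance, then affine."""
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    return centered / (var + eps).sqrt() * gain + bias


class Adam:
    """Adaptive-moment gradient descent over a list of parameter Tensors."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
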