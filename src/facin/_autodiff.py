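"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the edge-aware graph-attention model and the
mask explainer need: broadcasted arithmetic, matmul, row gather / segment sum
(the scatter-gather pair behind sparse message passing), pointwise
nonlinearities and reductions.  Gradients are accumulated on leaf tensors via
a topologically sorted tape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "concat", "segment_sum", "segment_softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    # ---- construction helpers -------------------------------------------
    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # ---- autodiff core ---------------------------------------------------
    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._backward is None:  # leaf
                t.grad = g if t.grad is None else t.grad + g
                continue
            for p, pg in zip(t._parents, t._backward(g)):
                if not p.requires_grad or pg is None:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg

    # ---- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = Tensor.as_tensor(other)
        a, b = self, other
        return self._make(
            a.data + b.data,
            (a, b),
            lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)
        a, b = self, other
        return self._make(
            a.data * b.data,
            (a, b),
            lambda g: (
                _unbroadcast(g * b.data, a.shape),
                _unbroadcast(g * a.data, b.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)
        a, b = self, other
        return self._make(
            a.data / b.data,
            (a, b),
            lambda g: (
                _unbroadcast(g / b.data, a.shape),
                _unbroadcast(-g * a.data / (b.data ** 2), b.shape),
            ),
        )

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)
        a, b = self, other
        return self._make(
            a.data @ b.data,
            (a, b),
            lambda g: (g @ b.data.T, a.data.T @ g),
        )

    # ---- pointwise -------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return self._make(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return self._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        return self._make(s, (self,), lambda g: (g * s * (1.0 - s),))

    def softplus(self):
        # numerically stable log(1 + exp(x))
        out = np.logaddexp(0.0, self.data)
        s = 1.0 / (1.0 + np.exp(-self.data))
        return self._make(out, (self,), lambda g: (g * s,))

    def relu(self):
        mask = self.data > 0
        return self._make(self.data * mask, (self,), lambda g: (g * mask,))

    def leaky_relu(self, slope: float = 0.2):
        mult = np.where(self.data > 0, 1.0, slope)
        return self._make(self.data * mult, (self,), lambda g: (g * mult,))

    # ---- shape / index ---------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        shape = self.shape

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, shape).copy(),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, shape).copy(),)

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        old = self.shape
        return self._make(self.data.reshape(*shape), (self,), lambda g: (g.reshape(old),))

    def gather(self, idx) -> "Tensor":
        """Row selection out[k] = self[idx[k]] with scatter-add backward."""
        idx = np.asarray(idx)
        shape = self.shape

        def backward(g):
            out = np.zeros(shape, dtype=np.float64)
            np.add.at(out, idx, g)
            return (out,)

        return self._make(self.data[idx], (self,), backward)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def segment_sum(t: Tensor, segment_ids, num_segments: int) -> Tensor:
    """out[s] = sum of rows of t whose segment_ids == s."""
    segment_ids = np.asarray(segment_ids)
    out_shape = (num_segments,) + t.data.shape[1:]
    data = np.zeros(out_shape, dtype=np.float64)
    np.add.at(data, segment_ids, t.data)

    def backward(g):
        return (g[segment_ids],)

    return t._make(data, (t,), backward)


def segment_softmax(scores: Tensor, segment_ids, num_segments: int) -> Tensor:
    """Softmax of `scores` (1-D) within groups given by segment_ids."""
    segment_ids = np.asarray(segment_ids)
    # shift by per-segment max (constant w.r.t. gradient, softmax-invariant)
    seg_max = np.full(num_segments, -np.inf)
    np.maximum.at(seg_max, segment_ids, scores.data)
    seg_max[~np.isfinite(seg_max)] = 0.0
    shifted = scores - Tensor(seg_max[segment_ids])
    e = shifted.exp()
    denom = segment_sum(e, segment_ids, num_segments).gather(segment_ids)
    return e / denom


class Adam:
    """Plain Adam over a list of leaf Tensors."""

    def __init__(self, params, lr=1e-2, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
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
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay:
                p.data = p.data - self.lr * self.weight_decay * p.data
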