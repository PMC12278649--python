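"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package's neural components (modality encoders, view augmentor, prediction
heads) are small dense networks; this module provides the tensor type, the
layers and the Adam optimizer they are built from.  Everything runs in float64,
which makes finite-difference gradient checks meaningful at tight tolerances
and keeps training bitwise reproducible for a fixed seed and thread count.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "constant",
    "parameter",
    "concat",
    "assemble_matrix",
    "softmax",
    "logsumexp",
    "dropout",
    "layer_norm",
    "Linear",
    "Adam",
    "warmup_poly_lr",
]


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus a backward closure for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")
    __array_priority__ = 100  # numpy defers binary ops to Tensor

    def __init__(self, data, requires_grad: bool = False, _prev=(), _backward=None):
        self.data = _as_array(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._prev = _prev
        self._backward = _backward

    # -- basic introspection ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- graph plumbing -----------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        return Tensor(data, requires_grad=req,
                      _prev=tuple(p for p in parents if p.requires_grad),
                      _backward=backward if req else None)

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(node):
            stack = [(node, False)]
            while stack:
                n, done = stack.pop()
                if done:
                    topo.append(n)
                    continue
                if id(n) in seen:
                    continue
                seen.add(id(n))
                stack.append((n, True))
                for p in n._prev:
                    stack.append((p, False))

        visit(self)
        self.grad = _as_array(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad):
        if self.grad is None:
            # copy: `grad` may be a view into another node's gradient buffer
            self.grad = np.array(grad, dtype=np.float64)
        else:
            self.grad += grad

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out = self._make(self.data + other.data, (self, other), None)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        out = self._make(self.data * other.data, (self, other), None)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** (-1.0)

    def __rtruediv__(self, other):
        return self._lift(other) * self ** (-1.0)

    def __pow__(self, p: float):
        out = self._make(self.data ** p, (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1.0))

        out._backward = backward
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        a, b = self.data, other.data
        if a.ndim > 2 or b.ndim > 2:
            raise ValueError("matmul supports 1-D and 2-D operands only")
        out = self._make(a @ b, (self, other), None)

        def backward(g):
            g = np.asarray(g)
            if self.requires_grad:
                if a.ndim == 2 and b.ndim == 2:
                    ga = g @ b.T
                elif a.ndim == 2 and b.ndim == 1:   # out (n,)
                    ga = np.outer(g, b)
                elif a.ndim == 1 and b.ndim == 2:   # out (p,)
                    ga = g @ b.T
                else:                               # scalar out
                    ga = g * b
                self._accum(ga)
            if other.requires_grad:
                if a.ndim == 2 and b.ndim == 2:
                    gb = a.T @ g
                elif a.ndim == 2 and b.ndim == 1:
                    gb = a.T @ g
                elif a.ndim == 1 and b.ndim == 2:
                    gb = np.outer(a, g)
                else:
                    gb = g * a
                other._accum(gb)

        out._backward = backward
        return out

    # -- elementwise nonlinearities ------------------------------------------
    def exp(self):
        e = np.exp(self.data)
        out = self._make(e, (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g * e)

        out._backward = backward
        return out

    def log(self):
        out = self._make(np.log(self.data), (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        out._backward = backward
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = self._make(t, (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - t * t))

        out._backward = backward
        return out

    def relu(self):
        mask = self.data > 0
        out = self._make(self.data * mask, (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        out._backward = backward
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = self._make(s, (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))

        out._backward = backward
        return out

    def clamp(self, lo: float, hi: float):
        """Clip values; gradient passes only through the interior."""
        mask = (self.data > lo) & (self.data < hi)
        out = self._make(np.clip(self.data, lo, hi), (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        out._backward = backward
        return out

    # -- reductions / shape -------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis=None, keepdims: bool = False):
        """Max reduction; the subgradient goes to the first argmax."""
        data = self.data.max(axis=axis, keepdims=keepdims)
        out = self._make(data, (self,), None)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                grad = np.zeros_like(self.data)
                grad.flat[int(np.argmax(self.data))] = float(np.asarray(g))
                self._accum(grad)
                return
            idx = np.argmax(self.data, axis=axis)
            grad = np.zeros_like(self.data)
            gg = g if keepdims else np.expand_dims(g, axis)
            np.put_along_axis(grad, np.expand_dims(idx, axis), gg, axis=axis)
            self._accum(grad)

        out._backward = backward
        return out

    def reshape(self, *shape):
        out = self._make(self.data.reshape(*shape), (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        out._backward = backward
        return out

    @property
    def T(self):
        out = self._make(self.data.T, (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g.T)

        out._backward = backward
        return out

    def take_rows(self, idx):
        """Row gather (embedding lookup); gradient scatters back with np.add.at."""
        idx = np.asarray(idx, dtype=np.intp)
        out = self._make(self.data[idx], (self,), None)

        def backward(g):
            if self.requires_grad:
                grad = np.zeros_like(self.data)
                np.add.at(grad, idx, g)
                self._accum(grad)

        out._backward = backward
        return out


# -- constructors -----------------------------------------------------------

def constant(x) -> Tensor:
    return Tensor(x)


def parameter(x) -> Tensor:
    return Tensor(x, requires_grad=True)


# -- composite ops ----------------------------------------------------------

def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad for t in tensors)
    out = Tensor(data, requires_grad=req,
                 _prev=tuple(t for t in tensors if t.requires_grad))

    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    out._backward = backward if req else None
    return out


def assemble_matrix(entries, shape) -> Tensor:
    """Build a dense (n, m) tensor from sparse column entries.

    `entries` is a list of (row_indices, col_index, vector_tensor); every
    vector lands in column `col_index` at the given rows.  Rows not covered
    stay zero.  Used to scatter per-view predictions into the dense
    per-triplet prediction matrix.
    """
    data = np.zeros(shape)
    parents = []
    for rows, col, vec in entries:
        data[np.asarray(rows, dtype=np.intp), col] = vec.data
        if vec.requires_grad:
            parents.append(vec)
    out = Tensor(data, requires_grad=bool(parents), _prev=tuple(parents))

    def backward(g):
        for rows, col, vec in entries:
            if vec.requires_grad:
                vec._accum(g[np.asarray(rows, dtype=np.intp), col])

    out._backward = backward if parents else None
    return out


def scatter_vector(values: Tensor, rows, cols, shape) -> Tensor:
    """Dense (n, m) tensor with `values` placed at (rows[i], cols[i]);
    positions must be unique, the rest stays zero."""
    rows = np.asarray(rows, dtype=np.intp)
    cols = np.asarray(cols, dtype=np.intp)
    data = np.zeros(shape)
    data[rows, cols] = values.data
    out = Tensor(data, requires_grad=values.requires_grad,
                 _prev=(values,) if values.requires_grad else ())

    def backward(g):
        values._accum(g[rows, cols])

    out._backward = backward if values.requires_grad else None
    return out


def logsumexp(x: Tensor, axis: int = -1, keepdims: bool = False) -> Tensor:
    m = constant(x.data.max(axis=axis, keepdims=True))
    s = (x - m).exp().sum(axis=axis, keepdims=True).log() + m
    if not keepdims:
        s = s.reshape(tuple(d for i, d in enumerate(s.shape) if i != (axis % x.ndim)))
    return s


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = constant(x.data.max(axis=axis, keepdims=True))
    e = (x - m).exp()
    return e / e.sum(axis=axis, keepdims=True)


def dropout(x: Tensor, rate: float, rng: np.random.Generator | None, train: bool) -> Tensor:
    """Inverted dropout; identity when rate == 0 or in eval mode."""
    if not train or rate <= 0.0:
        return x
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * constant(mask)


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-6) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    var = ((x - mu) ** 2.0).mean(axis=-1, keepdims=True)
    return (x - mu) / ((var + eps) ** 0.5) * gain + bias


class Linear:
    """Dense layer y = x W + b with uniform Kaiming-style init."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, bias: bool = True):
        bound = 1.0 / np.sqrt(n_in)
        self.W = parameter(rng.uniform(-bound, bound, size=(n_in, n_out)))
        self.b = parameter(rng.uniform(-bound, bound, size=(n_out,))) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = Tensor._lift(x) @ self.W
        return y + self.b if self.b is not None else y

    def parameters(self):
        return [self.W] + ([self.b] if self.b is not None else [])


class Adam:
    """Adam with optional decoupled (AdamW-style) weight decay."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
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

    def step(self, lr: float | None = None):
        lr = self.lr if lr is None else lr
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - lr * (mhat / (np.sqrt(vhat) + self.eps)
                                    + self.weight_decay * p.data)


def warmup_poly_lr(step: int, base_lr: float, warmup: int, total: int,
                   power: float = 1.0, end_lr: float = 0.0) -> float:
    """Linear warmup followed by polynomial decay to end_lr at `total` steps."""
    if warmup > 0 and step < warmup:
        return base_lr * (step + 1) / warmup
    if step >= total:
        return end_lr
    frac = (total - step) / max(1, total - warmup)
    return end_lr + (base_lr - end_lr) * frac ** power
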