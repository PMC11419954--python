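"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the miniature trainable models in this
package need: elementwise arithmetic with broadcasting, matmul, reductions,
smooth nonlinearities, absolute value / clamping (subgradient at kinks),
indexing and embedding lookup, concatenation, and a stride-1 2D
convolution. Gradients are accumulated by topological-order backprop;
analytic gradients are validated against central differences in the test
suite.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum-reduce ``grad`` back to ``shape`` after numpy broadcasting."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev=()):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._backward = None
        self._prev = _prev

    # -- infrastructure ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        g = np.array(g, dtype=float, copy=True)
        if self.grad is None:
            self.grad = g
        else:
            self.grad = self.grad + g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t: "Tensor"):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.asarray(grad, dtype=float))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)
        # graphs are one-shot: dismantle closure<->tensor reference cycles
        # so intermediate buffers free by refcount, not the cycle collector
        for t in topo:
            t._backward = None
            t._prev = ()

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ----------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bw(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))
        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _prev=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def bw(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * Tensor._lift(other) ** -1.0

    def __rtruediv__(self, other):
        return Tensor._lift(other) * self ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, _prev=(self,))
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def bw(g):
            a, b = self.data, other.data
            if a.ndim == 1 and b.ndim == 1:
                self._accum(g * b)
                other._accum(g * a)
            elif b.ndim == 1:
                self._accum(np.multiply.outer(g, b) if g.ndim else g * b)
                other._accum(np.tensordot(g, a, axes=(range(g.ndim), range(g.ndim))))
            elif a.ndim == 1:
                self._accum(g @ b.T if b.ndim == 2 else np.tensordot(g, b, axes=(-1, -1)))
                other._accum(np.multiply.outer(a, g))
            else:
                ga = g @ np.swapaxes(b, -1, -2)
                gb = np.swapaxes(a, -1, -2) @ g
                self._accum(_unbroadcast(ga, a.shape))
                other._accum(_unbroadcast(gb, b.shape))
        out._backward = bw
        return out

    # -- elementwise functions ------------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), _prev=(self,))
        out._backward = lambda g: self._accum(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def sqrt(self):
        out = Tensor(np.sqrt(self.data), _prev=(self,))
        out._backward = lambda g: self._accum(g * 0.5 / np.maximum(out.data, 1e-300))
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), _prev=(self,))
        out._backward = lambda g: self._accum(g * (1 - out.data ** 2))
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, _prev=(self,))
        out._backward = lambda g: self._accum(g * s * (1 - s))
        return out

    def abs(self):
        out = Tensor(np.abs(self.data), _prev=(self,))
        out._backward = lambda g: self._accum(g * np.sign(self.data))
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))
        out._backward = lambda g: self._accum(g * (self.data > 0))
        return out

    def clamp_max(self, hi: float):
        mask = self.data < hi
        out = Tensor(np.minimum(self.data, hi), _prev=(self,))
        out._backward = lambda g: self._accum(g * mask)
        return out

    def clamp_min(self, lo: float):
        mask = self.data > lo
        out = Tensor(np.maximum(self.data, lo), _prev=(self,))
        out._backward = lambda g: self._accum(g * mask)
        return out

    # -- reductions / shaping -------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape))
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _prev=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        axes = axes or None
        out = Tensor(self.data.transpose(axes), _prev=(self,))
        inv = np.argsort(axes) if axes else None
        out._backward = lambda g: self._accum(g.transpose(inv) if inv is not None else g.T)
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _prev=(self,))

        def bw(g):
            buf = np.zeros_like(self.data)
            np.add.at(buf, idx, g)
            self._accum(buf)
        out._backward = bw
        return out

    def norm(self, axis=-1, keepdims=False, eps: float = 1e-12):
        """Euclidean norm, epsilon-stabilized for differentiability at 0."""
        return ((self * self).sum(axis=axis, keepdims=keepdims) + eps).sqrt()


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accum(g[tuple(sl)])
    out._backward = bw
    return out


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), _prev=tuple(tensors))

    def bw(g):
        for i, t in enumerate(tensors):
            t._accum(np.take(g, i, axis=axis))
    out._backward = bw
    return out


def logsumexp(x: Tensor, axis: int = -1, keepdims: bool = False) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)  # detached shift, gradient-exact
    shifted = x - Tensor(m)
    out = shifted.exp().sum(axis=axis, keepdims=True).log() + Tensor(m)
    if not keepdims:
        ax = axis % out.ndim
        out = out.reshape(tuple(s for i, s in enumerate(out.shape) if i != ax))
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    return (x - logsumexp(x, axis=axis, keepdims=True)).exp()


def cross_entropy(logits: Tensor, target_index: np.ndarray, axis: int = -1) -> Tensor:
    """Mean softmax cross-entropy with integer targets along ``axis``."""
    logp = logits - logsumexp(logits, axis=axis, keepdims=True)
    if axis not in (-1, logits.ndim - 1):
        raise ValueError("targets must index the last axis")
    flat = logp.reshape(-1, logits.shape[-1])
    rows = np.arange(flat.shape[0])
    picked = flat[(rows, np.asarray(target_index).reshape(-1))]
    return -picked.mean()


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, padding: int = 0) -> Tensor:
    """Stride-1 2D convolution: x (N,C,H,W), w (F,C,kh,kw) -> (N,F,Ho,Wo)."""
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    N, C, H, W = xp.shape
    F, _, kh, kw = w.data.shape
    Ho, Wo = H - kh + 1, W - kw + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(N * Ho * Wo, C * kh * kw)
    wmat = w.data.reshape(F, -1)
    out_data = cols @ wmat.T
    if b is not None:
        out_data = out_data + b.data
    out_data = out_data.reshape(N, Ho, Wo, F).transpose(0, 3, 1, 2)
    prev = (x, w) + ((b,) if b is not None else ())
    out = Tensor(out_data, _prev=prev)

    def bw(g):
        g2 = g.transpose(0, 2, 3, 1).reshape(-1, F)
        w._accum((g2.T @ cols).reshape(w.data.shape))
        if b is not None:
            b._accum(g2.sum(axis=0))
        dcols = (g2 @ wmat).reshape(N, Ho, Wo, C, kh, kw)
        dxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i:i + Ho, j:j + Wo] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        if padding:
            dxp = dxp[:, :, padding:-padding, padding:-padding]
        x._accum(dxp)
    out._backward = bw
    return out


def cross(a: Tensor, b: Tensor) -> Tensor:
    """Cross product along the last axis (length 3)."""
    ax, ay, az = a[..., 0], a[..., 1], a[..., 2]
    bx, by, bz = b[..., 0], b[..., 1], b[..., 2]
    return stack([ay * bz - az * by, az * bx - ax * bz, ax * by - ay * bx], axis=-1)


class Parameter(Tensor):
    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def parameters_of(obj) -> list[Parameter]:
    """Collect Parameters from a (possibly nested) dict attribute tree."""
    out: list[Parameter] = []

    def walk(v):
        if isinstance(v, Parameter):
            out.append(v)
        elif isinstance(v, dict):
            for vv in v.values():
                walk(vv)
        elif isinstance(v, (list, tuple)):
            for vv in v:
                walk(vv)
    walk(obj)
    return out


class SGD:
    """Gradient descent with classical momentum."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3, momentum: float = 0.9):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.vel = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self.vel):
            if p.grad is None:
                continue
            v *= self.momentum
            v -= self.lr * p.grad
            p.data += v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class Adam:
    """Adam optimizer (bias-corrected first/second moments)."""

    def __init__(self, params: list[Parameter], lr: float = 1e-2,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            mh = m / (1 - self.b1 ** self.t)
            vh = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
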