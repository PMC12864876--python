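"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the package's training engine: a small tape-based autodiff with the
handful of operators the detector and classifier need (dense/conv linear maps,
elementwise nonlinearities, softmax, nearest-neighbour upsampling) plus an Adam
optimizer. Everything is float64 and fully deterministic given a seeded
``numpy.random.Generator`` for initialization.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "glorot", "he", "sigmoid", "tanh", "relu",
           "softmax", "log_softmax", "concat", "conv2d", "upsample2x"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
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
    """A numpy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make `ndarray <op> Tensor` defer to the reflected Tensor operators
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            return _unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape)

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            return (_unbroadcast(g * other.data, self.data.shape),
                    _unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bwd(g):
            return (_unbroadcast(g / other.data, self.data.shape),
                    _unbroadcast(-g * self.data / other.data ** 2, other.data.shape))

        out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, parents=(self,))
        out._backward = lambda g: (g * p * self.data ** (p - 1),)
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(np.matmul(self.data, other.data), parents=(self, other))

        def bwd(g):
            ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
            gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
            return _unbroadcast(ga, self.data.shape), _unbroadcast(gb, other.data.shape)

        out._backward = bwd
        return out

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), parents=(self,))
        out._backward = lambda g: (g.reshape(self.data.shape),)
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), parents=(self,))
        out._backward = lambda g: (g.transpose(inv),)
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        out._backward = bwd
        return out

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bwd(g):
            if axis is None:
                return (np.broadcast_to(g, self.data.shape).copy(),)
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, ax)
            return (np.broadcast_to(g, self.data.shape).copy(),)

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- autodiff driver ------------------------------------------------------
    def backward(self):
        order: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            stack = [(t, iter(t._parents))]
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen and p.requires_grad:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    order.append(node)
                    stack.pop()

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.ones_like(self.data)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:  # leaf parameter
                node.grad = g if node.grad is None else node.grad + g
                continue
            for p, pg in zip(node._parents, node._backward(g)):
                if p.requires_grad:
                    key = id(p)
                    grads[key] = pg if key not in grads else grads[key] + pg


# -- elementwise nonlinearities ----------------------------------------------

def sigmoid(x: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(y, parents=(x,))
    out._backward = lambda g: (g * y * (1 - y),)
    return out


def tanh(x: Tensor) -> Tensor:
    y = np.tanh(x.data)
    out = Tensor(y, parents=(x,))
    out._backward = lambda g: (g * (1 - y * y),)
    return out


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = Tensor(x.data * mask, parents=(x,))
    out._backward = lambda g: (g * mask,)
    return out


def exp(x: Tensor) -> Tensor:
    y = np.exp(x.data)
    out = Tensor(y, parents=(x,))
    out._backward = lambda g: (g * y,)
    return out


def log(x: Tensor) -> Tensor:
    out = Tensor(np.log(x.data), parents=(x,))
    out._backward = lambda g: (g / x.data,)
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(x.data.max(axis=axis, keepdims=True))  # constant, no grad
    e = exp(x - shift)
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    z = x - shift
    return z - log(exp(z).sum(axis=axis, keepdims=True))


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        return tuple(np.split(g, splits, axis=axis))

    out._backward = bwd
    return out


# -- spatial ops --------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]            # (N, C, Ho, Wo, kh, kw)
    n, c, ho, wo = win.shape[:4]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho, wo, c * kh * kw)
    return cols, x.shape, (ho, wo)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution. x: (N,C,H,W), w: (F,C,kh,kw), b: (F,)."""
    f, c, kh, kw = w.data.shape
    cols, padded_shape, (ho, wo) = _im2col(x.data, kh, kw, stride, pad)
    wmat = w.data.reshape(f, -1)
    out_d = cols @ wmat.T                          # (N, Ho, Wo, F)
    if b is not None:
        out_d = out_d + b.data
    out_d = out_d.transpose(0, 3, 1, 2)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_d, parents=parents)

    def bwd(g):
        gt = g.transpose(0, 2, 3, 1)               # (N, Ho, Wo, F)
        gw = np.tensordot(gt, cols, axes=([0, 1, 2], [0, 1, 2])).reshape(w.data.shape)
        gcols = gt @ wmat                          # (N, Ho, Wo, C*kh*kw)
        n = g.shape[0]
        gcols = gcols.reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
        gxp = np.zeros(padded_shape)
        for i in range(kh):
            for j in range(kw):
                gxp[:, :, i:i + ho * stride:stride,
                    j:j + wo * stride:stride] += gcols[:, :, :, :, i, j]
        gx = gxp if pad == 0 else gxp[:, :, pad:-pad, pad:-pad]
        if b is None:
            return gx, gw
        return gx, gw, gt.sum(axis=(0, 1, 2))

    out._backward = bwd
    return out


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling of (N,C,H,W)."""
    out = Tensor(x.data.repeat(2, axis=2).repeat(2, axis=3), parents=(x,))

    def bwd(g):
        n, c, h2, w2 = g.shape
        return (g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)),)

    out._backward = bwd
    return out


# -- parameters & optimization ------------------------------------------------

def glorot(rng: np.random.Generator, *shape) -> Tensor:
    fan_in, fan_out = shape[-2] if len(shape) > 1 else shape[0], shape[-1]
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-lim, lim, shape), requires_grad=True)


def he(rng: np.random.Generator, *shape) -> Tensor:
    """He-normal init; for conv weights (F,C,kh,kw) fan_in = C*kh*kw."""
    fan_in = int(np.prod(shape[1:])) if len(shape) > 1 else shape[0]
    return Tensor(rng.normal(0.0, np.sqrt(2.0 / fan_in), shape), requires_grad=True)


class Adam:
    """Adam with the standard bias correction; lr is the effective step size."""

    def __init__(self, params: list[Tensor], lr: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
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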