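"""Compact reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the partial-convolution UNet and its loss
need: broadcasting arithmetic, im2col-based 2-D convolution, ReLU/LeakyReLU,
absolute value, reductions, reshape/transpose, nearest-neighbour upsampling
and channel concatenation.  Gradients are accumulated in float64; every op is
checked against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward

    @property
    def shape(self):
        return self.data.shape

    # -- graph machinery ---------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.requires_grad:
                t.grad = g if t.grad is None else t.grad + g
            if t._backward is None:
                continue
            for parent, pg in zip(t._parents, t._backward(g)):
                if pg is None:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg

    def zero_grad(self) -> None:
        self.grad = None

    # -- elementwise arithmetic -------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        return Tensor(
            self.data + other.data,
            _parents=(self, other),
            _backward=lambda g: (
                _unbroadcast(g, self.data.shape),
                _unbroadcast(g, other.data.shape),
            ),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, _parents=(self,), _backward=lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        return Tensor(
            self.data * other.data,
            _parents=(self, other),
            _backward=lambda g: (
                _unbroadcast(g * other.data, self.data.shape),
                _unbroadcast(g * self.data, other.data.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return Tensor(
            self.data / other.data,
            _parents=(self, other),
            _backward=lambda g: (
                _unbroadcast(g / other.data, self.data.shape),
                _unbroadcast(-g * self.data / other.data**2, other.data.shape),
            ),
        )

    def __pow__(self, p: float):
        return Tensor(
            self.data**p,
            _parents=(self,),
            _backward=lambda g: (g * p * self.data ** (p - 1),),
        )

    def abs(self):
        return Tensor(
            np.abs(self.data),
            _parents=(self,),
            _backward=lambda g: (g * np.sign(self.data),),
        )

    def relu(self):
        return Tensor(
            np.maximum(self.data, 0.0),
            _parents=(self,),
            _backward=lambda g: (g * (self.data > 0),),
        )

    def leaky_relu(self, slope: float = 0.2):
        return Tensor(
            np.where(self.data > 0, self.data, slope * self.data),
            _parents=(self,),
            _backward=lambda g: (g * np.where(self.data > 0, 1.0, slope),),
        )

    # -- reductions / shape ------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def back(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.data.shape).copy(),)

        return Tensor(out, _parents=(self,), _backward=back)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        orig = self.data.shape
        return Tensor(
            self.data.reshape(*shape),
            _parents=(self,),
            _backward=lambda g: (g.reshape(orig),),
        )

    def transpose(self, *axes):
        inv = np.argsort(axes)
        return Tensor(
            self.data.transpose(*axes),
            _parents=(self,),
            _backward=lambda g: (g.transpose(*inv),),
        )

    def __matmul__(self, other):
        other = self._lift(other)
        return Tensor(
            self.data @ other.data,
            _parents=(self, other),
            _backward=lambda g: (
                _unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.data.shape),
                _unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.data.shape),
            ),
        )


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        _parents=tuple(tensors),
        _backward=back,
    )


def upsample_nearest(x: Tensor, factor: int = 2) -> Tensor:
    """Nearest-neighbour upsampling of an (N, C, H, W) tensor."""
    out = x.data.repeat(factor, axis=2).repeat(factor, axis=3)
    N, C, H, W = x.data.shape

    def back(g):
        g = g.reshape(N, C, H, factor, W, factor).sum(axis=(3, 5))
        return (g,)

    return Tensor(out, _parents=(x,), _backward=back)


# -- convolution ----------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    N, C, H, W = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    Ho = (H + 2 * pad - kh) // stride + 1
    Wo = (W + 2 * pad - kw) // stride + 1
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(N, C * kh * kw, Ho * Wo)
    return np.ascontiguousarray(cols), Ho, Wo


def _col2im(cols, xshape, kh, kw, stride, pad, Ho, Wo):
    N, C, H, W = xshape
    xp = np.zeros((N, C, H + 2 * pad, W + 2 * pad))
    cols = cols.reshape(N, C, kh, kw, Ho, Wo)
    for i in range(kh):
        for j in range(kw):
            xp[:, :, i : i + Ho * stride : stride, j : j + Wo * stride : stride] += cols[
                :, :, i, j
            ]
    return xp[:, :, pad : H + pad, pad : W + pad]


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, stride: int = 1,
           padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation) of (N,C,H,W) with (O,C,kh,kw)."""
    N, C, H, W = x.data.shape
    O, C2, kh, kw = weight.data.shape
    if C != C2:
        raise ValueError("channel mismatch in conv2d")
    cols, Ho, Wo = _im2col(x.data, kh, kw, stride, padding)
    w2 = weight.data.reshape(O, -1)
    out = (w2 @ cols).reshape(N, O, Ho, Wo)
    if bias is not None:
        out = out + bias.data.reshape(1, O, 1, 1)

    parents = (x, weight) + ((bias,) if bias is not None else ())

    def back(g):
        gf = g.reshape(N, O, Ho * Wo)
        dw = np.einsum("nol,nkl->ok", gf, cols).reshape(weight.data.shape)
        dcols = np.einsum("ok,nol->nkl", w2, gf)
        dx = _col2im(dcols, x.data.shape, kh, kw, stride, padding, Ho, Wo)
        if bias is not None:
            return dx, dw, g.sum(axis=(0, 2, 3))
        return dx, dw

    return Tensor(out, _parents=parents, _backward=back)


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 5e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * p.grad
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * p.grad**2
            mhat = self.m[i] / (1 - self.beta1**self.t)
            vhat = self.v[i] / (1 - self.beta2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
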