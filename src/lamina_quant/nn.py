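"""A minimal reverse-mode autodiff engine over numpy arrays.

Provides exactly the operations the package's miniature convolutional
networks need — elementwise arithmetic, matmul, 3x3/1x1 convolution via
im2col, 2x2 max-pooling, nearest-neighbour upsampling, channel
concatenation, reductions — plus an Adam optimiser. Everything is float64
numpy on CPU; gradients flow through a topologically sorted tape.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a broadcast gradient back down to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # keep numpy from broadcasting ndarray <op> Tensor elementwise; the
    # reflected operators below handle mixed operands instead
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False, _parents: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = lambda: None
        self._parents = _parents

    # -- graph bookkeeping --------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, free_graph: bool = True) -> None:
        """Backpropagate from this tensor.

        With ``free_graph`` (default) the tape is torn down afterwards —
        backward closures and non-leaf gradients are dropped so the large
        intermediate buffers they capture are freed promptly instead of
        lingering in reference cycles.
        """
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: "Tensor") -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            t._backward()
        if free_graph:
            noop = lambda: None  # noqa: E731
            for t in topo:
                t._parents = ()
                t._backward = noop
                if not t.requires_grad:
                    t.grad = None

    # -- elementwise --------------------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data + other.data, True, (self, other))

        def backward() -> None:
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(out.grad, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data * other.data, True, (self, other))

        def backward() -> None:
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(out.grad * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __neg__(self) -> "Tensor":
        return self * -1.0

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __pow__(self, exponent: float) -> "Tensor":
        out = Tensor(self.data**exponent, True, (self,))

        def backward() -> None:
            self._accumulate(out.grad * exponent * self.data ** (exponent - 1.0))

        out._backward = backward
        return out

    def __truediv__(self, other) -> "Tensor":
        return self * (self._lift(other) ** -1.0)

    def __rtruediv__(self, other) -> "Tensor":
        return self._lift(other) * (self**-1.0)

    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data), True, (self,))
        out._backward = lambda: self._accumulate(out.grad * out.data)
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), True, (self,))
        out._backward = lambda: self._accumulate(out.grad / self.data)
        return out

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), True, (self,))
        out._backward = lambda: self._accumulate(out.grad * (self.data > 0))
        return out

    def sigmoid(self) -> "Tensor":
        sig = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(sig, True, (self,))
        out._backward = lambda: self._accumulate(out.grad * sig * (1.0 - sig))
        return out

    # -- shape and reduction ------------------------------------------------
    def reshape(self, *shape: int) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), True, (self,))
        out._backward = lambda: self._accumulate(out.grad.reshape(self.data.shape))
        return out

    def transpose(self, *axes: int) -> "Tensor":
        out = Tensor(self.data.transpose(*axes), True, (self,))
        inv = np.argsort(axes)
        out._backward = lambda: self._accumulate(out.grad.transpose(*inv))
        return out

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), True, (self,))

        def backward() -> None:
            grad = out.grad
            if axis is not None and not keepdims:
                grad = np.expand_dims(grad, axis)
            self._accumulate(np.broadcast_to(grad, self.data.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def __matmul__(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data @ other.data, True, (self, other))

        def backward() -> None:
            self._accumulate(out.grad @ other.data.T)
            other._accumulate(self.data.T @ out.grad)

        out._backward = backward
        return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), True, tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward() -> None:
        for t, piece in zip(tensors, np.split(out.grad, splits, axis=axis)):
            t._accumulate(piece)

    out._backward = backward
    return out


# ---------------------------------------------------------------------------
# Convolution / pooling primitives (NCHW layout, stride 1, same padding)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, pad: int) -> np.ndarray:
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    view = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    # (N, C, H, W, kh, kw) -> (N*H*W, C*kh*kw)
    return view.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * kh * kw)


def _col2im(dcols: np.ndarray, x_shape: tuple[int, ...], kh: int, kw: int, pad: int) -> np.ndarray:
    n, c, h, w = x_shape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    d6 = dcols.reshape(n, h, w, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + h, j : j + w] += d6[:, :, :, :, i, j]
    return dxp[:, :, pad : pad + h, pad : pad + w]


def conv2d(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Same-padded stride-1 convolution; kernel shape (F, C, kh, kw)."""
    f, c, kh, kw = weight.data.shape
    pad = kh // 2
    n, _, h, w = x.data.shape
    cols = _im2col(x.data, kh, kw, pad)
    wmat = weight.data.reshape(f, -1)
    out_mat = cols @ wmat.T + bias.data
    out = Tensor(
        out_mat.reshape(n, h, w, f).transpose(0, 3, 1, 2), True, (x, weight, bias)
    )

    def backward() -> None:
        dmat = out.grad.transpose(0, 2, 3, 1).reshape(-1, f)
        weight._accumulate((dmat.T @ cols).reshape(weight.data.shape))
        bias._accumulate(dmat.sum(axis=0))
        if x.requires_grad or x._parents:
            x._accumulate(_col2im(dmat @ wmat, x.data.shape, kh, kw, pad))

    out._backward = backward
    return out


def maxpool2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2 (spatial dims must be even)."""
    n, c, h, w = x.data.shape
    xr = (
        x.data.reshape(n, c, h // 2, 2, w // 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, c, h // 2, w // 2, 4)
    )
    idx = xr.argmax(axis=-1)
    out = Tensor(np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0], True, (x,))

    def backward() -> None:
        dxr = np.zeros_like(xr)
        np.put_along_axis(dxr, idx[..., None], out.grad[..., None], axis=-1)
        dx = (
            dxr.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )
        x._accumulate(dx)

    out._backward = backward
    return out


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling."""
    out = Tensor(x.data.repeat(2, axis=2).repeat(2, axis=3), True, (x,))

    def backward() -> None:
        n, c, h2, w2 = out.grad.shape
        dx = out.grad.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))
        x._accumulate(dx)

    out._backward = backward
    return out


def softmax_channels(logits: Tensor) -> Tensor:
    """Numerically stable softmax over axis 1 (channels)."""
    shift = logits + (-logits.data.max(axis=1, keepdims=True))  # detached max
    e = shift.exp()
    return e / e.sum(axis=1, keepdims=True)


def he_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


class Adam:
    """Adam optimiser over a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
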