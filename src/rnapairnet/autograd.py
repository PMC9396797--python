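"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The package's trainable scorer and the unrolled constraint-projection layer
are built from the primitives here.  The engine is a plain dynamic tape:
every operation records its parents and a closure that accumulates gradients
into them; :meth:`Tensor.backward` runs the tape in reverse topological
order.  Broadcasting follows NumPy semantics; gradients of broadcast
operands are summed back to the operand's shape.

Only the operations the models need are implemented.  Convolution, pooling
and nearest-neighbour upsampling carry hand-written backward passes (im2col
based) because composing them from elementwise primitives would be far too
slow on CPU.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "astensor",
    "concat",
    "stack",
    "sigmoid",
    "tanh",
    "relu",
    "exp",
    "log",
    "log_sigmoid",
    "softmax",
    "conv2d",
    "avg_pool2d",
    "upsample_nearest2d",
    "broadcast_to",
]


def _sum_to_shape(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` (shaped by broadcasting) back to ``shape``."""
    if grad.shape == shape:
        return grad
    # sum leading broadcast axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray with a gradient slot and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_ = [self]
        while stack_:  # iterative DFS; tapes can be thousands of nodes deep
            node = stack_[-1]
            if id(node) in seen:
                stack_.pop()
                continue
            pending = [p for p in node._parents if id(p) not in seen and p.requires_grad]
            if pending:
                stack_.extend(pending)
            else:
                seen.add(id(node))
                topo.append(node)
                stack_.pop()
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @staticmethod
    def _accumulate(t: "Tensor", g: np.ndarray) -> None:
        if not t.requires_grad:
            return
        g = _sum_to_shape(g, t.data.shape)
        if t.grad is None:
            t.grad = g.copy()
        else:
            t.grad += g

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = astensor(other)
        out = Tensor(
            self.data + other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def backward(g):
            Tensor._accumulate(self, g)
            Tensor._accumulate(other, g)

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))
        out._backward = lambda g: Tensor._accumulate(self, -g)
        return out

    def __sub__(self, other):
        return self + (-astensor(other))

    def __rsub__(self, other):
        return astensor(other) + (-self)

    def __mul__(self, other):
        other = astensor(other)
        out = Tensor(
            self.data * other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def backward(g):
            Tensor._accumulate(self, g * other.data)
            Tensor._accumulate(other, g * self.data)

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = astensor(other)
        out = Tensor(
            self.data / other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def backward(g):
            Tensor._accumulate(self, g / other.data)
            Tensor._accumulate(other, -g * self.data / other.data**2)

        out._backward = backward
        return out

    def __rtruediv__(self, other):
        return astensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data**p, self.requires_grad, (self,))
        out._backward = lambda g: Tensor._accumulate(self, g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = astensor(other)
        out = Tensor(
            self.data @ other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def backward(g):
            Tensor._accumulate(self, g @ np.swapaxes(other.data, -1, -2))
            Tensor._accumulate(other, np.swapaxes(self.data, -1, -2) @ g)

        out._backward = backward
        return out

    # ----------------------------------------------------------- shape moves
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))
        out._backward = lambda g: Tensor._accumulate(self, g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))
        out._backward = lambda g: Tensor._accumulate(self, g.transpose(inv))
        return out

    def swapaxes(self, a: int, b: int):
        out = Tensor(np.swapaxes(self.data, a, b), self.requires_grad, (self,))
        out._backward = lambda g: Tensor._accumulate(self, np.swapaxes(g, a, b))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            Tensor._accumulate(self, full)

        out._backward = backward
        return out

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad, (self,))

        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            Tensor._accumulate(self, np.broadcast_to(g, self.data.shape))

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def abs(self):
        out = Tensor(np.abs(self.data), self.requires_grad, (self,))
        out._backward = lambda g: Tensor._accumulate(self, g * np.sign(self.data))
        return out


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def broadcast_to(x: Tensor, shape) -> Tensor:
    x = astensor(x)
    out = Tensor(np.broadcast_to(x.data, shape), x.requires_grad, (x,))
    out._backward = lambda g: Tensor._accumulate(x, g)
    return out


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        any(t.requires_grad for t in tensors),
        tuple(tensors),
    )
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            Tensor._accumulate(t, piece)

    out._backward = backward
    return out


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    out = Tensor(
        np.stack([t.data for t in tensors], axis=axis),
        any(t.requires_grad for t in tensors),
        tuple(tensors),
    )

    def backward(g):
        for i, t in enumerate(tensors):
            Tensor._accumulate(t, np.take(g, i, axis=axis))

    out._backward = backward
    return out


# ------------------------------------------------------------------ pointwise
def sigmoid(x: Tensor) -> Tensor:
    x = astensor(x)
    y = np.where(x.data >= 0, 1.0 / (1.0 + np.exp(-x.data)),
                 np.exp(x.data) / (1.0 + np.exp(x.data)))
    out = Tensor(y, x.requires_grad, (x,))
    out._backward = lambda g: Tensor._accumulate(x, g * y * (1.0 - y))
    return out


def tanh(x: Tensor) -> Tensor:
    x = astensor(x)
    y = np.tanh(x.data)
    out = Tensor(y, x.requires_grad, (x,))
    out._backward = lambda g: Tensor._accumulate(x, g * (1.0 - y**2))
    return out


def relu(x: Tensor) -> Tensor:
    x = astensor(x)
    out = Tensor(np.maximum(x.data, 0.0), x.requires_grad, (x,))
    out._backward = lambda g: Tensor._accumulate(x, g * (x.data > 0))
    return out


def exp(x: Tensor) -> Tensor:
    x = astensor(x)
    y = np.exp(x.data)
    out = Tensor(y, x.requires_grad, (x,))
    out._backward = lambda g: Tensor._accumulate(x, g * y)
    return out


def log(x: Tensor) -> Tensor:
    x = astensor(x)
    out = Tensor(np.log(x.data), x.requires_grad, (x,))
    out._backward = lambda g: Tensor._accumulate(x, g / x.data)
    return out


def log_sigmoid(x: Tensor) -> Tensor:
    """Numerically stable log(sigmoid(x)) = -softplus(-x)."""
    x = astensor(x)
    z = x.data
    y = np.where(z >= 0, -np.log1p(np.exp(-z)), z - np.log1p(np.exp(z)))
    out = Tensor(y, x.requires_grad, (x,))
    sig = np.where(z >= 0, 1.0 / (1.0 + np.exp(-z)), np.exp(z) / (1.0 + np.exp(z)))
    out._backward = lambda g: Tensor._accumulate(x, g * (1.0 - sig))
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = astensor(x)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, x.requires_grad, (x,))

    def backward(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        Tensor._accumulate(x, y * (g - dot))

    out._backward = backward
    return out


# --------------------------------------------------------------- convolution
def _im2col(x: np.ndarray, kh: int, kw: int, pad: int):
    """(B,C,H,W) -> (B, H*W, C*kh*kw) patches for stride-1 'same' conv."""
    b, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    # win: (B, C, H, W, kh, kw)
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(b, h * w, c * kh * kw)


def _col2im(cols: np.ndarray, shape, kh: int, kw: int, pad: int) -> np.ndarray:
    b, c, h, w = shape
    xp = np.zeros((b, c, h + 2 * pad, w + 2 * pad))
    cols = cols.reshape(b, h, w, c, kh, kw)
    for di in range(kh):
        for dj in range(kw):
            xp[:, :, di:di + h, dj:dj + w] += cols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
    return xp[:, :, pad:pad + h, pad:pad + w]


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Stride-1 'same' 2-D convolution; x (B,C,H,W), weight (O,C,kh,kw)."""
    x, weight = astensor(x), astensor(weight)
    b, c, h, w = x.data.shape
    o, c2, kh, kw = weight.data.shape
    if c != c2:
        raise ValueError(f"channel mismatch: input {c}, weight {c2}")
    pad = kh // 2
    cols = _im2col(x.data, kh, kw, pad)  # (B, HW, C*kh*kw)
    wmat = weight.data.reshape(o, -1)  # (O, C*kh*kw)
    y = cols @ wmat.T  # (B, HW, O)
    if bias is not None:
        y = y + bias.data
    out_data = y.transpose(0, 2, 1).reshape(b, o, h, w)
    req = x.requires_grad or weight.requires_grad or (bias is not None and bias.requires_grad)
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(out_data, req, parents)

    def backward(g):
        gmat = g.reshape(b, o, h * w).transpose(0, 2, 1)  # (B, HW, O)
        if weight.requires_grad:
            gw = np.einsum("bpo,bpk->ok", gmat, cols).reshape(weight.data.shape)
            Tensor._accumulate(weight, gw)
        if bias is not None and bias.requires_grad:
            Tensor._accumulate(bias, gmat.sum(axis=(0, 1)))
        if x.requires_grad:
            gcols = gmat @ wmat  # (B, HW, C*kh*kw)
            Tensor._accumulate(x, _col2im(gcols, x.data.shape, kh, kw, pad))

    out._backward = backward
    return out


def avg_pool2d(x: Tensor, k: int = 2) -> Tensor:
    x = astensor(x)
    b, c, h, w = x.data.shape
    if h % k or w % k:
        raise ValueError("spatial size must be divisible by the pooling factor")
    y = x.data.reshape(b, c, h // k, k, w // k, k).mean(axis=(3, 5))
    out = Tensor(y, x.requires_grad, (x,))

    def backward(g):
        g_up = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
        Tensor._accumulate(x, g_up)

    out._backward = backward
    return out


def upsample_nearest2d(x: Tensor, k: int = 2) -> Tensor:
    x = astensor(x)
    y = np.repeat(np.repeat(x.data, k, axis=2), k, axis=3)
    out = Tensor(y, x.requires_grad, (x,))

    def backward(g):
        b, c, h, w = x.data.shape
        Tensor._accumulate(x, g.reshape(b, c, h, k, w, k).sum(axis=(3, 5)))

    out._backward = backward
    return out
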