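"""Neural building blocks on top of :mod:`rnapairnet.autograd`.

Layers follow the usual conventions: parameters are ``Tensor`` objects with
``requires_grad=True``, modules expose ``parameters()`` as a flat ordered
dict of name -> Tensor, and initialization is driven by an explicit
``numpy.random.Generator`` so identical seeds give identical models.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = [
    "Module",
    "Linear",
    "Embedding",
    "LayerNorm",
    "BiLSTM",
    "MultiHeadSelfAttention",
    "TransformerEncoderLayer",
    "Adam",
]


class Module:
    """Base class: children and parameters are discovered by attribute scan."""

    def parameters(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, val in vars(self).items():
            if isinstance(val, Tensor):
                out[name] = val
            elif isinstance(val, Module):
                for sub, p in val.parameters().items():
                    out[f"{name}.{sub}"] = p
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        for sub, p in item.parameters().items():
                            out[f"{name}.{i}.{sub}"] = p
        return out

    def zero_grad(self) -> None:
        for p in self.parameters().values():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for k, p in params.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}: {p.data.shape} vs {state[k].shape}")
            p.data[...] = state[k]


def _glorot(rng: np.random.Generator, *shape) -> Tensor:
    fan_in, fan_out = shape[-2] if len(shape) > 1 else shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.weight = _glorot(rng, d_in, d_out)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Embedding(Module):
    def __init__(self, n_symbols: int, dim: int, rng: np.random.Generator):
        self.weight = Tensor(rng.normal(0.0, 0.1, size=(n_symbols, dim)), requires_grad=True)

    def __call__(self, codes: np.ndarray) -> Tensor:
        codes = np.asarray(codes, dtype=np.intp)
        return self.weight[codes]


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gain = Tensor(np.ones(dim), requires_grad=True)
        self.shift = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered * ((var + self.eps) ** -0.5) * self.gain + self.shift


class BiLSTM(Module):
    """Single-layer bidirectional LSTM; outputs the two directions concatenated."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        self.w_f = _glorot(rng, d_in + hidden, 4 * hidden)
        self.b_f = Tensor(np.zeros(4 * hidden), requires_grad=True)
        self.w_b = _glorot(rng, d_in + hidden, 4 * hidden)
        self.b_b = Tensor(np.zeros(4 * hidden), requires_grad=True)

    def _run(self, x: Tensor, w: Tensor, b: Tensor, reverse: bool) -> Tensor:
        bsz, length, _ = x.shape
        h = Tensor(np.zeros((bsz, self.hidden)))
        c = Tensor(np.zeros((bsz, self.hidden)))
        outs = [None] * length
        order = range(length - 1, -1, -1) if reverse else range(length)
        for t in order:
            xt = x[:, t, :]
            gates = ag.concat([xt, h], axis=-1) @ w + b
            i_g = ag.sigmoid(gates[:, : self.hidden])
            f_g = ag.sigmoid(gates[:, self.hidden : 2 * self.hidden])
            o_g = ag.sigmoid(gates[:, 2 * self.hidden : 3 * self.hidden])
            g_g = ag.tanh(gates[:, 3 * self.hidden :])
            c = f_g * c + i_g * g_g
            h = o_g * ag.tanh(c)
            outs[t] = h
        return ag.stack(outs, axis=1)

    def __call__(self, x: Tensor) -> Tensor:
        fwd = self._run(x, self.w_f, self.b_f, reverse=False)
        bwd = self._run(x, self.w_b, self.b_b, reverse=True)
        return ag.concat([fwd, bwd], axis=-1)


class MultiHeadSelfAttention(Module):
    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.q = Linear(d_model, d_model, rng)
        self.k = Linear(d_model, d_model, rng)
        self.v = Linear(d_model, d_model, rng)
        self.out = Linear(d_model, d_model, rng)

    def _split(self, x: Tensor) -> Tensor:
        b, l, d = x.shape
        return x.reshape(b, l, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

    def __call__(self, x: Tensor) -> Tensor:
        b, l, d = x.shape
        q, k, v = self._split(self.q(x)), self._split(self.k(x)), self._split(self.v(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (self.d_head ** -0.5)
        attn = ag.softmax(scores, axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(b, l, d)
        return self.out(ctx)


class TransformerEncoderLayer(Module):
    """Pre-norm encoder block: self-attention + position-wise feed-forward."""

    def __init__(self, d_model: int, n_heads: int, d_ff: int, rng: np.random.Generator):
        self.attn = MultiHeadSelfAttention(d_model, n_heads, rng)
        self.norm1 = LayerNorm(d_model)
        self.norm2 = LayerNorm(d_model)
        self.ff1 = Linear(d_model, d_ff, rng)
        self.ff2 = Linear(d_ff, d_model, rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        return x + self.ff2(ag.relu(self.ff1(self.norm2(x))))


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = dict(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in self.params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in self.params.items()}

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None
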