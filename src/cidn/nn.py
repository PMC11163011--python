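"""Neural layers built on the autodiff engine.

Layers hold their parameters as named :class:`~cidn.autodiff.Tensor` objects
and expose ``parameters()`` (ordered dict name -> tensor) for optimization
and checkpointing.  Initialization is Glorot-uniform from an explicit
``numpy`` generator so models are deterministic per seed.
"""

from __future__ import annotations

from collections import OrderedDict
from typing import Callable

import numpy as np

from .autodiff import Tensor, concat, stack

__all__ = [
    "Module",
    "Linear",
    "LSTM",
    "BiLSTM",
    "LayerNorm",
    "PReLU",
    "MultiHeadAttention",
    "TransformerBlock",
    "sinusoidal_encoding",
]


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


class Module:
    """Base class: recursive parameter collection and state I/O."""

    def parameters(self) -> "OrderedDict[str, Tensor]":
        out: OrderedDict[str, Tensor] = OrderedDict()
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                out[name] = value
            elif isinstance(value, Module):
                for sub, t in value.parameters().items():
                    out[f"{name}.{sub}"] = t
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        for sub, t in item.parameters().items():
                            out[f"{name}.{i}.{sub}"] = t
        return out

    def state_dict(self) -> dict:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict) -> None:
        params = self.parameters()
        for k, v in state.items():
            params[k].data = np.array(v, dtype=np.float64)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, bias: bool = True):
        self.weight = Tensor(glorot(rng, n_in, n_out), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        return y + self.bias if self.bias is not None else y


class LayerNorm(Module):
    def __init__(self, n: int):
        self.gamma = Tensor(np.ones(n), requires_grad=True)
        self.beta = Tensor(np.zeros(n), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.layer_norm(self.gamma, self.beta)


class PReLU(Module):
    def __init__(self, init: float = 0.25):
        self.alpha = Tensor(np.array(init), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.prelu(self.alpha)


class LSTM(Module):
    """Single-direction LSTM over (batch, time, features) input."""

    def __init__(self, n_in: int, n_units: int, rng: np.random.Generator):
        self.n_units = n_units
        self.wx = Tensor(glorot(rng, n_in, 4 * n_units), requires_grad=True)
        self.wh = Tensor(glorot(rng, n_units, 4 * n_units), requires_grad=True)
        b = np.zeros(4 * n_units)
        b[n_units : 2 * n_units] = 1.0  # forget-gate bias
        self.b = Tensor(b, requires_grad=True)

    def __call__(self, x: Tensor, reverse: bool = False) -> Tensor:
        batch, T, _ = x.shape
        n = self.n_units
        h = Tensor(np.zeros((batch, n)))
        c = Tensor(np.zeros((batch, n)))
        steps = range(T - 1, -1, -1) if reverse else range(T)
        outputs: list[Tensor] = [None] * T  # type: ignore[list-item]
        for t in steps:
            z = x[:, t, :] @ self.wx + h @ self.wh + self.b
            i = z[:, 0 * n : 1 * n].sigmoid()
            f = z[:, 1 * n : 2 * n].sigmoid()
            g = z[:, 2 * n : 3 * n].tanh()
            o = z[:, 3 * n : 4 * n].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outputs[t] = h
        return stack(outputs, axis=1)


class BiLSTM(Module):
    """Bidirectional LSTM; output width is 2 * n_units (or n_units if causal)."""

    def __init__(self, n_in: int, n_units: int, rng: np.random.Generator,
                 bidirectional: bool = True):
        self.bidirectional = bidirectional
        self.fwd = LSTM(n_in, n_units, rng)
        self.bwd = LSTM(n_in, n_units, rng) if bidirectional else None

    @property
    def n_out(self) -> int:
        return 2 * self.fwd.n_units if self.bidirectional else self.fwd.n_units

    def __call__(self, x: Tensor) -> Tensor:
        out = self.fwd(x)
        if self.bwd is not None:
            out = concat([out, self.bwd(x, reverse=True)], axis=-1)
        return out


def sinusoidal_encoding(length: int, dim: int) -> np.ndarray:
    """Standard sinusoidal positional encoding, (length, dim)."""
    pos = np.arange(length)[:, None]
    i = np.arange(dim)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / dim)
    enc = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return enc


class MultiHeadAttention(Module):
    """Self-attention over (batch, seq, dim)."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads:
            raise ValueError("dim must be divisible by n_heads")
        self.dim, self.n_heads = dim, n_heads
        self.wq = Linear(dim, dim, rng, bias=False)
        self.wk = Linear(dim, dim, rng, bias=False)
        self.wv = Linear(dim, dim, rng, bias=False)
        self.wo = Linear(dim, dim, rng, bias=False)

    def __call__(self, x: Tensor) -> Tensor:
        b, s, d = x.shape
        hd = d // self.n_heads

        def split(t: Tensor) -> Tensor:
            # (b, s, d) -> (b, heads, s, hd)
            return t.reshape(b, s, self.n_heads, hd).transpose(0, 2, 1, 3)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(hd))
        attn = scores.softmax(axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(b, s, d)
        return self.wo(ctx)


class TransformerBlock(Module):
    """Pre-norm transformer encoder block with sinusoidal positions."""

    def __init__(self, dim: int, n_heads: int, ff_dim: int, rng: np.random.Generator):
        self.ln1 = LayerNorm(dim)
        self.attn = MultiHeadAttention(dim, n_heads, rng)
        self.ln2 = LayerNorm(dim)
        self.ff1 = Linear(dim, ff_dim, rng)
        self.ff2 = Linear(ff_dim, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        pos = Tensor(sinusoidal_encoding(x.shape[1], x.shape[2]))
        h = x + self.attn(self.ln1(x + pos))
        return h + self.ff2(self.ff1(self.ln2(h)).relu())
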