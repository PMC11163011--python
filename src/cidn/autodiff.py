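"""Minimal reverse-mode automatic differentiation over numpy arrays.

The trainable models in this package (the recurrent mask estimator and the
dual-path separator) are small by design, so they are implemented directly on
this vectorized tape-based engine rather than on a deep-learning framework.
Supported operations are exactly those the two architectures need: broadcasted
arithmetic, matmul, the usual nonlinearities, reductions, indexing/reshaping,
softmax, layer normalization, framing (for differentiable STFT features), and
overlap-add.

All computation is float64 and single-threaded, which makes training
bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "tensor", "concat", "stack", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # ---- graph machinery -------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        # iterative topological sort (graphs can be deep for long sequences)
        visit_stack: list[tuple[Tensor, bool]] = [(self, False)]
        while visit_stack:
            node, processed = visit_stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            visit_stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    visit_stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64).reshape(self.data.shape)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # ---- helpers ---------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _binary(self, other, fwd, bwd_self, bwd_other) -> "Tensor":
        other = Tensor._lift(other)
        out_data = fwd(self.data, other.data)
        rg = self.requires_grad or other.requires_grad
        out = Tensor(out_data, rg, (self, other))
        if rg:
            def backward(grad):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(bwd_self(grad), self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(bwd_other(grad), other.shape))
            out._backward = backward
        return out

    def _unary(self, fwd_data, bwd) -> "Tensor":
        out = Tensor(fwd_data, self.requires_grad, (self,))
        if self.requires_grad:
            def backward(grad):
                self._accumulate(bwd(grad))
            out._backward = backward
        return out

    # ---- arithmetic ------------------------------------------------------
    def __add__(self, other):
        return self._binary(other, lambda a, b: a + b, lambda g: g, lambda g: g)

    __radd__ = __add__

    def __sub__(self, other):
        return self._binary(other, lambda a, b: a - b, lambda g: g, lambda g: -g)

    def __rsub__(self, other):
        return Tensor._lift(other).__sub__(self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        return self._binary(
            other, lambda a, b: a * b,
            lambda g: g * other.data, lambda g: g * self.data,
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        return self._binary(
            other, lambda a, b: a / b,
            lambda g: g / other.data,
            lambda g: -g * self.data / (other.data ** 2),
        )

    def __neg__(self):
        return self._unary(-self.data, lambda g: -g)

    def __matmul__(self, other):
        other = Tensor._lift(other)
        a, b = self.data, other.data
        return self._binary(
            other, lambda x, y: x @ y,
            lambda g: g @ np.swapaxes(b, -1, -2),
            lambda g: np.swapaxes(a, -1, -2) @ g,
        )

    def __pow__(self, p: float):
        return self._unary(self.data ** p, lambda g: g * p * self.data ** (p - 1))

    # ---- nonlinearities --------------------------------------------------
    def relu(self):
        mask = self.data > 0
        return self._unary(self.data * mask, lambda g: g * mask)

    def clamp01(self):
        """min(max(x, 0), 1) with pass-through gradient inside (0, 1)."""
        inside = (self.data > 0) & (self.data < 1)
        return self._unary(np.clip(self.data, 0.0, 1.0), lambda g: g * inside)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        return self._unary(s, lambda g: g * s * (1.0 - s))

    def tanh(self):
        t = np.tanh(self.data)
        return self._unary(t, lambda g: g * (1.0 - t * t))

    def exp(self):
        e = np.exp(self.data)
        return self._unary(e, lambda g: g * e)

    def sqrt(self):
        s = np.sqrt(self.data)
        return self._unary(s, lambda g: g * 0.5 / s)

    def prelu(self, alpha: "Tensor"):
        """Parametric ReLU with a scalar learnable slope for x < 0."""
        mask = self.data > 0
        neg = self.data * ~mask
        out_data = self.data * mask + alpha.data * neg
        out = Tensor(out_data, self.requires_grad or alpha.requires_grad, (self, alpha))

        def backward(grad):
            if self.requires_grad:
                self._accumulate(grad * (mask + alpha.data * ~mask))
            if alpha.requires_grad:
                alpha._accumulate(_unbroadcast(grad * neg, alpha.shape))

        out._backward = backward
        return out

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def bwd(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            return s * (g - dot)

        return self._unary(s, bwd)

    # ---- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if axis is None:
                return np.broadcast_to(g, self.shape).copy()
            g2 = g if keepdims else np.expand_dims(g, axis)
            return np.broadcast_to(g2, self.shape).copy()

        return self._unary(out_data, bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ---- shape ops -------------------------------------------------------
    def reshape(self, *shape):
        return self._unary(
            self.data.reshape(*shape), lambda g: g.reshape(self.shape)
        )

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)
        return self._unary(
            self.data.transpose(axes), lambda g: g.transpose(inv)
        )

    def __getitem__(self, idx):
        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return full

        return self._unary(self.data[idx], bwd)

    def frame(self, window: int, hop: int):
        """Strided framing along the first axis: (L,) -> (n_frames, window).

        The signal is zero-padded at the tail so every sample is covered;
        the backward pass scatter-adds frame gradients back onto samples.
        """
        L = self.shape[0]
        n_frames = 1 if L <= window else int(np.ceil((L - window) / hop)) + 1
        padded_len = (n_frames - 1) * hop + window
        idx = (np.arange(n_frames)[:, None] * hop + np.arange(window)[None, :])
        valid = idx < L
        safe = np.where(valid, idx, 0)
        out_data = self.data[safe] * valid

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, safe, g * valid)
            return full

        return self._unary(out_data, bwd)

    def overlap_add(self, hop: int, length: int):
        """(n_frames, window) -> (length,) by summing frames at hop offsets."""
        n_frames, window = self.shape
        idx = (np.arange(n_frames)[:, None] * hop + np.arange(window)[None, :])
        valid = idx < length
        safe = np.where(valid, idx, 0)

        out_data = np.zeros(length)
        np.add.at(out_data, safe, self.data * valid)

        def bwd(g):
            return g[safe] * valid

        return self._unary(out_data, bwd)

    # ---- normalization ---------------------------------------------------
    def layer_norm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-6):
        """Normalize over the last axis, then scale/shift."""
        mu = self.mean(axis=-1, keepdims=True)
        centered = self - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        inv = (var + eps) ** -0.5
        return centered * inv * gamma + beta


def tensor(data, requires_grad: bool = False) -> Tensor:
    return Tensor(data, requires_grad=requires_grad)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    rg = any(t.requires_grad for t in tensors)
    out = Tensor(out_data, rg, tuple(tensors))
    if rg:
        sizes = [d.shape[axis] for d in datas]
        splits = np.cumsum(sizes)[:-1]

        def backward(grad):
            for t, g in zip(tensors, np.split(grad, splits, axis=axis)):
                if t.requires_grad:
                    t._accumulate(g)

        out._backward = backward
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    out_data = np.stack([t.data for t in tensors], axis=axis)
    rg = any(t.requires_grad for t in tensors)
    out = Tensor(out_data, rg, tuple(tensors))
    if rg:
        def backward(grad):
            for i, t in enumerate(tensors):
                if t.requires_grad:
                    t._accumulate(np.take(grad, i, axis=axis))

        out._backward = backward
    return out


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-4,
                 betas: tuple = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
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

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
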