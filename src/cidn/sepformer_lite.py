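"""Dimension-reduced dual-path transformer separator.

Structure (faithful to the full-scale architecture, scaled to CPU size):

* learned single-layer conv encoder (kernel 16, stride 8; ReLU latent),
* masking network: per-frame layer norm -> linear -> chunking along time
  (50% overlap) -> alternating intra-chunk / inter-chunk transformer blocks
  -> PReLU + linear -> overlap-add of chunks -> two feed-forward mask heads
  with ReLU bounded at 1, emitting foreground/background masks m1 and m2,
* transposed-conv decoder (same kernel/stride, no bias) applied to each
  masked latent; outputs trimmed to the input length.

Training mirrors the recurrent enhancer: Adam on an MSE between the
foreground estimate's complex STFT and the clean target's (the complex —
not magnitude-only — difference is what constrains the decoder's output
phase; an optional negative-SI-SDR loss is available), seeded and with
per-epoch validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import spectral
from .autodiff import Adam, Tensor
from .mixer import MixtureTriplet
from .nn import LayerNorm, Linear, Module, PReLU, TransformerBlock
from .types import InvalidArgumentError, Waveform, require

__all__ = [
    "SeparatorConfig",
    "MaskPair",
    "SeparatorModel",
    "init_separator",
    "encode",
    "decode",
    "chunk",
    "overlap_add_chunks",
    "masking_network",
    "separate",
    "train_separator",
]


@dataclass(frozen=True)
class SeparatorConfig:
    """Separator hyperparameters. Reference scale: 256 filters, chunk 250,
    multiple dual-path blocks; test defaults are reduced for CPU runs."""

    n_filters: int = 64
    kernel_samples: int = 16
    stride_samples: int = 8
    chunk_size: int = 50
    chunk_overlap: float = 0.5
    intra_blocks: int = 1
    inter_blocks: int = 1
    n_heads: int = 4
    ff_dim: int = 128
    learning_rate: float = 3e-3
    epochs: int = 5
    batch_size: int = 8
    seed: int = 0
    rate: int = 16000
    loss: str = "spectral_mse"  # or "neg_sisdr"

    def __post_init__(self) -> None:
        require(0.0 < self.chunk_overlap < 1.0, "chunk_overlap must lie in (0, 1)")
        require(self.stride_samples <= self.kernel_samples, "stride must be <= kernel")
        require(self.chunk_size > 1, "chunk_size must exceed 1")
        require(self.loss in ("spectral_mse", "neg_sisdr"), "unknown loss")


@dataclass(frozen=True)
class MaskPair:
    """Foreground/background masks over the latent (frames x filters)."""

    m1: np.ndarray
    m2: np.ndarray

    def __post_init__(self) -> None:
        require(self.m1.shape == self.m2.shape, "mask shapes differ")
        for m in (self.m1, self.m2):
            if m.min() < 0.0 or m.max() > 1.0:
                raise InvalidArgumentError("mask entries must lie in [0, 1]")


class _SeparatorNet(Module):
    def __init__(self, config: SeparatorConfig):
        rng = np.random.default_rng(config.seed)
        self.config = config
        k, f = config.kernel_samples, config.n_filters
        self.enc_weight = Tensor(
            np.sqrt(2.0 / k) * rng.standard_normal((k, f)), requires_grad=True
        )
        self.enc_bias = Tensor(np.zeros(f), requires_grad=True)
        # decoder: transposed conv, deliberately bias-free so that a zero
        # latent decodes to exact digital silence
        self.dec_weight = Tensor(
            np.sqrt(2.0 / f) * rng.standard_normal((f, k)), requires_grad=True
        )
        self.norm = LayerNorm(f)
        self.pre_linear = Linear(f, f, rng)
        blocks: list[Module] = []
        for _ in range(max(config.intra_blocks, config.inter_blocks)):
            if len([b for b in blocks if getattr(b, "_path", "") == "intra"]) < config.intra_blocks:
                blk = TransformerBlock(f, config.n_heads, config.ff_dim, rng)
                blk._path = "intra"
                blocks.append(blk)
            if len([b for b in blocks if getattr(b, "_path", "") == "inter"]) < config.inter_blocks:
                blk = TransformerBlock(f, config.n_heads, config.ff_dim, rng)
                blk._path = "inter"
                blocks.append(blk)
        self.blocks = blocks
        self.prelu = PReLU()
        self.post_linear = Linear(f, f, rng)
        self.head1a = Linear(f, f, rng)
        self.head1b = Linear(f, f, rng)
        self.head2a = Linear(f, f, rng)
        self.head2b = Linear(f, f, rng)
        # start both masks near 0.5 so the clamped-ReLU heads have live
        # gradients for every unit at initialization
        self.head1b.bias.data += 0.5
        self.head2b.bias.data += 0.5


@dataclass
class SeparatorModel:
    config: SeparatorConfig
    net: _SeparatorNet
    history: list = field(default_factory=list)


def init_separator(config: SeparatorConfig) -> SeparatorModel:
    """Deterministically initialize a separator model."""
    return SeparatorModel(config=config, net=_SeparatorNet(config), history=[])


# ---- encoder / decoder ----------------------------------------------------

def _encode_t(net: _SeparatorNet, x: Tensor) -> Tensor:
    cfg = net.config
    frames = x.frame(cfg.kernel_samples, cfg.stride_samples)
    return (frames @ net.enc_weight + net.enc_bias).relu()


def _decode_t(net: _SeparatorNet, latent: Tensor, length: int) -> Tensor:
    cfg = net.config
    windows = latent @ net.dec_weight
    return windows.overlap_add(cfg.stride_samples, length)


def encode(model: SeparatorModel, w: Waveform) -> np.ndarray:
    """Learned filterbank analysis: waveform -> latent (frames x filters).

    frames = floor((L - kernel) / stride) + 1 when L >= kernel (the training
    path pads the tail; this public view drops it for the stated formula).
    """
    cfg = model.config
    if len(w) < cfg.kernel_samples:
        raise InvalidArgumentError("input shorter than one encoder kernel")
    n_frames = (len(w) - cfg.kernel_samples) // cfg.stride_samples + 1
    out = _encode_t(model.net, Tensor(w.samples)).data
    return out[:n_frames]


def decode(model: SeparatorModel, latent: np.ndarray, length: int) -> Waveform:
    """Transposed-conv synthesis of a (frames x filters) latent."""
    out = _decode_t(model.net, Tensor(np.asarray(latent, dtype=np.float64)), length)
    return Waveform(out.data, model.config.rate)


# ---- chunking -------------------------------------------------------------

def _chunk_geometry(n_frames: int, chunk_size: int, overlap: float) -> tuple[int, int]:
    hop = max(int(round(chunk_size * (1.0 - overlap))), 1)
    if n_frames <= chunk_size:
        n_chunks = 1
    else:
        n_chunks = int(np.ceil((n_frames - chunk_size) / hop)) + 1
    return hop, n_chunks


def chunk(latent: np.ndarray, chunk_size: int, overlap: float = 0.5) -> np.ndarray:
    """Buffer a (frames x filters) latent into (n_chunks, chunk_size, filters)
    with the given overlap; the tail chunk is zero-padded."""
    require(chunk_size > 1, "chunk_size must exceed 1")
    latent = np.asarray(latent)
    hop, n_chunks = _chunk_geometry(latent.shape[0], chunk_size, overlap)
    out = np.zeros((n_chunks, chunk_size, latent.shape[1]))
    for c in range(n_chunks):
        seg = latent[c * hop : c * hop + chunk_size]
        out[c, : seg.shape[0]] = seg
    return out


def overlap_add_chunks(
    stack: np.ndarray, overlap: float = 0.5, n_frames: int | None = None
) -> np.ndarray:
    """Invert :func:`chunk` exactly by overlap-add with averaging compensation."""
    n_chunks, chunk_size, n_filters = stack.shape
    hop = max(int(round(chunk_size * (1.0 - overlap))), 1)
    total = (n_chunks - 1) * hop + chunk_size
    num = np.zeros((total, n_filters))
    den = np.zeros(total)
    for c in range(n_chunks):
        num[c * hop : c * hop + chunk_size] += stack[c]
        den[c * hop : c * hop + chunk_size] += 1.0
    out = num / den[:, None]
    return out[:n_frames] if n_frames is not None else out


def _chunk_t(latent: Tensor, chunk_size: int, overlap: float) -> tuple[Tensor, int]:
    n_frames, n_filters = latent.shape
    hop, n_chunks = _chunk_geometry(n_frames, chunk_size, overlap)
    idx = np.arange(n_chunks)[:, None] * hop + np.arange(chunk_size)[None, :]
    valid = idx < n_frames
    safe = np.where(valid, idx, 0)
    gathered = latent[safe] * Tensor(valid[:, :, None].astype(float))
    return gathered, hop


def _overlap_add_t(stack: Tensor, hop: int, n_frames: int) -> Tensor:
    n_chunks, chunk_size, n_filters = stack.shape
    total = (n_chunks - 1) * hop + chunk_size
    den = np.zeros(total)
    for c in range(n_chunks):
        den[c * hop : c * hop + chunk_size] += 1.0
    flat = stack.reshape(n_chunks * chunk_size, n_filters)
    idx = (np.arange(n_chunks)[:, None] * hop + np.arange(chunk_size)[None, :]).ravel()
    out = np.zeros((total, n_filters))
    # scatter-add via autodiff: build with matmul-free op
    onehot_free = _ScatterAdd(idx, total)
    summed = onehot_free(flat)
    return summed[:n_frames] * Tensor(1.0 / den[:n_frames, None])


class _ScatterAdd:
    """Differentiable scatter-add of rows onto target positions."""

    def __init__(self, idx: np.ndarray, total: int):
        self.idx = idx
        self.total = total

    def __call__(self, rows: Tensor) -> Tensor:
        idx, total = self.idx, self.total
        out_data = np.zeros((total, rows.shape[1]))
        np.add.at(out_data, idx, rows.data)
        out = Tensor(out_data, rows.requires_grad, (rows,))
        if rows.requires_grad:
            def backward(grad):
                rows._accumulate(grad[idx])
            out._backward = backward
        return out


# ---- masking network ------------------------------------------------------

def _masking_network_t(net: _SeparatorNet, latent: Tensor) -> tuple[Tensor, Tensor]:
    cfg = net.config
    n_frames = latent.shape[0]
    h = net.pre_linear(net.norm(latent))
    chunks, hop = _chunk_t(h, cfg.chunk_size, cfg.chunk_overlap)
    for blk in net.blocks:
        if blk._path == "intra":
            chunks = blk(chunks)  # attention within each chunk
        else:
            swapped = chunks.transpose(1, 0, 2)  # attention across chunks
            chunks = blk(swapped).transpose(1, 0, 2)
    chunks = net.post_linear(net.prelu(chunks))
    merged = _overlap_add_t(chunks, hop, n_frames)
    m1 = net.head1b(net.head1a(merged).relu()).clamp01()
    m2 = net.head2b(net.head2a(merged).relu()).clamp01()
    return m1, m2


def masking_network(model: SeparatorModel, latent: np.ndarray) -> MaskPair:
    """Estimate bounded foreground/background masks for an encoded latent."""
    latent = np.asarray(latent, dtype=np.float64)
    require(latent.ndim == 2, "latent must be frames x filters")
    if latent.shape[1] != model.config.n_filters:
        raise InvalidArgumentError("latent width does not match n_filters")
    m1, m2 = _masking_network_t(model.net, Tensor(latent))
    return MaskPair(m1.data, m2.data)


def _separate_t(net: _SeparatorNet, x: Tensor, length: int) -> tuple[Tensor, Tensor]:
    latent = _encode_t(net, x)
    m1, m2 = _masking_network_t(net, latent)
    fg = _decode_t(net, m1 * latent, length)
    bg = _decode_t(net, m2 * latent, length)
    return fg, bg


def separate(model: SeparatorModel, mixture: Waveform) -> tuple[Waveform, Waveform]:
    """Separate a mixture into (foreground, background) waveforms."""
    if mixture.rate != model.config.rate:
        raise InvalidArgumentError("mixture rate does not match model rate")
    if len(mixture) < model.config.kernel_samples:
        raise InvalidArgumentError("input shorter than one encoder kernel")
    fg, bg = _separate_t(model.net, Tensor(mixture.samples), len(mixture))
    return Waveform(fg.data, mixture.rate), Waveform(bg.data, mixture.rate)


# ---- training -------------------------------------------------------------

def _dft_matrices(window: int, nfft: int) -> tuple[np.ndarray, np.ndarray]:
    n = np.arange(window)[:, None]
    k = np.arange(nfft // 2 + 1)[None, :]
    angle = -2.0 * np.pi * n * k / nfft
    return np.cos(angle), np.sin(angle)


def _spectrum_t(x: Tensor, window: int = spectral.DEFAULT_WINDOW,
                hop: int = spectral.DEFAULT_HOP,
                nfft: int = spectral.DEFAULT_NFFT) -> tuple[Tensor, Tensor]:
    """Differentiable one-sided STFT (real, imaginary) via DFT matrices."""
    win = spectral.hamming_window(window)
    cos_m, sin_m = _dft_matrices(window, nfft)
    frames = x.frame(window, hop) * Tensor(win)
    return frames @ Tensor(cos_m), frames @ Tensor(sin_m)


def _item_loss(net: _SeparatorNet, mixture: np.ndarray, clean: np.ndarray,
               loss_kind: str) -> Tensor:
    length = len(mixture)
    fg, _ = _separate_t(net, Tensor(mixture), length)
    if loss_kind == "neg_sisdr":
        ref = Tensor(clean - clean.mean())
        est = fg - fg.mean()
        alpha = (est * ref).sum() / float(np.dot(clean - clean.mean(), clean - clean.mean()))
        err = est - alpha * ref
        return (err * err).sum() / ((alpha * ref) * (alpha * ref)).sum()
    # MSE over the complex de-noised spectrum vs the clean spectrum.  The
    # complex (not magnitude-only) difference is essential here: the decoder
    # synthesizes the waveform, and a magnitude-only loss would leave its
    # phase unconstrained (and the waveform SI-SDR arbitrary).
    est_re, est_im = _spectrum_t(fg)
    ref_re, ref_im = _spectrum_t(Tensor(clean))
    d_re = est_re - ref_re
    d_im = est_im - ref_im
    return (d_re * d_re + d_im * d_im).mean()


def train_separator(
    model: SeparatorModel,
    train_set: Sequence[MixtureTriplet],
    val_set: Sequence[MixtureTriplet],
    config: SeparatorConfig | None = None,
) -> SeparatorModel:
    """Seeded Adam training on the foreground-vs-clean spectral MSE.

    Per-epoch validation loss is recorded; parameters with the best
    validation loss are restored at the end.
    """
    config = config or model.config
    if not train_set or not val_set:
        raise InvalidArgumentError("training and validation sets must be non-empty")
    train = [(tr.mixture.samples, tr.target.samples) for tr in train_set]
    val = [(tr.mixture.samples, tr.target.samples) for tr in val_set]
    params = list(model.net.parameters().values())
    opt = Adam(params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    best_state, best_val = None, np.inf
    history = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(train))
        train_losses = []
        for start in range(0, len(train), config.batch_size):
            idx = order[start : start + config.batch_size]
            opt.zero_grad()
            losses = [
                _item_loss(model.net, train[i][0], train[i][1], config.loss)
                for i in idx
            ]
            loss = losses[0]
            for extra in losses[1:]:
                loss = loss + extra
            loss = loss * (1.0 / len(losses))
            loss.backward()
            opt.step()
            train_losses.append(float(loss.data))
        val_losses = [
            float(_item_loss(model.net, m, c, config.loss).data) for m, c in val
        ]
        val_loss = float(np.mean(val_losses))
        if not np.isfinite(val_loss):
            raise RuntimeError(f"non-finite validation loss at epoch {epoch}")
        history.append({"train_loss": float(np.mean(train_losses)), "val_loss": val_loss})
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.net.state_dict()
    if best_state is not None:
        model.net.load_state_dict(best_state)
    model.history = history
    return model
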