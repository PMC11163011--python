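"""Recurrent soft-mask speech enhancement.

Pipeline (waveform in / waveform out):

    STFT -> add-one log magnitude features -> stacked (bi)LSTM layers, each
    followed by a ReLU projection -> logistic output layer (gains in [0, 1])
    -> mask applied to the noisy magnitude with the noisy phase -> iSTFT.

Training minimizes the spectral mean-square error between the masked noisy
magnitude and the clean target magnitude (linear-magnitude domain) with Adam;
per-epoch validation loss is recorded and the parameters with the best
validation loss are returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import spectral
from .autodiff import Adam, Tensor
from .mixer import MixtureTriplet
from .nn import BiLSTM, Linear, Module
from .spectral import Mask, SpectralFrames, apply_mask, istft, logmag_features, stft
from .types import InvalidArgumentError, Waveform, require

__all__ = [
    "EnhancerConfig",
    "TrainedEnhancer",
    "init_enhancer",
    "predict_mask",
    "spectral_mse_loss",
    "train_enhancer",
    "enhance",
]


@dataclass(frozen=True)
class EnhancerConfig:
    """Architecture + optimization hyperparameters.

    Reference-scale defaults: two bidirectional LSTM layers of 256 units,
    each followed by a 128-unit projection, learning rate 1e-4, 100 epochs.
    Tests use much smaller instances (e.g. one 32-unit layer, <=10 epochs).
    """

    n_bins: int = 257
    recurrent_layers: int = 2
    recurrent_units: int = 256
    projection_units: int = 128
    bidirectional: bool = True
    learning_rate: float = 1e-4
    epochs: int = 100
    batch_size: int = 8
    seed: int = 0
    window_samples: int = spectral.DEFAULT_WINDOW
    hop_samples: int = spectral.DEFAULT_HOP
    nfft: int = spectral.DEFAULT_NFFT
    rate: int = 16000
    output_activation: str = "sigmoid"  # or "relu_clamp"

    def __post_init__(self) -> None:
        require(self.n_bins >= 1, "n_bins must be >= 1")
        require(self.recurrent_layers >= 1, "need at least one recurrent layer")
        require(self.recurrent_units >= 1, "recurrent_units must be >= 1")
        require(self.projection_units >= 1, "projection_units must be >= 1")
        require(self.learning_rate >= 0, "learning_rate must be non-negative")
        require(self.epochs >= 1, "epochs must be >= 1")
        require(self.batch_size >= 1, "batch_size must be >= 1")
        require(self.output_activation in ("sigmoid", "relu_clamp"),
                "unknown output activation")


class _MaskNet(Module):
    def __init__(self, config: EnhancerConfig):
        rng = np.random.default_rng(config.seed)
        self.config = config
        self.layers: list[Module] = []
        n_in = config.n_bins
        for _ in range(config.recurrent_layers):
            lstm = BiLSTM(n_in, config.recurrent_units, rng, config.bidirectional)
            proj = Linear(lstm.n_out, config.projection_units, rng)
            self.layers.extend([lstm, proj])
            n_in = config.projection_units
        self.head = Linear(n_in, config.n_bins, rng)

    def __call__(self, features: Tensor) -> Tensor:
        h = features
        for i in range(0, len(self.layers), 2):
            h = self.layers[i](h)
            h = self.layers[i + 1](h).relu()
        z = self.head(h)
        if self.config.output_activation == "sigmoid":
            return z.sigmoid()
        return z.clamp01()


@dataclass
class TrainedEnhancer:
    """A mask-predicting model plus its training history."""

    config: EnhancerConfig
    net: _MaskNet
    history: list = field(default_factory=list)

    def state_dict(self) -> dict:
        return self.net.state_dict()


def init_enhancer(config: EnhancerConfig) -> TrainedEnhancer:
    """Deterministically initialize an (untrained but callable) enhancer."""
    return TrainedEnhancer(config=config, net=_MaskNet(config), history=[])


def predict_mask(model: TrainedEnhancer, features: np.ndarray) -> Mask:
    """Predict a bounded soft mask for a frames x n_bins feature matrix."""
    features = np.asarray(features, dtype=np.float64)
    require(features.ndim == 2, "features must be frames x bins")
    if features.shape[1] != model.config.n_bins:
        raise InvalidArgumentError(
            f"feature width {features.shape[1]} != n_bins {model.config.n_bins}"
        )
    out = model.net(Tensor(features[None, :, :]))
    return Mask(out.data[0])


def spectral_mse_loss(
    predicted_mask: Mask | np.ndarray,
    mixture_frames: SpectralFrames,
    clean_frames: SpectralFrames,
) -> float:
    """Mean over all T-F cells of (mask * |mixture| - |clean|)^2."""
    gains = predicted_mask.gains if isinstance(predicted_mask, Mask) else np.asarray(predicted_mask)
    require(
        gains.shape == mixture_frames.values.shape == clean_frames.values.shape,
        "shape mismatch between mask, mixture, and clean frames",
    )
    diff = gains * np.abs(mixture_frames.values) - np.abs(clean_frames.values)
    return float(np.mean(diff * diff))


def _features_and_mags(
    triplets: Sequence[MixtureTriplet], config: EnhancerConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack (features, |mixture|, |clean|) for same-length triplets."""
    feats, mixmags, cleanmags = [], [], []
    for tr in triplets:
        mix = stft(tr.mixture, config.window_samples, config.hop_samples, config.nfft)
        clean = stft(tr.target, config.window_samples, config.hop_samples, config.nfft)
        feats.append(logmag_features(mix))
        mixmags.append(np.abs(mix.values))
        cleanmags.append(np.abs(clean.values))
    return np.stack(feats), np.stack(mixmags), np.stack(cleanmags)


def _batch_loss(net: _MaskNet, feats, mixmag, cleanmag) -> Tensor:
    mask = net(Tensor(feats))
    diff = mask * Tensor(mixmag) - Tensor(cleanmag)
    return (diff * diff).mean()


class CidnTrainingError(RuntimeError):
    """Training diverged (non-finite loss)."""


def train_enhancer(
    model: TrainedEnhancer,
    train_set: Sequence[MixtureTriplet],
    val_set: Sequence[MixtureTriplet],
    config: EnhancerConfig | None = None,
) -> TrainedEnhancer:
    """Train by spectral MSE with Adam; returns the best-validation model.

    Both data order and initialization derive from ``config.seed``.  Training
    items must share one length (the synthetic fixtures do); per-epoch
    train/val losses are recorded in ``model.history``.
    """
    config = config or model.config
    if not train_set or not val_set:
        raise InvalidArgumentError("training and validation sets must be non-empty")
    feats, mixmag, cleanmag = _features_and_mags(train_set, config)
    vfeats, vmixmag, vcleanmag = _features_and_mags(val_set, config)

    params = list(model.net.parameters().values())
    opt = Adam(params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    n = feats.shape[0]
    best_state, best_val = None, np.inf
    history = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        train_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            opt.zero_grad()
            loss = _batch_loss(model.net, feats[idx], mixmag[idx], cleanmag[idx])
            loss.backward()
            opt.step()
            train_losses.append(float(loss.data))
        val_loss = float(_batch_loss(model.net, vfeats, vmixmag, vcleanmag).data)
        if not np.isfinite(val_loss):
            raise CidnTrainingError(f"non-finite validation loss at epoch {epoch}")
        history.append({"train_loss": float(np.mean(train_losses)), "val_loss": val_loss})
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.net.state_dict()
    if best_state is not None:
        model.net.load_state_dict(best_state)
    model.history = history
    return model


def enhance(model: TrainedEnhancer, noisy: Waveform) -> Waveform:
    """Full enhancement: mask the noisy magnitude, keep the noisy phase."""
    if noisy.rate != model.config.rate:
        raise InvalidArgumentError(
            f"rate {noisy.rate} != model rate {model.config.rate}"
        )
    cfg = model.config
    frames = stft(noisy, cfg.window_samples, cfg.hop_samples, cfg.nfft)
    mask = predict_mask(model, logmag_features(frames))
    return istft(apply_mask(frames, mask))
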