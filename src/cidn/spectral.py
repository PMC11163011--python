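"""Time-frequency analysis/synthesis and soft-mask application.

Analysis uses Hamming-windowed frames (default 512-sample window, 256-sample
hop, 512-point FFT at 16 kHz, i.e. 32 ms / 16 ms), one-sided spectra with
nfft/2+1 bins.  Synthesis is weighted overlap-add with window-square
normalization, which reconstructs the input exactly (to float precision)
for any strictly positive window.

Frame ``t`` covers samples ``[t*hop, t*hop + window)`` (0-based, half-open);
the tail is zero-padded so every input sample is covered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import InvalidArgumentError, Waveform, require

__all__ = [
    "SpectralFrames",
    "Mask",
    "stft",
    "istft",
    "logmag_features",
    "apply_mask",
    "ideal_ratio_mask",
    "hamming_window",
]

DEFAULT_WINDOW = 512
DEFAULT_HOP = 256
DEFAULT_NFFT = 512


def hamming_window(n: int) -> np.ndarray:
    """Periodic Hamming window (strictly positive, min 0.08)."""
    return 0.54 - 0.46 * np.cos(2.0 * np.pi * np.arange(n) / n)


@dataclass(frozen=True)
class SpectralFrames:
    """Complex one-sided STFT, frames x bins, with its analysis geometry."""

    values: np.ndarray
    window_samples: int
    hop_samples: int
    nfft: int
    rate: int
    original_length: int

    def __post_init__(self) -> None:
        require(self.values.ndim == 2, "frames must be a 2-D matrix")
        require(self.values.shape[1] == self.nfft // 2 + 1, "bins must equal nfft/2+1")
        require(self.hop_samples <= self.window_samples, "hop must not exceed window")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)

    def with_values(self, values: np.ndarray) -> "SpectralFrames":
        require(values.shape == self.values.shape, "shape mismatch")
        return SpectralFrames(
            values, self.window_samples, self.hop_samples, self.nfft,
            self.rate, self.original_length,
        )


@dataclass(frozen=True)
class Mask:
    """Bounded gain surface: every entry in [0, 1], shape = frames x bins.

    Out-of-range gains are a contract violation at construction, not
    silently clipped.
    """

    gains: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.gains, dtype=np.float64)
        require(g.ndim == 2, "mask must be 2-D")
        if not np.all(np.isfinite(g)):
            raise InvalidArgumentError("mask contains non-finite gains")
        if g.min() < 0.0 or g.max() > 1.0:
            raise InvalidArgumentError("mask gains must lie in [0, 1]")
        object.__setattr__(self, "gains", g)


def _frame_starts(length: int, window: int, hop: int) -> int:
    """Number of frames covering every sample of a signal of given length."""
    if length <= window:
        return 1
    return int(np.ceil((length - window) / hop)) + 1


def stft(
    w: Waveform,
    window_samples: int = DEFAULT_WINDOW,
    hop_samples: int = DEFAULT_HOP,
    nfft: int = DEFAULT_NFFT,
) -> SpectralFrames:
    """Hamming-windowed one-sided STFT.

    Inputs shorter than one window are zero-padded (the tail always is).
    """
    require(nfft >= window_samples, "nfft must be >= window size")
    require(hop_samples >= 1 and hop_samples <= window_samples, "invalid hop")
    x = w.samples
    n_frames = _frame_starts(len(x), window_samples, hop_samples)
    padded = np.zeros((n_frames - 1) * hop_samples + window_samples)
    padded[: len(x)] = x
    win = hamming_window(window_samples)
    frames = np.lib.stride_tricks.sliding_window_view(padded, window_samples)[
        :: hop_samples
    ][:n_frames]
    values = np.fft.rfft(frames * win, n=nfft, axis=1)
    return SpectralFrames(values, window_samples, hop_samples, nfft, w.rate, len(x))


def istft(frames: SpectralFrames) -> Waveform:
    """Weighted overlap-add inverse with window-square normalization.

    Output is truncated/padded to ``frames.original_length``.  Raises a
    configuration error if the overlapped squared window vanishes anywhere
    (cannot happen for the Hamming default).
    """
    win = hamming_window(frames.window_samples)
    hop = frames.hop_samples
    n_frames = frames.n_frames
    length = (n_frames - 1) * hop + frames.window_samples
    num = np.zeros(length)
    den = np.zeros(length)
    segs = np.fft.irfft(frames.values, n=frames.nfft, axis=1)[:, : frames.window_samples]
    for t in range(n_frames):
        sl = slice(t * hop, t * hop + frames.window_samples)
        num[sl] += segs[t] * win
        den[sl] += win * win
    if np.min(den) <= 1e-12:
        raise InvalidArgumentError(
            "window/hop configuration violates overlap-add invertibility"
        )
    out = num / den
    n = frames.original_length
    if len(out) < n:
        out = np.pad(out, (0, n - len(out)))
    return Waveform(out[:n], frames.rate)


def logmag_features(frames: SpectralFrames) -> np.ndarray:
    """Add-one log spectral magnitude, log(1 + |X|); non-negative."""
    return np.log1p(np.abs(frames.values))


def apply_mask(
    frames: SpectralFrames, m: Mask, phase_source: SpectralFrames | None = None
) -> SpectralFrames:
    """Apply a bounded gain surface to spectral magnitudes.

    Output magnitude is ``m * |frames|``; the phase is taken from
    ``phase_source`` (default: ``frames`` itself, i.e. the noisy-mixture
    phase, standard for magnitude-mask enhancement).
    """
    phase_source = phase_source or frames
    require(m.gains.shape == frames.values.shape, "mask/frames shape mismatch")
    require(
        phase_source.values.shape == frames.values.shape,
        "phase source shape mismatch",
    )
    phase = np.exp(1j * np.angle(phase_source.values))
    return frames.with_values(m.gains * np.abs(frames.values) * phase)


def ideal_ratio_mask(
    target_frames: SpectralFrames, noise_frames: SpectralFrames
) -> Mask:
    """Oracle soft mask |S| / (|S| + |N|), with 0/0 defined as 0."""
    require(
        target_frames.values.shape == noise_frames.values.shape,
        "target/noise shape mismatch",
    )
    s = np.abs(target_frames.values)
    n = np.abs(noise_frames.values)
    denom = s + n
    gains = np.divide(s, denom, out=np.zeros_like(s), where=denom > 0)
    return Mask(np.clip(gains, 0.0, 1.0))
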