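"""Objective evaluation metrics: SI-SDR, STOI, and a PESQ adapter.

SI-SDR projects the estimate onto the reference (optimal scaling ``alpha``)
and reports ``10 log10`` of the projected-target energy over the residual
energy: a scale-invariant distortion ratio in dB, capped at +140 dB when the
residual underflows.

STOI follows the published short-time objective intelligibility pipeline:
resample to 10 kHz, discard silent frames (40 dB below the loudest frame),
one-third-octave analysis (15 bands from 150 Hz) of 256-sample Hann frames,
384 ms segments, per-segment normalization and -15 dB clipping of the
degraded envelope, per-unit linear correlation, global mean.

PESQ (ITU-T P.862) is not re-implemented: an external conforming backend may
be registered; without one the metric is reported as absent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy import signal as sps

from .types import ContractViolationError, InvalidArgumentError, Waveform, require

__all__ = [
    "SISDRDecomposition",
    "si_sdr",
    "si_sdr_db",
    "stoi",
    "register_pesq_backend",
    "pesq_adapter",
]

SI_SDR_CAP_DB = 140.0


@dataclass(frozen=True)
class SISDRDecomposition:
    alpha: float
    target_energy: float
    error_energy: float
    si_sdr_db: float


def si_sdr(reference: Waveform | np.ndarray, estimate: Waveform | np.ndarray) -> SISDRDecomposition:
    """Scale-invariant source-to-distortion ratio of ``estimate`` w.r.t. ``reference``.

    Means are removed; ``alpha = <e, r> / <r, r>``; target = alpha * r;
    error = e - target.  Capped at +140 dB when the error energy underflows.
    """
    r = reference.samples if isinstance(reference, Waveform) else np.asarray(reference, float)
    e = estimate.samples if isinstance(estimate, Waveform) else np.asarray(estimate, float)
    if isinstance(reference, Waveform) and isinstance(estimate, Waveform):
        require(reference.rate == estimate.rate, "rates differ")
    if r.shape != e.shape:
        raise InvalidArgumentError("length mismatch between reference and estimate")
    r = r - r.mean()
    e = e - e.mean()
    rr = float(np.dot(r, r))
    if rr <= 0.0:
        raise InvalidArgumentError("reference is all-zero")
    alpha = float(np.dot(e, r) / rr)
    target = alpha * r
    err = e - target
    te = float(np.dot(target, target))
    ee = float(np.dot(err, err))
    if ee <= te * 10.0 ** (-SI_SDR_CAP_DB / 10.0) or ee == 0.0:
        value = SI_SDR_CAP_DB
    else:
        value = 10.0 * np.log10(te / ee)
    return SISDRDecomposition(alpha=alpha, target_energy=te, error_energy=ee,
                              si_sdr_db=float(value))


def si_sdr_db(reference, estimate) -> float:
    """Convenience scalar view of :func:`si_sdr`."""
    return si_sdr(reference, estimate).si_sdr_db


# ---- STOI -----------------------------------------------------------------

_STOI_RATE = 10000
_STOI_FRAME = 256
_STOI_NFFT = 512
_STOI_HOP = 128
_STOI_N_BANDS = 15
_STOI_BAND_BASE_HZ = 150.0
_STOI_SEGMENT_FRAMES = 30  # 384 ms at 10 kHz / 128-sample hop
_STOI_CLIP_DB = -15.0
_STOI_VAD_DB = 40.0


def _third_octave_matrix(rate: int, nfft: int) -> np.ndarray:
    freqs = np.fft.rfftfreq(nfft, 1.0 / rate)
    centers = _STOI_BAND_BASE_HZ * 2.0 ** (np.arange(_STOI_N_BANDS) / 3.0)
    mat = np.zeros((_STOI_N_BANDS, len(freqs)))
    for i, cf in enumerate(centers):
        lo, hi = cf / 2 ** (1 / 6), cf * 2 ** (1 / 6)
        mat[i, (freqs >= lo) & (freqs < hi)] = 1.0
    return mat


def _remove_silent_frames(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    win = np.hanning(_STOI_FRAME + 2)[1:-1]
    n_frames = max((len(x) - _STOI_FRAME) // _STOI_HOP + 1, 0)
    if n_frames == 0:
        return x, y
    idx = np.arange(n_frames)[:, None] * _STOI_HOP + np.arange(_STOI_FRAME)
    xf = x[idx] * win
    yf = y[idx] * win
    energies = 20.0 * np.log10(np.linalg.norm(xf, axis=1) + 1e-12)
    keep = energies >= energies.max() - _STOI_VAD_DB
    xf, yf = xf[keep], yf[keep]
    # re-synthesize kept frames by overlap-add
    out_len = (len(xf) - 1) * _STOI_HOP + _STOI_FRAME if len(xf) else 0
    xr = np.zeros(out_len)
    yr = np.zeros(out_len)
    for t in range(len(xf)):
        sl = slice(t * _STOI_HOP, t * _STOI_HOP + _STOI_FRAME)
        xr[sl] += xf[t] * win
        yr[sl] += yf[t] * win
    return xr, yr


def stoi(reference: Waveform, estimate: Waveform) -> float:
    """Short-time objective intelligibility score (~0..1)."""
    require(reference.rate == estimate.rate, "rates differ")
    if len(reference) != len(estimate):
        raise InvalidArgumentError("length mismatch between reference and estimate")
    x, y = reference.samples, estimate.samples
    if reference.rate != _STOI_RATE:
        g = np.gcd(reference.rate, _STOI_RATE)
        x = sps.resample_poly(x, _STOI_RATE // g, reference.rate // g)
        y = sps.resample_poly(y, _STOI_RATE // g, reference.rate // g)
    x, y = _remove_silent_frames(x, y)

    min_len = (_STOI_SEGMENT_FRAMES - 1) * _STOI_HOP + _STOI_FRAME
    if len(x) < min_len:
        raise InvalidArgumentError(
            "signal shorter than one STOI analysis segment after silence removal"
        )
    win = np.hanning(_STOI_FRAME + 2)[1:-1]
    n_frames = (len(x) - _STOI_FRAME) // _STOI_HOP + 1
    idx = np.arange(n_frames)[:, None] * _STOI_HOP + np.arange(_STOI_FRAME)
    X = np.fft.rfft(x[idx] * win, n=_STOI_NFFT, axis=1)
    Y = np.fft.rfft(y[idx] * win, n=_STOI_NFFT, axis=1)
    band = _third_octave_matrix(_STOI_RATE, _STOI_NFFT)
    Xb = np.sqrt(band @ (np.abs(X.T) ** 2)).T  # frames x bands
    Yb = np.sqrt(band @ (np.abs(Y.T) ** 2)).T

    # degraded envelope is normalized per segment/band, then clipped so the
    # local SDR cannot fall below the -15 dB bound
    clip_gain = 1.0 + 10.0 ** (-_STOI_CLIP_DB / 20.0)
    N = _STOI_SEGMENT_FRAMES
    corrs = []
    for m in range(N, n_frames + 1):
        xs = Xb[m - N : m]  # N x bands
        ys = Yb[m - N : m]
        norm = np.linalg.norm(xs, axis=0) / (np.linalg.norm(ys, axis=0) + 1e-12)
        ys_n = ys * norm
        ys_c = np.minimum(ys_n, xs * clip_gain)
        xm = xs - xs.mean(axis=0)
        ym = ys_c - ys_c.mean(axis=0)
        denom = np.linalg.norm(xm, axis=0) * np.linalg.norm(ym, axis=0)
        good = denom > 1e-12
        c = np.zeros(xs.shape[1])
        c[good] = np.sum(xm * ym, axis=0)[good] / denom[good]
        corrs.append(c)
    return float(np.mean(corrs))


# ---- PESQ adapter ---------------------------------------------------------

_pesq_backend: Optional[Callable[[Waveform, Waveform], float]] = None


def register_pesq_backend(backend: Optional[Callable[[Waveform, Waveform], float]]) -> None:
    """Register (or clear, with None) an external PESQ implementation."""
    global _pesq_backend
    _pesq_backend = backend


def pesq_adapter(reference: Waveform, estimate: Waveform) -> Optional[float]:
    """Delegate to a registered PESQ backend; None when absent.

    A returned score outside the documented [-0.5, 4.5] range raises
    :class:`ContractViolationError`.
    """
    if _pesq_backend is None:
        return None
    score = float(_pesq_backend(reference, estimate))
    if not (-0.5 <= score <= 4.5):
        raise ContractViolationError(
            f"PESQ backend returned {score}, outside [-0.5, 4.5]"
        )
    return score
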