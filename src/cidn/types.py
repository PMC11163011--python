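"""Core value types shared by every module.

The package exchanges audio as :class:`Waveform` objects: mono, finite,
dimensionless amplitude with nominal full scale +/-1, and an explicit sample
rate in Hz.  Everything downstream (mixing, STFT analysis, model training,
metrics) operates on these.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CidnError",
    "InvalidArgumentError",
    "NoActiveSignalError",
    "CannotMixError",
    "ContractViolationError",
    "Waveform",
]


class CidnError(Exception):
    """Base class for package errors."""


class InvalidArgumentError(CidnError, ValueError):
    """An argument violates a documented precondition."""


class NoActiveSignalError(CidnError):
    """Raised when a level measurement finds no voice-active frames."""


class CannotMixError(CidnError):
    """Raised when a mixture cannot be realized (e.g. zero-energy noise)."""


class ContractViolationError(CidnError):
    """An external component returned a value outside its contract."""


@dataclass(frozen=True)
class Waveform:
    """Mono audio signal.

    Parameters
    ----------
    samples
        1-D float array of amplitudes (nominal full scale +/-1.0).
    rate
        Sample rate in Hz, > 0.
    """

    samples: np.ndarray
    rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise InvalidArgumentError("waveform must be mono (1-D)")
        if not np.all(np.isfinite(samples)):
            raise InvalidArgumentError("waveform contains non-finite samples")
        if self.rate <= 0:
            raise InvalidArgumentError("sample rate must be positive")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return len(self) / self.rate

    def rms(self) -> float:
        return float(np.sqrt(np.mean(np.square(self.samples)))) if len(self) else 0.0

    def scaled(self, gain: float) -> "Waveform":
        return Waveform(self.samples * gain, self.rate)


def require(condition: bool, message: str) -> None:
    """Raise :class:`InvalidArgumentError` unless ``condition`` holds."""
    if not condition:
        raise InvalidArgumentError(message)
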