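"""Seeded parametric generators for speech-like and noise fixtures.

Real speech-in-noise experiments draw targets from read-speech corpora and
maskers from recorded environmental noise or multi-talker babble.  This module
replaces those recordings with parametric stand-ins that preserve the
statistical contrasts the enhancement algorithms exploit:

* harmonicity and formant structure of voiced speech,
* syllabic amplitude modulation with near-silent gaps,
* stationary speech-weighted noise (CCITT-like long-term spectrum),
* sparse transient-plus-floor environmental noise,
* N-talker babble built from pairwise-distinct synthetic talkers.

Every generator is a pure function of its arguments and seed: repeated calls
are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import signal as sps

from .types import InvalidArgumentError, Waveform, require

__all__ = [
    "TalkerProfile",
    "random_profile",
    "distinct_profiles",
    "make_speechlike",
    "g227_like_envelope",
    "make_speech_shaped_noise",
    "make_sparse_noise",
    "make_babble",
]

#: per-talker RMS used when babble components are equalized before summation
BABBLE_COMPONENT_RMS = 0.05


@dataclass(frozen=True)
class TalkerProfile:
    """Parametric description of one synthetic talker.

    f0 is the glottal fundamental (60-400 Hz), formant centers/bandwidths
    shape the vocal-tract resonances, and ``syllable_rate`` (2-8 Hz) drives
    the syllabic amplitude envelope.
    """

    f0: float = 120.0
    formant_centers: tuple = (500.0, 1500.0, 2500.0)
    formant_bandwidths: tuple = (90.0, 120.0, 160.0)
    syllable_rate: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        require(60.0 <= self.f0 <= 400.0, "f0 must lie in [60, 400] Hz")
        centers = tuple(float(c) for c in self.formant_centers)
        require(
            all(a < b for a, b in zip(centers, centers[1:])),
            "formant centers must be strictly increasing",
        )
        require(
            len(self.formant_bandwidths) == len(centers),
            "one bandwidth per formant center",
        )
        require(2.0 <= self.syllable_rate <= 8.0, "syllable_rate must lie in [2, 8] Hz")


# Seeded pool of talker parameters. Female-like vs male-like talkers differ
# only by f0 range; nothing downstream asserts gender.
_F0_RANGE = (85.0, 320.0)


def random_profile(rng: np.random.Generator, seed: int = 0) -> TalkerProfile:
    """Draw one talker profile from the seeded pool."""
    f0 = float(rng.uniform(*_F0_RANGE))
    f1 = float(rng.uniform(350.0, 750.0))
    f2 = float(rng.uniform(1100.0, 2000.0))
    f3 = float(rng.uniform(2300.0, 3100.0))
    bws = (
        float(rng.uniform(60.0, 120.0)),
        float(rng.uniform(90.0, 160.0)),
        float(rng.uniform(120.0, 220.0)),
    )
    rate = float(rng.uniform(2.5, 6.5))
    return TalkerProfile(f0, (f1, f2, f3), bws, rate, seed)


def distinct_profiles(n: int, seed: int) -> list[TalkerProfile]:
    """Draw ``n`` pairwise-distinct talker profiles from a seeded pool.

    Distinctness is enforced on the (f0, formant-center) tuple: redraws occur
    until all f0s differ by at least 5 Hz.
    """
    require(n >= 1, "need at least one talker")
    rng = np.random.default_rng(seed)
    profiles: list[TalkerProfile] = []
    while len(profiles) < n:
        cand = random_profile(rng, seed=int(rng.integers(0, 2**31 - 1)))
        if all(abs(cand.f0 - p.f0) >= 5.0 for p in profiles):
            profiles.append(cand)
    return profiles


def _syllable_envelope(n: int, rate: float, syllable_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Raised-cosine syllable bursts with near-silent inter-syllable gaps."""
    period = int(round(rate / syllable_rate))
    burst = int(round(period * 0.7))  # ~70% duty cycle
    env = np.full(n, 1e-3)
    t0 = int(rng.integers(0, period // 4 + 1))
    while t0 < n:
        length = min(burst, n - t0)
        window = 0.5 - 0.5 * np.cos(2.0 * np.pi * np.arange(length) / burst)
        amp = 0.6 + 0.4 * rng.random()  # syllable-to-syllable level variation
        env[t0 : t0 + length] = np.maximum(env[t0 : t0 + length], amp * window)
        t0 += period
    return env


def make_speechlike(profile: TalkerProfile, duration: float, rate: int = 16000) -> Waveform:
    """Synthesize a speech-like signal: harmonic source, formant filter, syllabic envelope.

    The source is a sum of harmonics of ``profile.f0`` with seeded random
    phases and 1/k amplitude roll-off; it is filtered through second-order
    resonators at the formant centers and gated by a syllabic envelope with
    near-silent gaps.  Deterministic for a fixed ``profile.seed``; peak
    amplitude is normalized to 0.95.
    """
    require(duration > 0, "duration must be positive")
    require(rate >= 8000, "rate must be at least 8 kHz")
    require(
        rate >= 2 * max(profile.formant_centers),
        "rate below twice the highest formant (aliasing)",
    )
    rng = np.random.default_rng(profile.seed)
    n = int(round(duration * rate))
    t = np.arange(n) / rate

    # harmonic source with slow f0 vibrato for naturalness
    f0 = profile.f0 * (1.0 + 0.01 * np.sin(2.0 * np.pi * 3.0 * t + rng.uniform(0, 2 * np.pi)))
    phase0 = np.cumsum(2.0 * np.pi * f0 / rate)
    n_harm = int(min(rate / 2.0, 5000.0) // profile.f0)
    src = np.zeros(n)
    for k in range(1, max(n_harm, 1) + 1):
        src += (1.0 / k) * np.cos(k * phase0 + rng.uniform(0, 2 * np.pi))
    src += 0.02 * rng.standard_normal(n)  # aspiration noise

    # formant shaping: parallel second-order resonators
    shaped = np.zeros(n)
    for fc, bw in zip(profile.formant_centers, profile.formant_bandwidths):
        r = np.exp(-np.pi * bw / rate)
        theta = 2.0 * np.pi * fc / rate
        a = [1.0, -2.0 * r * np.cos(theta), r * r]
        b = [1.0 - r]
        shaped += sps.lfilter(b, a, src)

    env = _syllable_envelope(n, rate, profile.syllable_rate, rng)
    out = shaped * env
    peak = np.max(np.abs(out))
    if peak > 0:
        out = out * (0.95 / peak)
    return Waveform(out, rate)


def g227_like_envelope(freqs_hz: np.ndarray) -> np.ndarray:
    """Speech-weighted amplitude envelope: flat to 1 kHz, -6 dB/octave above,
    floored at -60 dB beyond 6 kHz.

    A stand-in for the standardized CCITT speech-shaped spectrum; any tabulated
    envelope can be passed to :func:`make_speech_shaped_noise` instead.
    """
    f = np.asarray(freqs_hz, dtype=float)
    amp = np.ones_like(f)
    above = f > 1000.0
    amp[above] = 1000.0 / f[above]  # -6 dB/octave in amplitude
    amp[f > 6000.0] = 10.0 ** (-60.0 / 20.0)
    return amp


def make_speech_shaped_noise(
    duration: float,
    rate: int = 16000,
    shaping: Callable[[np.ndarray], np.ndarray] | None = None,
    seed: int = 0,
) -> Waveform:
    """Stationary Gaussian noise whose long-term spectrum follows ``shaping``.

    White Gaussian noise is shaped in the frequency domain by multiplying its
    spectrum with the envelope sampled at the FFT bin frequencies, which makes
    the long-term spectral match essentially exact.  Peak-normalized to 0.95.
    """
    require(duration >= 0.5, "duration too short for spectral estimation (< 0.5 s)")
    require(rate > 0, "rate must be positive")
    shaping = shaping or g227_like_envelope
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    spec *= shaping(freqs)
    out = np.fft.irfft(spec, n)
    peak = np.max(np.abs(out))
    if peak > 0:
        out = out * (0.95 / peak)
    return Waveform(out, rate)


def make_sparse_noise(
    duration: float,
    rate: int = 16000,
    event_rate: float = 2.0,
    seed: int = 0,
) -> Waveform:
    """Non-stationary environmental-style noise: Gaussian floor plus sparse
    band-limited transients at ``event_rate`` events/second.

    ``event_rate=0`` degenerates to the stationary floor alone.  Deterministic
    per seed; peak-limited to 0.95.
    """
    require(duration > 0, "duration must be positive")
    require(event_rate >= 0, "event_rate must be non-negative")
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    floor_sigma = 0.02
    out = floor_sigma * rng.standard_normal(n)

    n_events = rng.poisson(event_rate * duration)
    for _ in range(n_events):
        start = int(rng.integers(0, n))
        length = int(rng.uniform(0.03, 0.12) * rate)
        length = min(length, n - start)
        if length < 8:
            continue
        fc = rng.uniform(300.0, 4000.0)
        t = np.arange(length) / rate
        burst_env = np.sin(np.pi * np.arange(length) / length) ** 2
        burst = np.cos(2.0 * np.pi * fc * t + rng.uniform(0, 2 * np.pi))
        amp = floor_sigma * rng.uniform(8.0, 18.0)
        out[start : start + length] += amp * burst_env * burst

    peak = np.max(np.abs(out))
    if peak > 0.95:
        out = out * (0.95 / peak)
    return Waveform(out, rate)


def make_babble(
    n_talkers: int,
    duration: float,
    rate: int = 16000,
    seed: int = 0,
    component_rms: float = BABBLE_COMPONENT_RMS,
) -> Waveform:
    """N-talker babble: sum of pairwise-distinct speech-like talkers,
    each equalized to ``component_rms`` before summation (pure additivity —
    no post-sum normalization)."""
    require(n_talkers >= 1, "n_talkers must be at least 1")
    components = babble_components(n_talkers, duration, rate, seed, component_rms)
    out = np.sum([c.samples for c in components], axis=0)
    return Waveform(out, rate)


def babble_components(
    n_talkers: int,
    duration: float,
    rate: int = 16000,
    seed: int = 0,
    component_rms: float = BABBLE_COMPONENT_RMS,
) -> list[Waveform]:
    """The individual RMS-equalized talkers that sum to :func:`make_babble`."""
    require(n_talkers >= 1, "n_talkers must be at least 1")
    profiles = distinct_profiles(n_talkers, seed)
    comps = []
    for p in profiles:
        w = make_speechlike(p, duration, rate)
        r = w.rms()
        comps.append(w.scaled(component_rms / r if r > 0 else 0.0))
    return comps
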