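"""Speech-in-noise mixture construction and experiment manifests.

Mixing convention
-----------------
The target is first scaled so that its *active* speech level (RMS over
voice-active frames, a practical approximation of the ITU-T P.56 active
level) sits at a fixed anchor, -29 dBFS by default.  The noise is then
scaled so that the SNR — active level of the target minus overall RMS level
of the (seeded-offset-cropped) noise — equals the requested value.  The
mixture is the plain sample-wise sum; no clipping normalization is applied,
so additivity holds exactly in float.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .types import (
    CannotMixError,
    InvalidArgumentError,
    NoActiveSignalError,
    Waveform,
    require,
)
from . import synthgen

__all__ = [
    "NOISE_KINDS",
    "MixtureSpec",
    "MixtureTriplet",
    "active_level",
    "mix_at_snr",
    "plan_training_manifest",
    "plan_behavioral_manifest",
    "realize_mixture",
    "make_mixture_batch",
]

#: closed set of noise kinds used in training manifests
NOISE_KINDS = ("stationary", "sparse", "babble1", "babble2", "babble4")

DEFAULT_ANCHOR_DBFS = -29.0
DEFAULT_ACTIVITY_THRESHOLD_DB = 40.0


@dataclass(frozen=True)
class MixtureSpec:
    """A planned mixing job (no audio attached)."""

    id: str
    target_ref: str
    noise_kind: str
    snr_db: float
    split: str = "train"
    seed: int = 0

    def __post_init__(self) -> None:
        require(self.noise_kind in NOISE_KINDS, f"unknown noise kind {self.noise_kind!r}")
        require(np.isfinite(self.snr_db), "snr_db must be finite")
        require(self.split in ("train", "val", "test"), f"unknown split {self.split!r}")


@dataclass(frozen=True)
class MixtureTriplet:
    """Realized (target, noise, mixture) signals with the achieved SNR."""

    target: Waveform
    noise: Waveform
    mixture: Waveform
    achieved_snr_db: float
    target_level_dbfs: float

    def __post_init__(self) -> None:
        require(
            len(self.target) == len(self.noise) == len(self.mixture),
            "triplet signals must have equal lengths",
        )
        require(
            self.target.rate == self.noise.rate == self.mixture.rate,
            "triplet signals must share one rate",
        )


def active_level(
    w: Waveform, activity_threshold_db: float = DEFAULT_ACTIVITY_THRESHOLD_DB
) -> float:
    """Active speech level in dBFS.

    Frames of 50 ms with 50% overlap are classified active when their
    short-term energy is within ``activity_threshold_db`` of the
    maximum-energy frame; the returned level is 20*log10(RMS) over the
    active frames' samples.  Raises :class:`NoActiveSignalError` for an
    all-zero signal.
    """
    require(len(w) > 0, "waveform is empty")
    frame = max(int(round(0.05 * w.rate)), 1)
    hop = max(frame // 2, 1)
    x = w.samples
    n_frames = max(1 + (len(x) - frame) // hop, 1)
    energies = np.empty(n_frames)
    for t in range(n_frames):
        seg = x[t * hop : t * hop + frame]
        energies[t] = np.sum(seg * seg)
    if np.max(energies) <= 0.0:
        raise NoActiveSignalError("signal has no active frames (all zero)")
    with np.errstate(divide="ignore"):
        e_db = 10.0 * np.log10(energies / np.max(energies))
    active = e_db >= -activity_threshold_db
    # RMS over samples of active frames (frames are half-overlapping; samples
    # are accumulated with their multiplicity, which cancels in the mean)
    num = float(np.sum(energies[active]))
    count = int(np.sum(active)) * frame
    rms = np.sqrt(num / count)
    return float(20.0 * np.log10(rms))


def mix_at_snr(
    target: Waveform,
    noise: Waveform,
    snr_db: float,
    anchor_dbfs: float = DEFAULT_ANCHOR_DBFS,
    seed: int = 0,
    activity_threshold_db: float = DEFAULT_ACTIVITY_THRESHOLD_DB,
) -> MixtureTriplet:
    """Scale, crop, and sum ``target`` and ``noise`` at an exact SNR.

    The noise must be at least as long as the target; it is cropped with a
    seeded random offset.  SNR is the target's active level minus the cropped
    noise's overall RMS level.  Values may exceed +/-1; no clipping guard.
    """
    require(target.rate == noise.rate, "target and noise rates differ")
    if len(noise) < len(target):
        raise InvalidArgumentError("noise shorter than target")
    require(np.isfinite(snr_db), "snr_db must be finite")

    rng = np.random.default_rng(seed)
    offset = int(rng.integers(0, len(noise) - len(target) + 1))
    cropped = Waveform(noise.samples[offset : offset + len(target)], noise.rate)
    if cropped.rms() <= 0.0:
        raise CannotMixError("cropped noise has zero energy")

    level = active_level(target, activity_threshold_db)
    g_target = 10.0 ** ((anchor_dbfs - level) / 20.0)
    scaled_target = target.scaled(g_target)

    noise_level = 20.0 * np.log10(cropped.rms())
    g_noise = 10.0 ** ((anchor_dbfs - snr_db - noise_level) / 20.0)
    scaled_noise = cropped.scaled(g_noise)

    mixture = Waveform(scaled_target.samples + scaled_noise.samples, target.rate)
    achieved = (
        active_level(scaled_target, activity_threshold_db)
        - 20.0 * np.log10(scaled_noise.rms())
    )
    return MixtureTriplet(
        target=scaled_target,
        noise=scaled_noise,
        mixture=mixture,
        achieved_snr_db=float(achieved),
        target_level_dbfs=float(anchor_dbfs),
    )


def plan_training_manifest(
    n_per_noise_type: int,
    snr_lo: float = 1.0,
    snr_hi: float = 10.0,
    step: float = 1.0,
    seed: int = 0,
    split: str = "train",
    noise_kinds: Sequence[str] = ("sparse", "babble1", "babble2", "babble4"),
) -> list[MixtureSpec]:
    """Plan a training manifest with equal SNR representation.

    For each noise kind, ``n_per_noise_type`` specs are produced; each SNR in
    the ``snr_lo..snr_hi`` grid appears floor(n/k) or ceil(n/k) times, with
    any remainder distributed deterministically from the seed.
    """
    require(step > 0, "step must be positive")
    require(n_per_noise_type >= 1, "n_per_noise_type must be at least 1")
    n_steps = int(round((snr_hi - snr_lo) / step)) + 1
    snrs = [snr_lo + i * step for i in range(n_steps)]
    rng = np.random.default_rng(seed)
    specs: list[MixtureSpec] = []
    for kind in noise_kinds:
        base, rem = divmod(n_per_noise_type, n_steps)
        counts = np.full(n_steps, base, dtype=int)
        extra = rng.permutation(n_steps)[:rem]
        counts[extra] += 1
        i = 0
        for snr, count in zip(snrs, counts):
            for _ in range(count):
                specs.append(
                    MixtureSpec(
                        id=f"{split}-{kind}-{i:06d}",
                        target_ref=f"target-{kind}-{i:06d}",
                        noise_kind=kind,
                        snr_db=float(snr),
                        split=split,
                        seed=int(rng.integers(0, 2**31 - 1)),
                    )
                )
                i += 1
    return specs


# The behavioral grid: three processing conditions crossed with two maskers
# and two SNRs, plus a quiet reference condition.
BEHAVIORAL_PROCESSINGS = ("unprocessed", "rnn", "sepformer")
BEHAVIORAL_MASKERS = ("ccitt", "ttb")
BEHAVIORAL_SNRS_DB = (5.0, 10.0)


@dataclass(frozen=True)
class ConditionSpec:
    """One behavioral test condition with its allocated sentence ids."""

    condition_id: str
    processing: str
    masker: str | None
    snr_db: float | None
    sentence_ids: tuple


def plan_behavioral_manifest(
    sentences_per_condition: int, sentence_pool: int | None = None
) -> list[ConditionSpec]:
    """Enumerate the 13-condition behavioral grid with disjoint sentence ids.

    Grid: {unprocessed, rnn, sepformer} x {ccitt, ttb} x {+5, +10 dB} plus a
    quiet condition; ``sentences_per_condition`` sentence slots per condition,
    allocated disjointly from a pool (default: exactly as many as needed).
    """
    require(sentences_per_condition >= 1, "sentences_per_condition must be >= 1")
    conditions: list[tuple[str, str | None, float | None]] = [
        (p, m, s)
        for p in BEHAVIORAL_PROCESSINGS
        for m in BEHAVIORAL_MASKERS
        for s in BEHAVIORAL_SNRS_DB
    ]
    conditions.append(("quiet", None, None))
    needed = len(conditions) * sentences_per_condition
    pool = needed if sentence_pool is None else sentence_pool
    if pool < needed:
        raise InvalidArgumentError(
            f"sentence pool exhausted: need {needed}, have {pool}"
        )
    specs = []
    next_id = 0
    for proc, masker, snr in conditions:
        ids = tuple(range(next_id, next_id + sentences_per_condition))
        next_id += sentences_per_condition
        label = proc if masker is None else f"{proc}-{masker}-{int(snr)}dB"
        specs.append(ConditionSpec(label, proc, masker, snr, ids))
    return specs


def _noise_for_kind(kind: str, duration: float, rate: int, seed: int) -> Waveform:
    if kind == "stationary":
        return synthgen.make_speech_shaped_noise(duration, rate, seed=seed)
    if kind == "sparse":
        return synthgen.make_sparse_noise(duration, rate, seed=seed)
    if kind.startswith("babble"):
        n = int(kind.removeprefix("babble"))
        return synthgen.make_babble(n, duration, rate, seed=seed)
    raise InvalidArgumentError(f"unknown noise kind {kind!r}")


def realize_mixture(
    spec: MixtureSpec,
    duration: float = 1.0,
    rate: int = 16000,
    anchor_dbfs: float = DEFAULT_ANCHOR_DBFS,
) -> MixtureTriplet:
    """Generate target and noise from the spec's seed and mix them.

    The target is a synthetic talker drawn from the spec seed; the noise is
    generated per ``spec.noise_kind`` (slightly longer than the target so the
    crop offset is non-trivial).
    """
    rng = np.random.default_rng(spec.seed)
    talker_seed = int(rng.integers(0, 2**31 - 1))
    noise_seed = int(rng.integers(0, 2**31 - 1))
    crop_seed = int(rng.integers(0, 2**31 - 1))
    profile = synthgen.random_profile(np.random.default_rng(talker_seed), seed=talker_seed)
    target = synthgen.make_speechlike(profile, duration, rate)
    noise = _noise_for_kind(spec.noise_kind, duration * 1.25, rate, noise_seed)
    return mix_at_snr(target, noise, spec.snr_db, anchor_dbfs, seed=crop_seed)


def make_mixture_batch(
    n: int,
    snr_db: float,
    noise_kind: str = "stationary",
    duration: float = 1.0,
    rate: int = 16000,
    seed: int = 0,
    split: str = "train",
) -> list[MixtureTriplet]:
    """Convenience batch: ``n`` seeded mixtures at one SNR and noise kind."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        spec = MixtureSpec(
            id=f"{split}-{noise_kind}-{i:05d}",
            target_ref=f"target-{i:05d}",
            noise_kind=noise_kind,
            snr_db=snr_db,
            split=split,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        out.append(realize_mixture(spec, duration, rate))
    return out
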