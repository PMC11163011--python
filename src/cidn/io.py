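"""WAV and manifest I/O.

WAV files are RIFF mono, PCM16 or IEEE float32; mixtures default to float32
to preserve exact additivity (no clipping normalization is ever applied).
Manifests are JSONL (one object per line) or CSV with the MixtureSpec
columns {id, target_ref, noise_kind, snr_db, split, seed}.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .mixer import MixtureSpec
from .types import InvalidArgumentError, Waveform

__all__ = ["read_wav", "write_wav", "read_manifest", "write_manifest"]


def read_wav(path) -> Waveform:
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise InvalidArgumentError(f"{path}: expected mono audio")
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32768.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise InvalidArgumentError(f"{path}: unsupported sample format {data.dtype}")
    return Waveform(samples, int(rate))


def write_wav(path, w: Waveform, fmt: str = "float32") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "float32":
        wavfile.write(path, w.rate, w.samples.astype(np.float32))
    elif fmt == "pcm16":
        clipped = np.clip(w.samples, -1.0, 1.0 - 1.0 / 32768.0)
        wavfile.write(path, w.rate, (clipped * 32768.0).astype(np.int16))
    else:
        raise InvalidArgumentError(f"unsupported format {fmt!r}")


_SPEC_FIELDS = [f.name for f in dataclasses.fields(MixtureSpec)]


def write_manifest(path, specs: Iterable[MixtureSpec]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".csv":
        pd.DataFrame([dataclasses.asdict(s) for s in specs]).to_csv(path, index=False)
        return
    with open(path, "w") as fh:
        for s in specs:
            fh.write(json.dumps(dataclasses.asdict(s)) + "\n")


def read_manifest(path) -> list[MixtureSpec]:
    path = Path(path)
    if path.suffix == ".csv":
        rows = pd.read_csv(path).to_dict("records")
    else:
        with open(path) as fh:
            rows = [json.loads(line) for line in fh if line.strip()]
    return [
        MixtureSpec(**{k: row[k] for k in _SPEC_FIELDS if k in row}) for row in rows
    ]
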