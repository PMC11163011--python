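"""Shared fixtures.

Expensive artifacts (trained tiny models, mixture batches) are session-scoped
so the learning smoke tests and the acceptance suite share one training run.
"""

from __future__ import annotations

import numpy as np
import pytest

from cidn import mixer, rnn_enhancer, sepformer_lite, synthgen


@pytest.fixture(scope="session")
def talker():
    return synthgen.TalkerProfile(
        f0=120.0, formant_centers=(500.0, 1500.0, 2500.0),
        formant_bandwidths=(90.0, 120.0, 160.0), syllable_rate=4.0, seed=3,
    )


@pytest.fixture(scope="session")
def speech(talker):
    return synthgen.make_speechlike(talker, 2.0, 16000)


@pytest.fixture(scope="session")
def ssn():
    return synthgen.make_speech_shaped_noise(3.0, 16000, seed=9)


@pytest.fixture(scope="session")
def mixture_5db(speech, ssn):
    return mixer.mix_at_snr(speech, ssn, 5.0, seed=4)


# ---- learning smoke artifacts (shared with acceptance tests) --------------

SMOKE_TRAIN_SEED = 11
SMOKE_VAL_SEED = 12
SMOKE_TEST_SEED = 13


@pytest.fixture(scope="session")
def smoke_train_sets():
    """64 training + 8 validation mixtures at +5 dB in stationary noise."""
    train = mixer.make_mixture_batch(64, 5.0, "stationary", 1.0,
                                     seed=SMOKE_TRAIN_SEED, split="train")
    val = mixer.make_mixture_batch(8, 5.0, "stationary", 1.0,
                                   seed=SMOKE_VAL_SEED, split="val")
    return train, val


@pytest.fixture(scope="session")
def smoke_test_set():
    """12 held-out +5 dB stationary-noise mixtures."""
    return mixer.make_mixture_batch(12, 5.0, "stationary", 1.0,
                                    seed=SMOKE_TEST_SEED, split="test")


@pytest.fixture(scope="session")
def tiny_rnn(smoke_train_sets):
    """One bidirectional 32-unit layer trained 5 epochs on 64 mixtures."""
    train, val = smoke_train_sets
    cfg = rnn_enhancer.EnhancerConfig(
        recurrent_layers=1, recurrent_units=32, projection_units=32,
        epochs=5, learning_rate=3e-3, batch_size=8, seed=0,
    )
    return rnn_enhancer.train_enhancer(rnn_enhancer.init_enhancer(cfg), train, val)


@pytest.fixture(scope="session")
def smoke_train_sets_short():
    """Shorter (0.5 s) clips for the separator smoke run."""
    train = mixer.make_mixture_batch(64, 5.0, "stationary", 0.5,
                                     seed=SMOKE_TRAIN_SEED, split="train")
    val = mixer.make_mixture_batch(8, 5.0, "stationary", 0.5,
                                   seed=SMOKE_VAL_SEED, split="val")
    return train, val


@pytest.fixture(scope="session")
def smoke_test_set_short():
    return mixer.make_mixture_batch(12, 5.0, "stationary", 0.5,
                                    seed=SMOKE_TEST_SEED, split="test")


@pytest.fixture(scope="session")
def tiny_separator(smoke_train_sets_short):
    """64-filter separator with 1 intra + 1 inter block, 5 epochs."""
    train, val = smoke_train_sets_short
    cfg = sepformer_lite.SeparatorConfig(
        n_filters=64, intra_blocks=1, inter_blocks=1,
        epochs=5, learning_rate=3e-3, batch_size=8, seed=0,
    )
    return sepformer_lite.train_separator(
        sepformer_lite.init_separator(cfg), train, val
    )
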