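"""Dual-path separator: chunk algebra, mask bounds, smoke training."""

import numpy as np
import pytest

from cidn import metrics, sepformer_lite as sl
from cidn.types import InvalidArgumentError, Waveform

TINY = sl.SeparatorConfig(n_filters=16, intra_blocks=1, inter_blocks=1,
                          n_heads=2, ff_dim=32, epochs=1, seed=0)


class TestEncodeDecode:
    @pytest.mark.parametrize("length,expected", [(16, 1), (32, 3)])
    def test_frame_count_formula(self, length, expected):
        model = sl.init_separator(TINY)
        latent = sl.encode(model, Waveform(np.ones(length), 16000))
        assert latent.shape == (expected, 16)

    def test_encode_deterministic(self):
        model = sl.init_separator(TINY)
        w = Waveform(np.random.default_rng(0).standard_normal(400), 16000)
        np.testing.assert_array_equal(sl.encode(model, w), sl.encode(model, w))

    def test_too_short_rejected(self):
        with pytest.raises(InvalidArgumentError):
            sl.encode(sl.init_separator(TINY), Waveform(np.ones(8), 16000))

    def test_autoencoder_prefit_reaches_20db(self):
        # fit encoder/decoder only as an identity map on white noise
        from cidn.autodiff import Adam, Tensor

        cfg = sl.SeparatorConfig(n_filters=32, epochs=1, seed=1)
        net = sl.init_separator(cfg).net
        rng = np.random.default_rng(0)
        params = [net.enc_weight, net.enc_bias, net.dec_weight]
        opt = Adam(params, lr=1e-2)
        clips = [rng.standard_normal(800) for _ in range(12)]
        for _ in range(300):
            for x in clips:
                opt.zero_grad()
                latent = sl._encode_t(net, Tensor(x))
                rec = sl._decode_t(net, latent, len(x))
                ((rec - Tensor(x)) ** 2).mean().backward()
                opt.step()
        x = rng.standard_normal(800)
        rec = sl._decode_t(net, sl._encode_t(net, Tensor(x)), len(x)).data
        assert metrics.si_sdr_db(x, rec) > 20.0


class TestChunking:
    def test_inversion_contract_random_shapes(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            frames = int(rng.integers(5, 400))
            filters = int(rng.integers(1, 8))
            size = int(rng.integers(2, 60))
            x = rng.standard_normal((frames, filters))
            stack = sl.chunk(x, size, 0.5)
            back = sl.overlap_add_chunks(stack, 0.5, n_frames=frames)
            np.testing.assert_allclose(back, x, atol=1e-9)

    def test_exact_chunk_counts(self):
        assert sl.chunk(np.zeros((250, 4)), 250, 0.5).shape[0] == 1
        # 375 frames, hop 125 -> starts at 0 and 125, tail padded
        assert sl.chunk(np.zeros((375, 4)), 250, 0.5).shape[0] == 2


class TestMaskingNetwork:
    def test_shapes_and_bounds(self):
        model = sl.init_separator(TINY)
        rng = np.random.default_rng(2)
        latent = rng.uniform(0, 2, (137, 16))
        pair = sl.masking_network(model, latent)
        assert pair.m1.shape == latent.shape and pair.m2.shape == latent.shape
        for m in (pair.m1, pair.m2):
            assert m.min() >= 0.0 and m.max() <= 1.0

    def test_intra_only_network_is_chunk_local(self):
        cfg = sl.SeparatorConfig(n_filters=16, intra_blocks=1, inter_blocks=0,
                                 n_heads=2, ff_dim=32, chunk_size=10, seed=3)
        model = sl.init_separator(cfg)
        rng = np.random.default_rng(4)
        latent = rng.uniform(0, 1, (100, 16))
        # swap two hop-aligned 2-chunk regions far apart
        swapped = latent.copy()
        a, b, width = 10, 60, 20
        swapped[a:a + width], swapped[b:b + width] = (
            latent[b:b + width].copy(), latent[a:a + width].copy())
        m_orig = sl.masking_network(model, latent).m1
        m_swap = sl.masking_network(model, swapped).m1
        # interior frames of each swapped region are covered only by chunks
        # whose content moved wholesale
        inner = slice(5, 15)
        np.testing.assert_allclose(
            m_swap[a + 5:a + 15], m_orig[b + 5:b + 15], atol=1e-9)
        np.testing.assert_allclose(
            m_swap[b + 5:b + 15], m_orig[a + 5:a + 15], atol=1e-9)

    def test_width_mismatch_rejected(self):
        with pytest.raises(InvalidArgumentError):
            sl.masking_network(sl.init_separator(TINY), np.zeros((10, 7)))


class TestSeparate:
    def test_output_lengths(self):
        model = sl.init_separator(TINY)
        w = Waveform(np.random.default_rng(5).standard_normal(1234), 16000)
        fg, bg = sl.separate(model, w)
        assert len(fg) == len(bg) == 1234

    def test_frozen_zero_mask_gives_silence(self, monkeypatch):
        from cidn.autodiff import Tensor

        model = sl.init_separator(TINY)

        def frozen(net, latent):
            ones = Tensor(np.ones(latent.shape))
            zeros = Tensor(np.zeros(latent.shape))
            return ones, zeros

        monkeypatch.setattr(sl, "_masking_network_t", frozen)
        w = Waveform(np.random.default_rng(6).standard_normal(800), 16000)
        fg, bg = sl.separate(model, w)
        assert np.max(np.abs(bg.samples)) == 0.0  # bias-free decoder

    def test_rate_mismatch_rejected(self):
        model = sl.init_separator(TINY)
        with pytest.raises(InvalidArgumentError):
            sl.separate(model, Waveform(np.ones(100), 8000))


class TestTraining:
    def test_validation_loss_decreases(self, tiny_separator):
        hist = tiny_separator.history
        assert len(hist) == 5
        assert hist[-1]["val_loss"] < hist[0]["val_loss"]

    def test_zero_learning_rate_constant_losses(self, smoke_train_sets_short):
        train, val = smoke_train_sets_short
        cfg = sl.SeparatorConfig(n_filters=16, n_heads=2, ff_dim=32,
                                 epochs=2, learning_rate=0.0, seed=2)
        model = sl.train_separator(sl.init_separator(cfg), train[:6], val[:3])
        vals = [h["val_loss"] for h in model.history]
        assert max(vals) - min(vals) < 1e-12

    def test_seed_reproducible_history(self, smoke_train_sets_short):
        train, val = smoke_train_sets_short
        cfg = sl.SeparatorConfig(n_filters=16, n_heads=2, ff_dim=32,
                                 epochs=1, learning_rate=1e-3, seed=4)
        h1 = sl.train_separator(sl.init_separator(cfg), train[:6], val[:3]).history
        h2 = sl.train_separator(sl.init_separator(cfg), train[:6], val[:3]).history
        assert h1 == h2


class TestSmokeBenchmark:
    def test_foreground_improves_si_sdr(self, tiny_separator, smoke_test_set_short):
        imps = []
        for tr in smoke_test_set_short:
            fg, _ = sl.separate(tiny_separator, tr.mixture)
            imps.append(metrics.si_sdr_db(tr.target, fg)
                        - metrics.si_sdr_db(tr.target, tr.mixture))
        assert np.mean(imps) > 0.0
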