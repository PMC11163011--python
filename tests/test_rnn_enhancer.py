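"""Recurrent mask estimator: contracts, loss arithmetic, smoke training."""

import numpy as np
import pytest

from cidn import metrics, rnn_enhancer as rn, spectral as sp
from cidn.spectral import Mask
from cidn.types import InvalidArgumentError

TINY = rn.EnhancerConfig(recurrent_layers=1, recurrent_units=8,
                         projection_units=8, epochs=2, seed=0)


class TestInitAndPredict:
    def test_seeded_init_is_deterministic(self):
        feats = np.random.default_rng(0).uniform(0, 3, (10, 257))
        m1 = rn.predict_mask(rn.init_enhancer(TINY), feats)
        m2 = rn.predict_mask(rn.init_enhancer(TINY), feats)
        np.testing.assert_array_equal(m1.gains, m2.gains)

    @pytest.mark.parametrize("n_frames", [1, 1000])
    def test_variable_length_and_width(self, n_frames):
        feats = np.random.default_rng(1).uniform(0, 3, (n_frames, 257))
        mask = rn.predict_mask(rn.init_enhancer(TINY), feats)
        assert mask.gains.shape == (n_frames, 257)

    def test_untrained_output_bounded(self):
        feats = np.random.default_rng(2).uniform(-5, 5, (20, 257))
        mask = rn.predict_mask(rn.init_enhancer(TINY), feats)
        assert mask.gains.min() >= 0.0 and mask.gains.max() <= 1.0

    def test_width_mismatch_rejected(self):
        with pytest.raises(InvalidArgumentError):
            rn.predict_mask(rn.init_enhancer(TINY), np.zeros((5, 100)))


class TestSpectralMseLoss:
    def _frames(self, values):
        values = np.asarray(values, dtype=complex)
        nfft = 2 * (values.shape[1] - 1)
        return sp.SpectralFrames(values, nfft, nfft // 2, nfft, 16000, 100)

    def test_perfect_mask_zero_loss(self):
        fr = self._frames([[1.0, 2.0], [3.0, 4.0]])
        ones = np.ones((2, 2))
        assert rn.spectral_mse_loss(ones, fr, fr) == 0.0

    def test_zero_mask_closed_form(self):
        fr = self._frames([[1.0, 2.0], [3.0, 4.0]])
        zeros = np.zeros((2, 2))
        assert rn.spectral_mse_loss(zeros, fr, fr) == pytest.approx(
            np.mean([1.0, 4.0, 9.0, 16.0]))

    def test_hand_computed_2x2(self):
        mix = self._frames([[2.0, 4.0], [6.0, 8.0]])
        clean = self._frames([[1.0, 1.0], [3.0, 2.0]])
        mask = np.array([[0.5, 0.5], [0.5, 0.5]])
        # masked magnitudes: [[1,2],[3,4]]; diffs: [0,1,0,2] -> mean sq = 5/4
        assert rn.spectral_mse_loss(mask, mix, clean) == pytest.approx(1.25)


class TestTraining:
    def test_validation_loss_decreases(self, tiny_rnn):
        hist = tiny_rnn.history
        assert len(hist) == 5
        assert hist[-1]["val_loss"] < hist[0]["val_loss"]

    def test_zero_learning_rate_is_null_step(self, smoke_train_sets):
        train, val = smoke_train_sets
        cfg = rn.EnhancerConfig(recurrent_layers=1, recurrent_units=8,
                                projection_units=8, epochs=3,
                                learning_rate=0.0, seed=1)
        model = rn.init_enhancer(cfg)
        before = {k: v.copy() for k, v in model.net.state_dict().items()}
        model = rn.train_enhancer(model, train[:8], val[:4])
        after = model.net.state_dict()
        for k in before:
            np.testing.assert_array_equal(before[k], after[k])
        vals = [h["val_loss"] for h in model.history]
        assert max(vals) - min(vals) < 1e-12

    def test_training_is_seed_reproducible(self, smoke_train_sets):
        train, val = smoke_train_sets
        cfg = rn.EnhancerConfig(recurrent_layers=1, recurrent_units=8,
                                projection_units=8, epochs=2,
                                learning_rate=1e-3, seed=3)
        h1 = rn.train_enhancer(rn.init_enhancer(cfg), train[:8], val[:4]).history
        h2 = rn.train_enhancer(rn.init_enhancer(cfg), train[:8], val[:4]).history
        for a, b in zip(h1, h2):
            assert abs(a["val_loss"] - b["val_loss"]) < 1e-6

    def test_empty_manifest_rejected(self):
        with pytest.raises(InvalidArgumentError):
            rn.train_enhancer(rn.init_enhancer(TINY), [], [])


class TestEnhance:
    def test_output_length_preserved(self, tiny_rnn, mixture_5db):
        out = rn.enhance(tiny_rnn, mixture_5db.mixture)
        assert len(out) == len(mixture_5db.mixture)
        assert out.rate == mixture_5db.mixture.rate

    def test_unit_mask_returns_input(self, mixture_5db):
        model = rn.init_enhancer(TINY)

        class UnitNet:
            def __call__(self, t):
                from cidn.autodiff import Tensor
                return Tensor(np.ones(t.shape))

        model.net = UnitNet()
        out = rn.enhance(model, mixture_5db.mixture)
        x = mixture_5db.mixture.samples
        assert np.sqrt(np.mean((out.samples - x) ** 2)) < 1e-6 * np.sqrt(
            np.mean(x ** 2))

    def test_rate_mismatch_rejected(self, tiny_rnn, mixture_5db):
        from cidn.types import Waveform

        wrong = Waveform(mixture_5db.mixture.samples, 8000)
        with pytest.raises(InvalidArgumentError):
            rn.enhance(tiny_rnn, wrong)


def _improvements(model, test_set):
    out = []
    for tr in test_set:
        enhanced = rn.enhance(model, tr.mixture)
        out.append(metrics.si_sdr_db(tr.target, enhanced)
                   - metrics.si_sdr_db(tr.target, tr.mixture))
    return np.array(out)


def _irm_improvements(test_set):
    out = []
    for tr in test_set:
        tf, nf, mf = sp.stft(tr.target), sp.stft(tr.noise), sp.stft(tr.mixture)
        oracle = sp.istft(sp.apply_mask(mf, sp.ideal_ratio_mask(tf, nf)))
        out.append(metrics.si_sdr_db(tr.target, oracle)
                   - metrics.si_sdr_db(tr.target, tr.mixture))
    return np.array(out)


class TestSmokeBenchmark:
    def test_held_out_si_sdr_improvement_exceeds_3db(self, tiny_rnn, smoke_test_set):
        assert _improvements(tiny_rnn, smoke_test_set).mean() > 3.0

    def test_bounded_above_by_irm_oracle(self, tiny_rnn, smoke_test_set):
        assert _improvements(tiny_rnn, smoke_test_set).mean() <= _irm_improvements(
            smoke_test_set).mean()
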