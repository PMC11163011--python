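"""Evaluation grid rows, Wilcoxon vs enumeration, BH vs brute force."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cidn import evalgrid as eg, mixer, synthgen
from cidn.types import InvalidArgumentError


# ---- independent oracles --------------------------------------------------

def wilcoxon_enumeration_p(d):
    """Exact two-sided signed-rank p by full enumeration of sign vectors."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.array(ws)
    p_lo = np.mean(ws <= w_obs)
    p_hi = np.mean(ws >= w_obs)
    return min(1.0, 2.0 * min(p_lo, p_hi))


def bh_bruteforce(p):
    """Direct step-up definition of BH adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adjusted = np.empty(m)
    prev = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        val = min(prev, p[i] * m / (rank_idx + 1))
        adjusted[i] = val
        prev = val
    return adjusted


def _pair_table(values_a, values_b):
    rows = []
    for i, (a, b) in enumerate(zip(values_a, values_b)):
        rows.append({"item": i, "processing": "a", "value": a})
        rows.append({"item": i, "processing": "b", "value": b})
    return pd.DataFrame(rows)


class TestPairedWilcoxon:
    def test_six_all_positive_pairs_exact_p(self):
        table = _pair_table([1, 2, 3, 4, 5, 6], [0, 0, 0, 0, 0, 0])
        res = eg.paired_wilcoxon(table, "a", "b")
        assert res["p_value"] == pytest.approx(2 / 64)
        assert res["n"] == 6

    def test_antisymmetric_differences_give_p_one(self):
        table = _pair_table([1, -1, 2, -2, 3, -3], [0] * 6)
        res = eg.paired_wilcoxon(table, "a", "b")
        assert res["p_value"] == pytest.approx(1.0)

    def test_invariant_to_pair_relabeling(self):
        rng = np.random.default_rng(0)
        a, b = rng.standard_normal(12), rng.standard_normal(12)
        t1 = _pair_table(a, b)
        t2 = t1.copy()
        t2["item"] = t2["item"].map(lambda i: f"id-{i * 7}")
        r1, r2 = eg.paired_wilcoxon(t1, "a", "b"), eg.paired_wilcoxon(t2, "a", "b")
        assert r1 == r2

    def test_insufficient_pairs_rejected(self):
        table = _pair_table([1, 2, 3, 4], [0, 0, 0, 0])
        with pytest.raises(InvalidArgumentError):
            eg.paired_wilcoxon(table, "a", "b")

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.integers(min_value=-50, max_value=50), min_size=5,
                    max_size=10))
    def test_exact_matches_enumeration(self, deltas):
        # force no ties and no zeros by perturbing deterministically
        d = np.array(deltas, dtype=float) + np.linspace(0.01, 0.09, len(deltas))
        table = _pair_table(d, np.zeros(len(d)))
        res = eg.paired_wilcoxon(table, "a", "b")
        assert res["p_value"] == pytest.approx(wilcoxon_enumeration_p(d))


class TestFdrAdjust:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(eg.fdr_adjust([0.042]), [0.042])

    def test_hand_step_up_example(self):
        np.testing.assert_allclose(
            eg.fdr_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_adjusted_not_below_raw(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0, 1, 20)
        assert np.all(eg.fdr_adjust(p) >= p)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=20))
    def test_matches_bruteforce_step_up(self, p):
        np.testing.assert_allclose(eg.fdr_adjust(p), bh_bruteforce(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidArgumentError):
            eg.fdr_adjust([0.5, 1.5])


class TestPlannedComparisons:
    def test_default_grid_is_54(self):
        assert eg.count_planned_comparisons() == 54

    def test_degenerate_grid_is_one(self):
        grid = eg.ConditionGrid(maskers=("ccitt",), snrs_db=(5.0,),
                                processings=("unprocessed", "rnn"),
                                metrics=("stoi",))
        assert eg.count_planned_comparisons(grid) == 1

    def test_product_rule_in_snrs(self):
        base = eg.ConditionGrid()
        doubled = eg.ConditionGrid(snrs_db=(1.0, 5.0, 10.0, 15.0, 20.0, 25.0))
        assert eg.count_planned_comparisons(doubled) == 2 * eg.count_planned_comparisons(base)


class TestEvaluateGrid:
    @pytest.fixture(scope="class")
    def items(self):
        out = []
        for i, tr in enumerate(mixer.make_mixture_batch(
                10, 5.0, "stationary", 0.8, seed=21)):
            out.append(eg.EvalItem(id=f"i{i}", masker="ccitt", snr_db=5.0,
                                   clean=tr.target, noisy=tr.mixture))
        return out

    def test_row_count(self, items):
        table = eg.evaluate_grid({"rnn": lambda w: w, "sepformer": lambda w: w},
                                 items)
        assert len(table) == 10 * 3 * 3

    def test_unprocessed_si_sdr_near_snr(self):
        # near-orthogonal stationary target and noise (no silent gaps, so the
        # active level equals the overall level): mixture SI-SDR ~ SNR
        items = []
        for i in range(6):
            target = synthgen.make_speech_shaped_noise(1.0, seed=100 + i)
            noise = synthgen.make_speech_shaped_noise(2.0, seed=200 + i)
            tr = mixer.mix_at_snr(target, noise, 5.0, seed=i)
            items.append(eg.EvalItem(id=f"o{i}", masker="ccitt", snr_db=5.0,
                                     clean=tr.target, noisy=tr.mixture))
        grid = eg.ConditionGrid(processings=("unprocessed",),
                                metrics=("si_sdr",), snrs_db=(5.0,))
        table = eg.evaluate_grid({}, items, grid)
        assert table["value"].mean() == pytest.approx(5.0, abs=0.5)

    def test_identity_output_scores_stoi_one(self, items):
        perfect = [eg.EvalItem(id=i.id, masker=i.masker, snr_db=i.snr_db,
                               clean=i.clean, noisy=i.clean) for i in items]
        grid = eg.ConditionGrid(processings=("unprocessed",), metrics=("stoi",))
        table = eg.evaluate_grid({}, perfect, grid)
        assert np.allclose(table["value"], 1.0, atol=1e-6)
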