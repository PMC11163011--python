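"""Behavioral simulation and mixed-model machinery."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from cidn import behavioral as bh
from cidn.types import InvalidArgumentError


def noise_cells(scores):
    return scores[scores.percent_correct.notna() & (scores.processing != "quiet")]


class TestSimulate:
    def test_zero_variance_reproduces_cell_means(self):
        sc = bh.simulate_behavioral(5, sd_participant=0.0, sd_residual=0.0,
                                    sd_participant_quality=0.0,
                                    sd_residual_quality=0.0, seed=0)
        sub = noise_cells(sc)
        for (m, s, p), mu in bh.DEFAULT_CELL_MEANS.items():
            vals = sub[(sub.masker == m) & (sub.snr_db == s)
                       & (sub.processing == p)].percent_correct
            assert np.all(vals == mu)

    def test_record_count_13_participants_13_cells(self):
        sc = bh.simulate_behavioral(13, seed=1)
        assert len(sc[sc.percent_correct.notna()]) == 13 * 13

    def test_between_participant_variance_recovery(self):
        sc = bh.simulate_behavioral(200, sd_participant=12.0, sd_residual=8.0,
                                    seed=2)
        means = noise_cells(sc).groupby("participant").percent_correct.mean()
        assert abs(means.var(ddof=1) / 12.0**2 - 1.0) < 0.15

    def test_missing_cells_rejected(self):
        with pytest.raises(InvalidArgumentError):
            bh.simulate_behavioral(3, cell_means={("ccitt", 5.0, "rnn"): 50.0})


class TestIntelligibilityModel:
    def test_zero_participant_variance_matches_ols(self):
        sc = bh.simulate_behavioral(13, sd_participant=0.0, sd_residual=8.0,
                                    seed=1)
        fit = bh.fit_intelligibility_model(sc)
        ols = smf.ols(bh.INTELLIGIBILITY_FORMULA, data=noise_cells(sc)).fit()
        np.testing.assert_allclose(fit.result.fe_params.values,
                                   ols.params.values, atol=1e-4)

    def test_constant_shift_moves_only_intercept(self):
        sc = bh.simulate_behavioral(13, seed=3)
        fit = bh.fit_intelligibility_model(sc)
        shifted = sc.copy()
        shifted["percent_correct"] = shifted["percent_correct"] + 7.0
        fit2 = bh.fit_intelligibility_model(shifted)
        delta = fit2.result.fe_params - fit.result.fe_params
        assert delta["Intercept"] == pytest.approx(7.0, abs=1e-6)
        others = delta.drop("Intercept").abs().max()
        assert others < 1e-6

    def test_type_iii_table_terms(self):
        fit = bh.fit_intelligibility_model(bh.simulate_behavioral(13, seed=4))
        table = fit.type_iii_table()
        assert list(table["df_num"]) == [2, 1, 1, 2]
        assert (table["F"] >= 0).all()
        # 13 participants x 12 noise cells, containment denominator df
        assert (table["df_den"] == 156 - 13).all()


class TestEmm:
    def test_balanced_saturated_emm_equals_cell_mean(self):
        sc = bh.simulate_behavioral(13, seed=5)
        fit = bh.fit_intelligibility_model(
            sc, formula=bh.SATURATED_INTELLIGIBILITY_FORMULA)
        table = bh.emm(fit)
        cell = noise_cells(sc).groupby(
            ["masker", "snr_db", "processing"]).percent_correct.mean()
        for _, r in table.iterrows():
            assert r.emm == pytest.approx(
                cell.loc[(r.masker, r.snr_db, r.processing)], abs=1e-6)
            assert r.ci_lo <= r.emm <= r.ci_hi
            assert r.se > 0

    def test_balanced_design_ses_all_equal(self):
        sc = bh.simulate_behavioral(13, seed=6)
        fit = bh.fit_intelligibility_model(sc)
        ses = bh.emm(fit)["se"].to_numpy()
        np.testing.assert_allclose(ses, ses[0], rtol=1e-6)

    def test_absent_level_rejected(self):
        sc = bh.simulate_behavioral(13, seed=7)
        fit = bh.fit_intelligibility_model(sc)
        grid = pd.DataFrame([{"masker": "pink", "snr_db": 5.0,
                              "processing": "rnn"}])
        with pytest.raises(InvalidArgumentError):
            bh.emm(fit, grid)


class TestContrasts:
    def test_diff_equals_emm_difference(self):
        sc = bh.simulate_behavioral(13, seed=8)
        fit = bh.fit_intelligibility_model(sc)
        emms = bh.emm(fit).set_index(["masker", "snr_db", "processing"])
        for _, r in bh.pairwise_contrasts(fit).iterrows():
            expected = (emms.loc[(r.masker, r.snr_db, r.level_a)].emm
                        - emms.loc[(r.masker, r.snr_db, r.level_b)].emm)
            assert r["diff"] == pytest.approx(expected, abs=1e-9)

    def test_null_calibration_tukey_rate(self):
        flat = {k: 55.0 for k in bh.DEFAULT_CELL_MEANS}
        hits, total = 0, 0
        for rep in range(20):
            sc = bh.simulate_behavioral(13, cell_means=flat, seed=500 + rep)
            fit = bh.fit_intelligibility_model(sc)
            ct = bh.pairwise_contrasts(fit)
            hits += int((ct["p_value"] < 0.05).sum())
            total += len(ct)
        assert hits / total <= 0.10

    def test_power_for_20_point_effect(self):
        means = dict(bh.DEFAULT_CELL_MEANS)
        for m in bh.MASKERS:
            for s in bh.SNRS_DB:
                means[(m, s, "rnn")] = means[(m, s, "unprocessed")] + 20.0
        wins = 0
        n_reps = 200
        for rep in range(n_reps):
            sc = bh.simulate_behavioral(13, cell_means=means, sd_residual=8.0,
                                        seed=900 + rep)
            fit = bh.fit_intelligibility_model(sc)
            ct = bh.pairwise_contrasts(fit)
            sub = ct[((ct.level_a == "rnn") & (ct.level_b == "unprocessed"))
                     | ((ct.level_a == "unprocessed") & (ct.level_b == "rnn"))]
            wins += int((sub["p_value"] < 0.05).all())
        assert wins / n_reps >= 0.95


class TestQualityModel:
    def test_saturated_estimates_equal_cell_means(self):
        sc = bh.simulate_behavioral(13, sd_participant_quality=0.0,
                                    sd_residual_quality=0.2, seed=9)
        fit = bh.fit_quality_model(sc)
        cell = sc[sc.quality.notna()].groupby(
            ["masker", "processing"]).quality.mean()
        table = bh.emm(fit)
        for _, r in table.iterrows():
            assert r.emm == pytest.approx(cell.loc[(r.masker, r.processing)],
                                          abs=1e-6)

    def test_constant_shift_equivariance(self):
        sc = bh.simulate_behavioral(13, seed=10)
        fit = bh.fit_quality_model(sc)
        shifted = sc.copy()
        shifted["quality"] = shifted["quality"] + 0.5
        fit2 = bh.fit_quality_model(shifted)
        delta = fit2.result.fe_params - fit.result.fe_params
        assert delta["Intercept"] == pytest.approx(0.5, abs=1e-6)
        assert delta.drop("Intercept").abs().max() < 1e-6


class TestStepwiseAic:
    def test_trace_non_increasing(self):
        sc = bh.simulate_behavioral(13, seed=11)
        res = bh.stepwise_aic(bh.improvement_table(sc))
        aics = [a for _, a in res["trace"]]
        assert all(b <= a + 1e-9 for a, b in zip(aics, aics[1:]))

    def test_strong_age_effect_is_retained(self):
        kept = 0
        n_reps = 20
        for rep in range(n_reps):
            sc = bh.simulate_behavioral(13, seed=1500 + rep)
            deltas = bh.improvement_table(sc)
            age_z = (deltas["age_at_test"] - 58.6) / 14.7
            deltas["delta"] = deltas["delta"] + 15.0 * age_z
            res = bh.stepwise_aic(deltas)
            kept += int("age_at_test" in res["selected_terms"])
        assert kept / n_reps >= 0.95
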