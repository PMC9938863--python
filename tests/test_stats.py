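"""Scoring, RAU transform and the inferential battery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sst

from tcspeech import (
    Condition,
    PsychometricModel,
    TrialScore,
    normality_check,
    posthoc_pairwise,
    rau,
    repackaging_benefit,
    rm_anova,
    score_keywords,
    simulate_responses,
    welch_t,
)


class TestScoreKeywords:
    def test_perfect_recall(self):
        s = score_keywords(["vliegtuig", "stortte"], ["vliegtuig", "stortte"])
        assert (s.n_correct, s.n_keywords) == (2, 2)
        assert s.percent == 100.0

    def test_empty_response_scores_zero(self):
        assert score_keywords([], ["a", "b"]).n_correct == 0

    def test_partial_overlap(self):
        s = score_keywords(["a", "c", "d"], ["a", "b", "c"])
        assert s.n_correct == 2 and s.n_keywords == 3

    def test_case_and_punctuation_folding_and_single_credit(self):
        s = score_keywords(["Bank!", "bank"], ["bank"])
        assert s.n_correct == 1
        assert score_keywords(["BANK."], ["bank"]).n_correct == 1

    def test_empty_keywords_rejected(self):
        with pytest.raises(ValueError):
            score_keywords(["a"], [])


class TestRau:
    def test_published_closed_form_endpoints(self):
        # Frozen from direct evaluation of the transform.
        assert rau(0, 33) == pytest.approx(-15.0, abs=0.1)
        assert rau(33, 33) == pytest.approx(115.0, abs=0.1)

    def test_midpoint_maps_near_fifty(self):
        assert rau(16, 32) == pytest.approx(50.0, abs=0.5)

    def test_strictly_increasing_and_range(self):
        vals = [rau(x, 33) for x in range(34)]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert vals[0] > -23.5 and vals[-1] < 123.5
        # the asymptotic range limits are approached for large N
        assert rau(0, 10**6) == pytest.approx(-23.0, abs=0.1)
        assert rau(10**6, 10**6) == pytest.approx(123.0, abs=0.1)

    def test_accepts_trial_score(self):
        assert rau(TrialScore(33, 10)) == pytest.approx(rau(10, 33))

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            rau(5, 4)


class TestWelchT:
    def test_equal_variance_equal_n_gives_pooled_df(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=10)
        b = a + 1.0  # identical variance, shifted mean
        _, df, _ = welch_t(a, b)
        assert df == pytest.approx(18.0)

    def test_same_data_gives_zero_t(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=15)
        t, _, p = welch_t(a, np.random.default_rng(2).permutation(a))
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_brute_force_welch_formulas(self):
        """Oracle: direct evaluation of the Welch statistic and the
        Satterthwaite df formula."""
        rng = np.random.default_rng(3)
        for _ in range(10):
            na, nb = rng.integers(5, 40, size=2)
            a = rng.normal(0, 1, na)
            b = rng.normal(0.4, 2.0, nb)
            t, df, p = welch_t(a, b)
            va, vb = a.var(ddof=1), b.var(ddof=1)
            se2 = va / na + vb / nb
            t_ref = (a.mean() - b.mean()) / np.sqrt(se2)
            df_ref = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
            p_ref = 2 * sst.t.sf(abs(t_ref), df_ref)
            assert t == pytest.approx(t_ref, abs=1e-8)
            assert df == pytest.approx(df_ref, abs=1e-8)
            assert p == pytest.approx(p_ref, abs=1e-8)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0, 1.0], [1.0, 1.0])


def _hand_table(rng=None, n_subjects=4, effect=0.0):
    """Small balanced 2x3 within-subjects table."""
    rng = rng or np.random.default_rng(42)
    rows = []
    for s in range(n_subjects):
        base = rng.normal(50, 8)
        for sil in (False, True):
            for spec in ("8ch", "16ch", "original"):
                rows.append(
                    {
                        "subject": s,
                        "silence_added": sil,
                        "spectral_content": spec,
                        "percent": base + effect * sil + rng.normal(0, 5),
                    }
                )
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_two_level_factor_has_unit_epsilon(self):
        table = _hand_table()
        res = rm_anova(table, dv="percent", within=["silence_added"]).iloc[0]
        assert res["epsilon"] == 1.0
        assert res["p"] == res["p_unc"]
        assert not res["gg_applied"]

    def test_matches_independent_implementations(self):
        """Oracle: pingouin (F, GG epsilon, generalized eta-squared, GG p)
        and statsmodels AnovaRM (F, dfs) on the same table."""
        import pingouin as pg
        from statsmodels.stats.anova import AnovaRM

        table = _hand_table()
        mine = rm_anova(table, dv="percent", within=["silence_added", "spectral_content"])
        ref = pg.rm_anova(
            data=table, dv="percent", within=["silence_added", "spectral_content"],
            subject="subject", effsize="ng2",
        )
        for i in range(3):
            assert mine["F"].iloc[i] == pytest.approx(ref["F"].iloc[i], abs=1e-6)
            assert mine["ges"].iloc[i] == pytest.approx(ref["ng2"].iloc[i], abs=1e-6)
            assert mine["epsilon"].iloc[i] == pytest.approx(ref["eps"].iloc[i], abs=1e-6)
            assert mine["p_gg"].iloc[i] == pytest.approx(ref["p_GG_corr"].iloc[i], abs=1e-6)
        sm = AnovaRM(
            table, "percent", "subject", within=["silence_added", "spectral_content"]
        ).fit()
        for eff_mine, eff_sm in [
            ("silence_added", "silence_added"),
            ("spectral_content", "spectral_content"),
            ("silence_added * spectral_content", "silence_added:spectral_content"),
        ]:
            row = mine[mine["effect"] == eff_mine].iloc[0]
            assert row["F"] == pytest.approx(sm.anova_table.loc[eff_sm, "F Value"], abs=1e-6)

    def test_three_way_matches_statsmodels(self):
        from statsmodels.stats.anova import AnovaRM

        design = [
            Condition(0.166, spec, sil, meas)
            for sil in (False, True)
            for spec in ("8ch", "16ch", "original")
            for meas in ("test", "retest")
        ]
        table = simulate_responses(PsychometricModel.published_pattern(), design, 8, 33, seed=9)
        within = ["silence_added", "spectral_content", "measurement"]
        mine = rm_anova(table, dv="percent", within=within)
        sm = AnovaRM(table, "percent", "subject", within=within).fit().anova_table
        for _, row in mine.iterrows():
            key = row["effect"].replace(" * ", ":")
            assert row["F"] == pytest.approx(sm.loc[key, "F Value"], abs=1e-6)
            assert row["df_num"] == sm.loc[key, "Num DF"]
            assert row["df_den"] == sm.loc[key, "Den DF"]

    def test_gg_corrected_p_never_below_uncorrected(self):
        table = simulate_responses(
            PsychometricModel.published_pattern(),
            [Condition(0.166, sp, si) for si in (False, True) for sp in ("8ch", "16ch", "original")],
            14, 33, seed=3,
        )
        res = rm_anova(table, dv="percent", within=["silence_added", "spectral_content"])
        big = res[res["F"] >= 1.0]  # the ordering is guaranteed only for F >= 1
        assert len(big) >= 2
        assert (big["p_gg"] >= big["p_unc"] - 1e-12).all()
        k = 3  # levels of the spectral factor
        spec_row = res[res["effect"] == "spectral_content"].iloc[0]
        assert 1.0 / (k - 1) <= spec_row["epsilon"] <= 1.0

    def test_f_invariant_to_adding_a_constant(self):
        table = _hand_table()
        shifted = table.assign(percent=table["percent"] + 17.3)
        a = rm_anova(table, dv="percent", within=["silence_added", "spectral_content"])
        b = rm_anova(shifted, dv="percent", within=["silence_added", "spectral_content"])
        np.testing.assert_allclose(a["F"], b["F"], atol=1e-9)

    def test_unbalanced_design_rejected(self):
        table = _hand_table().iloc[:-1]
        with pytest.raises(ValueError, match="unbalanced|every subject"):
            rm_anova(table, dv="percent", within=["silence_added", "spectral_content"])


class TestPosthocPairwise:
    def _table(self, seed=0, n=10):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n):
            for lvl, shift in [("8ch", 0.0), ("16ch", 5.0), ("original", 9.0)]:
                rows.append(
                    {"subject": s, "spectral_content": lvl, "rau": rng.normal(50 + shift, 6)}
                )
        return pd.DataFrame(rows)

    def test_identical_paired_values_give_t_zero_p_one(self):
        table = self._table()
        table["rau"] = 42.0
        res = posthoc_pairwise(table, "spectral_content")
        assert (res["t"] == 0.0).all()
        assert (res["p_adjusted"] == 1.0).all()

    def test_single_comparison_is_uncorrected(self):
        table = self._table()
        res = posthoc_pairwise(table[table["spectral_content"] != "16ch"], "spectral_content")
        assert len(res) == 1
        assert res["p_adjusted"].iloc[0] == pytest.approx(res["p_unc"].iloc[0])

    def test_bonferroni_multiplies_and_caps(self):
        res = posthoc_pairwise(self._table(), "spectral_content")
        assert len(res) == 3
        for _, row in res.iterrows():
            assert row["p_adjusted"] == pytest.approx(min(1.0, row["p_unc"] * 3))


class TestRepackagingBenefit:
    def _table(self, diff_by_spec):
        rows = []
        for s in range(4):
            for spec, diff in diff_by_spec.items():
                for sil in (False, True):
                    for meas in ("test", "retest"):
                        pct = 30.0 + (diff if sil else 0.0)
                        n_corr = int(round(pct / 100 * 32))
                        rows.append(
                            {
                                "subject": s,
                                "spectral_content": spec,
                                "silence_added": sil,
                                "measurement": meas,
                                "percent": pct,
                                "rau": rau(n_corr, 32),
                            }
                        )
        return pd.DataFrame(rows)

    def test_identical_scores_give_zero_benefit(self):
        res = repackaging_benefit(self._table({"8ch": 0.0}))
        assert np.allclose(res["benefit_percent"], 0.0)
        assert np.allclose(res["benefit_rau"], 0.0)

    def test_simple_difference(self):
        res = repackaging_benefit(self._table({"original": 10.0}))
        assert np.allclose(res["benefit_percent"], 10.0)

    def test_missing_counterpart_rejected(self):
        table = self._table({"8ch": 5.0})
        broken = table[table["silence_added"]]
        with pytest.raises(ValueError, match="cell"):
            repackaging_benefit(broken)


class TestNormalityCheck:
    def test_null_p_values_are_uniform(self):
        """Under normal data the Shapiro-Wilk p value is uniform on [0,1]
        (KS check over 200 replicates)."""
        rng = np.random.default_rng(0)
        pvals = [normality_check(rng.normal(size=50))[1] for _ in range(200)]
        assert sst.kstest(pvals, "uniform").pvalue > 0.01

    def test_detects_heavy_skew(self):
        rng = np.random.default_rng(1)
        hits = sum(normality_check(rng.exponential(size=100))[1] < 0.05 for _ in range(100))
        assert hits >= 90

    def test_minimal_n_and_degenerate_input(self):
        W, p = normality_check([1.0, 2.0, 3.0])
        assert np.isfinite(W)
        with pytest.raises(ValueError):
            normality_check([5.0, 5.0, 5.0])
        with pytest.raises(ValueError):
            normality_check([1.0, 2.0])
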