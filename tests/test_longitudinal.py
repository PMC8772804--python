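import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from gutpipe.longitudinal import (
    compare_fold_changes,
    lmm_feature,
    paired_clinical,
    significance_stars,
    stratify_by_median,
    transition_test,
)


class TestStratify:
    def test_textbook_median_split(self):
        rich = pd.Series(np.arange(1.0, 11.0), index=[f"s{i}" for i in range(10)])
        strata = stratify_by_median(rich)
        assert (strata.iloc[:5] == "low").all()
        assert (strata.iloc[5:] == "high").all()

    def test_all_equal_goes_low(self, caplog):
        rich = pd.Series([5.0, 5.0, 5.0])
        with caplog.at_level("WARNING", logger="gutpipe"):
            strata = stratify_by_median(rich)
        assert (strata == "low").all()

    def test_reference_set_threshold(self):
        rich = pd.Series([1.0, 2.0], index=["a", "b"])
        reference = pd.Series(np.arange(100.0))  # median 49.5
        strata = stratify_by_median(rich, reference)
        assert (strata == "low").all()
        with pytest.raises(ValueError, match="empty"):
            stratify_by_median(rich, pd.Series(dtype=float))

    def test_low_concentration_subjects_in_low_stratum(self, cohort_small, genus_table):
        """Generator subjects from the low-concentration Bact2 archetype land
        predominantly in the low stratum (>= 80% concordance)."""
        from gutpipe.ecology import alpha_diversity
        from gutpipe import taxprofile

        rar = taxprofile.rarefy(cohort_small.abundance_v1, 10_000, seed=1)
        div = alpha_diversity(rar)
        rich = div["richness"].copy()
        rich.index = [s.rsplit("_", 1)[0] for s in rich.index]
        strata = stratify_by_median(rich)
        truth = cohort_small.truth["component_v1"]
        bact2 = [s for s in strata.index if truth[s] == "Bact2"]
        concordance = (strata.loc[bact2] == "low").mean()
        assert concordance >= 0.8


class TestFoldChanges:
    def test_identity_case(self):
        v = pd.Series([10.0, 20.0, 30.0, 40.0], index=list("abcd"))
        strata = pd.Series(["low", "low", "high", "high"], index=list("abcd"))
        fc, tests = compare_fold_changes(v, v, strata)
        assert (fc == 1.0).all()
        assert tests["between_p"] == 1.0

    def test_planted_low_stratum_improvement_detected(self):
        """Planted +0.25 mean log-fold in the low stratum yields a
        between-stratum p < 0.05 in >= 90% of replicates at n = 80."""
        hits = 0
        for rep in range(100):
            r = np.random.default_rng(rep)
            idx = [f"s{i}" for i in range(80)]
            strata = pd.Series(["low"] * 40 + ["high"] * 40, index=idx)
            v1 = pd.Series(r.uniform(300, 600, 80), index=idx)
            logfc = np.where(strata == "low", 0.25, 0.0) + r.normal(0, 0.25, 80)
            v2 = v1 * np.exp(logfc)
            _, tests = compare_fold_changes(v1, v2, strata)
            hits += tests["between_p"] < 0.05
        assert hits >= 90

    def test_rank_statistic_matches_brute_force_u(self):
        """Between-stratum test statistic equals the exhaustively counted
        Mann-Whitney U on a 6+6 fixture."""
        r = np.random.default_rng(5)
        lo = r.normal(1.2, 0.1, 6)
        hi = r.normal(1.0, 0.1, 6)
        u_brute = sum((x > y) + 0.5 * (x == y) for x in lo for y in hi)
        u_scipy = st.mannwhitneyu(lo, hi, alternative="two-sided").statistic
        assert u_scipy == pytest.approx(u_brute)

    def test_zero_baseline_excluded(self, caplog):
        v1 = pd.Series([0.0, 10.0], index=["a", "b"])
        v2 = pd.Series([5.0, 20.0], index=["a", "b"])
        strata = pd.Series(["low", "low"], index=["a", "b"])
        with caplog.at_level("INFO", logger="gutpipe"):
            fc, _ = compare_fold_changes(v1, v2, strata)
        assert list(fc.index) == ["b"]


class TestTransitions:
    def test_identity_labels_give_zero_statistic(self):
        labs = pd.Series(["Bact1", "Bact2", "Rum", "Bif"] * 5,
                         index=[f"s{i}" for i in range(20)])
        table, stat, p = transition_test(labs, labs)
        assert stat == 0.0
        assert p == 1.0
        assert np.trace(table.counts.to_numpy()) == 20

    def test_published_style_switch_percent(self):
        """A fixture with 36 baseline-Bact2 subjects of whom 16 move to Bact1
        reports the switch as 16/36 = 44%."""
        subj = [f"s{i}" for i in range(60)]
        v1 = pd.Series(["Bact2"] * 36 + ["Bact1"] * 24, index=subj)
        v2 = pd.Series(["Bact1"] * 16 + ["Bact2"] * 14 + ["Rum"] * 6 + ["Bact1"] * 24,
                       index=subj)
        table, _, _ = transition_test(v1, v2)
        switch = table.switch_summary("Bact2", "Bact1")
        assert switch == {"numerator": 16, "denominator": 36, "percent": 44}
        stay = table.switch_summary("Bact2", "Bact2")
        assert stay["percent"] == 39

    def test_chi_square_matches_hand_computation(self):
        v1 = pd.Series(["A"] * 30 + ["B"] * 10 + ["C"] * 5 + ["D"] * 5)
        v2 = pd.Series(["A"] * 15 + ["B"] * 20 + ["C"] * 10 + ["D"] * 5)
        v1.index = v2.index = [f"s{i}" for i in range(50)]
        _, stat, p = transition_test(v1, v2)
        obs = np.array([[30, 10, 5, 5], [15, 20, 10, 5]], dtype=float)
        expected = obs.sum(1, keepdims=True) * obs.sum(0) / obs.sum()
        hand = ((obs - expected) ** 2 / expected).sum()
        assert stat == pytest.approx(hand)
        assert p == pytest.approx(st.chi2.sf(hand, df=3))

    def test_stuart_maxwell_identity_is_zero(self):
        labs = pd.Series(["A", "B", "C"] * 4, index=[f"s{i}" for i in range(12)])
        _, stat, p = transition_test(labs, labs, method="stuart_maxwell")
        assert stat == pytest.approx(0.0)

    def test_counts_conserve_subjects(self):
        r = np.random.default_rng(2)
        subj = [f"s{i}" for i in range(40)]
        v1 = pd.Series(r.choice(list("ABCD"), 40), index=subj)
        v2 = pd.Series(r.choice(list("ABCD"), 40), index=subj)
        table, _, _ = transition_test(v1, v2, stratum="low")
        assert table.n_subjects == 40
        marg = table.marginals()
        assert marg["V1"].sum() == pytest.approx(1.0)


class TestLMM:
    def _paired(self, n, beta, subj_sd, seed, sigma=0.05):
        r = np.random.default_rng(seed)
        u = r.normal(0, subj_sd, n)
        y1 = 0.2 + u + r.normal(0, sigma, n)
        y2 = 0.2 + beta + u + r.normal(0, sigma, n)
        values = np.concatenate([y1, y2])
        visit = ["V1"] * n + ["V2"] * n
        subject = [f"s{i}" for i in range(n)] * 2
        return values, visit, subject

    def test_zero_subject_variance_matches_ols(self):
        """With no planted subject effect the LMM collapses to OLS: the time
        coefficient matches the least-squares fit to 1e-6 and covers the
        planted 0.03 shift."""
        import statsmodels.api as sm

        values, visit, subject = self._paired(100, 0.03, 0.0, seed=1)
        res = lmm_feature(values, visit, subject)
        x = sm.add_constant((np.array(visit) == "V2").astype(float))
        ols = sm.OLS(values, x).fit()
        assert res.beta_time == pytest.approx(ols.params[1], abs=1e-6)
        assert res.beta_time - 1.96 * res.se <= 0.03 <= res.beta_time + 1.96 * res.se

    def test_planted_effect_coverage(self):
        hits = 0
        for rep in range(60):
            values, visit, subject = self._paired(80, 0.03, 0.02, seed=100 + rep)
            res = lmm_feature(values, visit, subject)
            hits += res.beta_time - 1.96 * res.se <= 0.03 <= res.beta_time + 1.96 * res.se
        assert hits >= 54  # >= 90%

    def test_wald_z_squared_matches_paired_t(self):
        """Balanced paired design: the LMM Wald z^2 agrees with the paired t
        statistic squared within 5% at n = 100."""
        values, visit, subject = self._paired(100, 0.05, 0.3, seed=7)
        res = lmm_feature(values, visit, subject)
        diffs = values[100:] - values[:100]
        t = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(100))
        z2 = (res.beta_time / res.se) ** 2
        assert z2 == pytest.approx(t**2, rel=0.05)

    def test_constant_feature_degenerate(self):
        values = np.ones(20)
        res = lmm_feature(values, ["V1"] * 10 + ["V2"] * 10,
                          [f"s{i}" for i in range(10)] * 2)
        assert res.beta_time == 0.0
        assert res.flag == "degenerate"

    def test_single_level_lmp_reduced(self, caplog):
        values, visit, subject = self._paired(30, 0.1, 0.1, seed=3)
        with caplog.at_level("INFO", logger="gutpipe"):
            res = lmm_feature(values, visit, subject, lmp=[True] * 60)
        assert np.isnan(res.var_lmp)
        assert res.converged

    def test_lmp_variance_component_estimated(self):
        values, visit, subject = self._paired(60, 0.05, 0.2, seed=11)
        lmp = ([True] * 30 + [False] * 30) * 2
        res = lmm_feature(values, visit, subject, lmp=lmp)
        assert res.var_lmp >= 0.0
        assert res.var_subject > 0.0

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="2 subjects"):
            lmm_feature([1.0, 2.0], ["V1", "V2"], ["s1", "s1"])


class TestPairedClinical:
    def _clin(self, n, delta, seed, sd=16.3):
        r = np.random.default_rng(seed)
        w1 = r.normal(90.5, sd, n)
        w2 = w1 + delta + r.normal(0, 2.0, n)
        return pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)] * 2,
            "visit": ["V1"] * n + ["V2"] * n,
            "weight": np.concatenate([w1, w2]),
        })

    def test_identical_visits_ns(self):
        clin = self._clin(20, 0.0, seed=1)
        clin.loc[clin.visit == "V2", "weight"] = clin.loc[clin.visit == "V1", "weight"].to_numpy()
        out = paired_clinical(clin, variables=["weight"])
        assert out.loc["weight", "t"] == 0.0
        assert out.loc["weight", "stars"] == "ns"

    def test_planted_weight_loss_strongly_significant(self):
        """A -10% weight drop at n = 163 with cohort-scale SD reaches **** in
        >= 99% of replicates."""
        hits = 0
        for rep in range(100):
            out = paired_clinical(self._clin(163, -9.0, seed=rep), variables=["weight"])
            hits += out.loc["weight", "stars"] == "****"
        assert hits >= 99

    def test_paired_t_equals_one_sample_t_on_differences(self):
        clin = self._clin(30, -3.0, seed=5)
        out = paired_clinical(clin, variables=["weight"])
        v1 = clin[clin.visit == "V1"].set_index("subject_id")["weight"]
        v2 = clin[clin.visit == "V2"].set_index("subject_id")["weight"]
        t_one = st.ttest_1samp(v2 - v1, 0.0)
        assert out.loc["weight", "t"] == pytest.approx(-t_one.statistic)
        assert out.loc["weight", "p_value"] == pytest.approx(t_one.pvalue)

    def test_few_pairs_skipped(self):
        out = paired_clinical(self._clin(2, -5.0, seed=1), variables=["weight"])
        assert out.empty


def test_significance_star_bands():
    assert significance_stars(0.2) == "ns"
    assert significance_stars(0.04) == "*"
    assert significance_stars(0.009) == "**"
    assert significance_stars(0.0009) == "***"
    assert significance_stars(0.00005) == "****"


def test_between_stratum_type_one_error():
    """Null fold-change comparison keeps type-I error within [0.03, 0.07]."""
    rejections = 0
    n_rep = 1000
    for rep in range(n_rep):
        r = np.random.default_rng(rep)
        idx = [f"s{i}" for i in range(60)]
        strata = pd.Series(["low"] * 30 + ["high"] * 30, index=idx)
        v1 = pd.Series(r.uniform(300, 600, 60), index=idx)
        v2 = v1 * np.exp(r.normal(0, 0.2, 60))
        _, tests = compare_fold_changes(v1, v2, strata)
        rejections += tests["between_p"] < 0.05
    assert 0.03 <= rejections / n_rep <= 0.07
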