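"""Rank-sum effect sizes, ROC AUC, circular-linear and Spearman correlations."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

import szmarkers as sz
from szmarkers.stats import (
    auc_category,
    circular_linear_rank_corr,
    effect_category,
    effect_size_r,
    longitudinal_corr,
    ranksum_effect,
    roc_auc,
)


class TestEffectSize:
    def test_formula_analytic_case(self):
        assert effect_size_r(3.0, 36) == 0.5
        assert effect_size_r(-3.0, 36) == 0.5

    @pytest.mark.parametrize(
        "r, cat",
        [(0.05, "negligible"), (0.1, "small"), (0.29, "small"),
         (0.3, "moderate"), (0.49, "moderate"), (0.5, "large"), (0.9, "large")],
    )
    def test_category_boundaries(self, r, cat):
        assert effect_category(r) == cat


class TestRanksum:
    def test_identical_groups_null(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = ranksum_effect(a, a.copy())
        assert res.r == pytest.approx(0.0, abs=0.05)
        assert res.p > 0.9

    def test_symmetry(self, rng):
        a, b = rng.standard_normal(8), rng.standard_normal(12) + 1
        r1, r2 = ranksum_effect(a, b), ranksum_effect(b, a)
        assert r1.r == pytest.approx(r2.r, rel=1e-12)
        assert r1.p == pytest.approx(r2.p, rel=1e-12)

    def test_p_close_to_exact_enumeration(self, rng):
        """Normal-approximation p within 0.02 of the exact permutation p at n1=n2=5."""
        for seed in range(10):
            g = np.random.default_rng(seed)
            pooled = g.standard_normal(10)
            a, b = pooled[:5], pooled[5:]
            res = ranksum_effect(a, b)
            ranks = sps.rankdata(pooled)
            obs = abs(ranks[:5].sum() - 27.5)
            hits = sum(
                abs(sum(ranks[list(idx)]) - 27.5) >= obs - 1e-12
                for idx in itertools.combinations(range(10), 5)
            )
            p_exact = hits / 252
            assert abs(res.p - p_exact) < 0.02

    def test_matches_scipy_mannwhitneyu(self, rng):
        a, b = rng.standard_normal(15), rng.standard_normal(20) + 0.5
        res = ranksum_effect(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            ranksum_effect([1.0], [2.0, 3.0])


class TestRocAuc:
    def test_perfect_separation(self):
        scores = np.array([0.1, 0.2, 0.3, 0.8, 0.9, 1.0])
        labels = np.array([0, 0, 0, 1, 1, 1])
        assert roc_auc(scores, labels) == pytest.approx(1.0, abs=0.01)

    def test_independent_labels_near_half(self, rng):
        scores = rng.random(2000)
        labels = rng.random(2000) < 0.5
        assert roc_auc(scores, labels) == pytest.approx(0.5, abs=0.03)

    def test_matches_rank_based_closed_form(self, rng):
        scores = rng.random(400)
        labels = rng.random(400) < 0.4
        u = sps.mannwhitneyu(scores[labels], scores[~labels], alternative="two-sided")
        auc_rank = u.statistic / (labels.sum() * (~labels).sum())
        assert abs(roc_auc(scores, labels) - auc_rank) < 0.01

    def test_complement_symmetry(self, rng):
        scores = rng.random(300)
        labels = rng.random(300) < 0.5
        assert roc_auc(1 - scores, labels) == pytest.approx(1 - roc_auc(scores, labels), abs=0.01)

    def test_unscaled_scores_handled(self, rng):
        scores = rng.standard_normal(200) * 50 + 10
        labels = scores + rng.standard_normal(200) * 10 > 10
        assert roc_auc(scores, labels) > 0.7

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc(np.array([0.1, 0.9]), np.array([1, 1]))

    @pytest.mark.parametrize(
        "auc, cat",
        [(0.65, "unacceptable"), (0.75, "acceptable"), (0.85, "excellent"), (0.95, "outstanding")],
    )
    def test_auc_categories(self, auc, cat):
        assert auc_category(auc) == cat


class TestCircularLinear:
    def test_cosine_construction_high_rho(self, rng):
        t = rng.uniform(0, 86400, 50)
        v = np.cos(2 * np.pi * t / 86400)
        res = circular_linear_rank_corr(t, v, seed=0)
        assert res.rho > 0.95
        assert res.p_perm == pytest.approx(1 / 1001)

    def test_smallest_attainable_p(self, rng):
        t = rng.uniform(0, 86400, 40)
        v = np.cos(2 * np.pi * t / 86400)
        res = circular_linear_rank_corr(t, v, n_perm=1000, seed=0)
        assert res.p_perm == 1 / 1001

    def test_seed_reproducibility(self, rng):
        t = rng.uniform(0, 86400, 30)
        v = rng.standard_normal(30)
        r1 = circular_linear_rank_corr(t, v, seed=5)
        r2 = circular_linear_rank_corr(t, v, seed=5)
        assert r1.p_perm == r2.p_perm and r1.rho == r2.rho

    def test_invariant_to_day_shift_and_monotone_values(self, rng):
        t = rng.uniform(0, 86400, 30)
        v = rng.standard_normal(30)
        base = circular_linear_rank_corr(t, v, seed=3)
        shifted = circular_linear_rank_corr(t + 86400, v, seed=3)
        mono = circular_linear_rank_corr(t, np.exp(v), seed=3)
        assert base.rho == pytest.approx(shifted.rho, rel=1e-12)
        assert base.rho == pytest.approx(mono.rho, rel=1e-12)

    def test_all_tied_values_missing(self, rng):
        t = rng.uniform(0, 86400, 25)
        res = circular_linear_rank_corr(t, np.ones(25), seed=0)
        assert np.isnan(res.rho)

    def test_small_n_warns(self, rng):
        with pytest.warns(UserWarning, match="unreliable"):
            circular_linear_rank_corr(rng.uniform(0, 86400, 10), rng.standard_normal(10), seed=0)


class TestLongitudinal:
    def test_monotone_extremes(self):
        t = np.arange(10.0)
        rho_up, _ = longitudinal_corr(t, t**2)
        rho_dn, _ = longitudinal_corr(t, -t)
        assert rho_up == pytest.approx(1.0)
        assert rho_dn == pytest.approx(-1.0)

    def test_matches_pearson_on_ranks(self, rng):
        t = rng.random(40)
        v = rng.random(40)
        rho, _ = longitudinal_corr(t, v)
        oracle = np.corrcoef(sps.rankdata(t), sps.rankdata(v))[0, 1]
        assert rho == pytest.approx(oracle, rel=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            longitudinal_corr(np.arange(5.0), np.ones(5))


class TestEvaluation:
    def test_type_contrast_inclusion_rule(self):
        tbl = sz.simulate_cohort_markers(24, seed=0)
        small = sz.simulate_cohort_markers(4, seed=1, patient_id="tiny")
        import pandas as pd

        table = pd.concat([tbl, small], ignore_index=True)
        result, excluded = sz.evaluate_type_contrast(table)
        assert "tiny" in excluded
        assert set(result["patient_id"]) == {"simpat"}

    def test_circadian_inclusion_rule(self):
        import pandas as pd

        t19 = sz.simulate_cohort_markers(19, seed=2, patient_id="p19")
        t25 = sz.simulate_cohort_markers(25, seed=3, patient_id="p25")
        result, excluded = sz.evaluate_circadian(
            pd.concat([t19, t25], ignore_index=True), n_perm=200, seed=0
        )
        assert excluded == ["p19"]
        assert set(result["patient_id"]) == {"p25"}

    def test_long_format_columns(self):
        tbl = sz.simulate_cohort_markers(20, seed=4)
        long = sz.long_format_table(tbl)
        assert {"patient_id", "marker", "value", "time_since_first"} <= set(long.columns)
        assert long["marker"].nunique() == 16
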