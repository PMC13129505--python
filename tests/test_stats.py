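"""Pooled t, FDR, chi-square, ROC/AUC — with independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from benage.stats import (
    ROCResult,
    StatsError,
    SummaryStats,
    chi_square_2x2,
    corr_with_age,
    discriminate,
    fdr_bh,
    group_difference_table,
    roc_auc,
    t_from_summary,
    t_two_sample,
)


class TestTFromSummary:
    @pytest.mark.parametrize(
        "g1, g2, expected_t",
        [
            ((27.31, 0.80, 49), (33.05, 1.21, 35), -26.18),
            ((27.27, 0.79, 49), (32.54, 1.67, 35), -19.30),
            ((27.54, 0.73, 49), (32.77, 1.34, 35), -22.99),
        ],
    )
    def test_reference_group_summaries(self, g1, g2, expected_t):
        """Pooled t reproduces published group-comparison values from their
        printed (mean, SD, n) summaries."""
        t, df, p = t_from_summary(SummaryStats(*g1), SummaryStats(*g2))
        assert t == pytest.approx(expected_t, abs=0.005)
        assert df == 82
        assert p < 1e-30

    def test_identical_groups(self):
        t, df, p = t_from_summary(SummaryStats(5, 1, 10), SummaryStats(5, 1, 10))
        assert t == 0.0 and p == 1.0

    def test_zero_variance_unequal_means_infinite(self):
        t, _, p = t_from_summary(SummaryStats(5, 0, 10), SummaryStats(6, 0, 10))
        assert np.isinf(t) and t < 0 and p == 0.0


class TestTTwoSample:
    def test_agrees_with_scipy_pooled(self, rng):
        for _ in range(100):
            x1 = rng.standard_normal(rng.integers(3, 30))
            x2 = rng.standard_normal(rng.integers(3, 30)) + rng.normal()
            t, df, p = t_two_sample(x1, x2)
            ref = sps.ttest_ind(x1, x2, equal_var=True)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_identity_with_summary_form(self, rng):
        x1, x2 = rng.standard_normal(20), rng.standard_normal(15) + 1
        direct = t_two_sample(x1, x2)
        via_summary = t_from_summary(SummaryStats.of(x1), SummaryStats.of(x2))
        assert direct[0] == pytest.approx(via_summary[0], abs=1e-10)

    def test_copied_sample_gives_zero(self, rng):
        x = rng.standard_normal(10)
        assert t_two_sample(x, x)[0] == 0.0

    def test_expected_noncentrality(self, rng):
        # unit-variance normals, n=50 each, shift 1 -> E[t] ~ 5
        ts = [
            t_two_sample(rng.standard_normal(50) + 1, rng.standard_normal(50))[0]
            for _ in range(200)
        ]
        assert np.mean(ts) == pytest.approx(5.0, abs=0.5)


class TestFDR:
    def test_hand_computed_example(self):
        # p*m/rank = [.04, .04, .04, .04] after cummin from the largest
        np.testing.assert_allclose(
            fdr_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_flat_pvalues_unchanged(self):
        np.testing.assert_allclose(fdr_bh([0.5, 0.5, 0.5]), 0.5)

    def test_single_and_empty(self):
        np.testing.assert_allclose(fdr_bh([0.123]), [0.123])
        assert fdr_bh([]).size == 0

    def test_monotone_and_dominating(self, rng):
        p = rng.uniform(size=50)
        adj = fdr_bh(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(StatsError):
            fdr_bh([0.5, 1.2])


class TestCorrWithAge:
    def test_perfect_and_antiperfect(self):
        x = np.arange(10.0)
        assert corr_with_age(x, x)[0] == pytest.approx(1.0)
        assert corr_with_age(-x, x)[0] == pytest.approx(-1.0)

    def test_constant_rejected(self):
        with pytest.raises(StatsError):
            corr_with_age(np.ones(10), np.arange(10.0))


class TestChiSquare:
    def test_reference_sex_table(self):
        """Pearson chi-square (no continuity correction) on the published
        sex counts reproduces the printed 0.22."""
        chi2, df, p = chi_square_2x2(14, 23, 21, 28)
        assert chi2 == pytest.approx(0.22, abs=0.005)
        assert df == 1

    def test_proportional_table_zero(self):
        assert chi_square_2x2(10, 10, 20, 20)[0] == pytest.approx(0.0, abs=1e-12)

    def test_perfect_association(self):
        assert chi_square_2x2(50, 0, 0, 50)[0] == pytest.approx(100.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(StatsError):
            chi_square_2x2(5, 0, 7, 0)


class TestROC:
    def test_perfect_separation(self):
        res = roc_auc([1, 2, 3, 10, 11, 12], list("nnnppp"), "p")
        assert res.auc == 1.0

    def test_all_tied_scores(self):
        res = roc_auc(np.ones(10), ["p"] * 5 + ["n"] * 5, "p")
        assert res.auc == 0.5

    def test_orientation_flag(self):
        res = roc_auc([10, 9, 8, 1, 2, 3], list("nnnppp"), "p")
        assert res.auc == 1.0 and not res.higher_is_positive

    def test_matches_sklearn_and_trapezoid(self, rng):
        """Pair-counting AUC equals sklearn's and the swept curve's
        trapezoid area, on continuous and heavily tied scores."""
        for i in range(50):
            n = int(rng.integers(10, 60))
            y = rng.random(n) < 0.4
            if y.all() or not y.any():
                continue
            scores = (
                rng.standard_normal(n)
                if i % 2
                else rng.integers(0, 4, n).astype(float)
            )
            res = roc_auc(scores, y, True)
            ref = roc_auc_score(y, scores)
            assert res.auc == pytest.approx(max(ref, 1 - ref), abs=1e-12)
            assert res.auc_trapezoid == pytest.approx(res.auc, abs=1e-12)

    def test_null_auc_centered_at_half(self, rng):
        scores = rng.standard_normal(84)
        aucs = []
        for _ in range(1000):
            labels = rng.permutation(["p"] * 35 + ["n"] * 49)
            pos = labels == "p"
            ranks = sps.rankdata(scores)
            aucs.append((ranks[pos].sum() - 35 * 18) / (35 * 49))
        # permuting labels is symmetric around 1/2
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.01)

    def test_single_class_rejected(self):
        with pytest.raises(StatsError):
            roc_auc([1, 2, 3], ["p", "p", "p"], "p")


class TestGroupTable:
    def test_planted_difference_detected_null_not(self, rng):
        n1, n2 = 30, 30
        X = pd.DataFrame(
            {
                "shifted": np.r_[rng.standard_normal(n1), rng.standard_normal(n2) + 2],
                "null": rng.standard_normal(n1 + n2),
            }
        )
        labels = np.array(["HC"] * n1 + ["MDD"] * n2)
        out = group_difference_table(X, labels)
        assert bool(out.loc["shifted", "significant"])
        assert out.loc["shifted", "direction"] == -1  # HC - MDD < 0
        assert out.loc["null", "p_fdr"] >= out.loc["null", "p"] - 1e-15

    def test_age_correlation_columns(self, rng):
        age = rng.uniform(18, 65, 40)
        X = pd.DataFrame({"agey": age + rng.normal(0, 3, 40)})
        labels = np.array(["HC"] * 20 + ["MDD"] * 20)
        out = group_difference_table(X, labels, age=age)
        assert out.loc["agey", "r_age"] > 0.8
        assert out.loc["agey", "r_age_p_fdr"] < 0.01


class TestDiscriminate:
    def test_planted_offset_combination_near_perfect(self, rng):
        n1 = n2 = 42
        base = rng.standard_normal((n1 + n2, 10))
        base[n1:] += 2.0  # 2 SD offset on all 10 channels
        X = pd.DataFrame(base, columns=[f"c{i}" for i in range(10)])
        labels = np.array(["HC"] * n1 + ["MDD"] * n2)
        single, combo = discriminate(X, labels)
        assert combo["auc_in_sample"] >= 0.99
        assert combo["auc_cv"] >= 0.95

    def test_noise_feature_auc_near_half(self, rng):
        """Null single-feature AUC concentrates near 1/2 (sd ~ 0.063 at
        49 vs 35); at least 90% of seeds fall in [0.35, 0.65] after the
        >= 0.5 orientation fold."""
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            scores = r.standard_normal(84)
            labels = np.array(["HC"] * 49 + ["MDD"] * 35)
            auc = roc_auc(scores, labels, "MDD").auc
            hits += 0.35 <= auc <= 0.65
        assert hits >= 0.90 * n_seeds

    def test_constant_feature_skipped(self, rng):
        X = pd.DataFrame(
            {"const": np.ones(20), "ok": rng.standard_normal(20)}
        )
        labels = np.array(["HC"] * 10 + ["MDD"] * 10)
        single, combo = discriminate(X, labels)
        assert "const" not in single.index
        assert combo["columns"] == ["ok"]
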