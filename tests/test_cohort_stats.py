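import numpy as np
import pytest
from scipy import stats

from ivimkurt.cohort_stats import (
    LesionRecord,
    choose_and_run_group_test,
    icc,
    icc_category,
    rank_sum_test,
    spearman_gs,
    t_statistic_from_summary,
)
from ivimkurt.exceptions import InsufficientDataError, ValidationError


class TestSummaryTStatistic:
    def test_agrees_with_scipy_from_stats(self, rng):
        for _ in range(25):
            ma, mb = rng.normal(size=2)
            sa, sb = rng.uniform(0.5, 3, size=2)
            na, nb = rng.integers(5, 40, size=2)
            for welch in (False, True):
                t, df, p = t_statistic_from_summary(ma, sa, na, mb, sb, nb, welch=welch)
                ref = stats.ttest_ind_from_stats(ma, sa, na, mb, sb, nb, equal_var=not welch)
                assert t == pytest.approx(ref.statistic, rel=1e-12)
                assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_equal_group_sizes_make_pooled_and_welch_statistics_coincide(self, rng):
        for _ in range(20):
            ma, mb = rng.normal(size=2)
            sa, sb = rng.uniform(0.2, 5, size=2)
            n = int(rng.integers(5, 50))
            tp, _, _ = t_statistic_from_summary(ma, sa, n, mb, sb, n, welch=False)
            tw, _, _ = t_statistic_from_summary(ma, sa, n, mb, sb, n, welch=True)
            assert tp == pytest.approx(tw, rel=1e-12)

    def test_degenerate_zero_se(self):
        assert t_statistic_from_summary(1, 0, 10, 1, 0, 10) == (0.0, 18.0, 1.0)
        t, _, p = t_statistic_from_summary(2, 0, 10, 1, 0, 10)
        assert np.isinf(t) and p == 0.0


class TestGroupTestGate:
    def test_identical_groups_are_maximally_insignificant(self, rng):
        x = rng.normal(size=20)
        res = choose_and_run_group_test(x, x.copy())
        assert res.pvalue >= 0.99
        if res.test != "wilcoxon":
            assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_equal_variance_groups_choose_pooled_t(self):
        # class-mean-like conditions: two near-equal-variance normal samples;
        # the gates false-reject at their alpha (~0.95³ ≈ 86% pooled rate)
        chosen = 0
        for seed in range(30):
            r = np.random.default_rng(seed)
            a = r.normal(0.85, 0.24, 20)
            b = r.normal(1.34, 0.30, 20)
            res = choose_and_run_group_test(a, b)
            chosen += res.test == "pooled-t"
            if res.test == "pooled-t":
                assert res.pvalue < 0.05
        assert chosen >= 24  # large majority of the fixed seeds

    def test_wildly_unequal_variances_choose_welch(self):
        # PSA-like: SDs 17.85 vs 1.72
        for seed in range(5):
            r = np.random.default_rng(seed)
            a = np.abs(r.normal(18.84, 17.85, 20))
            b = r.normal(6.07, 1.72, 20)
            res = choose_and_run_group_test(a, b)
            if res.shapiro_p[0] > 0.05 and res.shapiro_p[1] > 0.05:
                assert res.test == "welch-t"
                assert res.levene_p <= 0.05

    def test_t_branch_matches_summary_path_exactly(self, rng):
        a = rng.normal(0, 1, 15)
        b = rng.normal(0.5, 1, 18)
        res = choose_and_run_group_test(a, b)
        if res.test in ("pooled-t", "welch-t"):
            t, df, p = t_statistic_from_summary(
                a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size,
                welch=res.test == "welch-t",
            )
            assert res.statistic == pytest.approx(t, rel=1e-12)
            assert res.pvalue == pytest.approx(p, rel=1e-12)

    def test_wilcoxon_branch_invariant_under_monotone_transform(self, rng):
        a = rng.lognormal(0, 1, 15)
        b = rng.lognormal(0.8, 1, 15)
        z1, p1 = rank_sum_test(a, b)
        z2, p2 = rank_sum_test(np.log(a), np.log(b))
        assert z1 == pytest.approx(z2, rel=1e-12)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_rank_sum_matches_scipy_mannwhitney_with_ties(self, rng):
        a = rng.integers(0, 6, 18).astype(float)
        b = rng.integers(0, 6, 22).astype(float)
        _, p = rank_sum_test(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_too_small_groups_rejected(self):
        with pytest.raises(InsufficientDataError):
            choose_and_run_group_test([1, 2], [3, 4, 5])


def brute_force_mean_squares(x):
    """Independent two-way ANOVA oracle with explicit loops."""
    n, k = x.shape
    grand = x.mean()
    msr = sum(k * (x[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
    msc = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    sse = sum(
        (x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
        for i in range(n) for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    return msr, msc, mse


class TestICC:
    def test_identical_raters_give_exactly_one_for_all_forms(self, rng):
        a = rng.normal(size=12)
        ratings = np.column_stack([a, a])
        for form in ("agreement", "consistency"):
            res = icc(ratings, form=form)
            assert res.value == pytest.approx(1.0, abs=1e-12)
            assert res.category == "excellent"

    def test_constant_shift_splits_consistency_from_agreement(self, rng):
        a = rng.normal(size=15)
        ratings = np.column_stack([a, a + 1.0])
        cons = icc(ratings, form="consistency")
        agree = icc(ratings, form="agreement")
        assert cons.value == pytest.approx(1.0, abs=1e-12)
        assert agree.value < 1.0
        # verify against the textbook ANOVA identity via the brute-force oracle
        msr, msc, mse = brute_force_mean_squares(ratings)
        n, k = ratings.shape
        expected = (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))
        assert agree.value == pytest.approx(expected, rel=1e-12)

    def test_matches_pingouin_on_random_data(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        x = rng.normal(size=(12, 3)) + rng.normal(size=(12, 1))
        long = pd.DataFrame(
            {
                "target": np.repeat(np.arange(12), 3),
                "rater": np.tile(np.arange(3), 12),
                "score": x.ravel(),
            }
        )
        ref = pg.intraclass_corr(long, targets="target", raters="rater", ratings="score")
        ref = ref.set_index("Type")
        assert icc(x, "agreement").value == pytest.approx(ref.loc["ICC(A,1)", "ICC"], rel=1e-9)
        assert icc(x, "consistency").value == pytest.approx(ref.loc["ICC(C,1)", "ICC"], rel=1e-9)
        lo, hi = icc(x, "agreement").ci95
        assert (lo, hi) == pytest.approx(tuple(ref.loc["ICC(A,1)", "CI95"]), abs=5e-3)

    def test_category_thresholds_inclusive_upward(self):
        assert icc_category(0.39) == "poor"
        assert icc_category(0.40) == "fair"
        assert icc_category(0.59) == "fair"
        assert icc_category(0.60) == "good"
        assert icc_category(0.74) == "good"
        assert icc_category(0.75) == "excellent"

    def test_preconditions(self, rng):
        with pytest.raises(InsufficientDataError):
            icc(rng.normal(size=(4, 2)))
        with pytest.raises(InsufficientDataError):
            icc(rng.normal(size=(10, 1)))
        bad = rng.normal(size=(10, 2))
        bad[3, 1] = np.nan
        with pytest.raises(ValidationError):
            icc(bad)


class TestSpearman:
    def test_perfect_monotone_relations(self):
        # tie structure shared between values and scores → |rho| exactly 1
        gs = [6, 6, 7, 7, 8, 9]
        up = spearman_gs([1, 1, 2, 2, 3, 4], gs)
        down = spearman_gs([4, 4, 3, 3, 2, 1], gs)
        assert up.rho == pytest.approx(1.0)
        assert down.rho == pytest.approx(-1.0)

    def test_tie_structure_matches_average_rank_pearson_oracle(self, rng):
        # cohort-like Gleason tie structure: 5×6, 8×7, 3×8, 4×9
        gs = np.repeat([6, 7, 8, 9], [5, 8, 3, 4]).astype(float)
        vals = rng.normal(size=20)
        res = spearman_gs(vals, gs)
        ranks_v = stats.rankdata(vals)
        ranks_g = stats.rankdata(gs)
        oracle = np.corrcoef(ranks_v, ranks_g)[0, 1]
        assert res.rho == pytest.approx(oracle, rel=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValidationError):
            spearman_gs([1, 1, 1, 1, 1], [6, 7, 8, 9, 6])


class TestLesionRecord:
    def test_gleason_consistency_enforced(self):
        summaries = {p: object() for p in ("D", "Dstar", "f", "K", "ADC")}
        LesionRecord(1, "PCa", summaries, gleason=7)
        with pytest.raises(ValidationError):
            LesionRecord(1, "PCa", summaries, gleason=None)
        with pytest.raises(ValidationError):
            LesionRecord(2, "BPH/prostatitis", summaries, gleason=7)
        with pytest.raises(ValidationError):
            LesionRecord(3, "PCa", {"D": object()}, gleason=7)
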