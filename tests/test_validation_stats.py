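"""Statistical battery: ANOVA, Fisher r×c, Pearson, Bland–Altman, ROC, ICC."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats

from cmrdiast import (
    GroupSummary,
    anova_oneway,
    bland_altman,
    fisher_exact_rxc,
    format_p,
    icc_two_way_random,
    paired_mean_comparison,
    pearson_linear,
    roc_auc_with_band,
)
from cmrdiast.errors import (
    DegenerateLabelsError,
    IncompleteMatrixError,
    ParameterError,
    UndefinedStatisticError,
)


# ------------------------------------------------------------- oracles


def fisher_oracle_2xc(table):
    """Exact two-sided Freeman–Halton p by brute force with rational
    arithmetic: enumerate every 2×c table with the observed margins and
    sum the probabilities not exceeding the observed one."""
    table = np.asarray(table, int)
    row0 = table[0]
    col_m = table.sum(axis=0)
    n0 = int(table[0].sum())

    def prob(cells0):
        num = Fraction(1)
        for cnt, margin in zip(cells0, col_m):
            num *= math.comb(margin, cnt)
        return Fraction(num, math.comb(int(col_m.sum()), n0))

    p_obs = prob(tuple(row0))
    total = Fraction(0)
    ranges = [range(min(n0, m) + 1) for m in col_m]
    for cells in itertools.product(*ranges):
        if sum(cells) != n0:
            continue
        p = prob(cells)
        if p <= p_obs:
            total += p
    return float(total)


def auc_oracle(scores, labels):
    """All-pairs comparison count with half credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = sum(
        1.0 if p > n else 0.5 if p == n else 0.0
        for p in pos for n in neg
    )
    return wins / (len(pos) * len(neg))


def icc21_oracle(m):
    """ICC(2,1) by the explicit mean-squares recipe, written out long-hand."""
    m = np.asarray(m, float)
    n, k = m.shape
    subject_means = m.mean(axis=1)
    rater_means = m.mean(axis=0)
    grand = m.mean()
    msr = k / (n - 1) * np.sum((subject_means - grand) ** 2)
    msc = n / (k - 1) * np.sum((rater_means - grand) ** 2)
    sse = np.sum((m - subject_means[:, None] - rater_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


# --------------------------------------------------------------- ANOVA


class TestAnova:
    def test_identical_means_give_f_zero_p_one(self):
        s = GroupSummary(ns=(10, 12, 9), means=(5.0, 5.0, 5.0), sds=(1.0, 2.0, 1.5))
        F, p = anova_oneway(s)
        assert F == 0.0 and p == 1.0

    def test_summary_equals_raw_on_moment_matched_data(self, rng):
        # two-point groups with exactly the requested mean and sd
        for _ in range(20):
            means = rng.uniform(-5, 5, 3)
            sds = rng.uniform(0.5, 3.0, 3)
            groups = [
                np.array([m - s / np.sqrt(2), m + s / np.sqrt(2)])
                for m, s in zip(means, sds)
            ]
            F_raw, p_raw = anova_oneway(groups)
            F_sum, p_sum = anova_oneway(
                GroupSummary(ns=(2, 2, 2), means=tuple(means), sds=tuple(sds))
            )
            assert F_sum == pytest.approx(F_raw, rel=1e-12)
            assert p_sum == pytest.approx(p_raw, rel=1e-12)

    def test_matches_scipy_on_raw_groups(self, rng):
        groups = [rng.normal(i * 0.5, 1.0, 15) for i in range(3)]
        F, p = anova_oneway(groups)
        F_ref, p_ref = stats.f_oneway(*groups)
        assert F == pytest.approx(F_ref, rel=1e-10)
        assert p == pytest.approx(p_ref, rel=1e-10)

    def test_zero_variance_equal_means_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            anova_oneway(GroupSummary(ns=(3, 3), means=(2.0, 2.0), sds=(0.0, 0.0)))

    def test_single_group_rejected(self):
        with pytest.raises(ParameterError):
            GroupSummary(ns=(5,), means=(1.0,), sds=(1.0,))


# ------------------------------------------------------------- Fisher


class TestFisherExact:
    def test_two_by_two_diagonal(self):
        assert fisher_exact_rxc([[1, 0], [0, 1]]) == pytest.approx(1.0)

    def test_matches_scipy_on_2x2(self, rng):
        for _ in range(10):
            t = rng.integers(0, 12, (2, 2))
            if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
                continue
            _, p_ref = stats.fisher_exact(t)
            assert fisher_exact_rxc(t) == pytest.approx(p_ref, abs=1e-10)

    def test_matches_enumeration_oracle_on_small_2x3(self, rng):
        for _ in range(15):
            t = rng.integers(0, 6, (2, 3))
            if t.sum() == 0 or t.sum() > 30:
                continue
            assert fisher_exact_rxc(t) == pytest.approx(fisher_oracle_2xc(t), abs=1e-10)

    def test_three_by_three_agrees_with_oracle_transpose(self):
        # r x c result is invariant to transposition
        t = np.array([[3, 1, 0], [2, 4, 1], [0, 2, 3]])
        assert fisher_exact_rxc(t) == pytest.approx(fisher_exact_rxc(t.T), abs=1e-10)

    def test_reference_contingency_rows(self):
        # frozen oracle values verified against R fisher.test (Freeman-Halton)
        race = [[41, 11, 6], [25, 10, 9]]
        hypertension = [[33, 7, 9], [33, 14, 6]]
        diabetes = [[3, 2, 3], [63, 19, 12]]
        assert fisher_exact_rxc(race) == pytest.approx(0.2259549, abs=1e-4)
        assert fisher_exact_rxc(hypertension) == pytest.approx(0.2561543, abs=1e-4)
        assert fisher_exact_rxc(diabetes) == pytest.approx(0.1139268, abs=1e-4)

    def test_monte_carlo_close_to_exact(self):
        t = [[8, 3, 2], [4, 7, 6]]
        exact = fisher_exact_rxc(t)
        mc = fisher_exact_rxc(t, monte_carlo=True, n_samples=20000, seed=11)
        assert mc == pytest.approx(exact, abs=0.02)

    def test_p_in_unit_interval(self, rng):
        for _ in range(10):
            t = rng.integers(0, 8, (2, 3)) + np.array([[1, 0, 0], [0, 1, 0]])
            p = fisher_exact_rxc(t)
            assert 0.0 < p <= 1.0


# ------------------------------------------------------------- Pearson


class TestPearson:
    def test_perfect_positive_line(self):
        x = np.arange(10.0)
        r, p, slope, intercept = pearson_linear(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert slope == pytest.approx(2.0) and intercept == pytest.approx(1.0)

    def test_perfect_negative_line(self):
        x = np.arange(10.0)
        r, _, slope, _ = pearson_linear(x, -x)
        assert r == pytest.approx(-1.0) and slope == pytest.approx(-1.0)

    def test_matches_covariance_oracle(self, rng):
        x = rng.normal(0, 2, 10)
        y = 0.7 * x + rng.normal(0, 1, 10)
        r, _, slope, intercept = pearson_linear(x, y)
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        r_ref = cov / (x.std() * y.std())
        assert r == pytest.approx(r_ref, rel=1e-10)
        assert slope == pytest.approx(cov / x.var(), rel=1e-10)
        assert intercept == pytest.approx(y.mean() - slope * x.mean(), rel=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            pearson_linear(np.ones(5), np.arange(5.0))


# --------------------------------------------------------- Bland-Altman


class TestBlandAltman:
    def test_identical_series(self):
        x = np.arange(8.0)
        assert bland_altman(x, x) == (0.0, 0.0, 0.0)

    def test_constant_offset(self):
        x = np.arange(8.0)
        bias, lo, hi = bland_altman(x, x + 3.5)
        assert (bias, lo, hi) == (3.5, 3.5, 3.5)

    def test_fixed_pairs_match_formula(self, rng):
        x = rng.normal(10, 2, 8)
        y = x + rng.normal(0.5, 1.0, 8)
        bias, lo, hi = bland_altman(x, y)
        d = y - x
        assert bias == pytest.approx(d.mean())
        assert lo == pytest.approx(d.mean() - 1.96 * d.std(ddof=1))
        assert hi == pytest.approx(d.mean() + 1.96 * d.std(ddof=1))

    def test_limits_cover_about_95_percent_of_normal_differences(self, rng):
        n = 10_000
        x = rng.normal(100, 10, n)
        y = x + rng.normal(0.5, 2.0, n)
        bias, lo, hi = bland_altman(x, y)
        d = y - x
        coverage = np.mean((d >= lo) & (d <= hi))
        assert 0.94 <= coverage <= 0.96


# ----------------------------------------------------------------- ROC


class TestRoc:
    def test_perfect_separation(self):
        res = roc_auc_with_band([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0 and res.band == "excellent"

    def test_all_tied_scores(self):
        res = roc_auc_with_band([5.0] * 8, [0, 1] * 4)
        assert res.auc == 0.5 and res.band == "poor"

    def test_matches_all_pairs_oracle_and_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(25):
            n = int(rng.integers(6, 50))
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            scores = np.round(rng.normal(labels.astype(float), 1.2), 1)  # induce ties
            res = roc_auc_with_band(scores, labels)
            assert res.auc == pytest.approx(auc_oracle(scores, labels), abs=1e-12)
            assert res.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-10)

    def test_complement_under_score_negation(self, rng):
        scores = rng.normal(0, 1, 30)
        labels = rng.integers(0, 2, 30)
        labels[0], labels[1] = 0, 1
        a = roc_auc_with_band(scores, labels).auc
        b = roc_auc_with_band(-scores, labels).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_lower_direction_flips_orientation(self, rng):
        scores = rng.normal(0, 1, 30)
        labels = rng.integers(0, 2, 30)
        labels[0], labels[1] = 0, 1
        assert roc_auc_with_band(scores, labels, "lower").auc == pytest.approx(
            roc_auc_with_band(-scores, labels, "higher").auc, abs=1e-12
        )

    def test_band_edges(self):
        # 0.70 and 0.90 are inclusive lower edges of good/excellent
        from cmrdiast.validation_stats import auc_band

        assert auc_band(0.69) == "poor"
        assert auc_band(0.70) == "good"
        assert auc_band(0.90) == "excellent"

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateLabelsError):
            roc_auc_with_band([1.0, 2.0], [1, 1])


# ----------------------------------------------------------------- ICC


class TestIcc:
    def test_duplicate_columns_give_unity(self, rng):
        col = rng.normal(50, 10, 8)
        res = icc_two_way_random(np.column_stack([col, col]))
        assert res.icc == pytest.approx(1.0, abs=1e-12)
        assert res.band == "excellent"
        assert res.bias == pytest.approx(0.0)

    def test_fixed_matrix_matches_mean_squares_oracle(self):
        m = np.array([
            [9.0, 2.0], [4.5, 4.0], [7.0, 6.5],
            [10.0, 9.0], [6.0, 5.5], [8.0, 7.0],
        ])
        res = icc_two_way_random(m)
        assert res.icc == pytest.approx(icc21_oracle(m), abs=1e-12)

    def test_matches_pingouin_icc2(self, rng):
        import pandas as pd
        import pingouin as pg

        m = rng.normal(60, 15, (10, 3)) + rng.normal(0, 3, (10, 1))
        res = icc_two_way_random(m)
        n, k = m.shape
        df = pd.DataFrame({
            "targets": np.repeat(np.arange(n), k),
            "raters": np.tile(np.arange(k), n),
            "ratings": m.ravel(),
        })
        ref = pg.intraclass_corr(df, "targets", "raters", "ratings")
        # single-measure absolute-agreement two-way: labelled ICC2 or ICC(A,1)
        mask = ref["Type"].isin(["ICC2", "ICC(A,1)"])
        icc2 = ref.loc[mask, "ICC"].iloc[0]
        assert res.icc == pytest.approx(icc2, abs=1e-10)

    def test_invariance_to_shift_and_scale(self, rng):
        m = rng.normal(0, 1, (9, 2)) + rng.normal(0, 2, (9, 1))
        base = icc_two_way_random(m).icc
        assert icc_two_way_random(m + 13.7).icc == pytest.approx(base, abs=1e-10)
        assert icc_two_way_random(m * 4.2).icc == pytest.approx(base, abs=1e-10)

    def test_band_cutoffs(self):
        from cmrdiast.validation_stats import icc_band

        assert icc_band(0.89) == "excellent"  # an excellent mean agreement
        assert icc_band(0.75) == "fair-to-good"
        assert icc_band(0.40) == "fair-to-good"
        assert icc_band(0.39) == "poor"

    def test_missing_cells_rejected(self):
        m = np.ones((6, 2))
        m[2, 1] = np.nan
        with pytest.raises(IncompleteMatrixError):
            icc_two_way_random(m)

    def test_too_small_matrix_rejected(self):
        with pytest.raises(ParameterError):
            icc_two_way_random(np.ones((3, 2)))


# -------------------------------------------------------------- paired


class TestPairedComparison:
    def test_identical_pairs(self):
        x = np.arange(5.0)
        assert paired_mean_comparison(x, x) == (0.0, 1.0)

    def test_recovers_known_shift(self, rng):
        x = rng.normal(500, 50, 400)
        y = x + 12.0 + rng.normal(0, 5, 400)
        d = (y - x).mean()
        assert d == pytest.approx(12.0, abs=1.0)
        t, p = paired_mean_comparison(x, y)
        assert p < 1e-6  # a real 12 ms shift is detected

    def test_fixed_pairs_match_closed_form(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([1.4, 2.1, 3.5, 3.9, 5.6])
        d = y - x
        t_ref = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
        p_ref = 2 * stats.t.sf(abs(t_ref), d.size - 1)
        t, p = paired_mean_comparison(x, y)
        assert t == pytest.approx(t_ref, rel=1e-10)
        assert p == pytest.approx(p_ref, rel=1e-10)


class TestFormatP:
    @pytest.mark.parametrize(
        "p,text",
        [(0.5, "0.50"), (0.03, "0.03"), (0.0021, "0.0021"), (5e-5, "<0.0001")],
    )
    def test_report_style(self, p, text):
        assert format_p(p) == text
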