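"""Outlier screening, ICC inference, and the ICC-difference permutation test."""

import numpy as np
import pandas as pd
import pytest

from rapidffr.reliability import (holm_correction, icc, permute_icc_difference,
                                  reject_outliers)
from rapidffr.reliability import _icc_value_stack


class TestRejectOutliers:
    def test_single_large_value_within_leave_in_band(self):
        # {0,0,0,0,100}: mean 20, sd ~44.7 -> z(100) ~ 1.8, all kept
        kept = reject_outliers([0, 0, 0, 0, 100])
        assert kept.all()

    def test_all_equal_values_kept(self):
        assert reject_outliers([5.0] * 10).all()

    def test_clear_outlier_rejected(self):
        # 19 zeros and one 10: z(10) ~ 4.2 > 2.5
        values = [0.0] * 19 + [10.0]
        kept = reject_outliers(values)
        assert kept[:19].all() and not kept[19]

    def test_matches_brute_force_rule(self, rng):
        x = rng.standard_normal(40) * 3
        kept = reject_outliers(x)
        mean, sd = x.mean(), x.std(ddof=1)
        expected = np.array([abs(v - mean) <= 2.5 * sd for v in x])
        np.testing.assert_array_equal(kept, expected)


def _oracle_icc(x, model):
    """Brute-force ANOVA sums-of-squares oracle (independent arithmetic)."""
    n, k = x.shape
    grand = x.sum() / (n * k)
    ssb = k * sum((x[i].mean() - grand) ** 2 for i in range(n))
    ssc = n * sum((x[:, j].mean() - grand) ** 2 for j in range(k))
    sst = ((x - grand) ** 2).sum()
    msb = ssb / (n - 1)
    if model == "oneway":
        msw = (sst - ssb) / (n * (k - 1))
        return (msb - msw) / (msb + (k - 1) * msw)
    mse = (sst - ssb - ssc) / ((n - 1) * (k - 1))
    msc = ssc / (k - 1)
    return (msb - mse) / (msb + (k - 1) * mse + k * (msc - mse) / n)


class TestIcc:
    @pytest.mark.parametrize("model", ["oneway", "twoway"])
    def test_matches_anova_oracle(self, model, rng):
        for _ in range(20):
            x = rng.standard_normal((10, 2)) + rng.standard_normal((10, 1))
            assert icc(x, model).icc == pytest.approx(
                _oracle_icc(x, model), abs=1e-10)

    @pytest.mark.parametrize("model,col", [("oneway", "ICC(1,1)"),
                                           ("twoway", "ICC(A,1)")])
    def test_matches_pingouin(self, model, col, rng):
        import pingouin as pg
        x = rng.standard_normal((12, 2)) + 2 * rng.standard_normal((12, 1))
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(12), 2),
            "rater": np.tile(["a", "b"], 12),
            "value": x.reshape(-1),
        })
        table = pg.intraclass_corr(long, targets="subject", raters="rater",
                                   ratings="value").set_index("Type")
        assert icc(x, model).icc == pytest.approx(table.loc[col, "ICC"],
                                                  abs=1e-10)

    def test_oneway_df_for_16_by_2(self, rng):
        res = icc(rng.standard_normal((16, 2)), "oneway")
        assert res.df == (15.0, 16.0)

    def test_twoway_df_is_satterthwaite(self, rng):
        res = icc(rng.standard_normal((16, 2)) + rng.standard_normal((16, 1)),
                  "twoway")
        assert res.df[0] == 15.0
        assert res.df[1] != round(res.df[1])  # generally non-integer

    def test_perfect_agreement(self):
        col = np.arange(1.0, 9.0)
        x = np.c_[col, col]
        for model in ("oneway", "twoway"):
            res = icc(x, model)
            assert res.icc == pytest.approx(1.0)
            assert res.p == 0.0

    def test_ci_contains_estimate(self, rng):
        x = rng.standard_normal((14, 2)) + rng.standard_normal((14, 1))
        for model in ("oneway", "twoway"):
            res = icc(x, model)
            assert res.ci95[0] <= res.icc <= res.ci95[1]

    def test_invariance_to_shift_and_positive_scale(self, rng):
        x = rng.standard_normal((10, 2)) + rng.standard_normal((10, 1))
        for model in ("oneway", "twoway"):
            base = icc(x, model).icc
            assert icc(3.2 * x + 7.0, model).icc == pytest.approx(base, abs=1e-12)

    def test_listwise_deletion(self, rng):
        x = rng.standard_normal((10, 2)) + rng.standard_normal((10, 1))
        x_nan = np.vstack([x, [np.nan, 1.0]])
        assert icc(x_nan, "oneway").n == 10
        assert icc(x_nan, "oneway").icc == pytest.approx(icc(x, "oneway").icc)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="3"):
            icc(np.zeros((2, 2)), "oneway")

    def test_vectorized_values_match_scalar(self, rng):
        mats = rng.standard_normal((5, 10, 2)) + rng.standard_normal((5, 10, 1))
        for model in ("oneway", "twoway"):
            stack = _icc_value_stack(mats, model)
            for i in range(5):
                assert stack[i] == pytest.approx(icc(mats[i], model).icc,
                                                 abs=1e-12)


class TestPermutationTest:
    def test_reproducible_with_seed(self, rng):
        a = rng.standard_normal((12, 2))
        b = rng.standard_normal((12, 2))
        r1 = permute_icc_difference(a, b, n_perm=100, seed=5)
        r2 = permute_icc_difference(a, b, n_perm=100, seed=5)
        assert r1.p_c == r2.p_c
        np.testing.assert_array_equal(r1.null_values, r2.null_values)

    def test_constant_second_column_gives_p_zero(self, rng):
        # shuffling a constant column changes nothing, so no null difference
        # can strictly exceed the observed one
        a = np.c_[rng.standard_normal(10), np.ones(10)]
        b = np.c_[rng.standard_normal(10), np.ones(10)]
        res = permute_icc_difference(a, b, n_perm=50, seed=1, model="oneway")
        assert res.p_c == 0.0

    def test_identical_datasets_give_p_one(self, rng):
        # obs = 0 while permuted differences are almost surely nonzero
        a = rng.standard_normal((12, 2)) + rng.standard_normal((12, 1))
        res = permute_icc_difference(a, a.copy(), n_perm=200, seed=2)
        assert res.obs == 0.0
        assert res.p_c == 1.0

    def test_null_count_rule(self, rng):
        a = rng.standard_normal((12, 2))
        b = rng.standard_normal((12, 2))
        res = permute_icc_difference(a, b, n_perm=300, seed=9)
        expected = np.count_nonzero(np.abs(res.null_values) > abs(res.obs)) / 300
        assert res.p_c == expected
        assert len(res.null_values) == 300

    def test_invalid_n_perm(self, rng):
        a = rng.standard_normal((10, 2))
        with pytest.raises(ValueError, match="n_perm"):
            permute_icc_difference(a, a, n_perm=0)


class TestHolm:
    def test_never_more_rejections_than_uncorrected(self, rng):
        p = rng.uniform(0, 0.2, size=12)
        adj, reject = holm_correction(p)
        assert reject.sum() <= (p < 0.05).sum()
        assert (adj >= p - 1e-15).all()
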