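"""Agreement statistics against closed forms and independent oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sp_stats

from arval.agreement import (
    bland_altman_np,
    icc,
    ks_normality,
    mad,
    mard,
    rmse,
    sample_size_correlation,
    spearman,
)
from arval.errors import DegenerateDataError, ValidationError


class TestMadRmse:
    def test_identical_inputs_zero(self):
        a = np.arange(10.0)
        assert mad(a, a) == (0.0, 0.0)
        assert rmse(a, a) == 0.0

    def test_constant_offset(self):
        a = np.arange(10.0)
        m, sd = mad(a, a + 7.0)
        assert m == pytest.approx(7.0)
        assert sd == pytest.approx(0.0)
        assert rmse(a, a + 7.0) == pytest.approx(7.0)

    def test_gaussian_differences_closed_form(self):
        """|N(0,20)| has mean 20*sqrt(2/pi) (folded normal) and RMS 20."""
        rng = np.random.default_rng(1)
        a = np.zeros(10**6)
        b = rng.normal(0.0, 20.0, 10**6)
        m, _ = mad(a, b)
        assert m == pytest.approx(20.0 * np.sqrt(2.0 / np.pi), rel=0.01)
        assert rmse(a, b) == pytest.approx(20.0, rel=0.01)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            mad([1.0], [1.0, 2.0])

    @given(
        st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=100),
        st.integers(0, 2**31 - 1),
    )
    def test_rmse_dominates_mad_mean(self, values, seed):
        """Power-mean inequality: RMS of |d| >= mean of |d| on any input."""
        a = np.array(values)
        b = a + np.random.default_rng(seed).normal(size=a.size)
        m, _ = mad(a, b)
        assert rmse(a, b) >= m - 1e-9

    def test_reordering_invariance(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=50), rng.normal(size=50)
        perm = rng.permutation(50)
        assert mad(a, b) == pytest.approx(mad(a[perm], b[perm]), rel=1e-12)
        assert rmse(a, b) == pytest.approx(rmse(a[perm], b[perm]), rel=1e-12)


class TestMard:
    def test_identical_zero(self):
        assert mard([500.0, 300.0], [500.0, 300.0]) == 0.0

    def test_two_percent_offset(self):
        assert mard([510.0] * 5, [500.0] * 5) == pytest.approx(0.02)

    def test_mixed_set(self):
        assert mard([90.0, 220.0], [100.0, 200.0]) == pytest.approx(0.10)

    def test_zero_reference_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluded 1"):
            value = mard([90.0, 50.0], [100.0, 0.0])
        assert value == pytest.approx(0.10)


class TestSpearman:
    def test_monotone_pairs(self):
        a = np.arange(10.0)
        assert spearman(a, a**3)[0] == pytest.approx(1.0)
        assert spearman(a, -a)[0] == pytest.approx(-1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateDataError):
            spearman(np.ones(5), np.arange(5.0))

    def test_matches_average_rank_oracle_with_ties(self):
        """Brute-force oracle: Pearson correlation of average ranks."""
        a = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([2.0, 1.0, 4.0, 3.0, 3.0, 6.0])

        def avg_ranks(x):
            order = np.argsort(x, kind="stable")
            ranks = np.empty(x.size)
            i = 0
            sx = x[order]
            while i < x.size:
                j = i
                while j < x.size and sx[j] == sx[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2.0  # average of 1-based ranks
                i = j
            return ranks

        ra, rb = avg_ranks(a), avg_ranks(b)
        oracle = np.corrcoef(ra, rb)[0, 1]
        rho, _ = spearman(a, b)
        assert rho == pytest.approx(oracle, abs=1e-10)


class TestIcc:
    def test_perfect_agreement(self):
        a = np.array([310.0, 320.0, 355.0, 340.0, 362.0, 330.0])
        res = icc(a, a)
        assert res.icc == 1.0
        assert res.p == 0.0

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(7)
        res = icc(rng.normal(size=200), rng.normal(size=200))
        assert abs(res.icc) < 0.15

    def test_matches_anova_mean_squares_oracle(self):
        """Explicit MSR/MSC/MSE arithmetic on a 6x2 table, to 1e-10."""
        tg = np.array([10.0, 12.0, 11.5, 14.0, 9.0, 13.0])
        ref = np.array([10.5, 11.0, 12.0, 13.0, 9.5, 12.5])
        x = np.stack([tg, ref], axis=1)
        n, k = x.shape
        grand = x.mean()
        msr = k * ((x.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((x.mean(axis=0) - grand) ** 2).sum() / (k - 1)
        sse = ((x - x.mean(axis=1, keepdims=True) - x.mean(axis=0) + grand) ** 2).sum()
        mse = sse / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        res = icc(tg, ref)
        assert res.icc == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pingouin_cross_check(self, seed):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(seed)
        base = rng.normal(300.0, 40.0, 20)
        tg = base + rng.normal(0.0, 10.0, 20)
        ref = base + rng.normal(0.0, 10.0, 20)
        res = icc(tg, ref)
        df = pd.DataFrame(
            {
                "targets": np.tile(np.arange(20), 2),
                "raters": np.repeat(["tg", "ref"], 20),
                "ratings": np.concatenate([tg, ref]),
            }
        )
        pg = pingouin.intraclass_corr(df, targets="targets", raters="raters", ratings="ratings")
        row = pg[pg["Type"].isin(["ICC2", "ICC(A,1)"])].iloc[0]
        ci_col = "CI95%" if "CI95%" in pg.columns else "CI95"
        assert res.icc == pytest.approx(row["ICC"], abs=1e-8)
        assert res.p == pytest.approx(row["pval"], rel=1e-6)
        # pingouin rounds the interval to 2 decimals
        assert res.ci_low == pytest.approx(row[ci_col][0], abs=0.006)
        assert res.ci_high == pytest.approx(row[ci_col][1], abs=0.006)

    def test_degenerate_rejected(self):
        with pytest.raises(DegenerateDataError):
            icc(np.full(6, 5.0), np.full(6, 5.0))

    def test_small_n_rejected(self):
        with pytest.raises(ValidationError):
            icc([1.0, 2.0], [1.0, 2.0])


class TestKsNormality:
    def test_uniform_sample_rejected(self):
        rng = np.random.default_rng(3)
        _, p = ks_normality(rng.uniform(size=500))
        assert p < 0.01

    def test_normal_sample_not_rejected(self):
        rng = np.random.default_rng(4)
        _, p = ks_normality(rng.normal(size=500))
        assert p > 0.05

    def test_small_n_rejected(self):
        with pytest.raises(ValidationError):
            ks_normality([1.0, 2.0, 3.0, 4.0])

    def test_constant_rejected(self):
        with pytest.raises(DegenerateDataError):
            ks_normality(np.ones(10))

    def test_statistic_matches_statsmodels(self):
        statsmodels = pytest.importorskip("statsmodels.stats.diagnostic")
        rng = np.random.default_rng(5)
        x = rng.normal(size=80)
        stat, p = ks_normality(x)
        sm_stat, sm_p = statsmodels.lilliefors(x, dist="norm")
        assert stat == pytest.approx(sm_stat, abs=1e-12)
        assert p == pytest.approx(sm_p, abs=0.05)


class TestBlandAltman:
    def test_identical_inputs_all_zero(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        ba = bland_altman_np(a, a)
        assert (ba.median, ba.loa_low, ba.loa_high) == (0.0, 0.0, 0.0)

    def test_hand_evaluated_percentiles(self):
        """diffs {-2,-1,0,1,2}: linear-interpolation percentiles give
        -1.9 and 1.9 at the 2.5th/97.5th, median 0."""
        ref = np.zeros(5)
        tg = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        ba = bland_altman_np(tg, ref)
        assert ba.median == 0.0
        assert ba.loa_low == pytest.approx(-1.9)
        assert ba.loa_high == pytest.approx(1.9)

    def test_sign_convention_tg_minus_ref(self):
        tg = np.array([11.0, 12.0, 13.0, 14.0])
        ref = np.array([10.0, 10.0, 10.0, 10.0])
        ba = bland_altman_np(tg, ref)
        assert ba.median > 0
        np.testing.assert_allclose(ba.diffs, tg - ref)

    def test_parametric_variant(self):
        rng = np.random.default_rng(6)
        ref = np.zeros(10**4)
        tg = rng.normal(0.0, 5.0, 10**4)
        ba = bland_altman_np(tg, ref, parametric=True)
        assert ba.loa_high == pytest.approx(1.96 * 5.0, rel=0.05)

    def test_small_n_rejected(self):
        with pytest.raises(ValidationError):
            bland_altman_np([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


class TestSampleSize:
    def test_strong_correlation_gives_29(self):
        assert sample_size_correlation(0.5, 0.05, 0.2) == 29

    def test_perfect_correlation_limit(self):
        assert sample_size_correlation(0.999999) == 4

    def test_invalid_r_rejected(self):
        for r in (0.0, 1.0, -0.5):
            with pytest.raises(ValidationError):
                sample_size_correlation(r)

    def test_monotone_in_r(self):
        ns = [sample_size_correlation(r) for r in (0.2, 0.3, 0.5, 0.8)]
        assert ns == sorted(ns, reverse=True)

    def test_power_at_returned_n_by_simulation(self):
        """Monte-Carlo power of the Fisher-z test at rho=0.3: the returned
        n achieves ~80% power and clearly more than a much smaller n."""
        r, alpha = 0.3, 0.05
        n = sample_size_correlation(r, alpha, 0.2)
        assert n == 85

        def power(n_sub, sims=2000):
            rng = np.random.default_rng(11)
            cov = [[1.0, r], [r, 1.0]]
            hits = 0
            z_crit = sp_stats.norm.ppf(1 - alpha / 2)
            for _ in range(sims):
                xy = rng.multivariate_normal([0, 0], cov, size=n_sub)
                rr = np.corrcoef(xy[:, 0], xy[:, 1])[0, 1]
                z = np.arctanh(rr) * np.sqrt(n_sub - 3)
                hits += abs(z) > z_crit
            return hits / sims

        p_n = power(n)
        assert 0.75 <= p_n <= 0.86
        assert power(n // 2) < p_n
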