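"""Unit and property tests for the exact statistical primitives."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cistrans.stats import (
    DegenerateTableError,
    UndefinedTestError,
    bh_fdr,
    binomial_exact_two_sided,
    chi2_heterogeneity,
    fisher_exact_two_sided,
    nb_exact_test,
    one_way_anova,
    spearman_correlation,
)

from oracles import (
    bh_oracle,
    binomial_two_sided_oracle,
    fisher_two_sided_oracle,
    spearman_exact_permutation_p,
)


class TestBinomial:
    @pytest.mark.parametrize(
        "k,n,p0,expected",
        [
            (5, 10, 0.5, 1.0),
            (10, 10, 0.5, 0.001953125),
            (0, 10, 0.5, 0.001953125),  # symmetric to the previous case
        ],
    )
    def test_reference_values(self, k, n, p0, expected):
        assert binomial_exact_two_sided(k, n, p0) == pytest.approx(expected, abs=1e-12)

    def test_zero_trials_undefined(self):
        with pytest.raises(UndefinedTestError):
            binomial_exact_two_sided(0, 0, 0.5)

    def test_invalid_null_proportion(self):
        with pytest.raises(ValueError):
            binomial_exact_two_sided(1, 2, 1.0)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        n=st.integers(1, 60),
        frac=st.integers(0, 60),
        p0=st.sampled_from([0.5, 0.3, 0.7, 1 / 3, 0.05, 0.9]),
    )
    def test_matches_enumeration_oracle(self, n, frac, p0):
        k = min(frac, n)
        impl = binomial_exact_two_sided(k, n, p0)
        oracle = binomial_two_sided_oracle(k, n, p0)
        assert impl == pytest.approx(oracle, abs=1e-10)
        assert 0 < impl <= 1


class TestFisher:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[5, 5], [5, 5]], 1.0),
            ([[10, 0], [0, 10]], 2 / 184756),  # 2 / C(20,10)
            ([[3, 1], [1, 3]], 0.4857142857142857),
        ],
    )
    def test_reference_values(self, table, expected):
        assert fisher_exact_two_sided(table) == pytest.approx(expected, abs=1e-12)

    def test_empty_table_undefined(self):
        with pytest.raises(UndefinedTestError):
            fisher_exact_two_sided([[0, 0], [0, 0]])

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        a=st.integers(0, 15),
        b=st.integers(0, 15),
        c=st.integers(0, 15),
        d=st.integers(0, 15),
    )
    def test_matches_enumeration_oracle(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        table = [[a, b], [c, d]]
        impl = fisher_exact_two_sided(table)
        oracle = fisher_two_sided_oracle(table)
        assert impl == pytest.approx(oracle, abs=1e-10)
        assert 0 < impl <= 1


class TestChi2:
    def test_homogeneous_table(self):
        stat, p = chi2_heterogeneity([[50, 50], [50, 50]])
        assert stat == 0.0
        assert p == 1.0

    def test_hand_computed_example(self):
        stat, p = chi2_heterogeneity([[20, 10], [10, 20]])
        assert stat == pytest.approx(20 / 3, abs=1e-10)
        assert p == pytest.approx(0.00982, abs=1e-5)

    def test_identical_rows_give_zero(self):
        stat, _ = chi2_heterogeneity([[7, 3]] * 5)
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_column(self):
        with pytest.raises(DegenerateTableError):
            chi2_heterogeneity([[5, 0], [3, 0]])

    def test_matches_scipy_pearson(self, rng):
        from scipy.stats import chi2_contingency

        for _ in range(20):
            t = rng.integers(1, 50, size=(rng.integers(2, 6), 2))
            stat, p = chi2_heterogeneity(t)
            ref = chi2_contingency(t, correction=False)
            assert stat == pytest.approx(ref.statistic, rel=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)


class TestBH:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.2], [0.2]),
            ([0.001, 0.5], [0.002, 0.5]),
        ],
    )
    def test_reference_values(self, p, expected):
        assert bh_fdr(p) == pytest.approx(expected, abs=1e-14)

    def test_empty_vector(self):
        assert bh_fdr([]).size == 0

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_matches_independent_implementations(self, p):
        impl = bh_fdr(p)
        assert impl == pytest.approx(bh_oracle(p), abs=0)
        # statsmodels as an established independent cross-check
        from statsmodels.stats.multitest import multipletests

        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert impl == pytest.approx(q_sm, abs=1e-12)
        # step-up monotonicity in sorted-p order
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(impl[order]) >= -1e-15).all()
        assert (impl >= np.asarray(p) * 0).all() and (impl <= 1).all()


class TestSpearman:
    def test_monotone_transform_is_perfect(self):
        x = np.arange(1, 8, dtype=float)
        rho, p = spearman_correlation(x, x**2)
        assert rho == 1.0 and p == 0.0
        rho, _ = spearman_correlation(x, x[::-1])
        assert rho == -1.0

    def test_hand_ranked_example(self):
        rho, _ = spearman_correlation([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert rho == pytest.approx(0.8, abs=1e-12)

    def test_constant_vector_undefined(self):
        with pytest.raises(UndefinedTestError):
            spearman_correlation([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])

    def test_t_approximation_tracks_exact_permutation(self):
        # small-n sanity: the approximate p agrees with full enumeration to
        # within a factor adequate for alpha=0.05 decisions
        x = [1, 2, 3, 4, 5, 6]
        y = [2, 1, 4, 3, 6, 5]
        _, p_approx = spearman_correlation(x, y)
        p_exact = spearman_exact_permutation_p(x, y)
        assert p_approx == pytest.approx(p_exact, abs=0.05)


class TestAnova:
    def test_identical_groups(self):
        f, p = one_way_anova([[1.0, 1.0], [1.0, 1.0]])
        assert f == 0.0 and p == 1.0

    def test_hand_computed_f(self):
        f, p = one_way_anova([[1.0, 1.2], [2.0, 2.2]])
        assert f == pytest.approx(50.0, rel=1e-10)
        assert p == pytest.approx(0.0194, abs=1e-3)

    def test_zero_within_variance_sentinel(self):
        f, p = one_way_anova([[1.0, 1.0], [2.0, 2.0]])
        assert np.isinf(f) and p == 0.0

    def test_null_p_values_roughly_uniform(self, rng):
        pvals = []
        for _ in range(400):
            groups = rng.normal(size=(4, 3))
            pvals.append(one_way_anova(list(groups))[1])
        frac = np.mean(np.asarray(pvals) < 0.05)
        assert frac == pytest.approx(0.05, abs=0.03)


class TestNBExact:
    def test_reduces_to_binomial_at_zero_dispersion(self):
        p_nb = nb_exact_test(30, 60, 3, 3, 0.0)
        assert p_nb == pytest.approx(binomial_exact_two_sided(60, 90, 0.5), abs=1e-12)

    def test_balanced_split_is_null(self):
        assert nb_exact_test(100, 100, 3, 3, 0.05) == pytest.approx(1.0, abs=1e-9)

    def test_dispersion_widens_the_null(self):
        # the same imbalance is less surprising under higher dispersion
        p_small = nb_exact_test(100, 200, 3, 3, 0.01)
        p_large = nb_exact_test(100, 200, 3, 3, 0.2)
        assert p_large > p_small
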