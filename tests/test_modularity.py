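import math
from itertools import combinations

import numpy as np
import pytest
from sklearn.base import clone

from florahex.modularity import (
    CovarianceRatio,
    cr_bootstrap_ci,
    cr_permutation_test,
    cr_statistic,
    default_module_assignment,
    normalize_excitations,
)


def brute_force_cr(X, labels):
    """Element-by-element covariance summation, independent of the implementation."""
    X = np.asarray(X, float)
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    S = np.empty((p, p))
    for i in range(p):
        for j in range(p):
            S[i, j] = np.dot(Xc[:, i], Xc[:, j]) / (n - 1)
    mods = sorted(set(labels))
    crs = []
    for m1, m2 in combinations(mods, 2):
        i1 = [i for i in range(p) if labels[i] == m1]
        i2 = [i for i in range(p) if labels[i] == m2]
        num = sum(S[a, b] ** 2 for a in i1 for b in i2)
        d1 = sum(S[a, b] ** 2 for a in i1 for b in i1 if a != b)
        d2 = sum(S[a, b] ** 2 for a in i2 for b in i2 if a != b)
        crs.append(math.sqrt(num / math.sqrt(d1 * d2)))
    return float(np.mean(crs))


class TestCRStatistic:
    def test_perfectly_correlated_four_variables_give_sqrt_two(self, rng):
        """Four scaled copies of one variable split 2/2: all correlation blocks
        are +-1, so tr(S12 S21) = 4 and each within trace is 2 -> CR = sqrt(2)."""
        z = rng.normal(size=40)
        X = np.outer(z, [1.0, 2.0, -1.0, 0.5])
        Xz = (X - X.mean(0)) / X.std(0, ddof=1)
        cr = cr_statistic(Xz, [1, 1, 2, 2])
        assert cr == pytest.approx(math.sqrt(2.0), abs=1e-10)

    def test_independent_blocks_at_large_n_give_small_cr(self, rng):
        n = 2000
        A = rng.normal(size=(n, 1)) + 0.8 * rng.normal(size=(n, 3))
        B = rng.normal(size=(n, 1)) + 0.8 * rng.normal(size=(n, 3))
        X = np.hstack([A, B])
        assert cr_statistic(X, [1] * 3 + [2] * 3) < 0.15

    def test_matches_brute_force_oracle_on_seeded_matrices(self):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(6, 4))
            labels = [1, 1, 2, 2]
            assert cr_statistic(X, labels) == pytest.approx(
                brute_force_cr(X, labels), abs=1e-10
            )

    def test_invariant_to_module_label_permutation(self, rng):
        X = rng.normal(size=(20, 9))
        a = [1] * 3 + [2] * 3 + [3] * 3
        b = [3] * 3 + [1] * 3 + [2] * 3
        assert cr_statistic(X, a) == pytest.approx(cr_statistic(X, b), abs=1e-12)

    def test_invariant_to_reordering_within_modules(self, rng):
        X = rng.normal(size=(15, 6))
        base = cr_statistic(X, [1, 1, 1, 2, 2, 2])
        shuffled = X[:, [2, 0, 1, 5, 3, 4]]
        assert cr_statistic(shuffled, [1, 1, 1, 2, 2, 2]) == pytest.approx(base, abs=1e-12)

    def test_scale_invariance_after_zscoring(self, rng):
        X = rng.normal(size=(25, 6))
        scaled = X * np.array([1, 10, 0.1, 5, 2, 100.0])

        def z(M):
            return (M - M.mean(0)) / M.std(0, ddof=1)

        labels = [1, 1, 2, 2, 3, 3]
        assert cr_statistic(z(scaled), labels) == pytest.approx(
            cr_statistic(z(X), labels), abs=1e-10
        )

    def test_degenerate_inputs_rejected(self, rng):
        with pytest.raises(ValueError, match="3 rows"):
            cr_statistic(rng.normal(size=(2, 4)), [1, 1, 2, 2])
        with pytest.raises(ValueError, match="2 modules"):
            cr_statistic(rng.normal(size=(5, 4)), [1, 1, 1, 1])


class TestNormalizeExcitations:
    def test_columns_standardised(self, table):
        X = normalize_excitations(table)
        assert X.shape == (30, 18)
        np.testing.assert_allclose(X.mean(), 0.0, atol=1e-12)
        np.testing.assert_allclose(X.std(ddof=1), 1.0, atol=1e-12)

    def test_constant_column_named_in_error(self, table):
        t = table.copy()
        t.loc[(t.structure == "sepal") & (t.position == "tip"), "E_uv"] = 0.5
        with pytest.raises(ValueError, match="sepal_tip:E_uv"):
            normalize_excitations(t)

    def test_incomplete_design_rejected(self, table):
        with pytest.raises(ValueError, match="incomplete"):
            normalize_excitations(table.iloc[:-1])


class TestPermutationTest:
    def test_p_value_uses_add_one_convention(self, rng):
        X = rng.normal(size=(20, 6))
        res = cr_permutation_test(X, [1, 1, 1, 2, 2, 2], n_perm=999, rng=0)
        expected = (1 + np.sum(res.perm_values <= res.observed_cr + 1e-15)) / 1000
        assert res.p_value == pytest.approx(expected)
        assert 0 < res.p_value <= 1

    def test_reproducible_under_fixed_seed(self, rng):
        X = rng.normal(size=(20, 6))
        r1 = cr_permutation_test(X, [1, 1, 1, 2, 2, 2], n_perm=300, rng=7)
        r2 = cr_permutation_test(X, [1, 1, 1, 2, 2, 2], n_perm=300, rng=7)
        np.testing.assert_array_equal(r1.perm_values, r2.perm_values)
        assert r1.p_value == r2.p_value

    def test_tiny_n_perm_warns(self, rng):
        X = rng.normal(size=(20, 6))
        with pytest.warns(UserWarning, match="n_perm"):
            cr_permutation_test(X, [1, 1, 1, 2, 2, 2], n_perm=50, rng=0)

    def test_planted_modularity_detected(self, table):
        X = normalize_excitations(table).to_numpy()
        res = cr_permutation_test(X, default_module_assignment(), n_perm=999, rng=3)
        assert res.observed_cr < 1.0
        assert res.p_value < 0.05


class TestBootstrapCI:
    def test_single_resample_collapses_interval(self, rng):
        X = rng.normal(size=(15, 6))
        lo, hi = cr_bootstrap_ci(X, [1, 1, 1, 2, 2, 2], n_boot=1, rng=0)
        assert lo == hi

    def test_reproducible_under_fixed_seed(self, rng):
        X = rng.normal(size=(15, 6))
        ci1 = cr_bootstrap_ci(X, [1, 1, 1, 2, 2, 2], n_boot=200, rng=5)
        ci2 = cr_bootstrap_ci(X, [1, 1, 1, 2, 2, 2], n_boot=200, rng=5)
        assert ci1 == ci2

    def test_interval_brackets_point_estimate_on_default_data(self, table):
        X = normalize_excitations(table).to_numpy()
        labels = default_module_assignment()
        cr = cr_statistic(X, labels)
        lo, hi = cr_bootstrap_ci(X, labels, n_boot=400, rng=1)
        assert lo <= cr <= hi

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 10"):
            cr_bootstrap_ci(rng.normal(size=(6, 4)), [1, 1, 2, 2], n_boot=10)


class TestCovarianceRatioEstimator:
    def test_sklearn_conventions(self):
        est = CovarianceRatio(n_permutations=200, n_bootstrap=50, random_state=0)
        est2 = clone(est)
        assert est2.get_params()["n_permutations"] == 200

    def test_fit_exposes_result_attributes(self, table):
        X = normalize_excitations(table).to_numpy()
        est = CovarianceRatio(n_permutations=500, n_bootstrap=100, random_state=0).fit(X)
        assert est.n_features_in_ == 18
        assert est.null_distribution_.shape == (500,)
        assert 0 < est.cr_ and est.ci_[0] <= est.ci_[1]
        assert 0 < est.p_value_ <= 1

    def test_default_assignment_is_twelve_three_three(self):
        labels = default_module_assignment()
        _, counts = np.unique(labels, return_counts=True)
        assert sorted(counts) == [3, 3, 12]
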