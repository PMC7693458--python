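import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from florahex.calibration import purity_anova_null_pvalues
from florahex.distances import PATCHES
from florahex.stats import (
    CircularTestResult,
    bh_fdr,
    block_anova,
    circ_sd_deg,
    circular_anova,
    compact_letters,
    pairwise_patch_tests,
    purity_block_anova,
    sqrt_distance_anova,
    watson_u2,
)


def _bh_oracle(p, q):
    """Direct statement of the step-up rule, independent of the implementation."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    thresh = q * (np.arange(m) + 1) / m
    below = p[order] <= thresh
    k = np.max(np.nonzero(below)[0]) + 1 if below.any() else 0
    reject = np.zeros(m, bool)
    reject[order[:k]] = True
    return reject


class TestBHFDR:
    def test_single_pvalue(self):
        adj, rej = bh_fdr([0.04], q=0.05)
        assert adj[0] == pytest.approx(0.04)
        assert rej[0]

    def test_all_ones_rejects_nothing(self):
        _, rej = bh_fdr([1.0] * 5)
        assert not rej.any()

    @pytest.mark.parametrize(
        "pvals",
        [
            (0.005, 0.01, 0.03, 0.04),
            (0.01, 0.02, 0.03, 0.04, 0.05),
        ],
    )
    def test_printed_examples_all_rejected(self, pvals):
        _, rej = bh_fdr(pvals, q=0.05)
        assert rej.all()
        assert _bh_oracle(pvals, 0.05).all()

    def test_matches_step_up_oracle_on_random_sets(self, rng):
        for _ in range(50):
            p = rng.uniform(0, 1, rng.integers(1, 20))
            _, rej = bh_fdr(p, q=0.05)
            np.testing.assert_array_equal(rej, _bh_oracle(p, 0.05))

    def test_bh_rejections_superset_of_bonferroni(self, rng):
        for _ in range(20):
            p = rng.uniform(0, 0.2, 15)
            _, rej = bh_fdr(p, q=0.05)
            bonf = p <= 0.05 / len(p)
            assert np.all(rej[bonf])

    def test_empty_input(self):
        adj, rej = bh_fdr([])
        assert adj.size == 0 and rej.size == 0


def _balanced_table(n_plants, effects=None, seed=0, noise=1.0):
    rng = np.random.default_rng(seed)
    rows = []
    for plant in range(n_plants):
        b = rng.normal(0, 1)
        for s, p in PATCHES:
            y = b + rng.normal(0, noise) + (effects or {}).get((s, p), 0.0)
            rows.append(dict(plant_id=plant, structure=s, position=p, purity=y))
    return pd.DataFrame(rows)


class TestBlockAnova:
    def test_missing_patch_is_an_error(self):
        t = _balanced_table(5).iloc[:-1]
        with pytest.raises(ValueError, match="unbalanced"):
            purity_block_anova(t)

    def test_matches_statsmodels_ols_decomposition(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        t = _balanced_table(8, effects={("labellum", "tip"): 1.0}, seed=3)
        mine = purity_block_anova(t)
        fit = smf.ols(
            "purity ~ C(plant_id) + C(structure) * C(position)", data=t
        ).fit()
        ref = sm.stats.anova_lm(fit, typ=2)
        for term, name in [
            ("C(structure)", "structure"),
            ("C(position)", "position"),
            ("C(structure):C(position)", "structure:position"),
        ]:
            assert mine.loc[name, "F"] == pytest.approx(ref.loc[term, "F"], rel=1e-9)
            assert mine.loc[name, "p"] == pytest.approx(ref.loc[term, "PR(>F)"], rel=1e-9)

    def test_matches_matrix_projection_oracle_on_four_plant_toy(self):
        """F from explicit design-matrix least squares (full vs reduced model)."""
        t = _balanced_table(4, effects={("petal", "base"): 0.8}, seed=5)
        y = t["purity"].to_numpy()

        def dummies(col):
            return pd.get_dummies(t[col], drop_first=True, dtype=float).to_numpy()

        inter = pd.get_dummies(
            t["structure"].astype(str) + ":" + t["position"].astype(str),
            drop_first=True, dtype=float,
        ).to_numpy()
        ones = np.ones((len(t), 1))
        X_full = np.hstack([ones, dummies("plant_id"), inter])  # saturated in cells + block
        X_red = np.hstack([ones, dummies("plant_id"), dummies("structure"), dummies("position")])

        def rss(X):
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ beta
            return float(r @ r)

        df_err = len(t) - np.linalg.matrix_rank(X_full)
        q = np.linalg.matrix_rank(X_full) - np.linalg.matrix_rank(X_red)
        f_oracle = ((rss(X_red) - rss(X_full)) / q) / (rss(X_full) / df_err)
        mine = purity_block_anova(t)
        assert mine.loc["structure:position", "F"] == pytest.approx(f_oracle, rel=1e-9)
        assert int(mine.loc["structure:position", "df"]) == q == 2
        assert int(mine.loc["residual", "df"]) == df_err

    def test_null_interaction_pvalues_approximately_uniform(self):
        p = purity_anova_null_pvalues(n_datasets=200, seed=10)
        assert sps.kstest(p, "uniform").pvalue > 0.01

    def test_constant_response_gives_zero_f(self):
        t = _balanced_table(4)
        t["purity"] = 1.0
        out = purity_block_anova(t)
        assert out.loc["structure:position", "F"] == 0.0


class TestSqrtDistanceAnova:
    def test_record_counts_and_backtransform(self):
        rng = np.random.default_rng(2)
        rows = []
        for a in range(10):
            for b in range(a + 1, 10):
                for s, p in PATCHES:
                    rows.append(dict(plant_a=a, plant_b=b, structure=s, position=p,
                                     euclidean=rng.uniform(0.01, 0.2)))
        rec = pd.DataFrame(rows)
        out = sqrt_distance_anova(rec)
        assert int(out.loc["residual", "df"]) == 5 * (45 - 1)
        means = out.attrs["patch_means_backtransformed"]
        assert len(means) == 6 and all(v > 0 for v in means.values())

    def test_equal_distances_give_zero_f(self):
        rows = [
            dict(plant_a=a, plant_b=b, structure=s, position=p, euclidean=0.04)
            for a in range(5) for b in range(a + 1, 5) for s, p in PATCHES
        ]
        out = sqrt_distance_anova(pd.DataFrame(rows))
        assert out.loc["structure", "F"] == 0.0
        assert out.loc["structure:position", "F"] == 0.0


class TestPairwisePatchTests:
    def test_fifteen_comparisons(self):
        out = pairwise_patch_tests(_balanced_table(10))
        assert len(out) == 15

    def test_identical_patches_flagged_degenerate(self):
        t = _balanced_table(6)
        wide = t.pivot_table(index="plant_id", columns=["structure", "position"],
                             values="purity")
        t2 = wide.copy()
        t2[("sepal", "tip")] = t2[("sepal", "base")]
        t = t2.stack([0, 1], future_stack=True).rename("purity").reset_index()
        out = pairwise_patch_tests(t)
        pair = {"sepal_tip", "sepal_base"}
        row = out[out.apply(lambda r: {r.patch_a, r.patch_b} == pair, axis=1)]
        assert row["degenerate"].item()
        assert not row["reject"].item()

    def test_planted_difference_detected_and_lettered(self):
        t = _balanced_table(20, effects={("labellum", "tip"): 3.0}, seed=8)
        out = pairwise_patch_tests(t)
        hit = out[(out.patch_a == "labellum_tip") | (out.patch_b == "labellum_tip")]
        assert hit["reject"].all()
        letters = out.attrs["letters"]
        assert letters["labellum_tip"] not in {
            letters[k] for k in letters if k != "labellum_tip"
        }


class TestCompactLetters:
    def test_no_differences_single_letter(self):
        out = compact_letters(["a", "b", "c"], set())
        assert len(set(out.values())) == 1

    def test_all_different_all_distinct(self):
        labs = ["a", "b", "c"]
        out = compact_letters(labs, {("a", "b"), ("a", "c"), ("b", "c")})
        assert len({out[l] for l in labs}) == 3


class TestCircularAnova:
    def test_identical_angles_give_zero_f(self):
        res = circular_anova([[10.0] * 5, [10.0] * 5])
        assert res.statistic == 0.0

    def test_shifted_groups_strongly_rejected(self, rng):
        a = np.degrees(sps.vonmises.rvs(20, size=30, random_state=rng)) % 360
        b = (a + 90.0) % 360
        res = circular_anova([a, b])
        assert res.p_value < 1e-6

    def test_undefined_mean_direction_is_an_error(self):
        with pytest.raises(ValueError, match="resultant"):
            circular_anova([[0.0, 90.0, 180.0, 270.0], [10.0, 20.0, 30.0]])

    def test_dispersed_samples_warn(self, rng):
        a = rng.uniform(0, 360, 25)
        b = rng.uniform(0, 360, 25)
        try:
            with pytest.warns(UserWarning, match="kappa"):
                circular_anova([a, b])
        except ValueError:
            pass  # near-zero resultant is a legitimate rejection of uniform data


class TestWatsonU2:
    def test_duplicated_sample_is_clearly_null(self, rng):
        a = np.degrees(sps.vonmises.rvs(5, size=20, random_state=rng)) % 360
        res = watson_u2(a, a.copy(), n_perm=999, rng=1)
        assert res.p_value >= 0.5

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            watson_u2([1, 2, 3], [4, 5, 6, 7, 8, 9, 10, 11])

    def test_opposed_concentrated_samples_rejected_at_conservative_level(self, rng):
        a = np.degrees(sps.vonmises.rvs(20, size=30, random_state=rng)) % 360
        b = (a + 180.0) % 360
        res = watson_u2(a, b, n_perm=1999, alpha=0.001, rng=2)
        assert res.p_value <= 0.001
        assert res.reject

    def test_statistic_invariant_to_rotation_of_origin(self, rng):
        a = np.degrees(sps.vonmises.rvs(8, size=25, random_state=rng)) % 360
        b = np.degrees(sps.vonmises.rvs(8, size=25, random_state=rng)) % 360
        s0 = watson_u2(a, b, n_perm=100, rng=0).statistic
        s1 = watson_u2((a + 123.4) % 360, (b + 123.4) % 360, n_perm=100, rng=0).statistic
        assert s1 == pytest.approx(s0, abs=1e-9)

    def test_reproducible_under_fixed_seed(self, rng):
        a = rng.uniform(0, 360, 20)
        b = rng.uniform(0, 360, 20)
        r1 = watson_u2(a, b, n_perm=500, rng=42)
        r2 = watson_u2(a, b, n_perm=500, rng=42)
        assert r1.p_value == r2.p_value


class TestCircularDescriptors:
    def test_circular_sd_decreases_with_concentration(self, rng):
        tight = np.degrees(sps.vonmises.rvs(50, size=200, random_state=rng))
        loose = np.degrees(sps.vonmises.rvs(2, size=200, random_state=rng))
        assert circ_sd_deg(tight) < circ_sd_deg(loose)
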