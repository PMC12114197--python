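"""ANOVA/Tukey letters, PCA, Mantel, RF importance, path analysis."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from skbio import DistanceMatrix
from skbio.stats.distance import mantel as skbio_mantel

from soilemf import (
    AbundanceTable,
    PathAnalysis,
    anova_tukey,
    mantel,
    mantel_grid,
    path_analysis,
    pca_summary,
    rf_importance,
    simulate_path_data,
)
from soilemf.drivers import (
    _insert_absorb,
    bray_curtis_distance,
    euclidean_distance,
)


class TestAnovaTukey:
    def test_separated_group_gets_distinct_letter(self, rng):
        vals = pd.Series(
            np.r_[rng.normal(0, 0.1, 3), rng.normal(0, 0.1, 3), rng.normal(10, 0.1, 3)]
        )
        grp = pd.Series(["g1"] * 3 + ["g2"] * 3 + ["g3"] * 3)
        rep = anova_tukey(vals, grp)
        letters = rep.table["letters"]
        assert letters["g1"] == letters["g2"]
        assert letters["g3"] not in (letters["g1"], letters["g2"])
        assert rep.p_value < 1e-6

    def test_null_groups_share_a_letter_most_seeds(self):
        shares = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            vals = pd.Series(rng.normal(0, 1, 15))
            grp = pd.Series(np.repeat(list("abcde"), 3))
            letters = anova_tukey(vals, grp).table["letters"]
            if len(set(letters)) == 1:
                shares += 1
        assert shares >= 9

    def test_two_groups_matches_pooled_t_test(self, rng):
        vals = pd.Series(np.r_[rng.normal(0, 1, 6), rng.normal(1, 1, 6)])
        grp = pd.Series(["a"] * 6 + ["b"] * 6)
        rep = anova_tukey(vals, grp)
        # with k=2 the Tukey q test reduces to the pooled two-sample t test
        t_p = stats.ttest_ind(vals[:6], vals[6:]).pvalue
        assert float(rep.pairwise["p-adj"].iloc[0]) == pytest.approx(t_p, abs=5e-4)
        assert rep.p_value == pytest.approx(t_p, rel=1e-6)

    @pytest.mark.parametrize("n_groups", [3, 4, 5, 6])
    def test_letter_display_reconstructs_significance(self, n_groups, rng):
        """Insert-and-absorb letters vs brute force: groups share a letter
        iff their pair is not significant, for random significance sets."""
        groups = [f"g{i}" for i in range(n_groups)]
        pairs = list(itertools.combinations(groups, 2))
        for _ in range(20):
            sig = {frozenset(p) for p in pairs if rng.random() < 0.4}
            letters = _insert_absorb(groups, sig)
            for a, b in pairs:
                share = bool(set(letters[a]) & set(letters[b]))
                assert share == (frozenset((a, b)) not in sig)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            anova_tukey(pd.Series([1.0, 2.0]), pd.Series(["a", "a"]))
        with pytest.raises(ValueError, match="fewer than 2"):
            anova_tukey(pd.Series([1.0, 2.0, 3.0]), pd.Series(["a", "a", "b"]))
        with pytest.raises(ValueError, match="variance"):
            anova_tukey(
                pd.Series([1.0, 1.0, 2.0, 2.0]), pd.Series(["a", "a", "b", "b"])
            )


class TestPCA:
    def test_variance_explained_sums_to_100(self, rng):
        table = AbundanceTable(
            pd.DataFrame(rng.integers(1, 100, size=(10, 12)))
        )
        _, pct = pca_summary(table)
        assert pct.sum() == pytest.approx(100.0, abs=1e-9)

    def test_duplicated_samples_coincide(self, rng):
        data = pd.DataFrame(rng.normal(size=(5, 4)))
        data.iloc[4] = data.iloc[0]
        scores, _ = pca_summary(data)
        assert np.allclose(scores.iloc[4], scores.iloc[0], atol=1e-9)

    def test_rank_two_input_explained_by_two_axes(self, rng):
        u = rng.normal(size=(8, 2))
        v = rng.normal(size=(2, 6))
        scores, pct = pca_summary(pd.DataFrame(u @ v))
        assert pct.iloc[:2].sum() == pytest.approx(100.0, abs=1e-6)

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="3 samples"):
            pca_summary(pd.DataFrame([[1, 2], [3, 4]]))


class TestMantel:
    @pytest.fixture()
    def distances(self, rng):
        x = pd.DataFrame(rng.normal(size=(10, 4)), index=[f"s{i}" for i in range(10)])
        y = pd.DataFrame(rng.normal(size=(10, 4)), index=[f"s{i}" for i in range(10)])
        return euclidean_distance(x), euclidean_distance(y)

    def test_identity_gives_r1_and_minimal_p(self, distances):
        d1, _ = distances
        res = mantel(d1, d1, n_permutations=199, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 200)

    def test_relabeling_invariance(self, distances):
        d1, d2 = distances
        mapping = {f"s{i}": f"x{i}" for i in range(10)}
        r1 = mantel(d1, d2, 99, seed=3).r
        d1r = d1.rename(index=mapping, columns=mapping)
        d2r = d2.rename(index=mapping, columns=mapping)
        assert mantel(d1r, d2r, 99, seed=3).r == pytest.approx(r1)

    def test_statistic_matches_skbio(self, distances):
        d1, d2 = distances
        ours = mantel(d1, d2, n_permutations=0, seed=0)
        ref_r, _, _ = skbio_mantel(
            DistanceMatrix(d1.to_numpy(), ids=list(d1.index)),
            DistanceMatrix(d2.to_numpy(), ids=list(d2.index)),
            method="spearman",
            permutations=0,
        )
        assert ours.r == pytest.approx(float(ref_r), abs=1e-12)

    def test_mismatched_ids_rejected(self, distances):
        d1, d2 = distances
        d2 = d2.rename(index={"s0": "zz"}, columns={"s0": "zz"})
        with pytest.raises(ValueError, match="different samples"):
            mantel(d1, d2)

    def test_zero_variance_rejected(self):
        ids = [f"s{i}" for i in range(6)]
        flat = pd.DataFrame(1.0 - np.eye(6), index=ids, columns=ids)
        with pytest.raises(ValueError, match="zero-variance"):
            mantel(flat, flat)

    def test_grid_shape_and_bh(self, rng):
        indicators = pd.DataFrame(
            rng.normal(size=(8, 3)),
            index=[f"s{i}" for i in range(8)],
            columns=["a", "b", "c"],
        )
        table = AbundanceTable(
            pd.DataFrame(
                rng.integers(1, 50, size=(8, 10)), index=indicators.index
            )
        )
        grid = mantel_grid(indicators, {"bacteria": table}, n_permutations=49, seed=0)
        assert len(grid) == 3
        assert (grid["p_adj"] >= grid["p"] - 1e-12).all()

    def test_bray_curtis_matches_scipy_definition(self, small_table):
        d = bray_curtis_distance(small_table)
        a = small_table.counts.loc["s1"].to_numpy(float)
        b = small_table.counts.loc["s2"].to_numpy(float)
        expected = np.abs(a - b).sum() / (a + b).sum()
        assert d.loc["s1", "s2"] == pytest.approx(expected)


class TestRandomForest:
    def test_informative_predictor_ranked_first(self, rng):
        X = pd.DataFrame(rng.normal(size=(100, 6)), columns=list("abcdef"))
        y = 3 * X["a"] + rng.normal(size=100)
        rep = rf_importance(X, y, n_trees=100, seed=0)
        assert rep.index[0] == "a"

    def test_pure_noise_importances_center_on_zero(self):
        signs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd"))
            y = pd.Series(rng.normal(size=40))
            rep = rf_importance(X, y, n_trees=50, seed=seed)
            signs.extend(np.sign(rep["importance_pct"]))
        # under the null positive and negative importances are about equally
        # likely; a strong positive excess would indicate leakage
        assert abs(np.mean(signs)) < 0.5

    def test_duplicated_predictor_does_not_inflate_unrelated_one(self, rng):
        X = pd.DataFrame(rng.normal(size=(80, 4)), columns=list("abcd"))
        y = 2 * X["a"] + rng.normal(size=80)
        base = rf_importance(X, y, n_trees=100, seed=1)
        X2 = X.assign(a_copy=X["a"])
        dup = rf_importance(X2, y, n_trees=100, seed=1)
        assert dup.loc["c", "importance_pct"] <= base.loc["c", "importance_pct"] + 25

    def test_input_validation(self, rng):
        X = pd.DataFrame(rng.normal(size=(12, 3)))
        with pytest.raises(ValueError, match="constant"):
            rf_importance(X, pd.Series(np.ones(12)))
        with pytest.raises(ValueError, match=">= 10"):
            rf_importance(X.iloc[:5], pd.Series(rng.normal(size=5)))

    def test_deterministic_under_seed(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        y = X["a"] + rng.normal(size=30)
        r1 = rf_importance(X, y, n_trees=50, seed=7)
        r2 = rf_importance(X, y, n_trees=50, seed=7)
        pd.testing.assert_frame_equal(r1, r2)


class TestPathAnalysis:
    def test_single_parent_equals_pearson_correlation(self, rng):
        data = pd.DataFrame(rng.normal(size=(50, 2)), columns=["x", "y"])
        fit = path_analysis(data, [("x", "y")])
        expected = np.corrcoef(data["x"], data["y"])[0, 1]
        assert fit.coefficients_["coefficient"].iloc[0] == pytest.approx(
            expected, abs=1e-10
        )

    def test_recovers_generating_coefficients(self):
        truth = {("A", "D"): 0.6, ("B", "D"): 0.4, ("C", "D"): -0.3}
        data = simulate_path_data(truth, n=500, seed=4)
        fit = path_analysis(data, list(truth))
        for row in fit.coefficients_.itertuples():
            assert row.coefficient == pytest.approx(
                truth[(row.parent, row.child)], abs=0.1
            )

    def test_null_coefficient_within_two_se(self):
        hits = 0
        for seed in range(20):
            data = simulate_path_data({("A", "C"): 0.5, ("B", "C"): 0.0},
                                      n=200, seed=seed)
            fit = path_analysis(data, [("A", "C"), ("B", "C")])
            row = fit.coefficients_.set_index("parent").loc["B"]
            if abs(row["coefficient"]) <= 2 * row["se"]:
                hits += 1
        assert hits >= 18

    def test_cyclic_model_rejected(self, rng):
        data = pd.DataFrame(rng.normal(size=(30, 2)), columns=["x", "y"])
        with pytest.raises(ValueError, match="cyclic"):
            PathAnalysis([("x", "y"), ("y", "x")]).fit(data)

    def test_collinear_parents_rejected(self, rng):
        x = rng.normal(size=40)
        data = pd.DataFrame({"a": x, "b": 2 * x, "y": rng.normal(size=40)})
        with pytest.raises(ValueError, match="collinear"):
            path_analysis(data, [("a", "y"), ("b", "y")])

    def test_missing_variable_and_small_n_rejected(self, rng):
        data = pd.DataFrame(rng.normal(size=(30, 2)), columns=["x", "y"])
        with pytest.raises(ValueError, match="absent"):
            path_analysis(data, [("z", "y")])
        with pytest.raises(ValueError, match="too few"):
            path_analysis(data.iloc[:3], [("x", "y")])

    def test_r2_reported_per_endogenous_variable(self):
        data = simulate_path_data({("A", "B"): 0.7, ("B", "C"): 0.5}, n=300, seed=1)
        fit = path_analysis(data, [("A", "B"), ("B", "C")])
        assert set(fit.r2_.index) == {"B", "C"}
        assert 0 < fit.r2_["B"] < 1
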