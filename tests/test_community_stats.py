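import io

import numpy as np
import pandas as pd
import pytest
import skbio
from scipy import stats
from scipy.spatial.distance import pdist, squareform

import terraomics as t


def _counts(vals, prefix="s"):
    vals = np.asarray(vals, dtype=float)
    return t.FeatureTable(vals, [f"{prefix}{i}" for i in range(vals.shape[0])],
                          [chr(65 + j) for j in range(vals.shape[1])], "counts")


@pytest.fixture
def caterpillar_tree():
    return skbio.TreeNode.read(io.StringIO(
        "((((A:0.1,B:0.2):0.3,C:0.4):0.5,D:0.6):0.7,E:0.8):0;"))


class TestAlphaDiversity:
    def test_richness(self):
        table = _counts([[1, 0, 2, 0], [5, 5, 5, 5]])
        vals = t.alpha_diversity(table, "richness")
        assert vals.tolist() == [2.0, 4.0]

    def test_faith_pd_star_tree(self, star_tree):
        table = _counts([[3, 4, 0, 0], [1, 1, 1, 1]])
        pd_vals = t.alpha_diversity(table, "faith_pd", tree=star_tree)
        assert pd_vals.iloc[0] == pytest.approx(2.0)
        assert pd_vals.iloc[1] == pytest.approx(4.0)

    def test_faith_pd_matches_branch_enumeration(self, caterpillar_tree):
        rng = np.random.default_rng(0)
        tree = caterpillar_tree
        for _ in range(20):
            x = rng.integers(0, 5, size=(1, 5)).astype(float)
            if x.sum() == 0:
                continue
            table = _counts(x)
            mine = t.alpha_diversity(table, "faith_pd", tree=tree).iloc[0]
            # oracle: walk every branch, add length if any descendant tip observed
            present = {n for n, v in zip("ABCDE", x[0]) if v > 0}
            total = 0.0
            for node in tree.traverse(include_self=False):
                tips = {tp.name for tp in node.tips(include_self=True)}
                if tips & present:
                    total += node.length
            assert mine == pytest.approx(total, abs=1e-12)

    def test_weighted_faith_pd_matches_enumeration(self, caterpillar_tree):
        rng = np.random.default_rng(1)
        x = rng.integers(1, 9, size=(1, 5)).astype(float)
        table = _counts(x)
        mine = t.alpha_diversity(table, "weighted_faith_pd",
                                 tree=caterpillar_tree).iloc[0]
        rel = dict(zip("ABCDE", x[0] / x[0].sum()))
        total = 0.0
        for node in caterpillar_tree.traverse(include_self=False):
            tips = [tp.name for tp in node.tips(include_self=True)]
            total += node.length * np.mean([rel[n] for n in tips])
        assert mine == pytest.approx(total, abs=1e-12)

    def test_pd_without_tree_errors(self):
        with pytest.raises(ValueError, match="phylogeny"):
            t.alpha_diversity(_counts([[1, 1]]), "faith_pd")

    def test_faith_pd_monotone_in_observed_tips(self, caterpillar_tree):
        base = np.array([[1.0, 0, 0, 0, 0]])
        grown = base.copy()
        pd0 = t.alpha_diversity(_counts(base), "faith_pd", tree=caterpillar_tree).iloc[0]
        for j in range(1, 5):
            grown[0, j] = 1.0
            pd1 = t.alpha_diversity(_counts(grown), "faith_pd",
                                    tree=caterpillar_tree).iloc[0]
            assert pd1 >= pd0
            pd0 = pd1


class TestWeightedUnifrac:
    def test_identical_samples_zero(self, star_tree):
        table = _counts([[1, 2, 3, 4], [2, 4, 6, 8]])
        dm = t.weighted_unifrac(table, star_tree)
        assert dm.data[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_star_tree_disjoint_mass(self, star_tree):
        table = _counts([[10, 0, 0, 0], [0, 10, 0, 0]])
        dm = t.weighted_unifrac(table, star_tree)
        assert dm.data[0, 1] == pytest.approx(2.0)

    def test_matches_skbio_on_random_instances(self, caterpillar_tree):
        rng = np.random.default_rng(2)
        x = rng.integers(1, 30, size=(6, 5)).astype(float)
        table = _counts(x)
        mine = t.weighted_unifrac(table, caterpillar_tree)
        ref = skbio.diversity.beta_diversity(
            "weighted_unifrac", x, ids=table.sample_ids,
            taxa=list("ABCDE"), tree=caterpillar_tree)
        np.testing.assert_allclose(mine.data, ref.data, atol=1e-12)

    def test_zero_sample_errors(self, star_tree):
        with pytest.raises(ValueError, match="zero total"):
            t.weighted_unifrac(_counts([[1, 1, 0, 0], [0, 0, 0, 0]]), star_tree)


class TestPermanova:
    def test_matches_hand_formula_on_toy(self):
        x = np.array([[0.0], [0.1], [0.2], [5.0], [5.1], [5.2]])
        d = squareform(pdist(x))
        dm = t.make_distance_matrix(d, [f"s{i}" for i in range(6)])
        g = ["a", "a", "a", "b", "b", "b"]
        res = t.permanova(dm, g, n_permutations=99, seed=0)
        # direct sums of squared distances
        d2 = d ** 2
        n, k = 6, 2
        ss_total = d2[np.triu_indices(6, 1)].sum() / n
        ss_within = (d2[:3, :3][np.triu_indices(3, 1)].sum() / 3
                     + d2[3:, 3:][np.triu_indices(3, 1)].sum() / 3)
        f_hand = ((ss_total - ss_within) / (k - 1)) / (ss_within / (n - k))
        assert res.statistic == pytest.approx(f_hand, rel=1e-12)

    def test_invariant_to_sample_order(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(8, 2))
        d = squareform(pdist(x))
        ids = [f"s{i}" for i in range(8)]
        g = pd.Series(["a"] * 4 + ["b"] * 4, index=ids)
        f1 = t.permanova(t.make_distance_matrix(d, ids), g, 9, seed=0).statistic
        perm = rng.permutation(8)
        dm2 = t.make_distance_matrix(d[np.ix_(perm, perm)], [ids[i] for i in perm])
        f2 = t.permanova(dm2, g, 9, seed=0).statistic
        assert f1 == pytest.approx(f2, rel=1e-12)

    def test_separated_clusters_reach_min_p(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 0.1, size=(10, 2))
        b = rng.normal(20, 0.1, size=(10, 2))
        d = squareform(pdist(np.vstack([a, b])))
        dm = t.make_distance_matrix(d, [f"s{i}" for i in range(20)])
        res = t.permanova(dm, ["a"] * 10 + ["b"] * 10, 999, seed=1)
        assert res.p_value == pytest.approx(0.001)

    def test_singleton_grouping_errors(self):
        d = squareform(pdist(np.arange(4.0)[:, None]))
        dm = t.make_distance_matrix(d, list("wxyz"))
        with pytest.raises(ValueError, match="singleton"):
            t.permanova(dm, ["a", "b", "c", "d"], 9, seed=0)


class TestMantel:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(6)
        d = squareform(pdist(rng.normal(size=(8, 3))))
        dm = t.make_distance_matrix(d, [f"s{i}" for i in range(8)])
        res = t.mantel(dm, dm, 99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_rank_reversal_gives_minus_one(self):
        rng = np.random.default_rng(7)
        d = squareform(pdist(rng.normal(size=(7, 3))))
        rev = d.max() + 1.0 - d
        np.fill_diagonal(rev, 0.0)
        ids = [f"s{i}" for i in range(7)]
        res = t.mantel(t.make_distance_matrix(d, ids),
                       t.make_distance_matrix(rev, ids), 99, seed=0)
        assert res.statistic == pytest.approx(-1.0)

    def test_too_few_shared_samples_errors(self):
        a = t.make_distance_matrix(np.zeros((2, 2)), ["s1", "s2"])
        with pytest.raises(ValueError, match=">=3 shared"):
            t.mantel(a, a, 9, seed=0)


class TestMultilevelSpearman:
    def test_single_group_equals_ordinary_spearman(self):
        rng = np.random.default_rng(8)
        x = pd.Series(rng.normal(size=25))
        y = pd.Series(x + rng.normal(0, 0.7, size=25))
        g = pd.Series(["only"] * 25)
        res = t.multilevel_spearman(x, y, g)
        assert res.statistic == pytest.approx(stats.spearmanr(x, y).statistic,
                                              abs=1e-12)

    def test_removes_study_level_offsets(self):
        # Simpson's paradox: perfect within-group monotonicity, opposite
        # group offsets -> multilevel rho = 1 while pooled Spearman < 1
        x = pd.Series(np.r_[np.arange(10.0), np.arange(10.0)])
        y = pd.Series(np.r_[np.arange(10.0) + 100, np.arange(10.0) - 100])
        g = pd.Series(["a"] * 10 + ["b"] * 10)
        res = t.multilevel_spearman(x, y, g)
        assert res.statistic == pytest.approx(1.0)
        assert stats.spearmanr(x, y).statistic < 1.0

    def test_all_singleton_groups_error(self):
        x = pd.Series([1.0, 2.0])
        g = pd.Series(["a", "b"])
        with pytest.raises(ValueError, match="size 1"):
            t.multilevel_spearman(x, x, g)

    def test_bh_family_adjustment_attached(self):
        rng = np.random.default_rng(9)
        x = pd.Series(rng.normal(size=20))
        y = pd.Series(rng.normal(size=20))
        g = pd.Series(["a"] * 10 + ["b"] * 10)
        res = t.multilevel_spearman(x, y, g, bh_family=[0.001, 0.5])
        assert res.adjusted_p is not None
        assert res.adjusted_p >= res.p_value


class TestKruskalWallis:
    def test_hand_computed_statistic(self):
        vals = pd.Series([1.0, 2, 3, 4, 5, 6])
        grp = pd.Series(["a"] * 3 + ["b"] * 3)
        res = t.kruskal_wallis(vals, grp)
        assert res.statistic == pytest.approx(3.857142857, abs=1e-6)

    def test_identical_groups_zero(self):
        vals = pd.Series([1.0, 2, 3, 1, 2, 3])
        grp = pd.Series(["a"] * 3 + ["b"] * 3)
        assert t.kruskal_wallis(vals, grp).statistic == pytest.approx(0.0)

    def test_constant_values(self):
        vals = pd.Series([2.0, 2, 2, 2])
        grp = pd.Series(["a", "a", "b", "b"])
        res = t.kruskal_wallis(vals, grp)
        assert res.statistic == 0.0
        assert res.p_value == 1.0


class TestLogRatio:
    def test_basic_value(self):
        table = _counts([[100.0, 10.0]])
        lr = t.log_ratio(table, ["A"], ["B"])
        assert lr.iloc[0] == pytest.approx(np.log(10.0))

    def test_equal_sums_zero(self):
        table = _counts([[5.0, 5.0]])
        assert t.log_ratio(table, ["A"], ["B"]).iloc[0] == pytest.approx(0.0)

    def test_zero_denominator_sample_dropped(self):
        table = _counts([[5.0, 5.0], [5.0, 0.0]])
        lr = t.log_ratio(table, ["A"], ["B"])
        assert list(lr.index) == ["s0"]

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            t.log_ratio(_counts([[1.0, 1.0]]), ["A"], ["A", "B"])


class TestWelch:
    def test_identical_groups(self):
        v = pd.Series([1.0, 2, 3, 1, 2, 3], index=list("abcdef"))
        mask = pd.Series([True] * 3 + [False] * 3, index=v.index)
        res = t.two_group_ttest(v, mask)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_welch_formula(self):
        a = np.array([1.0, 2, 3, 4, 5])
        b = np.array([2.0, 4, 6, 8, 12])
        v = pd.Series(np.r_[a, b], index=[f"s{i}" for i in range(10)])
        mask = pd.Series([True] * 5 + [False] * 5, index=v.index)
        res = t.two_group_ttest(v, mask)
        se = np.sqrt(a.var(ddof=1) / 5 + b.var(ddof=1) / 5)
        t_hand = (a.mean() - b.mean()) / se
        assert res.statistic == pytest.approx(t_hand, rel=1e-12)

    def test_strong_separation_significant(self):
        rng = np.random.default_rng(10)
        v = pd.Series(np.r_[rng.normal(0, 0.01, 4), rng.normal(1, 0.01, 4)])
        mask = pd.Series([True] * 4 + [False] * 4)
        assert t.two_group_ttest(v, mask).p_value < 0.001


class TestTypeIErrorRates:
    """Permutation tests hold their nominal level under the null."""

    def test_permanova_level(self):
        rng = np.random.default_rng(42)
        rej = 0
        n_rep = 200
        for rep in range(n_rep):
            x = rng.normal(size=(18, 4))
            dm = t.make_distance_matrix(squareform(pdist(x)),
                                        [f"s{i}" for i in range(18)])
            res = t.permanova(dm, ["a"] * 9 + ["b"] * 9, 199, seed=rep)
            rej += res.p_value <= 0.05
        assert 0.03 <= rej / n_rep <= 0.07

    def test_mantel_level(self):
        rng = np.random.default_rng(43)
        rej = 0
        n_rep = 200
        for rep in range(n_rep):
            ids = [f"s{i}" for i in range(12)]
            a = squareform(pdist(rng.normal(size=(12, 3))))
            b = squareform(pdist(rng.normal(size=(12, 3))))
            res = t.mantel(t.make_distance_matrix(a, ids),
                           t.make_distance_matrix(b, ids), 199, seed=rep)
            rej += res.p_value <= 0.05
        assert 0.03 <= rej / n_rep <= 0.07

    def test_multilevel_spearman_level(self):
        rng = np.random.default_rng(44)
        rej = 0
        n_rep = 200
        for _ in range(n_rep):
            x = pd.Series(rng.normal(size=40))
            y = pd.Series(rng.normal(size=40))
            g = pd.Series(["g1"] * 20 + ["g2"] * 20)
            rej += t.multilevel_spearman(x, y, g).p_value <= 0.05
        assert 0.03 <= rej / n_rep <= 0.07
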