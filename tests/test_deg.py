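import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.cluster.hierarchy import cophenet
from scipy.spatial.distance import pdist

from oiserum import deg
from oiserum.containers import ExpressionMatrix
from oiserum.deg import (
    DemocraticVoteSelector,
    QuantileNormalizer,
    VoteConfig,
    democratic_vote,
    log2p1,
    paired_t,
    pca_scores,
    quantile_normalize,
    select_highly_variable,
    upgma_cluster,
)

from conftest import make_paired_matrix
from oracles import oracle_vote


# ---------------------------------------------------------------------- QN

class TestQuantileNormalize:
    def test_two_sample_hand_example(self):
        df = pd.DataFrame({"s1": [1.0, 3.0], "s2": [2.0, 4.0]}, index=["g1", "g2"])
        out = quantile_normalize(df)
        expected = pd.DataFrame({"s1": [1.5, 3.5], "s2": [1.5, 3.5]}, index=["g1", "g2"])
        pd.testing.assert_frame_equal(out, expected)

    def test_single_sample_unchanged(self):
        df = pd.DataFrame({"s1": [5.0, 1.0, 2.0]})
        pd.testing.assert_frame_equal(quantile_normalize(df), df)

    def test_rank_order_preserved_within_column(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.exponential(size=(50, 4)))
        out = quantile_normalize(df)
        for c in df.columns:
            assert (np.argsort(out[c].values, kind="stable")
                    == np.argsort(df[c].values, kind="stable")).all()

    def test_ties_get_identical_values(self):
        df = pd.DataFrame({"s1": [1.0, 1.0, 3.0], "s2": [2.0, 4.0, 9.0]})
        out = quantile_normalize(df)
        assert out["s1"][0] == out["s1"][1]

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            QuantileNormalizer().fit(np.empty((0, 0)))

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(2, 6), st.integers(2, 30), st.integers(0, 10_000))
    def test_sorted_columns_identical_and_idempotent(self, n_samples, n_genes, seed):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(rng.normal(size=(n_genes, n_samples)) ** 2)
        out = quantile_normalize(df)
        ref = np.sort(out[0].values)
        for c in out.columns:
            np.testing.assert_allclose(np.sort(out[c].values), ref)
        # continuous draws are tie-free, so a second pass is the identity
        pd.testing.assert_frame_equal(quantile_normalize(out), out)


class TestLog2p1:
    @pytest.mark.parametrize("x,expected", [(0.0, 0.0), (1.0, 1.0), (3.0, 2.0)])
    def test_anchor_values(self, x, expected):
        out = log2p1(pd.DataFrame({"s": [x]}))
        assert out.iloc[0, 0] == expected

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            log2p1(pd.DataFrame({"s": [-0.1]}))


# ---------------------------------------------------------------- paired t

class TestPairedT:
    def test_textbook_formula(self):
        d = np.array([0.2, 0.2, 0.2, -0.2])
        basal = np.zeros(4)
        t, p = paired_t(basal, basal + d)
        mean, sd = d.mean(), d.std(ddof=1)
        np.testing.assert_allclose(t, mean / (sd / np.sqrt(4)))
        from scipy import stats
        np.testing.assert_allclose(p, stats.t.sf(t, 3))

    def test_identical_pairs_symmetric_null(self):
        t, p = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 0.5

    def test_constant_nonzero_difference_excluded(self):
        t, p = paired_t([0.0, 0.0, 0.0], [1.0, 1.0, 1.0])
        assert np.isnan(t) and p == 1.0

    def test_tail_direction(self):
        basal, post = np.zeros(5), np.full(5, 1.0) + np.arange(5) * 0.01
        _, p_up = paired_t(basal, post, alternative="greater")
        _, p_down = paired_t(basal, post, alternative="less")
        assert p_up < 0.05 < p_down


# ----------------------------------------------------------------- voting

class TestDemocraticVote:
    def test_null_matrix_selects_nothing(self):
        m = make_paired_matrix(np.tile(np.array([3.0, 5.0])[:, None], (1, 20)), 10)
        res = democratic_vote(m, VoteConfig())
        assert (res["direction"] == "none").all()
        assert (res[["votes_for_up", "votes_for_down"]] == 0).all().all()

    def test_nine_for_one_against_hand_example(self):
        # one gene: +0.2 in 9 lines, -0.2 in the tenth
        basal = np.full(10, 5.0)
        post = basal + np.array([0.2] * 9 + [-0.2])
        values = np.empty((1, 20))
        values[0, 0::2], values[0, 1::2] = basal, post
        m = make_paired_matrix(values, 10)
        res = democratic_vote(m, VoteConfig(theta_vote=0.1, min_votes=9))
        row = res.iloc[0]
        assert row["votes_for_up"] == 9 and row["votes_against_up"] == 1
        _, p = paired_t(basal, post)
        assert (row["direction"] == "up") == (p < 0.05)

    def test_matches_brute_force_oracle_small_table(self):
        rng = np.random.default_rng(42)
        values = 5.0 + rng.normal(scale=0.3, size=(3, 20))
        m = make_paired_matrix(values, 10)
        res = democratic_vote(m, VoteConfig())
        ref = oracle_vote(m.values, m.pairing, 0.1, 9, 0.05)
        for gene in m.gene_ids:
            for key in ("votes_for_up", "votes_against_up", "votes_for_down",
                        "votes_against_down", "direction"):
                assert res.loc[gene, key] == ref[gene][key], (gene, key)

    def test_direction_exclusive_with_majority_rule(self):
        rng = np.random.default_rng(7)
        m = make_paired_matrix(5 + rng.normal(scale=1.0, size=(50, 20)), 10)
        res = democratic_vote(m, VoteConfig(min_votes=6))
        # min_votes > n_lines/2: each gene can reach it in at most one direction
        assert ((res["votes_for_up"] >= 6) & (res["votes_for_down"] >= 6)).sum() == 0

    def test_raising_theta_never_adds_votes(self):
        rng = np.random.default_rng(11)
        m = make_paired_matrix(5 + rng.normal(scale=0.5, size=(40, 20)), 10)
        lo = democratic_vote(m, VoteConfig(theta_vote=0.05))
        hi = democratic_vote(m, VoteConfig(theta_vote=0.2))
        assert (hi["votes_for_up"] <= lo["votes_for_up"]).all()
        assert (hi["votes_for_down"] <= lo["votes_for_down"]).all()

    def test_raising_min_votes_shrinks_selection(self):
        rng = np.random.default_rng(13)
        m = make_paired_matrix(5 + rng.normal(scale=0.5, size=(60, 20)), 10)
        loose = democratic_vote(m, VoteConfig(min_votes=7))
        strict = democratic_vote(m, VoteConfig(min_votes=9))
        sel_loose = set(loose.index[loose["direction"] != "none"])
        sel_strict = set(strict.index[strict["direction"] != "none"])
        assert sel_strict <= sel_loose

    def test_ranks_are_permutation_ordered_by_p(self):
        rng = np.random.default_rng(5)
        shift = np.where(rng.random(30) < 0.5, 0.8, 0.0)
        values = 5 + rng.normal(scale=0.1, size=(30, 20))
        values[:, 1::2] += shift[:, None]
        m = make_paired_matrix(values, 10)
        res = democratic_vote(m, VoteConfig())
        sel = res[res["direction"] != "none"].sort_values("rank")
        assert list(sel["rank"]) == list(range(1, len(sel) + 1))
        assert sel["p"].is_monotonic_increasing
        assert res.loc[res["direction"] == "none", "rank"].isna().all()

    def test_votes_beyond_min_but_insignificant_p_not_selected(self):
        # all ten lines vote up, but the spread keeps one-tailed p above alpha
        d = np.array([3.0, 3.0, 0.11, 0.11, 0.11, 0.11, 0.11, 0.11, -3.0 + 0.2, 0.11])
        values = np.empty((1, 20))
        values[0, 0::2], values[0, 1::2] = 5.0, 5.0 + d
        # make one line vote against so votes stay 9 for / 1 against, p large
        m = make_paired_matrix(values, 10)
        res = democratic_vote(m, VoteConfig())
        row = res.iloc[0]
        assert row["votes_for_up"] == 9
        assert row["p"] >= 0.05 and row["direction"] == "none"

    def test_rejects_min_votes_above_n_lines(self):
        m = make_paired_matrix(np.full((2, 6), 1.0), 3)
        with pytest.raises(ValueError, match="min_votes"):
            democratic_vote(m, VoteConfig(min_votes=4))

    def test_selector_sklearn_transform_subsets_genes(self):
        rng = np.random.default_rng(3)
        values = 5 + rng.normal(scale=0.05, size=(10, 20))
        values[0, 1::2] += 1.0  # one strongly shifted gene
        X = values.T
        y = ["basal", "post"] * 10
        groups = np.repeat([f"L{j}" for j in range(10)], 2)
        sel = DemocraticVoteSelector().fit(X, y, groups=groups)
        assert sel.get_support()[0]
        assert sel.transform(X).shape == (20, int(sel.get_support().sum()))


# ------------------------------------------------------------- companions

class TestHighlyVariable:
    def test_constant_matrix_breaks_ties_lexicographically(self):
        df = pd.DataFrame(np.ones((8, 3)), index=[f"g{i}" for i in range(8)])
        assert select_highly_variable(df, 5) == sorted(df.index)[:5]

    def test_injected_spread_ranks_first(self):
        df = pd.DataFrame(np.ones((10, 4)), index=[f"g{i:02d}" for i in range(10)])
        df.loc["g07"] = [0.0, 5.0, 10.0, 20.0]
        assert select_highly_variable(df, 1) == ["g07"]

    def test_k_equals_n_returns_all(self):
        df = pd.DataFrame(np.arange(12.0).reshape(4, 3))
        assert len(select_highly_variable(df, 4)) == 4

    def test_rejects_nonpositive_k(self):
        with pytest.raises(ValueError):
            select_highly_variable(pd.DataFrame(np.ones((2, 2))), 0)


class TestUPGMA:
    def test_three_sample_hand_computation(self):
        # columns A, B, C with d(A,B)=1, d(A,C)=5, d(B,C)=4
        df = pd.DataFrame([[0.0, 1.0, 5.0]], columns=["A", "B", "C"])
        tree = upgma_cluster(df)
        # A,B merge first at height 1; C joins at mean(5,4)=4.5
        np.testing.assert_allclose(tree.heights, [1.0, 4.5])
        assert set(tree.linkage[0, :2]) == {0.0, 1.0}
        newick = tree.to_newick()
        assert "(A:1,B:1)" in newick and newick.endswith(";")

    def test_duplicate_sample_merges_at_zero(self):
        df = pd.DataFrame({"A": [1.0, 2.0], "B": [1.0, 2.0], "C": [9.0, 9.0]})
        tree = upgma_cluster(df)
        assert tree.heights[0] == 0.0

    def test_heights_monotone_and_cophenetic_consistent(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(20, 6)))
        tree = upgma_cluster(df)
        assert (np.diff(tree.heights) >= 0).all()
        c, _ = cophenet(tree.linkage, pdist(df.values.T))
        assert c > 0

    def test_rejects_single_sample(self):
        with pytest.raises(ValueError):
            upgma_cluster(pd.DataFrame({"A": [1.0]}))


class TestPCA:
    def test_mirrored_samples_symmetric_scores(self):
        df = pd.DataFrame({"s1": [1.0, -2.0, 3.0], "s2": [-1.0, 2.0, -3.0]})
        res = pca_scores(df)
        np.testing.assert_allclose(res.scores["PC1"].sum(), 0.0, atol=1e-12)

    def test_score_variance_equals_eigenvalues(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.normal(size=(12, 5)))
        res = pca_scores(df)
        np.testing.assert_allclose(
            res.scores.var(axis=0, ddof=1).values, res.explained_variance, atol=1e-10
        )

    def test_matches_hand_eigendecomposition_small_matrix(self):
        df = pd.DataFrame([[2.0, 0.0, 1.0], [0.0, 2.0, 1.0], [1.0, 1.0, 4.0]])
        res = pca_scores(df)
        A = df.values.T - df.values.T.mean(axis=0)
        evals, evecs = np.linalg.eigh(A.T @ A)  # independent eigen route
        order = np.argsort(evals)[::-1]
        scores_ref = A @ evecs[:, order]
        for j in range(2):  # compare up to sign, component-wise
            ours = res.scores.iloc[:, j].values
            ref = scores_ref[:, j]
            assert np.allclose(ours, ref, atol=1e-8) or np.allclose(ours, -ref, atol=1e-8)

    def test_sign_convention_largest_loading_positive(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(9, 4)))
        res = pca_scores(df)
        for c in res.loadings.columns:
            v = res.loadings[c].values
            assert v[np.argmax(np.abs(v))] > 0

    def test_rejects_constant_matrix(self):
        with pytest.raises(ValueError):
            pca_scores(pd.DataFrame(np.ones((3, 4))))
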