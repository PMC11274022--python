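import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from seedgo.clustering import (
    Dendrogram,
    choose_cluster_count,
    fit_glm_log_link,
    hcluster_rows,
)
from seedgo.errors import SeedgoError


def chain_dendrogram(heights):
    """A caterpillar merge sequence with prescribed (sorted) heights."""
    m = len(heights)
    n = m + 1
    Z = np.zeros((m, 4))
    Z[0] = [0, 1, heights[0], 2]
    for i in range(1, m):
        Z[i] = [n + i - 1, i + 1, heights[i], i + 2]
    return Dendrogram([f"t{i}" for i in range(n)], Z)


def union_find_partition(dend, n_merges):
    """Oracle: memberships from replaying the first n_merges merges."""
    n = dend.n_leaves
    parent = list(range(n + n_merges))
    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x
    for i, (a, b, _) in enumerate(dend.merges[:n_merges]):
        new = n + i
        parent[find(a)] = new
        parent[find(b)] = new
    groups = {}
    for leaf in range(n):
        groups.setdefault(find(leaf), set()).add(dend.labels[leaf])
    return {frozenset(g) for g in groups.values()}


class TestHcluster:
    def test_identical_rows_merge_at_zero(self):
        df = pd.DataFrame([[1.0, 2.0], [1.0, 2.0]], index=["a", "b"])
        dend = hcluster_rows(df)
        assert dend.heights.tolist() == [0.0]

    def test_hand_distance_matrix_complete_linkage(self):
        # d(a,b)=3, d(a,c)=4, d(b,c)=5; complete linkage final merge at 5
        df = pd.DataFrame([[0, 0], [0, 3], [4, 0]], index=["a", "b", "c"])
        dend = hcluster_rows(df)
        assert dend.heights.tolist() == [3.0, 5.0]
        assert {dend.labels[int(dend.merges[0][0])],
                dend.labels[int(dend.merges[0][1])]} == {"a", "b"}

    def test_permutation_invariant_heights(self, rng):
        data = rng.normal(size=(12, 4))
        df = pd.DataFrame(data, index=[f"t{i}" for i in range(12)])
        perm = rng.permutation(12)
        h1 = hcluster_rows(df).heights
        h2 = hcluster_rows(df.iloc[perm]).heights
        assert np.allclose(np.sort(h1), np.sort(h2))

    def test_single_row_fatal(self):
        with pytest.raises(SeedgoError, match="skip"):
            hcluster_rows(pd.DataFrame([[1.0]], index=["a"]))


class TestGlmFit:
    def test_recovers_exact_exponential(self):
        h = np.exp(0.5 + 0.2 * np.arange(1, 11))
        fit = fit_glm_log_link(h)
        assert fit.beta0 == pytest.approx(0.5, abs=1e-6)
        assert fit.beta1 == pytest.approx(0.2, abs=1e-6)
        assert np.all(np.abs(fit.residuals) < 1e-6 * h.max())

    def test_constant_heights_flat_fit(self):
        fit = fit_glm_log_link(np.full(8, 3.0))
        assert fit.beta1 == pytest.approx(0.0, abs=1e-8)
        assert np.allclose(fit.fitted, 3.0)

    def test_all_zero_heights_fatal(self):
        with pytest.raises(SeedgoError):
            fit_glm_log_link(np.zeros(5))

    @pytest.mark.parametrize(
        "heights",
        [
            [0.1, 0.11, 0.12, 0.13, 5.0],
            [0.5, 0.9, 1.2, 1.4, 2.0, 2.1, 7.0, 9.0],
            [1.0, 1.0, 1.0, 1.0, 1.0, 10.0, 10.0],
        ],
    )
    def test_matches_independent_irls_oracle(self, heights):
        """Gaussian-family log-link fit agrees with an independent IRLS."""
        h = np.asarray(heights, float)
        fit = fit_glm_log_link(h)
        X = sm.add_constant(np.arange(1, len(h) + 1, dtype=float))
        ref = sm.GLM(h, X, family=sm.families.Gaussian(sm.families.links.Log())).fit(
            start_params=[fit.beta0, fit.beta1], maxiter=200
        )
        assert np.allclose([fit.beta0, fit.beta1], ref.params, atol=1e-8)
        assert np.allclose(fit.fitted, ref.fittedvalues, atol=1e-8)


class TestChooseClusterCount:
    def test_exact_exponential_gives_single_cluster(self):
        h = np.exp(0.3 + 0.15 * np.arange(1, 10))
        dend = chain_dendrogram(h)
        assign = choose_cluster_count(dend)
        assert assign.k == 1 and assign.i_star is None
        assert set(assign.assignment.values()) == {1}

    def test_cut_rule_arithmetic(self):
        # 6 leaves, first positive residual forced at i* = 5 -> k = 2
        h = np.array([1.0, 1.1, 1.2, 1.3, 1.4])
        dend = chain_dendrogram(h)
        fit = fit_glm_log_link(h)
        fit.residuals = np.array([-1.0, -1.0, -1.0, -1.0, 1.0])
        assign = choose_cluster_count(dend, fit)
        assert assign.i_star == 5
        assert assign.k == 6 - (5 - 1)

    @pytest.mark.parametrize("n_low,n_high", [(3, 3), (5, 5), (4, 6)])
    def test_two_level_heights_cut_at_the_jump(self, n_low, n_high):
        """A low plateau followed by a high plateau: the first above-trend
        merge is the jump, and the cut keeps the low-plateau merges."""
        h = np.array([1.0] * n_low + [10.0] * n_high)
        dend = chain_dendrogram(h)
        assign = choose_cluster_count(dend, fit_glm_log_link(h))
        assert assign.i_star == n_low + 1
        assert assign.k == dend.n_leaves - (assign.i_star - 1)

    def test_k_equals_leaves_iff_first_merge_breaks_trend(self):
        h = np.array([2.0, 2.1, 2.2])
        dend = chain_dendrogram(h)
        fit = fit_glm_log_link(h)
        fit.residuals = np.array([1.0, -1.0, -1.0])  # force i* = 1
        assign = choose_cluster_count(dend, fit)
        assert assign.k == dend.n_leaves

    def test_assignment_consistent_with_union_find(self, rng):
        for _ in range(25):
            data = rng.normal(size=(rng.integers(4, 12), 3))
            df = pd.DataFrame(data, index=[f"t{i}" for i in range(len(data))])
            dend = hcluster_rows(df)
            assign = choose_cluster_count(dend)
            i_star = assign.i_star or dend.n_leaves
            expected = union_find_partition(dend, i_star - 1)
            produced = {}
            for label, c in assign.assignment.items():
                produced.setdefault(c, set()).add(label)
            assert {frozenset(g) for g in produced.values()} == expected

    def test_two_tight_groups_detected(self, rng):
        a = rng.normal(0, 0.05, size=(5, 3))
        b = rng.normal(5, 0.05, size=(5, 3)) + 5
        df = pd.DataFrame(np.vstack([a, b]), index=[f"t{i}" for i in range(10)])
        assign = choose_cluster_count(hcluster_rows(df))
        groups = {}
        for label, c in assign.assignment.items():
            groups.setdefault(c, set()).add(label)
        # the cut never mixes the two planted groups
        left = {f"t{i}" for i in range(5)}
        for g in groups.values():
            assert g <= left or g.isdisjoint(left)

    def test_deterministic_across_runs(self, rng):
        data = rng.normal(size=(10, 4))
        df = pd.DataFrame(data, index=[f"t{i}" for i in range(10)])
        runs = [choose_cluster_count(hcluster_rows(df)) for _ in range(3)]
        assert len({r.k for r in runs}) == 1
        assert all(r.assignment == runs[0].assignment for r in runs)
        assert 1 <= runs[0].k <= len(df)
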