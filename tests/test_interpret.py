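"""Component matching, clustering, specific-CpG selection, marker selection."""

import numpy as np
import pytest

from methdecon import (
    LMCMatrix,
    MethylationMatrix,
    cluster_lmcs,
    lmc_specific_cpgs,
    match_lmcs,
    pairwise_specific_cpgs,
    reference_proportions,
    select_discriminative_cpgs,
    select_most_variable,
)


def pearson(x, y):
    x = x - x.mean()
    y = y - y.mean()
    return float((x * y).sum() / np.sqrt((x * x).sum() * (y * y).sum()))


class TestMatchLMCs:
    def test_identity_match(self, rng):
        T = LMCMatrix(rng.uniform(0, 1, (20, 4)))
        res = match_lmcs(T, T)
        assert res.epsilon == 1.0
        assert sorted(res.pairs) == [(i, i) for i in range(4)]

    def test_permutation_recovered(self, rng):
        vals = rng.uniform(0, 1, (20, 4))
        perm = [2, 0, 3, 1]
        T = LMCMatrix(vals)
        T_ref = LMCMatrix(vals[:, perm], lmc_ids=[f"r{i}" for i in range(4)])
        res = match_lmcs(T, T_ref)
        assert res.epsilon == 1.0
        assert sorted(res.pairs, key=lambda p: p[1]) == [
            (perm[j], j) for j in range(4)
        ]

    def test_correlations_match_direct_formula(self, rng):
        X = rng.uniform(0, 1, (6, 3))
        Y = rng.uniform(0, 1, (6, 2))
        T, T_ref = LMCMatrix(X), LMCMatrix(Y, lmc_ids=["a", "b"])
        res = match_lmcs(T, T_ref, center=False)
        for i in range(3):
            for j in range(2):
                assert res.S[i, j] == pytest.approx(pearson(X[:, i], Y[:, j]), abs=1e-12)
        # epsilon by brute force: count mutual maxima over min(k, k*)
        mutual = sum(
            1
            for j in range(2)
            for i in [int(res.S[:, j].argmax())]
            if res.S[i, j] == res.S[i, :].max()
        )
        assert res.epsilon == mutual / 2

    def test_centering_changes_correlations(self, rng):
        X = rng.uniform(0, 1, (15, 3))
        Y = rng.uniform(0, 1, (15, 3))
        r_cent = match_lmcs(LMCMatrix(X), LMCMatrix(Y), center=True)
        r_raw = match_lmcs(LMCMatrix(X), LMCMatrix(Y), center=False)
        assert not np.allclose(r_cent.S, r_raw.S)

    def test_affine_rescaling_invariance(self, rng):
        # Pearson correlation is invariant to positive affine column rescaling
        X = rng.uniform(0, 1, (12, 2))
        Y = rng.uniform(0, 1, (12, 2))
        Y2 = Y.copy()
        Y2[:, 0] = 0.2 + 0.5 * Y2[:, 0]
        a = match_lmcs(LMCMatrix(X), LMCMatrix(Y), center=False)
        b = match_lmcs(LMCMatrix(X), LMCMatrix(Y2), center=False)
        np.testing.assert_allclose(a.S, b.S, atol=1e-12)

    def test_zero_variance_column_warns(self, rng):
        X = rng.uniform(0, 1, (10, 2))
        Y = np.column_stack([np.full(10, 0.5), rng.uniform(0, 1, 10)])
        with pytest.warns(UserWarning, match="zero-variance"):
            res = match_lmcs(LMCMatrix(X), LMCMatrix(Y), center=False)
        assert np.isnan(res.S[:, 0]).all()

    def test_too_few_shared_probes_rejected(self, rng):
        T1 = LMCMatrix(rng.uniform(0, 1, (5, 2)), cpg_ids=list("abcde"))
        T2 = LMCMatrix(rng.uniform(0, 1, (5, 2)), cpg_ids=list("abxyz"))
        with pytest.raises(ValueError, match="shared"):
            match_lmcs(T1, T2)


class TestClusterLMCs:
    def test_identical_columns_merge_at_zero(self, rng):
        v = rng.uniform(0, 1, 10)
        T = LMCMatrix(np.column_stack([v, rng.uniform(0, 1, 10)]))
        ref = LMCMatrix(v[:, None], lmc_ids=["r"])
        Z = cluster_lmcs(T, ref)
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_pair_merges_at_two(self):
        v = np.linspace(0.1, 0.9, 8)
        T = LMCMatrix(v[:, None])
        ref = LMCMatrix((1 - v)[:, None], lmc_ids=["r"])
        Z = cluster_lmcs(T, ref)
        assert Z[0, 2] == pytest.approx(2.0, abs=1e-12)

    def test_matches_bruteforce_average_linkage(self, rng):
        X = rng.uniform(0, 1, (12, 3))
        Y = rng.uniform(0, 1, (12, 2))
        Z = cluster_lmcs(LMCMatrix(X), LMCMatrix(Y, lmc_ids=["a", "b"]))

        # independent agglomeration: average linkage on 1 - Pearson
        cols = [X[:, i] for i in range(3)] + [Y[:, j] for j in range(2)]
        n = len(cols)
        dist = {(i, j): 1 - pearson(cols[i], cols[j])
                for i in range(n) for j in range(i + 1, n)}
        clusters = {i: [i] for i in range(n)}
        heights = []
        next_id = n
        while len(clusters) > 1:
            (ci, cj), h = min(
                (
                    ((a, b),
                     sum(dist[tuple(sorted((x, y)))]
                         for x in clusters[a] for y in clusters[b])
                     / (len(clusters[a]) * len(clusters[b])))
                    for a in clusters for b in clusters if a < b
                ),
                key=lambda t: t[1],
            )
            heights.append(h)
            clusters[next_id] = clusters.pop(ci) + clusters.pop(cj)
            next_id += 1
        np.testing.assert_allclose(Z[:, 2], heights, atol=1e-10)


class TestSpecificCpGs:
    def test_clear_specificity_selected(self):
        T = LMCMatrix(np.array([[0.9, 0.1, 0.1], [0.5, 0.5, 0.5]]))
        s = lmc_specific_cpgs(T, 0, theta=0.33)
        assert s.cpg_ids == ["cpg1"]
        assert s.deltas[0] == pytest.approx(0.8)

    def test_constant_row_never_specific(self):
        T = LMCMatrix(np.full((3, 3), 0.4))
        for i in range(3):
            assert lmc_specific_cpgs(T, i).cpg_ids == []

    def test_matches_loop_oracle(self, rng):
        vals = rng.uniform(0, 1, (50, 3))
        T = LMCMatrix(vals)
        for i in range(3):
            s = lmc_specific_cpgs(T, i, theta=0.33)
            expected = set()
            for l in range(50):
                others = [vals[l, j] for j in range(3) if j != i]
                if abs(vals[l, i] - sum(others) / len(others)) > 0.33:
                    expected.add(T.cpg_ids[l])
            assert set(s.cpg_ids) == expected
            assert (np.abs(s.deltas) > 0.33).all()
            assert (np.diff(np.abs(s.deltas)) <= 1e-15).all()  # sorted desc

    def test_literal_sum_reading_available(self):
        T = LMCMatrix(np.array([[0.9, 0.3, 0.3]]))
        mean_read = lmc_specific_cpgs(T, 0, theta=0.5)
        sum_read = lmc_specific_cpgs(T, 0, theta=0.5, literal_sum=True)
        assert mean_read.cpg_ids == ["cpg1"]  # |0.9 - 0.3| = 0.6 > 0.5
        assert sum_read.cpg_ids == []  # |0.9 - 0.6| = 0.3 < 0.5

    def test_pairwise_matches_loop(self, rng):
        vals = rng.uniform(0, 1, (30, 3))
        T = LMCMatrix(vals)
        s = pairwise_specific_cpgs(T, 0, 2, theta=0.33)
        expected = {T.cpg_ids[l] for l in range(30)
                    if abs(vals[l, 0] - vals[l, 2]) > 0.33}
        assert set(s.cpg_ids) == expected

    def test_pairwise_theta_one_is_empty(self, rng):
        T = LMCMatrix(rng.uniform(0, 1, (30, 2)))
        assert pairwise_specific_cpgs(T, 0, 1, theta=1.0).cpg_ids == []

    def test_invalid_theta_rejected(self):
        T = LMCMatrix(np.full((3, 2), 0.5))
        with pytest.raises(ValueError):
            lmc_specific_cpgs(T, 0, theta=1.5)


class TestReferenceProportions:
    def test_pure_sample(self, rng):
        T_ref = LMCMatrix(rng.uniform(0, 1, (20, 3)))
        D = MethylationMatrix(T_ref.values[:, [2]])
        A = reference_proportions(D, T_ref)
        np.testing.assert_allclose(A.values.ravel(), [0, 0, 1], atol=1e-7)

    def test_even_mixture(self):
        T_ref = LMCMatrix(np.array([[0.0, 1.0], [1.0, 0.0], [0.5, 0.9]]))
        D = MethylationMatrix(T_ref.values @ np.array([[0.5], [0.5]]))
        A = reference_proportions(D, T_ref)
        np.testing.assert_allclose(A.values.ravel(), [0.5, 0.5], atol=1e-6)

    def test_noisy_mixture_matches_simplex_grid_oracle(self, rng):
        T_ref = LMCMatrix(rng.uniform(0, 1, (30, 3)))
        a_true = np.array([0.2, 0.5, 0.3])
        d = np.clip(T_ref.values @ a_true + rng.normal(0, 0.03, 30), 0, 1)
        A = reference_proportions(MethylationMatrix(d[:, None]), T_ref)
        # exhaustive scan over the simplex with step 0.01
        best, arg = np.inf, None
        for a1 in np.arange(0, 1.0001, 0.01):
            for a2 in np.arange(0, 1.0001 - a1, 0.01):
                a = np.array([a1, a2, 1 - a1 - a2])
                obj = ((T_ref.values @ a - d) ** 2).sum()
                if obj < best:
                    best, arg = obj, a
        np.testing.assert_allclose(A.values.ravel(), arg, atol=0.02)

    def test_probe_intersection_respected(self, rng):
        ids = [f"c{i}" for i in range(10)]
        T_ref = LMCMatrix(rng.uniform(0, 1, (10, 2)), cpg_ids=ids)
        D = MethylationMatrix(T_ref.values[2:8, [0]], cpg_ids=ids[2:8])
        A = reference_proportions(D, T_ref)
        np.testing.assert_allclose(A.values.ravel(), [1, 0], atol=1e-7)


class TestCpGSelection:
    def test_most_variable_full_count_is_identity(self, rng):
        D = MethylationMatrix(rng.uniform(0, 1, (10, 5)))
        sub = select_most_variable(D, 10)
        np.testing.assert_array_equal(sub.values, D.values)

    def test_single_varying_row_found(self, rng):
        vals = np.full((5, 4), 0.5)
        vals[3] = [0.1, 0.9, 0.2, 0.8]
        sub = select_most_variable(MethylationMatrix(vals), 1)
        assert sub.cpg_ids == ["cpg4"]

    def test_matches_variance_ranking_loop(self, rng):
        vals = rng.uniform(0, 1, (100, 8))
        D = MethylationMatrix(vals)
        sub = select_most_variable(D, 10)
        variances = [(np.var(vals[i], ddof=1), i) for i in range(100)]
        top = sorted(sorted(variances, key=lambda t: -t[0])[:10], key=lambda t: t[1])
        assert sub.cpg_ids == [D.cpg_ids[i] for _, i in top]

    def test_anova_matches_textbook_formula(self, rng):
        vals = rng.uniform(0, 1, (50, 12))
        labels = np.repeat(["a", "b", "c"], 4)
        D = MethylationMatrix(vals)
        sub = select_discriminative_cpgs(D, labels, 5)

        def f_stat(row):
            groups = [row[labels == g] for g in "abc"]
            grand = row.mean()
            ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
            ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
            return (ssb / 2) / (ssw / (12 - 3))

        F = np.array([f_stat(vals[i]) for i in range(50)])
        expected = sorted(np.argsort(-F, kind="stable")[:5])
        assert sub.cpg_ids == [D.cpg_ids[i] for i in expected]

    def test_separated_groups_rank_first(self, rng):
        vals = rng.uniform(0.45, 0.55, (20, 8))
        vals[7] = [0.2] * 4 + [0.8] * 4
        labels = ["x"] * 4 + ["y"] * 4
        sub = select_discriminative_cpgs(MethylationMatrix(vals), labels, 1)
        assert sub.cpg_ids == ["cpg8"]

    def test_degenerate_groups_rejected(self, rng):
        D = MethylationMatrix(rng.uniform(0, 1, (5, 3)))
        with pytest.raises(ValueError):
            select_discriminative_cpgs(D, ["a", "a", "b"], 2)
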