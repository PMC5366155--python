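"""Core factorization: objective, exact subproblem solvers, alternating fit."""

import numpy as np
import pytest

from methdecon import (
    FactorizationConfig,
    LMCMatrix,
    MethylationMatrix,
    ProportionMatrix,
    factorize,
    init_random,
    objective,
    opt_A,
    opt_T,
)
from methdecon.factorization import factorize_arrays

from conftest import brute_force_objective


class TestObjective:
    def test_exact_binary_fit_is_zero(self, rng):
        T = (rng.uniform(0, 1, (8, 3)) > 0.5).astype(float)
        A = rng.dirichlet(np.ones(3), size=5).T
        D = T @ A
        assert objective(D, T, A, lam=7.3) == pytest.approx(0.0, abs=1e-12)

    def test_half_methylated_penalty(self):
        # ||0.5 - 0.5*1||^2 + 1 * 0.5*(1-0.5) = 0.25
        val = objective(np.array([[0.5]]), np.array([[0.5]]), np.array([[1.0]]), 1.0)
        assert val == pytest.approx(0.25)

    def test_matches_elementwise_loop(self, rng):
        m, k, n = 10, 3, 4
        T = rng.uniform(0, 1, (m, k))
        A = rng.dirichlet(np.ones(k), size=n).T
        D = rng.uniform(0, 1, (m, n))
        lam = 0.37
        assert objective(D, T, A, lam) == pytest.approx(
            brute_force_objective(D, T, A, lam), rel=1e-12
        )

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="shape"):
            objective(rng.uniform(0, 1, (5, 3)), rng.uniform(0, 1, (4, 2)),
                      np.full((2, 3), 0.5), 0.0)

    def test_nan_rejected(self):
        D = np.array([[0.5, np.nan]])
        with pytest.raises(ValueError, match="NaN"):
            objective(D, np.array([[0.5]]), np.array([[1.0, 0.0]]), 0.0)


class TestOptA:
    def test_single_component_gives_all_ones(self, rng):
        D = rng.uniform(0, 1, (6, 4))
        T = rng.uniform(0, 1, (6, 1))
        A = opt_A(D, T)
        np.testing.assert_allclose(A.values, 1.0, atol=1e-9)

    def test_pure_sample_yields_indicator(self, rng):
        T = rng.uniform(0, 1, (10, 3))
        D = T[:, [1]]
        A = opt_A(D, T)
        np.testing.assert_allclose(A.values.ravel(), [0, 1, 0], atol=1e-7)

    def test_matches_1d_grid_oracle(self, rng):
        # k=2: the simplex is a segment, scan a from 0 to 1
        T = np.array([[0.9, 0.1], [0.2, 0.8], [0.7, 0.3]])
        d = np.clip(0.63 * T[:, 0] + 0.37 * T[:, 1] + rng.normal(0, 0.05, 3), 0, 1)
        A = opt_A(d[:, None], T)
        grid = np.linspace(0, 1, 10001)
        objs = ((T @ np.vstack([grid, 1 - grid]) - d[:, None]) ** 2).sum(axis=0)
        assert abs(A.values[0, 0] - grid[objs.argmin()]) < 1e-3

    def test_inequality_mode_allows_deficit(self):
        # target shorter than any profile: the sub-simplex shrinks the sum
        T = np.array([[1.0], [1.0]])
        d = np.array([[0.4], [0.4]])
        A = opt_A(d, T, mode="inequality")
        assert A.values[0, 0] == pytest.approx(0.4, abs=1e-9)

    def test_degenerate_identical_columns_feasible(self, rng):
        T = np.tile(rng.uniform(0, 1, (5, 1)), (1, 3))
        A = opt_A(rng.uniform(0, 1, (5, 2)), T)
        np.testing.assert_allclose(A.values.sum(axis=0), 1.0, atol=1e-6)
        assert (A.values >= -1e-9).all()


class TestOptT:
    def test_identity_proportions_reproduce_data(self, rng):
        D = (rng.uniform(0, 1, (12, 3)) > 0.5).astype(float)
        A = np.eye(3)
        T = opt_T(D, A, lam=0.0, T_init=np.full((12, 3), 0.5))
        np.testing.assert_allclose(T.values, D, atol=1e-9)

    def test_huge_penalty_forces_binary(self, rng):
        D = rng.uniform(0, 1, (10, 4))
        A = rng.dirichlet(np.ones(2), size=4).T
        T = opt_T(D, A, lam=1e6, T_init=rng.uniform(0, 1, (10, 2)))
        dist = np.minimum(T.values, 1 - T.values)
        assert dist.max() < 1e-3

    def test_matches_2d_grid_oracle(self, rng):
        # single CpG, two components: scan (T11, T12) on a fine grid
        A = rng.dirichlet(np.ones(2), size=3).T  # 2 x 3
        d = rng.uniform(0, 1, (1, 3))
        lam = 0.1
        T = opt_T(d, A, lam=lam, T_init=np.array([[0.5, 0.5]]))
        got = objective(d, T, ProportionMatrix(A), lam)
        g = np.linspace(0, 1, 1001)
        tt = np.stack(np.meshgrid(g, g), axis=-1).reshape(-1, 2)
        objs = ((tt @ A - d) ** 2).sum(axis=1) + lam * (tt * (1 - tt)).sum(axis=1)
        assert got <= objs.min() + 2e-3

    def test_negative_lambda_rejected(self, rng):
        with pytest.raises(ValueError):
            opt_T(rng.uniform(0, 1, (3, 2)), np.eye(2)[:, :2], lam=-1.0,
                  T_init=np.zeros((3, 2)))


class TestFactorize:
    def test_recovers_vertices_present_in_data(self, rng):
        # all pure prototypes appear as samples: lam=0 suffices
        m, k = 40, 3
        T_true = (rng.uniform(0, 1, (m, k)) > 0.5).astype(float)
        mix = rng.dirichlet(np.ones(k), size=12).T
        A_true = np.hstack([np.eye(k), mix])
        D = T_true @ A_true
        best = None
        for seed in range(5):
            res = factorize(D, FactorizationConfig(k=k, lam=0.0, seed=seed))
            if best is None or res.objective < best.objective:
                best = res
        # match columns by nearest ground-truth vertex
        perm = [int(np.abs(best.T.values - T_true[:, [j]]).sum(axis=0).argmin())
                for j in range(k)]
        assert sorted(set(perm)) == list(range(k))
        dev = max(np.abs(best.T.values[:, perm[j]] - T_true[:, j]).max()
                  for j in range(k))
        assert dev < 1e-3

    def test_deterministic_given_seed(self, rng):
        D = rng.uniform(0, 1, (30, 8))
        cfg = FactorizationConfig(k=2, lam=1e-3, seed=42)
        r1 = factorize(D, cfg)
        r2 = factorize(D, cfg)
        assert r1.objective_trace == r2.objective_trace
        np.testing.assert_array_equal(r1.T.values, r2.T.values)

    def test_trace_consistency_and_feasibility(self, rng):
        D = rng.uniform(0, 1, (25, 10))
        res = factorize(D, FactorizationConfig(k=3, lam=1e-2, seed=0))
        assert res.objective_trace[-1] == pytest.approx(res.rss + res.penalty, rel=1e-6)
        diffs = np.diff(res.objective_trace)
        assert (diffs <= 1e-8).all()
        assert res.T.values.min() >= 0 and res.T.values.max() <= 1
        np.testing.assert_allclose(res.A.values.sum(axis=0), 1.0, atol=1e-6)

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ValueError):
            factorize(rng.uniform(0, 1, (10, 3)), FactorizationConfig(k=5))

    def test_sample_permutation_equivariance(self, rng):
        D = rng.uniform(0, 1, (20, 9))
        perm = rng.permutation(9)
        T0, A0 = init_random(20, 3, 9, seed=7)
        cfg = FactorizationConfig(k=3, lam=1e-3, seed=7)
        r = factorize(D, cfg, T_init=T0, A_init=A0)
        r_perm = factorize(D[:, perm], cfg, T_init=T0,
                           A_init=ProportionMatrix(A0.values[:, perm]))
        np.testing.assert_allclose(r_perm.T.values, r.T.values, atol=1e-9)
        np.testing.assert_allclose(r_perm.A.values, r.A.values[:, perm], atol=1e-9)

    def test_stronger_regularization_gives_more_binary_profiles(self, rng):
        m, n, k = 200, 10, 3
        T_true = (rng.uniform(0, 1, (m, k)) > 0.5).astype(float)
        A_true = rng.dirichlet(np.ones(k) * 5, size=n).T
        D = np.clip(T_true @ A_true + rng.normal(0, 0.05, (m, n)), 0, 1)
        fracs = []
        for lam in (0.0, 1e-3, 1e-1, 10.0):
            res = factorize(D, FactorizationConfig(k=k, lam=lam, seed=11))
            T = res.T.values
            fracs.append(float((np.minimum(T, 1 - T) < 0.05).mean()))
        assert all(b >= a - 1e-12 for a, b in zip(fracs, fracs[1:]))
        assert fracs[-1] > 0.99


class TestInitRandom:
    def test_reproducible(self):
        T1, A1 = init_random(10, 3, 6, seed=5)
        T2, A2 = init_random(10, 3, 6, seed=5)
        np.testing.assert_array_equal(T1.values, T2.values)
        np.testing.assert_array_equal(A1.values, A2.values)

    def test_proportion_columns_on_simplex(self):
        _, A = init_random(4, 5, 50, seed=1)
        np.testing.assert_allclose(A.values.sum(axis=0), 1.0, atol=1e-12)

    def test_profile_entries_uniform_mean(self):
        T, _ = init_random(10000, 10, 1, seed=3)
        assert T.values.mean() == pytest.approx(0.5, abs=0.01)

    def test_invalid_dims_rejected(self):
        with pytest.raises(ValueError):
            init_random(0, 2, 3, seed=0)
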