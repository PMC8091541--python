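"""QP term assembly, the fixed-hyperparameter solver, and the grid search."""

import numpy as np
import pytest

from modalign import (
    DegenerateModalityError,
    HyperParams,
    InvalidInputError,
    NoFeasibleSolutionError,
    build_qp_terms,
    grid_search,
    pearson_corr,
    solve_fixed,
)

from conftest import random_qp_instance, two_pass_pearson


def direct_cov_var(D, rho):
    """Independent covariance/variance route via numpy's covariance matrix."""
    cov_vec = np.array(
        [np.cov(D[:, i], rho, bias=True)[0, 1] for i in range(D.shape[1])]
    )
    V = np.atleast_2d(np.cov(D.T, bias=True))
    return cov_vec, V


def brute_force_max(D, rho, lam, alpha, beta, lo=0.0, hi=3.0, step=1e-3):
    """Exhaustive grid maximization of the regularized covariance objective (k=2)."""
    cov_vec, V = direct_cov_var(D, rho)
    g, _ = direct_cov_var(D, D.sum(axis=1))
    grid = np.arange(lo, hi + step / 2, step)
    W1, W2 = np.meshgrid(grid, grid, indexing="ij")
    obj = (
        cov_vec[0] * W1
        + cov_vec[1] * W2
        - alpha * (V[0, 0] * W1**2 + 2 * V[0, 1] * W1 * W2 + V[1, 1] * W2**2)
        - lam * ((W1 - 1) ** 2 + (W2 - 1) ** 2)
    )
    feasible = g[0] * W1 + g[1] * W2 >= beta
    obj = np.where(feasible, obj, -np.inf)
    i, j = np.unravel_index(np.argmax(obj), obj.shape)
    return np.array([grid[i], grid[j]])


class TestBuildTerms:
    @pytest.mark.parametrize("seed", range(5))
    def test_covariance_matches_direct_oracle(self, seed):
        D, rhos, gammas = random_qp_instance(seed, n_pairs=20, k=3)
        terms = build_qp_terms(D, rhos, gammas)
        P = terms.P_size
        rng = np.random.default_rng(seed + 100)
        w = rng.uniform(0.1, 2.0, size=3)
        lhs = (terms.a[0] / P - terms.b[0] / P**2) @ w
        direct = np.cov(D @ w, rhos[0], bias=True)[0, 1]
        assert lhs == pytest.approx(direct, rel=1e-9)
        # at w = 1 the covariance is with the unweighted primary distances
        ones_cov = (terms.a[0] / P - terms.b[0] / P**2) @ np.ones(3)
        assert ones_cov == pytest.approx(
            np.cov(D.sum(axis=1), rhos[0], bias=True)[0, 1], rel=1e-9
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_variance_matches_direct_oracle(self, seed):
        D, rhos, gammas = random_qp_instance(seed, n_pairs=20, k=3)
        terms = build_qp_terms(D, rhos, gammas)
        ones = np.ones(3)
        assert ones @ terms.V @ ones == pytest.approx(
            np.var(D.sum(axis=1)), rel=1e-9
        )

    def test_variance_matrix_is_psd(self):
        for seed in range(10):
            D, rhos, gammas = random_qp_instance(seed, n_pairs=40, k=4)
            terms = build_qp_terms(D, rhos, gammas)
            assert np.linalg.eigvalsh(terms.V).min() >= -1e-8

    def test_all_zero_D_yields_zero_terms_and_degenerate_fit(self):
        D = np.zeros((10, 3))
        terms = build_qp_terms(D, [np.arange(10.0)], [1.0])
        assert np.all(terms.a == 0) and np.all(terms.S == 0) and np.all(terms.T == 0)
        with pytest.raises(DegenerateModalityError):
            solve_fixed(terms, lam=1.0, alpha=1.0, beta=0.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            build_qp_terms(np.ones((5, 2)), [np.ones(4)], [1.0])


class TestPearsonCorr:
    def test_self_correlation_is_one(self, rng):
        D = rng.uniform(0, 1, size=(30, 4))
        w = rng.uniform(0.5, 2.0, size=4)
        assert pearson_corr(w, D, D @ w) == pytest.approx(1.0, abs=1e-12)

    def test_negated_shifted_copy_gives_minus_one(self, rng):
        D = rng.uniform(0, 1, size=(30, 4))
        w = np.ones(4)
        assert pearson_corr(w, D, 5.0 - D @ w) == pytest.approx(-1.0, abs=1e-12)

    def test_matches_textbook_two_pass_implementation(self, rng):
        D = rng.uniform(0, 1, size=(50, 3))
        rho = rng.uniform(0, 2, size=50)
        w = rng.uniform(0.1, 3.0, size=3)
        assert pearson_corr(w, D, rho) == pytest.approx(
            two_pass_pearson(D @ w, rho), abs=1e-12
        )

    @pytest.mark.parametrize("c", [0.1, 10.0])
    def test_invariant_to_positive_rescaling(self, rng, c):
        D = rng.uniform(0, 1, size=(40, 3))
        rho = rng.uniform(0, 2, size=40)
        w = rng.uniform(0.1, 2.0, size=3)
        assert pearson_corr(c * w, D, rho) == pytest.approx(
            pearson_corr(w, D, rho), abs=1e-12
        )

    def test_zero_variance_rejected(self):
        D = np.ones((10, 2))
        with pytest.raises(DegenerateModalityError):
            pearson_corr(np.ones(2), D, np.arange(10.0))


class TestSolveFixed:
    def test_huge_lambda_pins_weights_to_ones(self):
        D, rhos, gammas = random_qp_instance(0, n_pairs=40, k=5)
        terms = build_qp_terms(D, rhos, gammas)
        sol = solve_fixed(terms, lam=1e6, alpha=1.0, beta=0.0)
        assert np.max(np.abs(sol.w - 1.0)) < 1e-3

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_grid_oracle(self, seed):
        D, rhos, _ = random_qp_instance(seed, n_pairs=30, k=2)
        terms = build_qp_terms(D, rhos, [1.0])
        lam, alpha = 0.05, 0.02
        beta = 0.1 * terms.primary_var
        sol = solve_fixed(terms, lam, alpha, beta)
        # the oracle mesh covers [0, 3]^2: the comparison is only meaningful
        # for interior optima, so fail loudly if an instance ever drifts out
        assert sol.w.max() < 2.9
        expected = brute_force_max(D, rhos[0], lam, alpha, beta)
        assert np.max(np.abs(sol.w - expected)) < 5e-3

    def test_exchangeable_features_get_equal_weights(self, rng):
        # both features are the same i.i.d. column duplicated: the problem is
        # symmetric under swapping them, so the strictly convex QP must be too
        col = rng.uniform(0, 1, size=50)
        D = np.column_stack([col, col])
        rho = col * 2.0 + rng.normal(0, 0.05, size=50)
        terms = build_qp_terms(D, [rho], [1.0])
        sol = solve_fixed(terms, lam=0.5, alpha=0.1, beta=0.2 * terms.primary_var)
        assert abs(sol.w[0] - sol.w[1]) <= 1e-4

    def test_nonnegativity_exact(self):
        for seed in range(5):
            D, rhos, _ = random_qp_instance(seed, n_pairs=25, k=4)
            # anti-correlated secondary pushes weights toward the zero boundary
            terms = build_qp_terms(D, [rhos[0].max() - rhos[0]], [2.0])
            sol = solve_fixed(terms, lam=0.01, alpha=0.01, beta=0.0)
            assert sol.w.min() >= 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_regularization_monotonically_shrinks_distance_to_ones(self, seed):
        D, rhos, gammas = random_qp_instance(seed, n_pairs=40, k=4)
        terms = build_qp_terms(D, rhos, gammas)
        dists = []
        for lam in (0.01, 0.1, 1.0, 10.0, 100.0):
            sol = solve_fixed(terms, lam=lam, alpha=0.05, beta=0.0)
            dists.append(np.linalg.norm(sol.w - 1.0))
        assert all(b <= a + 1e-9 for a, b in zip(dists, dists[1:]))


class TestGridSearch:
    def test_secondary_equal_to_primary_needs_no_reweighting(self):
        D, _, _ = random_qp_instance(1, n_pairs=60, k=4)
        rho = D.sum(axis=1)  # secondary identical to unweighted primary distances
        terms = build_qp_terms(D, [rho], [1.0])
        sol = grid_search(terms, HyperParams(s=0.99))
        assert sol.feasible
        assert sol.achieved_corr[0] == pytest.approx(1.0, abs=1e-3)
        assert sol.achieved_corr[1] == pytest.approx(1.0, abs=1e-3)
        assert np.allclose(sol.w_mean1, 1.0, atol=0.05)

    def test_relaxing_s_never_hurts_secondary_correlation(self):
        for seed in range(6):
            rng = np.random.default_rng(seed)
            D = rng.uniform(0, 1, size=(80, 5))
            rho = D[:, :2].sum(axis=1) + rng.normal(0, 0.05, size=80)
            terms = build_qp_terms(D, [rho], [1.0])
            prev = -np.inf
            for s in (0.9999, 0.99, 0.95, 0.90):
                sol = grid_search(terms, HyperParams(s=s))
                assert sol.achieved_corr[1] >= prev - 1e-9
                prev = sol.achieved_corr[1]

    def test_tight_s_keeps_weights_near_ones(self):
        rng = np.random.default_rng(2)
        D = rng.uniform(0, 1, size=(80, 5))
        rho = D[:, 0] + rng.normal(0, 0.05, size=80)
        terms = build_qp_terms(D, [rho], [1.0])
        sol = grid_search(terms, HyperParams(s=0.999999))
        assert sol.achieved_corr[0] >= 0.999999 - 1e-6
        assert np.max(np.abs(sol.w_mean1 - 1.0)) < 0.1

    def test_feasible_solutions_reverify_from_raw_data(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            D = rng.uniform(0, 1, size=(100, 6))
            rho = D[:, :3].sum(axis=1) + rng.normal(0, 0.1, size=100)
            terms = build_qp_terms(D, [rho], [1.0])
            hp = HyperParams(s=0.95)
            sol = grid_search(terms, hp)
            assert pearson_corr(sol.w, D, D.sum(axis=1)) >= hp.s - 1e-6
            assert sol.w.max() / sol.w.sum() <= hp.q / D.shape[1] + 1e-9

    def test_impossible_concentration_bound_raises(self):
        D, rhos, gammas = random_qp_instance(0, n_pairs=40, k=4)
        terms = build_qp_terms(D, rhos, gammas)
        # ||w||_inf / ||w||_1 >= 1/k always, so q < 1 is unsatisfiable
        with pytest.raises(NoFeasibleSolutionError, match="lowering s"):
            grid_search(terms, HyperParams(s=0.9, q=0.5))

    def test_feasibility_table_covers_the_grid(self):
        D, rhos, gammas = random_qp_instance(3, n_pairs=40, k=3)
        terms = build_qp_terms(D, rhos, gammas)
        hp = HyperParams(s=0.9, lambda_grid=[0.1, 1.0], alpha_grid=[0.01], beta_grid=[0.0, 0.1])
        sol = grid_search(terms, hp)
        assert len(sol.feasibility_table) == 4
        assert {"lambda", "alpha", "beta", "feasible", "primary_corr"} <= set(
            sol.feasibility_table[0]
        )

    def test_hyperparameter_validation(self):
        with pytest.raises(InvalidInputError):
            HyperParams(s=1.0)
        with pytest.raises(InvalidInputError):
            HyperParams(lambda_grid=[])
        with pytest.raises(InvalidInputError):
            HyperParams(alpha_grid=[-1.0])
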