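"""The balanced-prior composite objective and its derivative-free minimization."""

import numpy as np
import pytest

from ppoc import (
    ObjectiveConfig,
    SampleSet,
    estimate_soft_params,
    fit_ppoc,
    hard_assign,
    hard_regularizer,
    kmeans_fit,
    kmeans_quantization_error,
    main_objective_term,
    minimize_derivative_free,
    objective,
    objective_components,
    priors_from_hard_assignment,
    soft_regularizer,
)


class TestMainObjectiveTerm:
    @pytest.mark.parametrize(
        "priors,expected",
        [
            ([0.5, 0.5], 0.0),  # uniform priors: term vanishes
            ([1.0, 0.0], 1.0),  # maximal imbalance: |1-1/2| + |0-1/2|
            ([0.5, 0.25, 0.25], 1.0 / 3.0),
        ],
    )
    def test_hand_computed_values(self, priors, expected):
        assert main_objective_term(np.array(priors)) == pytest.approx(expected)

    def test_rejects_unnormalized_priors(self):
        with pytest.raises(ValueError, match="sum to 1"):
            main_objective_term(np.array([0.5, 0.2]))

    def test_bounded_and_zero_iff_uniform(self, rng):
        for _ in range(50):
            K = int(rng.integers(2, 10))
            w = rng.dirichlet(np.ones(K))
            val = main_objective_term(w)
            assert 0.0 <= val <= 2.0 * (K - 1) / K + 1e-12
        assert main_objective_term(np.full(7, 1 / 7)) == pytest.approx(0.0, abs=1e-12)


class TestPriorsFromHardAssignment:
    def test_balanced_and_degenerate_splits(self):
        np.testing.assert_allclose(
            priors_from_hard_assignment(np.array([0, 0, 1, 1]), 2), [0.5, 0.5]
        )
        np.testing.assert_allclose(
            priors_from_hard_assignment(np.zeros(5, dtype=int), 3), [1.0, 0.0, 0.0]
        )

    def test_matches_naive_counting(self, rng):
        assign = rng.integers(0, 6, size=1000)
        got = priors_from_hard_assignment(assign, 6)
        naive = np.array([(assign == k).sum() / 1000 for k in range(6)])
        np.testing.assert_array_equal(got, naive)
        assert got.sum() == pytest.approx(1.0, abs=1e-12)


class TestHardRegularizer:
    def test_zero_when_samples_on_means(self):
        pts = np.array([[0.0], [1.0]])
        assert hard_regularizer(SampleSet(pts), pts) == 0.0

    def test_hand_computed_single_mean(self):
        samples = SampleSet(np.array([[0.0], [1.0]]))
        assert hard_regularizer(samples, np.array([[0.5]])) == pytest.approx(0.25)

    def test_equals_quantization_error_over_T(self, rng):
        samples = SampleSet(rng.normal(size=(40, 2)))
        means = rng.normal(size=(5, 2))
        expected = kmeans_quantization_error(samples, means) / samples.T
        assert hard_regularizer(samples, means) == pytest.approx(expected, abs=1e-12)


class TestEstimateSoftParams:
    def test_balanced_assignment_gives_uniform_priors(self, two_blobs):
        means = np.array([[0.0, 0.0], [10.0, 10.0]])
        priors, _ = estimate_soft_params(two_blobs, means)
        np.testing.assert_allclose(priors, [0.5, 0.5])

    def test_identical_points_floor_the_variance(self):
        pts = np.tile(np.array([[1.0, 2.0]]), (5, 1))
        _, variances = estimate_soft_params(SampleSet(pts), np.array([[1.0, 2.0]]), floor=1e-6)
        np.testing.assert_array_equal(variances, np.full((1, 2), 1e-6))

    def test_empty_cluster_gets_zero_weight_floor_variance(self):
        pts = np.zeros((4, 1))
        means = np.array([[0.0], [100.0]])
        priors, variances = estimate_soft_params(SampleSet(pts), means, floor=1e-6)
        assert priors[1] == 0.0
        np.testing.assert_array_equal(variances[1], [1e-6])

    def test_matches_naive_per_cluster_moments(self, rng):
        pts = rng.normal(size=(50, 3))
        means = rng.normal(size=(4, 3))
        samples = SampleSet(pts)
        priors, variances = estimate_soft_params(samples, means, floor=1e-12)
        assign = hard_assign(samples, means)
        for k in range(4):
            members = pts[assign == k]
            assert priors[k] == pytest.approx(len(members) / 50)
            if len(members):
                naive = ((members - means[k]) ** 2).mean(axis=0)
                np.testing.assert_allclose(variances[k], np.maximum(naive, 1e-12), atol=1e-10)


class TestSoftRegularizer:
    def test_hand_computed_1d(self):
        # {0,1,2,3} vs means {0.5, 2.5}: each cluster has second moment 0.25
        # about its mean, every sample's Mahalanobis term is 0.25/0.25 = 1,
        # squared -> 1, averaged -> 1
        samples = SampleSet(np.array([[0.0], [1.0], [2.0], [3.0]]))
        means = np.array([[0.5], [2.5]])
        _, variances = estimate_soft_params(samples, means)
        assert soft_regularizer(samples, means, variances) == pytest.approx(1.0)

    def test_zero_when_samples_on_means(self):
        pts = np.array([[0.0], [5.0]])
        assert soft_regularizer(SampleSet(pts), pts, np.full((2, 1), 0.3)) == 0.0

    def test_doubling_variances_quarters_squared_terms(self, rng):
        samples = SampleSet(rng.normal(size=(30, 1)))
        means = np.array([[0.0]])
        var = np.array([[0.5]])
        base = soft_regularizer(samples, means, var, square=True)
        assert soft_regularizer(samples, means, 2 * var, square=True) == pytest.approx(base / 4)


class TestObjective:
    def _instance(self):
        return SampleSet(np.array([[0.0], [1.0], [2.0], [3.0]])), np.array([0.5, 2.5])

    def test_lambda_zero_balanced_hard(self):
        samples, means = self._instance()
        config = ObjectiveConfig(mode="hard", K=2, lam=0.0)
        assert objective(samples, means, config) == pytest.approx(0.0)

    def test_lambda_one_hard(self):
        samples, means = self._instance()
        config = ObjectiveConfig(mode="hard", K=2, lam=1.0)
        assert objective(samples, means, config) == pytest.approx(0.25)

    def test_lambda_one_soft(self):
        samples, means = self._instance()
        config = ObjectiveConfig(mode="soft", K=2, lam=1.0)
        assert objective(samples, means, config) == pytest.approx(1.0)

    def test_non_finite_candidate_returns_inf(self):
        samples, _ = self._instance()
        config = ObjectiveConfig(mode="hard", K=2)
        assert objective(samples, np.array([np.nan, 1.0]), config) == np.inf

    @pytest.mark.parametrize("mode", ["hard", "soft"])
    def test_matches_independent_naive_reimplementation(self, mode, rng):
        """Dual-route check: explicit scalar loops, no shared code."""
        for _ in range(100):
            T, K, d = int(rng.integers(5, 20)), int(rng.integers(2, 5)), int(rng.integers(1, 4))
            pts = rng.normal(size=(T, d))
            flat = rng.normal(size=K * d)
            lam = float(rng.uniform(0, 2))
            config = ObjectiveConfig(mode=mode, K=K, lam=lam, floor=1e-6)
            got = objective(SampleSet(pts), flat, config)

            means = flat.reshape(K, d)
            assign = []
            for t in range(T):
                dists = [sum((pts[t][j] - means[k][j]) ** 2 for j in range(d)) for k in range(K)]
                assign.append(dists.index(min(dists)))
            w = [assign.count(k) / T for k in range(K)]
            main = sum(abs(wk - 1.0 / K) for wk in w)
            if mode == "hard":
                reg = sum(
                    sum((pts[t][j] - means[assign[t]][j]) ** 2 for j in range(d))
                    for t in range(T)
                ) / T
            else:
                var = [[1e-6] * d for _ in range(K)]
                for k in range(K):
                    members = [t for t in range(T) if assign[t] == k]
                    if members:
                        for j in range(d):
                            m2 = sum((pts[t][j] - means[k][j]) ** 2 for t in members) / len(members)
                            var[k][j] = max(m2, 1e-6)
                reg = sum(
                    sum((pts[t][j] - means[assign[t]][j]) ** 2 / var[assign[t]][j] for j in range(d)) ** 2
                    for t in range(T)
                ) / T
            assert got == pytest.approx(main + lam * reg, abs=1e-10)


class TestMinimizeDerivativeFree:
    @pytest.mark.parametrize("algorithm", ["neldermead", "subplex", "cobyla", "powell"])
    def test_convex_quadratic_reaches_near_zero(self, algorithm):
        f = lambda x: float(np.sum(x**2))  # noqa: E731
        res = minimize_derivative_free(f, np.array([1.0, 1.0]), budget=200, algorithm=algorithm)
        assert res.best_objective <= 1e-4
        assert res.n_evals <= 200

    def test_constant_function_returns_start_value(self):
        res = minimize_derivative_free(lambda x: 7.0, np.array([1.0, 2.0]), budget=50,
                                       algorithm="neldermead")
        assert res.best_objective == 7.0

    def test_budget_one_returns_x0_unchanged(self):
        x0 = np.array([3.0, -1.0])
        res = minimize_derivative_free(lambda x: float(np.sum(x**2)), x0, budget=1,
                                       algorithm="subplex")
        np.testing.assert_array_equal(res.best_flat_means, x0)
        assert res.best_objective == pytest.approx(10.0)
        assert res.n_evals == 1

    def test_best_never_worse_than_start(self, rng):
        rastrigin = lambda x: float(  # noqa: E731
            10 * len(x) + np.sum(x**2 - 10 * np.cos(2 * np.pi * x))
        )
        for algorithm in ["neldermead", "subplex", "cobyla"]:
            x0 = rng.uniform(-3, 3, size=6)
            res = minimize_derivative_free(rastrigin, x0, budget=300, algorithm=algorithm)
            assert res.best_objective <= rastrigin(x0) + 1e-15

    def test_unknown_algorithm_lists_backends(self):
        with pytest.raises(ValueError, match="subplex"):
            minimize_derivative_free(lambda x: 0.0, np.zeros(2), budget=10, algorithm="cmaes")

    def test_trace_is_monotone_improvements(self):
        f = lambda x: float(np.sum(x**2))  # noqa: E731
        res = minimize_derivative_free(f, np.array([2.0, 2.0]), budget=100, algorithm="subplex")
        values = [v for _, v in res.trace]
        assert values == sorted(values, reverse=True)
        assert res.best_objective == min(values)


class TestFitPpoc:
    def test_one_point_per_cluster_balances_exactly(self, rng):
        pts = rng.uniform(size=(4, 2)) * 10
        samples = SampleSet(pts)
        cb, res = fit_ppoc(samples, 4, mode="hard", budget=50, trials=1, warmstart_iters=5)
        assert main_objective_term(cb.priors) == pytest.approx(0.0)

    @pytest.mark.parametrize("mode", ["hard", "soft"])
    def test_improves_on_own_kmeans_warm_start(self, two_blobs, mode):
        config = ObjectiveConfig(mode=mode, K=2)
        warm, _ = kmeans_fit(two_blobs, 2, max_iter=10, seed=0)
        warm_J = objective(two_blobs, warm.means.ravel(), config)
        cb, res = fit_ppoc(two_blobs, 2, config=config, budget=100, trials=1, seeds=[0])
        assert res.best_objective <= warm_J + 1e-15

    def test_balanced_separated_recovery(self):
        """On 6 well-separated equal-size clusters the fitted priors are
        uniform and each mean sits near a true cluster center."""
        gen = np.random.default_rng(3)
        centers = np.array([[i, j] for i in range(3) for j in range(2)], dtype=float) * 5
        pts = np.vstack([gen.normal(c, 0.1, size=(40, 2)) for c in centers])
        samples = SampleSet(pts)
        cb, _ = fit_ppoc(samples, 6, mode="hard", budget=400, trials=2)
        assert main_objective_term(cb.priors) < 0.02
        for c in centers:
            nearest = np.min(np.linalg.norm(cb.means - c, axis=1))
            assert nearest < 3 * 0.1 / np.sqrt(40) + 0.05
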