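import numpy as np
import pytest

from mrsisep import (
    FactorizationConfig,
    InitResult,
    Method,
    PGParams,
    factorize,
    match_sources,
    reconstruction_error,
)
from mrsisep.initializers import init_kmeans, init_random
from mrsisep.nmf import (
    _obs_adjust_columns,
    _pg_subproblem,
    als_step,
    alsobs_step,
    alspg_step,
    convex_step,
    euc_step,
)

rng = np.random.default_rng(7)


def _exact_rank2(p=12, n=9, seed=0):
    r = np.random.default_rng(seed)
    W = r.uniform(0.1, 1.0, size=(p, 2))
    W /= W.sum(axis=0)  # unit column sums, the euc normalization convention
    H = r.uniform(0.1, 1.0, size=(2, n))
    return W, H, W @ H


class TestEuc:
    def test_fixed_point_at_exact_factorization(self):
        W, H, X = _exact_rank2()
        W1, H1 = euc_step(W, H, X)
        np.testing.assert_allclose(W1, W, atol=1e-6)
        np.testing.assert_allclose(H1, H, atol=1e-6)

    def test_columns_sum_to_one_after_step(self):
        W = rng.uniform(size=(10, 2))
        H = rng.uniform(size=(2, 6))
        X = rng.uniform(size=(10, 6))
        W1, _ = euc_step(W, H, X)
        np.testing.assert_allclose(W1.sum(axis=0), 1.0, atol=1e-9)

    def test_rescaling_preserves_reconstruction(self):
        W = rng.uniform(size=(10, 2))
        H = rng.uniform(size=(2, 6))
        X = rng.uniform(size=(10, 6))
        # one raw multiplicative update without rescaling, for comparison
        H_raw = H * (W.T @ X) / (W.T @ W @ H + 1e-12)
        W_raw = W * (X @ H_raw.T) / (W @ H_raw @ H_raw.T + 1e-12)
        W1, H1 = euc_step(W, H, X)
        np.testing.assert_allclose(W1 @ H1, W_raw @ H_raw, atol=1e-12)

    def test_error_trajectory_non_increasing(self):
        X = np.random.default_rng(1).uniform(size=(20, 10))
        res = factorize(
            X,
            FactorizationConfig(method=Method.EUC, k=2, max_iter=200, tol=0.0),
            init_random(X, 2, seed=3),
        )
        assert np.all(np.diff(res.error_trajectory) <= 1e-10)

    def test_mixed_sign_input_rejected(self):
        X = np.array([[1.0, -1.0], [2.0, 3.0]])
        with pytest.raises(ValueError, match="magnitude_transform"):
            factorize(X, FactorizationConfig(method=Method.EUC, k=1),
                      init_random(X, 1, seed=0))


class TestAls:
    def test_exact_start_unchanged(self):
        W, H, X = _exact_rank2()
        W1, H1 = als_step(W, H, X)
        np.testing.assert_allclose(W1, W, atol=1e-9)
        np.testing.assert_allclose(H1, H, atol=1e-9)

    def test_outputs_nonnegative(self):
        X = rng.uniform(size=(15, 8))
        W = rng.uniform(size=(15, 2))
        H = rng.uniform(size=(2, 8))
        for _ in range(10):
            W, H = als_step(W, H, X)
            assert W.min() >= 0 and H.min() >= 0

    def test_single_column_closed_form(self):
        # k=1, one voxel: H = max(0, (w.x)/(w.w))
        w = rng.uniform(size=(6, 1))
        x = rng.normal(size=(6, 1)) + 1.0
        _, H1 = als_step(w, np.array([[0.3]]), np.abs(x))
        expected = max(0.0, float(w[:, 0] @ np.abs(x)[:, 0]) / float(w[:, 0] @ w[:, 0]))
        assert H1[0, 0] == pytest.approx(expected, rel=1e-12)


class TestAlspg:
    def test_noop_at_exact_factorization(self):
        W, H, X = _exact_rank2()
        W1, H1 = alspg_step(W, H, X)
        np.testing.assert_allclose(W1, W, atol=1e-12)
        np.testing.assert_allclose(H1, H, atol=1e-12)

    def test_subproblem_objective_never_increases(self):
        X = rng.uniform(size=(12, 8))
        W = rng.uniform(size=(12, 2))
        H = rng.uniform(size=(2, 8))
        for _ in range(20):
            e0 = reconstruction_error(X, W, H)
            H = _pg_subproblem(W.T @ W, W.T @ X, H, PGParams())
            e1 = reconstruction_error(X, W, H)
            assert e1 <= e0 + 1e-12
            W = _pg_subproblem(H @ H.T, H @ X.T, W.T, PGParams()).T
            assert reconstruction_error(X, W, H) <= e1 + 1e-12

    def test_scalar_problem_converges_to_nnls_solution(self):
        # minimize 0.5 (a f - b)^2 over f >= 0 -> f* = max(0, b/a).
        # accuracy is limited by objective cancellation in the line
        # search near the optimum (~sqrt(machine eps) on the iterate)
        a, b = 2.0, -3.0
        F = _pg_subproblem(np.array([[a * a]]), np.array([[a * b]]),
                           np.array([[5.0]]), PGParams(inner_iters=200))
        assert F[0, 0] == pytest.approx(max(0.0, b / a), abs=1e-7)
        a, b = 2.0, 3.0
        F = _pg_subproblem(np.array([[a * a]]), np.array([[a * b]]),
                           np.array([[5.0]]), PGParams(inner_iters=200))
        assert F[0, 0] == pytest.approx(b / a, abs=1e-6)


class TestAlsobs:
    def test_identity_when_no_negative_elements(self):
        W, H, X = _exact_rank2()
        W1, H1 = alsobs_step(W, H, X)
        Wa, Ha = als_step(W, H, X)
        np.testing.assert_allclose(H1, Ha, atol=1e-9)
        np.testing.assert_allclose(W1, Wa, atol=1e-9)

    def test_large_damping_reduces_to_plain_als(self):
        X = rng.uniform(size=(10, 7))
        W = rng.uniform(size=(10, 3))
        H = rng.uniform(size=(3, 7))
        W1, H1 = alsobs_step(W, H, X, lambda_w=1e9, lambda_h=1e9)
        Wa, Ha = als_step(W, H, X)
        np.testing.assert_allclose(H1, Ha, atol=1e-6)
        np.testing.assert_allclose(W1, Wa, atol=1e-6)

    def test_single_prune_matches_textbook_obs(self):
        # 2x2 damped Hessian, one pruned coordinate: the closed form is
        # delta = -(f_j / (A^-1)_jj) A^-1 e_j
        A = np.array([[2.0, 0.5], [0.5, 1.0]])
        lam = 1e-3
        f = np.array([[0.8], [-0.3]])
        out = _obs_adjust_columns(f, A, lam)
        Ad = A + lam * np.eye(2)
        Ainv = np.linalg.inv(Ad)
        delta = -(f[1, 0] / Ainv[1, 1]) * Ainv[:, 1]
        expected = np.maximum(f[:, 0] + delta, 0.0)
        np.testing.assert_allclose(out[:, 0], expected, atol=1e-12)
        assert out[1, 0] == pytest.approx(0.0, abs=1e-12)


class TestConvex:
    def test_fixed_point_on_nonnegative_gram_identity(self):
        X = np.eye(3)
        G = np.eye(3)
        H = np.eye(3)
        G1, H1 = convex_step(G, H, X)
        np.testing.assert_allclose(G1, G, atol=1e-6)
        np.testing.assert_allclose(H1, H, atol=1e-6)

    def test_factors_stay_nonnegative(self):
        X = rng.normal(size=(15, 8))
        G = rng.uniform(size=(8, 2))
        H = rng.uniform(size=(2, 8))
        for _ in range(100):
            G, H = convex_step(G, H, X)
            assert G.min() >= 0 and H.min() >= 0

    def test_error_non_increasing_on_mixed_sign_data(self):
        X = np.random.default_rng(11).normal(size=(15, 8))
        res = factorize(
            X,
            FactorizationConfig(method=Method.CONVEX, k=2, max_iter=500, tol=0.0),
            init_random(X, 2, seed=0, convex=True),
        )
        assert np.all(np.diff(res.error_trajectory) <= 1e-8)

    def test_sources_lie_in_column_space(self):
        X = rng.normal(size=(12, 9))
        res = factorize(
            X,
            FactorizationConfig(method=Method.CONVEX, k=2, max_iter=50, tol=0.0),
            init_random(X, 2, seed=1, convex=True),
        )
        np.testing.assert_array_equal(res.W, X @ res.G)
        assert np.all(res.G >= 0)


class TestFactorizeDriver:
    def test_converges_immediately_at_exact_factorization(self):
        W, H, X = _exact_rank2()
        res = factorize(X, FactorizationConfig(method=Method.EUC, k=2),
                        InitResult(W0=W, H0=H))
        assert res.converged and res.iterations <= 2
        assert res.final_error < 1e-8

    def test_recovers_phantom_sources(self, phantom_clean):
        X = phantom_clean.dataset.X
        res = factorize(X, FactorizationConfig(method=Method.CONVEX, k=2),
                        init_kmeans(X, 2, seed=0, convex=True))
        _, score = match_sources(res.W, phantom_clean.true_sources)
        assert score > 0.99

    def test_deterministic_given_init(self):
        X = rng.uniform(size=(10, 6))
        init = init_random(X, 2, seed=4)
        a = factorize(X, FactorizationConfig(method=Method.EUC, k=2, max_iter=50), init)
        b = factorize(X, FactorizationConfig(method=Method.EUC, k=2, max_iter=50), init)
        np.testing.assert_array_equal(a.W, b.W)
        np.testing.assert_array_equal(a.H, b.H)

    def test_convex_requires_g0(self):
        X = rng.normal(size=(10, 6))
        with pytest.raises(ValueError, match="G0"):
            factorize(X, FactorizationConfig(method=Method.CONVEX, k=2),
                      init_random(X, 2, seed=0, convex=False))
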