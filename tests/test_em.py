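import numpy as np
import pytest
from scipy.optimize import minimize

from conftest import dataset_with_exact_covariance, random_model
from timefactor.em import (
    FitConfig,
    FitResult,
    e_step,
    estimate_latents,
    fit,
    initialize_parameters,
    m_step,
    run_em,
)
from timefactor.model import (
    IntervalDataset,
    TimingModel,
    log_likelihood,
    model_covariance,
    sample_dataset,
)


class TestInitialization:
    def test_ranges_follow_interval_variability(self, small_dataset, rng):
        col_var = small_dataset.centered().var(axis=0)
        draws_w, draws_e, draws_x = [], [], []
        for _ in range(500):
            m = initialize_parameters(small_dataset, 1, rng)
            draws_w.append(m.global_weights[:, 0])
            draws_e.append(m.independent_vars)
            draws_x.append(m.jitter_vars)
        assert np.all(np.asarray(draws_w) >= 0)
        assert np.all(np.asarray(draws_w) <= np.sqrt(col_var))
        assert np.all(np.asarray(draws_e) <= col_var)
        assert np.all(np.asarray(draws_x) <= 0.5 * col_var.mean())

    def test_constant_interval_gets_zero_scale(self, rng):
        Y = np.column_stack([np.full(30, 80.0), 50 + rng.normal(0, 1, 30), 60 + rng.normal(0, 1, 30)])
        data = IntervalDataset(Y)
        m = initialize_parameters(data, 1, np.random.default_rng(0))
        assert m.global_weights[0, 0] == 0.0
        assert m.independent_vars[0] == 0.0

    def test_deterministic_under_seed(self, small_dataset):
        a = initialize_parameters(small_dataset, 2, np.random.default_rng(42))
        b = initialize_parameters(small_dataset, 2, np.random.default_rng(42))
        np.testing.assert_array_equal(a.global_weights, b.global_weights)


def test_workspace_block_structure(small_model):
    from timefactor.em import EStepWorkspace

    ws = EStepWorkspace.from_model(small_model)
    K, M = small_model.n_intervals, small_model.n_global
    np.testing.assert_array_equal(ws.A[:, M:], small_model.differencing)
    np.testing.assert_array_equal(ws.A[:, :M], small_model.global_weights)
    np.testing.assert_array_equal(ws.C[:M, :M], np.eye(M))
    np.testing.assert_array_equal(ws.C[:M, M:], np.zeros((M, K - 1)))
    np.testing.assert_array_equal(ws.C[M:, M:], np.diag(small_model.jitter_vars))


def conditioning_oracle(model, Y):
    """Posterior of u=[z,x] by brute-force joint-Gaussian conditioning.

    Assembles the full (u, y) covariance and conditions via the Schur
    complement; independent of the precision-form E step it checks.
    """
    K, M = model.n_intervals, model.n_global
    A = np.hstack([model.global_weights, model.differencing])
    C = np.diag(np.concatenate([np.ones(M), model.jitter_vars]))
    S = A @ C @ A.T + np.diag(model.independent_vars)
    cov_uy = C @ A.T
    gain = np.linalg.solve(S, cov_uy.T).T  # C A' S^-1
    post_cov = C - gain @ cov_uy.T
    post_mean = Y @ gain.T
    return post_mean, post_cov


class TestEStep:
    @pytest.mark.parametrize("trial", range(10))
    def test_matches_joint_gaussian_conditioning(self, trial):
        rng = np.random.default_rng(100 + trial)
        K = int(rng.integers(3, 7))
        M = int(rng.integers(1, 4))
        model = random_model(rng, K, M)
        data, _ = sample_dataset(model, 40, seed=int(rng.integers(2**31)))
        post = e_step(model, data)
        mean_oracle, cov_oracle = conditioning_oracle(model, data.centered())
        np.testing.assert_allclose(post.post_cov, cov_oracle, atol=1e-10)
        np.testing.assert_allclose(post.post_mean, mean_oracle, atol=1e-10)

    def test_uninformative_likelihood_recovers_prior(self, small_model, small_dataset):
        vague = small_model.copy()
        vague.independent_vars = np.full(3, 1e8 * small_dataset.durations.var())
        post = e_step(vague, small_dataset)
        C = np.diag(np.concatenate([[1.0], vague.jitter_vars]))
        np.testing.assert_allclose(post.post_cov, C, atol=1e-3)
        np.testing.assert_allclose(post.post_mean, 0.0, atol=1e-3)

    def test_second_moment_identity(self, small_model, small_dataset):
        post = e_step(small_model, small_dataset)
        expected = post.post_cov + post.post_mean.T @ post.post_mean / small_dataset.n_trials
        np.testing.assert_allclose(post.second_moment, expected, atol=1e-12)


def expected_complete_loglik(W, psi_e, psi_x, post, data, T):
    """Oracle: expected complete-data log-likelihood under the posterior."""
    K = data.n_intervals
    N = data.n_trials
    Y = data.centered()
    S_hat = Y.T @ Y / N
    Syu = Y.T @ post.post_mean / N
    U2 = post.second_moment
    A = np.hstack([W.reshape(K, -1), T])
    M = A.shape[1] - (K - 1)
    C = np.diag(np.concatenate([np.ones(M), psi_x]))
    quad_y = np.trace(np.diag(1.0 / psi_e) @ (S_hat - 2 * Syu @ A.T + A @ U2 @ A.T))
    quad_u = np.trace(np.linalg.solve(C, U2))
    return -0.5 * N * (
        np.sum(np.log(psi_e)) + quad_y + np.log(np.linalg.det(C)) + quad_u
    )


class TestMStep:
    def test_population_fixed_point(self, small_model, rng):
        # data whose sample covariance equals the model covariance exactly:
        # one EM cycle must return the very same parameters
        S = model_covariance(small_model)
        data = dataset_with_exact_covariance(S, small_model.means, 60, rng)
        post = e_step(small_model, data)
        new = m_step(post, data, small_model)
        np.testing.assert_allclose(new.global_weights, small_model.global_weights, atol=1e-8)
        np.testing.assert_allclose(new.independent_vars, small_model.independent_vars, atol=1e-8)
        np.testing.assert_allclose(new.jitter_vars, small_model.jitter_vars, atol=1e-8)

    def test_matches_numerical_maximizer(self, small_model):
        data, _ = sample_dataset(small_model, 400, seed=1)
        current = TimingModel(
            np.array([0.7, 1.5, 2.5]),
            np.array([1.5, 0.9, 1.0]),
            np.array([0.3, 0.4]),
            data.column_means(),
        )
        post = e_step(current, data)
        T = current.differencing
        K = 3

        def neg(theta):
            return -expected_complete_loglik(
                theta[:K], theta[K : 2 * K], theta[2 * K :], post, data, T
            )

        x0 = np.concatenate(
            [current.global_weights.ravel(), current.independent_vars, current.jitter_vars]
        )
        res = minimize(
            neg,
            x0,
            method="L-BFGS-B",
            bounds=[(None, None)] * K + [(1e-8, None)] * (2 * K - 1),
            options={"maxiter": 20000, "ftol": 1e-15, "gtol": 1e-12},
        )
        closed = m_step(post, data, current)
        numeric = np.concatenate(
            [res.x[:K], res.x[K : 2 * K], res.x[2 * K :]]
        )
        closed_vec = np.concatenate(
            [closed.global_weights.ravel(), closed.independent_vars, closed.jitter_vars]
        )
        np.testing.assert_allclose(closed_vec, numeric, rtol=1e-4)

    def test_update_never_decreases_loglik(self):
        # EM guarantee on random tiny instances
        for trial in range(30):
            rng = np.random.default_rng(300 + trial)
            truth = random_model(rng, int(rng.integers(3, 6)))
            data, _ = sample_dataset(truth, 80, seed=int(rng.integers(2**31)))
            current = initialize_parameters(data, 1, rng)
            current.independent_vars = np.maximum(current.independent_vars, 1e-6)
            current.jitter_vars = np.maximum(current.jitter_vars, 1e-6)
            before = log_likelihood(current, data)
            post = e_step(current, data)
            after = log_likelihood(m_step(post, data, current), data)
            assert after >= before - 1e-9


class TestRunEm:
    def test_trace_non_decreasing(self, small_model):
        data, _ = sample_dataset(small_model, 300, seed=2)
        init = initialize_parameters(data, 1, np.random.default_rng(0))
        _, trace, converged = run_em(data, 1, init, tol=1e-8)
        assert converged
        assert np.all(np.diff(trace) > -1e-9)

    def test_deterministic_given_init(self, small_model):
        data, _ = sample_dataset(small_model, 300, seed=2)
        init = initialize_parameters(data, 1, np.random.default_rng(3))
        m1, t1, _ = run_em(data, 1, init, tol=1e-7)
        m2, t2, _ = run_em(data, 1, init, tol=1e-7)
        np.testing.assert_array_equal(t1, t2)
        np.testing.assert_array_equal(m1.global_weights, m2.global_weights)

    def test_fit_dominates_truth_on_sample(self, small_model):
        # the ML fit cannot be beaten by the generating parameters on the
        # same sample
        data, _ = sample_dataset(small_model, 2000, seed=4)
        result = fit(data, 1, FitConfig(n_restarts=5, n_keep=2, seed=0))
        assert result.loglik >= log_likelihood(small_model, data) - 1e-6


class TestCompiledKernel:
    def test_matches_pure_numpy_iteration(self, small_model, monkeypatch):
        # the jitted loop must reproduce the reference NumPy EM path
        import timefactor.em as em_mod

        if not em_mod.HAVE_NUMBA:
            return
        data, _ = sample_dataset(small_model, 250, seed=12)
        init = initialize_parameters(data, 1, np.random.default_rng(6))
        m_fast, t_fast, c_fast = run_em(data, 1, init, tol=1e-7, max_iter=500)
        monkeypatch.setattr(em_mod, "HAVE_NUMBA", False)
        m_ref, t_ref, c_ref = run_em(data, 1, init, tol=1e-7, max_iter=500)
        assert c_fast == c_ref and len(t_fast) == len(t_ref)
        np.testing.assert_allclose(t_fast, t_ref, atol=1e-7)
        np.testing.assert_allclose(m_fast.global_weights, m_ref.global_weights, atol=1e-10)
        np.testing.assert_allclose(m_fast.independent_vars, m_ref.independent_vars, atol=1e-10)
        np.testing.assert_allclose(m_fast.jitter_vars, m_ref.jitter_vars, atol=1e-10)


class TestFit:
    def test_best_restart_dominates(self, small_model):
        data, _ = sample_dataset(small_model, 300, seed=6)
        result = fit(data, 1, FitConfig(n_restarts=6, n_keep=3, seed=1))
        finite = result.restart_logliks[np.isfinite(result.restart_logliks)]
        assert result.loglik >= finite.max() - 1e-9
        assert result.converged

    def test_rejects_degenerate_factor_count(self, small_dataset):
        with pytest.raises(ValueError):
            fit(small_dataset, 0, FitConfig(n_restarts=2, n_keep=1, seed=0))

    def test_rejects_too_few_trials(self, small_model):
        data, _ = sample_dataset(small_model, 3, seed=0)
        with pytest.raises(ValueError):
            fit(data, 1, FitConfig(n_restarts=2, n_keep=1, seed=0))


class TestLatentEstimates:
    def test_residual_identity_exact(self, small_model):
        data, _ = sample_dataset(small_model, 150, seed=8)
        result = fit(data, 1, FitConfig(n_restarts=4, n_keep=2, seed=2))
        table = estimate_latents(result)
        m = result.model
        z = table[["z1"]].to_numpy()
        x = table[["x1", "x2"]].to_numpy()
        e = table[["e1", "e2", "e3"]].to_numpy()
        recon = m.means + z @ m.global_weights.T + x @ m.differencing.T + e
        np.testing.assert_allclose(recon, data.durations, atol=1e-10)

    def test_prior_dominated_limit_shrinks_latents(self, small_model, small_dataset):
        vague = small_model.copy()
        vague.independent_vars = np.full(3, 1e8 * small_dataset.durations.var())
        post = e_step(vague, small_dataset)
        assert np.max(np.abs(post.post_mean)) < 1e-3

    def test_metadata_carried_through(self, small_model):
        import pandas as pd

        data, _ = sample_dataset(small_model, 50, seed=8)
        data = IntervalDataset(
            data.durations,
            trial_meta=pd.DataFrame({"meta_day": np.repeat([1, 2], 25)}),
        )
        result = fit(data, 1, FitConfig(n_restarts=3, n_keep=1, seed=2))
        table = estimate_latents(result)
        assert "meta_day" in table.columns
        assert len(table) == 50
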