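import numpy as np
import pytest
from scipy import stats

from timefactor.model import (
    IntervalDataset,
    SingularCovarianceWarning,
    TimingModel,
    build_differencing_matrix,
    log_likelihood,
    model_covariance,
    sample_dataset,
)


class TestDifferencingMatrix:
    @pytest.mark.parametrize(
        "K, expected",
        [
            (2, [[1.0], [-1.0]]),
            (3, [[1.0, 0.0], [-1.0, 1.0], [0.0, -1.0]]),
        ],
    )
    def test_small_cases(self, K, expected):
        np.testing.assert_array_equal(build_differencing_matrix(K), expected)

    @pytest.mark.parametrize("K", [2, 3, 7, 20])
    def test_column_sums_zero(self, K):
        # a boundary shift conserves total sequence length
        T = build_differencing_matrix(K)
        np.testing.assert_array_equal(T.sum(axis=0), np.zeros(K - 1))
        assert T.shape == (K, K - 1)

    def test_rejects_degenerate_dimension(self):
        with pytest.raises(ValueError):
            build_differencing_matrix(1)


class TestModelCovariance:
    def test_pure_independent_noise_gives_identity(self):
        m = TimingModel(np.zeros((3, 1)), np.ones(3), np.zeros(2), np.full(3, 100.0))
        np.testing.assert_allclose(model_covariance(m), np.eye(3))

    def test_pure_shared_factor_gives_all_ones(self):
        m = TimingModel(np.ones((3, 1)), np.zeros(3), np.zeros(2), np.full(3, 100.0))
        np.testing.assert_allclose(model_covariance(m), np.ones((3, 3)))

    def test_adjacent_covariance_decreases_with_jitter(self, small_model):
        # covariance of neighbours is w_k w_{k+1} minus the shared-boundary jitter
        S = model_covariance(small_model)
        w = small_model.global_weights[:, 0]
        assert S[0, 1] == pytest.approx(w[0] * w[1] - small_model.jitter_vars[0])
        assert S[1, 2] == pytest.approx(w[1] * w[2] - small_model.jitter_vars[1])
        bumped = small_model.copy()
        bumped.jitter_vars = small_model.jitter_vars + np.array([0.3, 0.0])
        assert model_covariance(bumped)[0, 1] == pytest.approx(S[0, 1] - 0.3)

    def test_matches_large_sample_covariance(self, small_model):
        # Monte-Carlo oracle: the sample covariance of simulated trials
        # converges on the analytic covariance
        data, _ = sample_dataset(small_model, 1_000_000, seed=11)
        S = model_covariance(small_model)
        rel = np.linalg.norm(data.sample_covariance() - S) / np.linalg.norm(S)
        assert rel < 0.01


class TestLogLikelihood:
    def test_degenerate_data_under_identity_covariance(self):
        m = TimingModel(np.zeros((3, 1)), np.ones(3), np.zeros(2), np.full(3, 100.0))
        data = IntervalDataset(np.full((50, 3), 100.0))
        assert log_likelihood(m, data) == pytest.approx(-(50 * 3 / 2) * np.log(2 * np.pi))

    def test_matches_multivariate_normal_oracle(self, small_model, small_dataset):
        S = model_covariance(small_model)
        Y = small_dataset.centered()
        expected = stats.multivariate_normal(mean=np.zeros(3), cov=S).logpdf(Y).sum()
        assert log_likelihood(small_model, small_dataset) == pytest.approx(expected, abs=1e-8)

    def test_invariant_to_column_shift(self, small_model, small_dataset):
        shifted = IntervalDataset(small_dataset.durations + np.array([5.0, 0.0, 0.0]))
        assert log_likelihood(small_model, shifted) == pytest.approx(
            log_likelihood(small_model, small_dataset), rel=1e-12
        )

    def test_singular_covariance_reports_not_crashes(self, small_dataset):
        m = TimingModel(np.zeros((3, 1)), np.zeros(3), np.zeros(2), np.full(3, 100.0))
        with pytest.warns(SingularCovarianceWarning):
            assert log_likelihood(m, small_dataset) == -np.inf


class TestSampleDataset:
    def test_noiseless_model_reproduces_means(self):
        m = TimingModel(np.zeros((4, 1)), np.zeros(4), np.zeros(3), np.array([50.0, 60, 70, 80]))
        data, draws = sample_dataset(m, 10, seed=0)
        np.testing.assert_array_equal(data.durations, np.tile(m.means, (10, 1)))
        np.testing.assert_array_equal(draws.x, np.zeros((10, 3)))

    def test_fixed_seed_is_bit_identical(self, small_model):
        a, _ = sample_dataset(small_model, 100, seed=5)
        b, _ = sample_dataset(small_model, 100, seed=5)
        np.testing.assert_array_equal(a.durations, b.durations)

    def test_jitter_never_changes_sequence_length(self, small_model):
        # row-sum variance is (sum w)^2 + sum psi_e regardless of jitter
        analytic = small_model.global_weights.sum() ** 2 + small_model.independent_vars.sum()
        jittery = small_model.copy()
        jittery.jitter_vars = small_model.jitter_vars * 10
        data, _ = sample_dataset(jittery, 1_000_000, seed=3)
        observed = data.durations.sum(axis=1).var()
        assert observed == pytest.approx(analytic, rel=0.01)

    def test_returned_latents_reconstruct_durations(self, small_model):
        data, draws = sample_dataset(small_model, 20, seed=9)
        recon = (
            small_model.means
            + draws.z @ small_model.global_weights.T
            + draws.x @ small_model.differencing.T
            + draws.e
        )
        np.testing.assert_allclose(data.durations, recon, atol=1e-12)


class TestValidation:
    def test_dataset_rejects_nonpositive_durations(self):
        with pytest.raises(ValueError):
            IntervalDataset(np.array([[1.0, 2.0, -1.0], [1.0, 2.0, 3.0]]))

    def test_dataset_rejects_too_few_intervals(self):
        with pytest.raises(ValueError):
            IntervalDataset(np.ones((5, 2)))

    def test_model_rejects_negative_variances(self):
        with pytest.raises(ValueError):
            TimingModel(np.ones((3, 1)), np.array([1.0, -0.1, 1.0]), np.zeros(2), np.ones(3))

    def test_model_json_dict_round_trip(self, small_model):
        clone = TimingModel.from_dict(small_model.to_dict())
        np.testing.assert_array_equal(clone.global_weights, small_model.global_weights)
        np.testing.assert_array_equal(clone.jitter_vars, small_model.jitter_vars)
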