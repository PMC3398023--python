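import numpy as np
import pytest

from timefactor.model import IntervalDataset, TimingModel, sample_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_model():
    """K=3, M=1 model with all three variance components active."""
    return TimingModel(
        global_weights=np.array([1.0, 2.0, 3.0]),
        independent_vars=np.array([1.0, 1.2, 0.8]),
        jitter_vars=np.array([0.5, 0.25]),
        means=np.array([100.0, 80.0, 120.0]),
    )


def random_model(rng, n_intervals, n_global=1, mean_scale=100.0):
    """Random well-conditioned model at song-like scale."""
    W = rng.uniform(0.4, 1.5, size=(n_intervals, n_global)) * rng.choice(
        [1.0, 1.0, 1.0, -1.0], size=(n_intervals, n_global)
    )
    psi_e = rng.uniform(0.4, 2.0, size=n_intervals)
    psi_x = rng.uniform(0.3, 1.5, size=n_intervals - 1)
    means = rng.uniform(0.5, 2.0, size=n_intervals) * mean_scale
    return TimingModel(W, psi_e, psi_x, means)


def dataset_with_exact_covariance(S, means, n_trials, rng):
    """A dataset whose 1/N sample covariance equals ``S`` exactly.

    Whitens a random centered matrix to an exact identity sample covariance,
    then colours it by the Cholesky factor of ``S`` -- the empirical
    analogue of an infinite-data (population) E step.
    """
    K = S.shape[0]
    Z = rng.standard_normal((n_trials, K))
    Z -= Z.mean(axis=0)
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    white = U @ Vt * np.sqrt(n_trials)
    L = np.linalg.cholesky(S)
    Y = white @ L.T + np.asarray(means)
    return IntervalDataset(Y)


@pytest.fixture
def small_dataset(small_model):
    data, _ = sample_dataset(small_model, 200, seed=7)
    return data
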