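"""Generative model of trial-to-trial variability in action-sequence timing.

A rendition of a stereotyped K-interval sequence (for birdsong: syllables
and the silent gaps between them) deviates from its mean durations through
three kinds of latent timing noise:

* **global (tempo) factors** ``z`` -- M shared unit-variance factors whose
  weight matrix ``W`` (msec per unit latent) stretches or compresses many
  intervals together;
* **boundary jitter** ``x`` -- noise at each of the K-1 internal interval
  boundaries that lengthens one interval exactly as much as it shortens its
  neighbour, the Wing-Kristofferson signature of downstream timing noise;
* **independent noise** ``e`` -- per-interval noise, uncorrelated across
  intervals and trials.

With row-vector conventions the duration vector of trial ``n`` is

    y_n = mu + z_n W' + x_n T' + e_n

where ``T`` is the K x (K-1) differencing matrix mapping boundary shifts to
interval-length deviations.  All latents are zero mean and mutually
independent; ``z`` has unit variance, ``x`` and ``e`` have diagonal
covariances ``diag(psi_x)`` and ``diag(psi_e)`` (msec^2).  The implied
covariance of ``y`` is

    S = W W' + T diag(psi_x) T' + diag(psi_e)

Boundary jitter induces *negative* covariance between adjacent intervals,
which is how it can be separated from the other two components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "INTERVAL_LABELS",
    "SingularCovarianceWarning",
    "TimingModel",
    "IntervalDataset",
    "LatentDraws",
    "GaussianLatentSampler",
    "build_differencing_matrix",
    "model_covariance",
    "log_likelihood",
    "sample_dataset",
]

#: Recognized interval types (vocalization, silence within a motif, silence
#: between motifs).
INTERVAL_LABELS = ("syllable", "gap_within", "gap_between")

LN_2PI = float(np.log(2.0 * np.pi))


class SingularCovarianceWarning(UserWarning):
    """Model covariance is numerically singular; likelihood reported as -inf."""


def build_differencing_matrix(n_intervals: int) -> np.ndarray:
    """Return the K x (K-1) differencing matrix ``T``.

    Column ``k`` (0-based) represents the internal boundary between interval
    ``k`` and interval ``k+1``: ``T[k, k] = +1`` (the boundary shifts the
    offset of interval ``k``) and ``T[k+1, k] = -1`` (it shifts the onset of
    interval ``k+1``).  Column sums are exactly zero, so boundary jitter
    never changes the total length of a sequence.
    """
    if n_intervals < 2:
        raise ValueError(f"need at least 2 intervals to have a boundary, got {n_intervals}")
    T = np.zeros((n_intervals, n_intervals - 1))
    idx = np.arange(n_intervals - 1)
    T[idx, idx] = 1.0
    T[idx + 1, idx] = -1.0
    return T


@dataclass
class TimingModel:
    """All parameters of the timing-variability model for one sequence.

    Parameters
    ----------
    global_weights : (K, M) array
        Weight matrix ``W`` in msec per unit latent.  A 1-D array of length
        K is accepted for M=1 and reshaped to a column.
    independent_vars : (K,) array
        Per-interval independent variances ``psi_e`` (msec^2), >= 0.
    jitter_vars : (K-1,) array
        Variances ``psi_x`` of the K-1 *internal* boundary jitters (msec^2),
        >= 0.  ``jitter_vars[k]`` belongs to the boundary between interval
        ``k`` and ``k+1`` (0-based).  Jitter at the first onset and last
        offset of the sequence is not separately identifiable and is
        absorbed into ``independent_vars`` of the edge intervals.
    means : (K,) array
        Mean interval durations ``mu`` (msec); used for simulation offsets
        and CV-type diagnostics only.
    """

    global_weights: np.ndarray
    independent_vars: np.ndarray
    jitter_vars: np.ndarray
    means: np.ndarray

    def __post_init__(self) -> None:
        W = np.asarray(self.global_weights, dtype=float)
        if W.ndim == 1:
            W = W[:, None]
        if W.ndim != 2:
            raise ValueError("global_weights must be a (K, M) matrix")
        self.global_weights = W
        self.independent_vars = np.asarray(self.independent_vars, dtype=float).ravel()
        self.jitter_vars = np.asarray(self.jitter_vars, dtype=float).ravel()
        self.means = np.asarray(self.means, dtype=float).ravel()
        K, M = W.shape
        if K < 2:
            raise ValueError("model needs K >= 2 intervals")
        if M < 1:
            raise ValueError("model needs at least one global factor (M >= 1)")
        if self.independent_vars.shape != (K,):
            raise ValueError("independent_vars must have length K")
        if self.jitter_vars.shape != (K - 1,):
            raise ValueError("jitter_vars must have length K-1")
        if self.means.shape != (K,):
            raise ValueError("means must have length K")
        if np.any(self.independent_vars < 0) or np.any(self.jitter_vars < 0):
            raise ValueError("variances must be non-negative")
        if not (
            np.all(np.isfinite(W))
            and np.all(np.isfinite(self.independent_vars))
            and np.all(np.isfinite(self.jitter_vars))
            and np.all(np.isfinite(self.means))
        ):
            raise ValueError("model parameters must be finite")

    @property
    def n_intervals(self) -> int:
        return self.global_weights.shape[0]

    @property
    def n_global(self) -> int:
        return self.global_weights.shape[1]

    @property
    def differencing(self) -> np.ndarray:
        """The K x (K-1) differencing matrix ``T`` for this model."""
        return build_differencing_matrix(self.n_intervals)

    def copy(self) -> "TimingModel":
        return TimingModel(
            self.global_weights.copy(),
            self.independent_vars.copy(),
            self.jitter_vars.copy(),
            self.means.copy(),
        )

    def to_dict(self) -> dict:
        return {
            "K": self.n_intervals,
            "M": self.n_global,
            "means": self.means.tolist(),
            "global_weights": self.global_weights.tolist(),
            "independent_vars": self.independent_vars.tolist(),
            "jitter_vars": self.jitter_vars.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TimingModel":
        model = cls(
            np.asarray(d["global_weights"], dtype=float),
            np.asarray(d["independent_vars"], dtype=float),
            np.asarray(d["jitter_vars"], dtype=float),
            np.asarray(d["means"], dtype=float),
        )
        if "K" in d and model.n_intervals != int(d["K"]):
            raise ValueError("stored K inconsistent with array shapes")
        if "M" in d and model.n_global != int(d["M"]):
            raise ValueError("stored M inconsistent with array shapes")
        return model


@dataclass
class IntervalDataset:
    """An N x K table of interval durations with optional annotations.

    ``durations`` holds one row per sequence rendition and one column per
    interval, in msec; all entries must be finite and positive, with at
    least K >= 3 intervals so that one internal boundary is flanked on both
    sides.  ``interval_labels`` (optional) classifies each interval as
    ``syllable``, ``gap_within`` or ``gap_between``; ``trial_meta``
    (optional) carries per-trial metadata such as recording day and
    hour-of-day, aligned with rows of ``durations``.
    """

    durations: np.ndarray
    interval_labels: list[str] | None = None
    trial_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        Y = np.asarray(self.durations, dtype=float)
        if Y.ndim != 2:
            raise ValueError("durations must be a 2-D (trials x intervals) array")
        if Y.shape[1] < 3:
            raise ValueError(
                f"need K >= 3 intervals (one fully flanked internal boundary), got {Y.shape[1]}"
            )
        if not np.all(np.isfinite(Y)):
            raise ValueError("durations must be finite")
        if np.any(Y <= 0):
            raise ValueError("durations must be strictly positive")
        self.durations = Y
        if self.interval_labels is not None:
            labels = list(self.interval_labels)
            if len(labels) != Y.shape[1]:
                raise ValueError("interval_labels must have one entry per interval")
            bad = sorted(set(labels) - set(INTERVAL_LABELS))
            if bad:
                raise ValueError(f"unknown interval labels {bad}; expected {INTERVAL_LABELS}")
            self.interval_labels = labels
        if self.trial_meta is not None and len(self.trial_meta) != Y.shape[0]:
            raise ValueError("trial_meta must have one row per trial")

    @property
    def n_trials(self) -> int:
        return self.durations.shape[0]

    @property
    def n_intervals(self) -> int:
        return self.durations.shape[1]

    def column_means(self) -> np.ndarray:
        return self.durations.mean(axis=0)

    def centered(self) -> np.ndarray:
        """Durations with per-column sample means removed."""
        return self.durations - self.column_means()

    def sample_covariance(self) -> np.ndarray:
        """Data covariance ``S_hat`` with 1/N normalization."""
        Y = self.centered()
        return Y.T @ Y / self.n_trials


@dataclass
class LatentDraws:
    """True latent values behind one simulated dataset.

    ``z`` is N x M in latent (unit-variance) units; ``x`` (N x (K-1)) and
    ``e`` (N x K) are already scaled by their standard deviations, i.e. in
    msec.
    """

    z: np.ndarray
    x: np.ndarray
    e: np.ndarray


class GaussianLatentSampler:
    """Standard-normal draws for every latent variable (the model default)."""

    def sample(self, rng: np.random.Generator, n_trials: int, n_latents: int) -> np.ndarray:
        return rng.standard_normal((n_trials, n_latents))


def model_covariance(model: TimingModel) -> np.ndarray:
    """Model-implied covariance ``S = W W' + T diag(psi_x) T' + diag(psi_e)``.

    The jitter term contributes ``psi_x[k-1] + psi_x[k]`` to the variance of
    interval ``k`` and ``-psi_x[k]`` to the covariance of intervals ``k`` and
    ``k+1``; adjacent-interval covariance therefore decreases one-for-one
    with the jitter variance at the shared boundary.
    """
    W = model.global_weights
    T = model.differencing
    S = W @ W.T + (T * model.jitter_vars) @ T.T + np.diag(model.independent_vars)
    return 0.5 * (S + S.T)


def _loglik_from_cov(S: np.ndarray, S_hat: np.ndarray, n_trials: int) -> float:
    """Exact Gaussian log-likelihood -(N/2)[K ln 2pi + ln|S| + tr(S^-1 S_hat)].

    Returns ``-inf`` (with a warning) if ``S`` is numerically singular.
    """
    K = S.shape[0]
    sign, logdet = np.linalg.slogdet(S)
    if sign <= 0 or not np.isfinite(logdet):
        warnings.warn(
            "model covariance is singular or indefinite; log-likelihood is -inf",
            SingularCovarianceWarning,
            stacklevel=2,
        )
        return -np.inf
    try:
        trace_term = float(np.trace(np.linalg.solve(S, S_hat)))
    except np.linalg.LinAlgError:
        warnings.warn(
            "model covariance is singular; log-likelihood is -inf",
            SingularCovarianceWarning,
            stacklevel=2,
        )
        return -np.inf
    return -0.5 * n_trials * (K * LN_2PI + logdet + trace_term)


def log_likelihood(model: TimingModel, data: IntervalDataset) -> float:
    """Exact log-likelihood of the dataset under the model covariance.

    Column means are removed internally, so the value is invariant to adding
    a constant to any column; only the covariance structure matters.
    """
    if model.n_intervals != data.n_intervals:
        raise ValueError("model and data disagree on the number of intervals")
    return _loglik_from_cov(model_covariance(model), data.sample_covariance(), data.n_trials)


def sample_dataset(
    model: TimingModel,
    n_trials: int,
    latent_sampler=None,
    seed: int | np.random.Generator | None = None,
    interval_labels: Sequence[str] | None = None,
) -> tuple[IntervalDataset, LatentDraws]:
    """Run the model in generative mode.

    Draws standardized latents (zero mean, unit variance) from
    ``latent_sampler`` (Gaussian by default), scales jitter and independent
    draws by their model standard deviations and combines them into observed
    durations ``y_n = mu + z_n W' + x_n T' + e_n``.  Returns both the
    dataset and the true latent draws for recovery scoring.  Bit-identical
    under a fixed integer seed.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if latent_sampler is None:
        latent_sampler = GaussianLatentSampler()
    if not hasattr(latent_sampler, "sample"):
        raise TypeError("latent_sampler must provide a .sample(rng, n_trials, n_latents) method")
    K, M = model.n_intervals, model.n_global
    n_latents = M + (K - 1) + K
    draws = np.asarray(latent_sampler.sample(rng, n_trials, n_latents), dtype=float)
    if draws.shape != (n_trials, n_latents):
        raise ValueError("latent sampler returned draws of the wrong shape")
    z = draws[:, :M]
    x = draws[:, M : M + K - 1] * np.sqrt(model.jitter_vars)
    e = draws[:, M + K - 1 :] * np.sqrt(model.independent_vars)
    Y = model.means + z @ model.global_weights.T + x @ model.differencing.T + e
    labels = list(interval_labels) if interval_labels is not None else None
    return IntervalDataset(Y, interval_labels=labels), LatentDraws(z=z, x=x, e=e)
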