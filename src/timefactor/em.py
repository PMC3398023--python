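"""Constrained-EM maximum-likelihood fitting of the timing model.

The fit is a structural (confirmatory) factor analysis: the loading matrix
``A = [W | T]`` mixes M free tempo columns with the *fixed* differencing
matrix ``T``, and the latent prior covariance ``C = blockdiag(I_M,
diag(psi_x))`` mixes a pinned identity block with free jitter variances.
The E step conditions the concatenated latent row-vector ``u = [z, x]`` on
each trial's mean-subtracted durations; the M step maximizes the expected
complete-data log-likelihood jointly over ``W``, ``psi_x`` and ``psi_e``
with ``T`` and the unit z-variance held fixed.

Because the observed-data log-likelihood depends on the data only through
the K x K sample covariance, the iteration cost is independent of the
number of trials; per-trial posterior means are materialized only when the
latents are actually requested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve

from ._kernel import HAVE_NUMBA, em_kernel
from .model import (
    IntervalDataset,
    TimingModel,
    _loglik_from_cov,
    build_differencing_matrix,
    log_likelihood,
    model_covariance,
)

__all__ = [
    "EStepWorkspace",
    "LatentPosterior",
    "FitConfig",
    "FitResult",
    "FitError",
    "initialize_parameters",
    "e_step",
    "m_step",
    "run_em",
    "fit",
    "estimate_latents",
]

logger = logging.getLogger(__name__)


class FitError(RuntimeError):
    """All EM restarts failed; carries per-restart diagnostics."""

    def __init__(self, message: str, restart_errors=None):
        super().__init__(message)
        self.restart_errors = restart_errors or []


@dataclass
class EStepWorkspace:
    """Concatenated loading matrix ``A = [W | T]`` and latent prior ``C``.

    ``C`` is block diagonal: an M x M identity for the tempo factors and
    ``diag(psi_x)`` for the boundary jitters; the off-diagonal blocks are
    identically zero.
    """

    A: np.ndarray
    C: np.ndarray

    @classmethod
    def from_model(cls, model: TimingModel, variance_floor: float = 0.0) -> "EStepWorkspace":
        K, M = model.n_intervals, model.n_global
        A = np.hstack([model.global_weights, model.differencing])
        C = np.zeros((M + K - 1, M + K - 1))
        C[:M, :M] = np.eye(M)
        C[M:, M:] = np.diag(np.maximum(model.jitter_vars, variance_floor))
        return cls(A=A, C=C)


@dataclass
class LatentPosterior:
    """Gaussian posterior of the concatenated latents ``u = [z, x]``.

    The posterior covariance is shared by all trials (the model is
    homoscedastic); only the means vary with the data.  ``second_moment``
    is the trial-averaged posterior second moment
    ``post_cov + (1/N) sum_n <u_n>' <u_n>`` and retains the z-x
    cross-moments: independent a priori, the latents are correlated under
    the posterior.
    """

    post_cov: np.ndarray
    post_mean: np.ndarray
    second_moment: np.ndarray


@dataclass
class FitConfig:
    """Multi-restart EM protocol settings.

    Stage 1 runs ``n_restarts`` independent EM chains from random starting
    points to a loose log-likelihood criterion (increment < ``tol_loose``
    nats); the ``n_keep`` best are then continued until the maximum
    scale-relative change in the global weights and jitter variances drops
    below ``tol_strict`` (independent variances converge faster and are not
    monitored).  ``variance_floor`` (msec^2) guards against Heywood
    collapse of any variance estimate.
    """

    n_restarts: int = 100
    n_keep: int = 5
    tol_loose: float = 1e-6
    tol_strict: float = 1e-5
    max_iter: int = 10_000
    variance_floor: float = 1e-12
    seed: int | None = 0

    def __post_init__(self) -> None:
        if not (0 < self.n_keep <= self.n_restarts):
            raise ValueError("need 0 < n_keep <= n_restarts")
        if self.tol_loose <= 0 or self.tol_strict <= 0:
            raise ValueError("tolerances must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.variance_floor < 0:
            raise ValueError("variance_floor must be >= 0")


@dataclass
class FitResult:
    """Best model across restarts plus per-restart diagnostics and latents."""

    model: TimingModel
    loglik: float
    loglik_trace: dict[int, np.ndarray]
    converged: bool
    restart_logliks: np.ndarray
    latents: LatentPosterior
    data_cov: np.ndarray
    model_cov: np.ndarray
    dataset: IntervalDataset
    best_restart: int
    config: FitConfig | None = None
    restart_errors: list = field(default_factory=list)


def initialize_parameters(data: IntervalDataset, n_global: int, rng: np.random.Generator) -> TimingModel:
    """Random starting point scaled to the variability of each interval.

    Each global weight is uniform on (0, sd of its interval); each
    independent variance uniform on (0, sample variance of its interval);
    each jitter variance uniform on (0, half the average interval variance)
    -- jitter feeds two intervals, so its natural scale is half as large.
    """
    if n_global < 1:
        raise ValueError("need at least one global factor (M >= 1)")
    col_var = data.centered().var(axis=0)
    col_sd = np.sqrt(col_var)
    K = data.n_intervals
    W = rng.uniform(0.0, 1.0, size=(K, n_global)) * col_sd[:, None]
    psi_e = rng.uniform(0.0, 1.0, size=K) * col_var
    psi_x = rng.uniform(0.0, 0.5 * col_var.mean(), size=K - 1)
    return TimingModel(W, psi_e, psi_x, data.column_means())


def _posterior_ops(model: TimingModel, variance_floor: float) -> tuple[np.ndarray, np.ndarray]:
    """Shared posterior covariance Sigma and the projection B = Psi_e^-1 A Sigma.

    Sigma = (C^-1 + A' Psi_e^-1 A)^-1; a trial's posterior mean is y_n B.
    Variances are floored first so that C and Psi_e are invertible.
    """
    K, M = model.n_intervals, model.n_global
    psi_e = np.maximum(model.independent_vars, variance_floor)
    psi_x = np.maximum(model.jitter_vars, variance_floor)
    if np.any(psi_e <= 0) or np.any(psi_x <= 0):
        raise np.linalg.LinAlgError(
            "zero variance with no floor makes the E step ill-posed; set variance_floor > 0"
        )
    A = np.hstack([model.global_weights, model.differencing])
    c_inv = np.concatenate([np.ones(M), 1.0 / psi_x])
    precision = np.diag(c_inv) + A.T @ (A / psi_e[:, None])
    sigma = np.linalg.inv(precision)
    sigma = 0.5 * (sigma + sigma.T)
    B = (A / psi_e[:, None]) @ sigma
    return sigma, B


def e_step(model: TimingModel, data: IntervalDataset, variance_floor: float = 1e-12) -> LatentPosterior:
    """Posterior moments of ``u = [z, x]`` for every trial.

    By Bayes' theorem for jointly Gaussian variables the posterior is
    Gaussian with shared covariance ``Sigma = (C^-1 + A' Psi_e^-1 A)^-1``
    and per-trial mean ``<u_n> = y_n Psi_e^-1 A Sigma`` (row convention,
    ``y_n`` mean-subtracted).
    """
    if model.n_intervals != data.n_intervals:
        raise ValueError("model and data disagree on the number of intervals")
    sigma, B = _posterior_ops(model, variance_floor)
    Y = data.centered()
    post_mean = Y @ B
    second_moment = sigma + post_mean.T @ post_mean / data.n_trials
    return LatentPosterior(post_cov=sigma, post_mean=post_mean, second_moment=second_moment)


def _m_step_from_stats(
    S_hat: np.ndarray,
    Syu: np.ndarray,
    U2: np.ndarray,
    model: TimingModel,
    variance_floor: float,
) -> TimingModel:
    """Closed-form M step from pooled sufficient statistics.

    ``Syu = (1/N) sum_n y_n' <u_n>`` and ``U2 = (1/N) sum_n <u_n' u_n>``.
    The updates solve the joint stationarity conditions of the expected
    complete-data log-likelihood with ``T`` and the unit z-variance fixed:

    * ``psi_x``: the x-block diagonal of ``U2`` (the usual second-moment
      solution for a Gaussian variance; the z-block is pinned to identity);
    * ``W``: ``[Syu_z - T U2_xz] U2_zz^-1`` -- the regression of the data
      on the tempo factors after removing the fixed jitter pathway;
    * ``psi_e``: ``diag(S_hat - 2 Syu A_new' + A_new U2 A_new')`` evaluated
      at the updated loadings.  With ``T`` fixed the cross-term does not
      cancel against the quadratic term as it would in unconstrained factor
      analysis, so the full quadratic form is kept.
    """
    M = model.n_global
    T = model.differencing
    psi_x_new = np.maximum(np.diag(U2)[M:].copy(), variance_floor)
    U2_zz = U2[:M, :M]
    U2_xz = U2[M:, :M]
    W_new = np.linalg.solve(U2_zz.T, (Syu[:, :M] - T @ U2_xz).T).T
    A_new = np.hstack([W_new, T])
    psi_e_new = (
        np.diag(S_hat)
        - 2.0 * np.einsum("kl,kl->k", Syu, A_new)
        + np.einsum("kl,lj,kj->k", A_new, U2, A_new)
    )
    psi_e_new = np.maximum(psi_e_new, variance_floor)
    return TimingModel(W_new, psi_e_new, psi_x_new, model.means)


def m_step(
    posterior: LatentPosterior,
    data: IntervalDataset,
    model: TimingModel,
    variance_floor: float = 1e-12,
) -> TimingModel:
    """One closed-form M step given posterior moments from :func:`e_step`."""
    Y = data.centered()
    N = data.n_trials
    S_hat = Y.T @ Y / N
    Syu = Y.T @ posterior.post_mean / N
    return _m_step_from_stats(S_hat, Syu, posterior.second_moment, model, variance_floor)


def _relative_change(new: np.ndarray, old: np.ndarray) -> float:
    """Largest parameter change relative to the class's own magnitude scale."""
    scale = max(float(np.max(np.abs(old))), 1e-12)
    return float(np.max(np.abs(new - old))) / scale


def run_em(
    data: IntervalDataset,
    n_global: int,
    init: TimingModel,
    tol: float = 1e-6,
    max_iter: int = 10_000,
    criterion: str = "loglik",
    variance_floor: float = 1e-12,
) -> tuple[TimingModel, np.ndarray, bool]:
    """Iterate E/M steps from ``init`` until convergence or ``max_iter``.

    ``criterion='loglik'`` stops when the log-likelihood increment drops
    below ``tol`` (the loose, stage-1 rule); ``criterion='param'`` stops
    when the scale-relative change of the global weights and jitter
    variances both drop below ``tol`` (the strict, stage-2 rule).  Returns
    the final model, the per-iteration log-likelihood trace (non-decreasing
    up to round-off: the EM guarantee), and a convergence flag.
    """
    if init.n_global != n_global:
        raise ValueError("init has a different number of global factors than requested")
    if criterion not in ("loglik", "param"):
        raise ValueError("criterion must be 'loglik' or 'param'")
    S_hat = data.sample_covariance()
    N = data.n_trials
    K, M = init.n_intervals, init.n_global
    T = build_differencing_matrix(K)
    L = M + K - 1
    if HAVE_NUMBA:
        W, psi_e, psi_x, trace_arr, converged = em_kernel(
            S_hat,
            init.global_weights,
            init.independent_vars,
            init.jitter_vars,
            T,
            N,
            tol,
            max_iter,
            criterion == "param",
            variance_floor,
        )
        return TimingModel(W, psi_e, psi_x, init.means), trace_arr, converged
    # raw-array EM loop: algebraically identical to e_step + m_step but
    # without per-iteration dataclass validation / matrix rebuilds
    W = init.global_weights.copy()
    psi_e = np.maximum(init.independent_vars, variance_floor)
    psi_x = np.maximum(init.jitter_vars, variance_floor)
    s_hat_diag = np.diag(S_hat).copy()
    trace: list[float] = []
    converged = False
    base = -0.5 * N * K * np.log(2.0 * np.pi)

    def estep_and_loglik(W, psi_e, psi_x):
        """E-step quantities plus the observed loglik at the same parameters.

        By the matrix determinant lemma ln|S| = sum ln psi_e + sum ln psi_x
        + ln|C^-1 + A' Psi_e^-1 A|, and by Woodbury tr(S^-1 S_hat) =
        sum(diag(S_hat)/psi_e) - sum((Psi_e^-1 A) * (S_hat B)), so the
        likelihood costs one Cholesky shared with the posterior solve.
        """
        A = np.hstack([W, T])
        c_inv = np.concatenate([np.ones(M), 1.0 / psi_x])
        Ainv_psi = A / psi_e[:, None]
        precision = np.diag(c_inv) + A.T @ Ainv_psi
        try:
            cho = np.linalg.cholesky(precision)
        except np.linalg.LinAlgError:
            return None, -np.inf
        sigma = cho_solve((cho, True), np.eye(L), check_finite=False)
        B = Ainv_psi @ sigma
        Syu = S_hat @ B
        logdet_s = (
            float(np.sum(np.log(psi_e)))
            + float(np.sum(np.log(psi_x)))
            + 2.0 * float(np.sum(np.log(np.diag(cho))))
        )
        trace_term = float(np.sum(s_hat_diag / psi_e)) - float(np.sum(Ainv_psi * Syu))
        ll = base - 0.5 * N * (logdet_s + trace_term)
        return (A, sigma, B, Syu), ll

    prev_ll = -np.inf
    n_steps = 0
    for it in range(max_iter + 1):
        ops, ll = estep_and_loglik(W, psi_e, psi_x)
        if it > 0:
            trace.append(ll)  # loglik produced by M step `it`
        if ops is None or not np.isfinite(ll):
            break
        if it > 0 and criterion == "loglik" and np.isfinite(prev_ll) and ll - prev_ll < tol:
            converged = True
            break
        if converged or it == max_iter:
            break
        prev_ll = ll
        A, sigma, B, Syu = ops
        U2 = sigma + B.T @ Syu
        U2 = 0.5 * (U2 + U2.T)
        # M step (joint stationarity; T and the unit z-variance held fixed)
        psi_x_new = np.maximum(np.diag(U2)[M:].copy(), variance_floor)
        W_new = np.linalg.solve(U2[:M, :M].T, (Syu[:, :M] - T @ U2[M:, :M]).T).T
        A_new = np.hstack([W_new, T])
        psi_e_new = np.maximum(
            s_hat_diag
            - 2.0 * np.sum(Syu * A_new, axis=1)
            + np.sum((A_new @ U2) * A_new, axis=1),
            variance_floor,
        )
        if criterion == "param":
            dw = _relative_change(W_new, W)
            dx = _relative_change(psi_x_new, psi_x)
            if max(dw, dx) < tol:
                converged = True  # final loglik appended on the next pass
        W, psi_e, psi_x = W_new, psi_e_new, psi_x_new
        n_steps += 1
    model = TimingModel(W, psi_e, psi_x, init.means)
    return model, np.asarray(trace), converged


def fit(data: IntervalDataset, n_global: int, config: FitConfig | None = None) -> FitResult:
    """Two-stage multi-restart EM fit.

    Stage 1 runs ``config.n_restarts`` chains from independent random
    initializations (restart ``r`` uses the ``r``-th spawn of the seed
    sequence, so any single restart is reproducible in isolation) to the
    loose log-likelihood criterion.  Stage 2 continues the ``n_keep`` chains
    with the highest log-likelihood until the global and jitter parameters
    stabilize, then returns the argmax-likelihood result with posterior
    latents from a final E step.  Ties break toward the lowest restart
    index.
    """
    if config is None:
        config = FitConfig()
    if not isinstance(n_global, (int, np.integer)) or n_global < 1:
        raise ValueError("the number of global factors must be an integer >= 1")
    if data.n_trials < data.n_intervals + 1:
        raise ValueError(
            f"need N >= K+1 trials for a generically full-rank data covariance, "
            f"got N={data.n_trials}, K={data.n_intervals}"
        )
    seed_seq = np.random.SeedSequence(config.seed)
    children = seed_seq.spawn(config.n_restarts)

    stage1: list[tuple[float, TimingModel | None, np.ndarray]] = []
    restart_errors: list[tuple[int, str]] = []
    for r in range(config.n_restarts):
        rng = np.random.default_rng(children[r])
        try:
            init = initialize_parameters(data, n_global, rng)
            mdl, trace, _ = run_em(
                data,
                n_global,
                init,
                tol=config.tol_loose,
                max_iter=config.max_iter,
                criterion="loglik",
                variance_floor=config.variance_floor,
            )
            ll = trace[-1] if len(trace) else -np.inf
            if not np.isfinite(ll):
                raise np.linalg.LinAlgError("non-finite log-likelihood")
            stage1.append((float(ll), mdl, trace))
            logger.info("restart %d: loose-stage loglik %.6f", r, ll)
        except np.linalg.LinAlgError as err:
            stage1.append((-np.inf, None, np.asarray([])))
            restart_errors.append((r, str(err)))
            logger.warning("restart %d failed: %s", r, err)
    if all(m is None for _, m, _ in stage1):
        raise FitError("every EM restart failed", restart_errors)

    restart_logliks = np.asarray([ll for ll, _, _ in stage1])
    order = np.argsort(-restart_logliks, kind="stable")
    kept = [int(r) for r in order[: config.n_keep] if stage1[r][1] is not None]

    traces: dict[int, np.ndarray] = {}
    finals: list[tuple[int, float, TimingModel, bool]] = []
    for r in kept:
        _, mdl, trace1 = stage1[r]
        try:
            mdl2, trace2, conv = run_em(
                data,
                n_global,
                mdl,
                tol=config.tol_strict,
                max_iter=config.max_iter,
                criterion="param",
                variance_floor=config.variance_floor,
            )
        except np.linalg.LinAlgError as err:
            restart_errors.append((r, f"stage 2: {err}"))
            continue
        full_trace = np.concatenate([trace1, trace2])
        traces[r] = full_trace
        ll = float(full_trace[-1]) if len(full_trace) else -np.inf
        finals.append((r, ll, mdl2, conv))
    if not finals:
        raise FitError("every kept restart failed in stage 2", restart_errors)

    best_idx = int(np.argmax([ll for _, ll, _, _ in finals]))
    best_restart, best_ll, best_model, best_conv = finals[best_idx]
    latents = e_step(best_model, data, variance_floor=config.variance_floor)
    return FitResult(
        model=best_model,
        loglik=best_ll,
        loglik_trace=traces,
        converged=best_conv,
        restart_logliks=restart_logliks,
        latents=latents,
        data_cov=data.sample_covariance(),
        model_cov=model_covariance(best_model),
        dataset=data,
        best_restart=best_restart,
        config=config,
        restart_errors=restart_errors,
    )


def estimate_latents(result: FitResult) -> pd.DataFrame:
    """Trial-wise latent estimates (posterior means = modes) as a tidy table.

    Columns ``z1..zM`` are tempo-factor estimates, ``x1..x(K-1)`` boundary
    jitters (msec), ``e1..eK`` independent residuals (msec) defined so that
    ``y_n = mu_hat + z_n W' + x_n T' + e_n`` holds exactly.  Trial metadata
    is carried along so downstream circadian / drift analyses can join on
    it.
    """
    model = result.model
    data = result.dataset
    K, M = model.n_intervals, model.n_global
    z_hat = result.latents.post_mean[:, :M]
    x_hat = result.latents.post_mean[:, M:]
    Y = data.durations - model.means
    e_hat = Y - z_hat @ model.global_weights.T - x_hat @ model.differencing.T
    cols = {}
    for m in range(M):
        cols[f"z{m + 1}"] = z_hat[:, m]
    for k in range(K - 1):
        cols[f"x{k + 1}"] = x_hat[:, k]
    for k in range(K):
        cols[f"e{k + 1}"] = e_hat[:, k]
    table = pd.DataFrame(cols)
    table.insert(0, "trial", np.arange(data.n_trials))
    if data.trial_meta is not None:
        meta = data.trial_meta.reset_index(drop=True)
        table = pd.concat([table.iloc[:, :1], meta, table.iloc[:, 1:]], axis=1)
    return table
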