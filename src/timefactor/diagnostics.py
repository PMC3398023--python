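"""Goodness of fit and variance-decomposition summaries for fitted models.

The model-implied covariance splits exactly into three K x K components --
global ``W W'``, jitter ``T diag(psi_x) T'`` and independent
``diag(psi_e)`` -- which grounds both the per-interval summary measures
(component SDs, tempo elasticity, independent CV) and the sequence-level
decomposition, where shared tempo is amplified K-fold relative to the
per-interval picture while jitter cancels entirely.  Overall fit is scored
by the standardized root-mean-square residual (SRMR) between data and
model-implied correlation matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .model import TimingModel, model_covariance
from .selection import NoTempoDirectionError, apply_sign_convention, rotate_to_tempo_basis

__all__ = [
    "VarianceDecomposition",
    "srmr",
    "interval_variance_decomposition",
    "sequence_length_decomposition",
    "group_compare",
    "mad",
]


def mad(values: np.ndarray) -> float:
    """Raw median absolute deviation (no consistency factor)."""
    v = np.asarray(values, dtype=float)
    return float(np.median(np.abs(v - np.median(v))))


def srmr(data_cov: np.ndarray, model_cov: np.ndarray, include_diagonal: bool = True) -> float:
    """Standardized root-mean-square residual between two covariance matrices.

    Residuals are data correlations minus model covariances standardized by
    the *data* standard deviations; the RMS runs over the lower triangle
    with each unordered pair counted once, including the diagonal by
    default (set ``include_diagonal=False`` for the no-diagonal convention
    as a sensitivity check).  Zero when the model reproduces the data
    covariance exactly, and invariant to rescaling both matrices by the
    same positive constant.
    """
    data_cov = np.asarray(data_cov, dtype=float)
    model_cov = np.asarray(model_cov, dtype=float)
    if data_cov.shape != model_cov.shape or data_cov.ndim != 2 or data_cov.shape[0] != data_cov.shape[1]:
        raise ValueError("covariance matrices must be square and of equal shape")
    variances = np.diag(data_cov)
    bad = np.flatnonzero(variances <= 0)
    if bad.size:
        raise ValueError(f"data variance is zero (or negative) for interval(s) {bad.tolist()}")
    s = np.sqrt(variances)
    denom = np.outer(s, s)
    resid = data_cov / denom - model_cov / denom
    rows, cols = np.tril_indices(data_cov.shape[0], k=0 if include_diagonal else -1)
    return float(np.sqrt(np.mean(resid[rows, cols] ** 2)))


@dataclass
class VarianceDecomposition:
    """Component matrices (summing exactly to S) and per-interval summaries."""

    components: dict[str, np.ndarray]
    summary: pd.DataFrame


def interval_variance_decomposition(
    model: TimingModel,
    interval_labels: list[str] | None = None,
    keep_edges: bool = False,
) -> VarianceDecomposition:
    """Split the model covariance into components and summarize per interval.

    The summary reports, for each interval k: its mean duration; the global
    SD (row norm of W); the tempo weight (rotated factor 1 when M > 1,
    signed per convention); the independent SD; the jitter SD
    ``sqrt(psi_x[k-1] + psi_x[k])`` with edge boundaries contributing 0;
    the tempo elasticity ``w_k / mu_k`` (a partial CV with respect to
    tempo); and the analogous independent CV.  Edge intervals absorb
    unmodeled jitter at the sequence ends, so their estimates are
    inherently less accurate: they are flagged and, by default, dropped
    from the summary (``keep_edges=True`` retains them; the component
    matrices always cover all K intervals).
    """
    W = model.global_weights
    K, M = model.n_intervals, model.n_global
    T = model.differencing
    components = {
        "global": W @ W.T,
        "jitter": (T * model.jitter_vars) @ T.T,
        "independent": np.diag(model.independent_vars),
    }
    if M == 1:
        tempo_w = W[:, 0] if W[:, 0].sum() >= 0 else -W[:, 0]
    else:
        try:
            WR = rotate_to_tempo_basis(W).rotated_weights
            labels_for_sign = interval_labels if interval_labels is not None else ["syllable"] * K
            tempo_w = apply_sign_convention(WR, labels_for_sign)[:, 0]
        except NoTempoDirectionError:
            warnings.warn(
                "no tempo direction; reporting the global row norm as the tempo weight",
                stacklevel=2,
            )
            tempo_w = np.sqrt(np.sum(W**2, axis=1))
    jitter_var = np.zeros(K)
    jitter_var[:-1] += model.jitter_vars
    jitter_var[1:] += model.jitter_vars
    global_sd = np.sqrt(np.sum(W**2, axis=1))
    independent_sd = np.sqrt(model.independent_vars)
    edge = np.zeros(K, dtype=bool)
    edge[[0, -1]] = True
    summary = pd.DataFrame(
        {
            "interval": np.arange(K),
            "label": interval_labels if interval_labels is not None else [None] * K,
            "edge": edge,
            "mean": model.means,
            "tempo_weight": tempo_w,
            "global_sd": global_sd,
            "independent_sd": independent_sd,
            "jitter_sd": np.sqrt(jitter_var),
            "total_sd": np.sqrt(global_sd**2 + model.independent_vars + jitter_var),
            "tempo_elasticity": tempo_w / model.means,
            "independent_cv": independent_sd / model.means,
        }
    )
    if not keep_edges:
        summary = summary.loc[~summary["edge"]].reset_index(drop=True)
    return VarianceDecomposition(components=components, summary=summary)


def sequence_length_decomposition(model: TimingModel) -> dict[str, float]:
    """Variance of total sequence length split into global and independent parts.

    Global: ``||1'W||^2`` -- shared tempo is summed over all K intervals
    before squaring, so its contribution is amplified roughly K-fold.
    Independent: ``sum(psi_e)``.  Jitter moves boundaries without changing
    the total (column sums of T are zero) and contributes nothing.
    """
    t = model.global_weights.T @ np.ones(model.n_intervals)
    global_var = float(t @ t)
    independent_var = float(np.sum(model.independent_vars))
    return {
        "global_var": global_var,
        "independent_var": independent_var,
        "global_fraction": global_var / (global_var + independent_var),
    }


def group_compare(
    summary: pd.DataFrame,
    measures: tuple[str, ...] = ("tempo_elasticity", "independent_cv", "global_sd", "jitter_sd"),
    label_col: str = "label",
) -> dict:
    """Rank-based comparison of summary measures across interval types.

    For each measure: per-group median and raw MAD, Wilcoxon rank-sum
    p-values for every group pair, and the Spearman correlation of the
    measure against mean interval duration (pooled across groups).  These
    are thin wrappers around standard tests; the substance is in the
    measures themselves.
    """
    if label_col not in summary.columns or summary[label_col].isna().all():
        groups = {}
    else:
        groups = {name: g for name, g in summary.groupby(label_col, observed=True)}
    report: dict = {"groups": {}, "tests": {}, "scaling": {}}
    for measure in measures:
        if measure not in summary.columns:
            continue
        report["groups"][measure] = {
            name: {
                "n": int(len(g)),
                "median": float(np.median(g[measure])),
                "mad": mad(g[measure].to_numpy()),
            }
            for name, g in groups.items()
        }
        tests = {}
        for a, b in combinations(sorted(groups), 2):
            ga, gb = groups[a][measure].to_numpy(), groups[b][measure].to_numpy()
            if len(ga) and len(gb):
                stat, p = stats.ranksums(ga, gb)
                tests[f"{a}_vs_{b}"] = {"statistic": float(stat), "p": float(p)}
        report["tests"][measure] = tests
        rho, p = stats.spearmanr(summary["mean"], summary[measure])
        report["scaling"][measure] = {"spearman_rho": float(rho), "p": float(p)}
    return report
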