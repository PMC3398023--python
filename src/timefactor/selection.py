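"""Choosing the number of global factors and fixing factor indeterminacy.

The number of global (tempo-like) factors M is chosen by refitting the full
multi-restart EM for each candidate M and minimizing BIC.  Because only the
span of ``W`` is identified, the fitted weight matrix is then rotated so
that the first factor carries *all* global variance in total sequence
length (the tempo axis) and the remaining factors, which are
sequence-length-neutral by construction, are ordered as principal axes of
the residual global covariance.  A final sign convention makes the
tempo-weight sum positive and, for higher factors, the syllable-weight sum
positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .em import FitConfig, FitResult, fit
from .model import IntervalDataset

__all__ = [
    "SelectionRecord",
    "RotationResult",
    "NoTempoDirectionError",
    "count_parameters",
    "bic",
    "select_global_dimension",
    "rotate_to_tempo_basis",
    "apply_sign_convention",
]

#: Eigenvalues of the deflated global covariance below this are treated as
#: zero-space when completing the rotation basis.
_EIG_FLOOR = 1e-12


class NoTempoDirectionError(ValueError):
    """The weight matrix has (numerically) no net sequence-length sensitivity."""


def count_parameters(n_intervals: int, n_global: int) -> int:
    """Free-parameter count: K*M global weights + K independent + K-1 jitter."""
    if n_intervals < 3 or n_global < 1:
        raise ValueError("need K >= 3 and M >= 1")
    return n_intervals * n_global + n_intervals + (n_intervals - 1)


def bic(loglik: float, n_intervals: int, n_global: int, n_trials: int) -> float:
    """Bayesian Information Criterion ``-2 l + p ln N``."""
    if n_trials < 2:
        raise ValueError("need N >= 2 trials")
    return -2.0 * loglik + count_parameters(n_intervals, n_global) * float(np.log(n_trials))


@dataclass
class SelectionRecord:
    """Per-M fit summaries and the BIC-chosen dimensionality."""

    records: list[dict]
    chosen_m: int
    fits: dict[int, FitResult] = field(default_factory=dict)


def select_global_dimension(
    data: IntervalDataset,
    config: FitConfig | None = None,
    m_values: tuple[int, ...] = (1, 2, 3, 4),
) -> SelectionRecord:
    """Fit every candidate M with an identical protocol and pick min-BIC.

    Each candidate gets the same restart budget and seed.  A failed fit for
    some M is recorded with a warning and selection proceeds over the
    survivors; BIC ties break toward the smaller (more parsimonious) M.
    """
    if config is None:
        config = FitConfig()
    records: list[dict] = []
    fits: dict[int, FitResult] = {}
    for m in m_values:
        try:
            result = fit(data, m, config)
        except Exception as err:  # propagate only if nothing survives
            warnings.warn(f"fit with M={m} failed: {err}", stacklevel=2)
            records.append({"m": m, "loglik": None, "p": None, "bic": None, "error": str(err)})
            continue
        p = count_parameters(data.n_intervals, m)
        records.append(
            {
                "m": m,
                "loglik": result.loglik,
                "p": p,
                "bic": bic(result.loglik, data.n_intervals, m, data.n_trials),
            }
        )
        fits[m] = result
    ok = [r for r in records if r.get("bic") is not None]
    if not ok:
        raise RuntimeError("model selection failed for every candidate M")
    best = min(ok, key=lambda r: (r["bic"], r["m"]))
    return SelectionRecord(records=records, chosen_m=int(best["m"]), fits=fits)


@dataclass
class RotationResult:
    """Orthonormal rotation of the global weights into the tempo basis."""

    rotation: np.ndarray
    rotated_weights: np.ndarray
    tempo_direction: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray


def rotate_to_tempo_basis(W: np.ndarray) -> RotationResult:
    """Rotate ``W`` so factor 1 is the sequence-length (tempo) axis.

    The global contribution to total sequence length of a latent vector
    ``z`` is ``z W' 1``; all of it lies along the unit latent direction
    ``v1 = W'1 / ||W'1||``.  An orthonormal ``R`` with first column ``v1``
    therefore confines sequence-length variance to factor 1, and every
    other rotated factor is exactly length-neutral.  The remaining columns
    are chosen as principal axes of the deflated global covariance
    ``B = W (I - v1 v1') W'``: column j+1 of ``R`` is ``(I - v1 v1') W' u_j
    / sqrt(lambda_j)`` for the j-th leading eigenpair of ``B``, which makes
    ``R`` exactly orthonormal and sorts factors 2..M by the global data
    variance they carry.  Eigenpairs with eigenvalues below 1e-12 are
    treated as zero-space and the basis is completed arbitrarily within it.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim == 1:
        W = W[:, None]
    K, M = W.shape
    ones = np.ones(K)
    t = W.T @ ones
    norm = float(np.linalg.norm(t))
    scale = float(np.max(np.abs(W))) if W.size else 0.0
    if norm <= 1e-10 * max(scale, 1.0):
        raise NoTempoDirectionError(
            "W'1 is numerically zero: no net sequence-length sensitivity to define a tempo axis"
        )
    v1 = t / norm
    proj = np.eye(M) - np.outer(v1, v1)
    B = W @ proj @ W.T
    B = 0.5 * (B + B.T)
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    n_use = min(M - 1, int(np.sum(eigval > _EIG_FLOOR)))
    lam = eigval[:n_use]
    U = eigvec[:, :n_use]
    cols = [v1[:, None]]
    if n_use:
        cols.append(proj @ W.T @ U / np.sqrt(lam))
    R = np.hstack(cols)
    if R.shape[1] < M:
        # degenerate residual space: complete with an arbitrary orthonormal basis
        q, _ = np.linalg.qr(np.hstack([R, np.random.default_rng(0).standard_normal((M, M))]))
        R = np.hstack([R, q[:, R.shape[1] : M]])
    gram_err = float(np.max(np.abs(R.T @ R - np.eye(M))))
    if gram_err > 1e-8:
        raise RuntimeError(f"rotation failed orthonormality check (error {gram_err:.2e})")
    return RotationResult(
        rotation=R,
        rotated_weights=W @ R,
        tempo_direction=v1,
        eigenvalues=lam,
        eigenvectors=U,
    )


def apply_sign_convention(
    rotated_weights: np.ndarray, interval_labels: list[str] | None
) -> np.ndarray:
    """Resolve each factor column's sign indeterminacy for reporting.

    Factor 1 is flipped so the sum of its (tempo) weights is positive;
    factors 2..M are flipped so the sum of their *syllable* weights is
    positive.  Flipping a column never changes ``W W'`` or any variance
    decomposition.  An exactly zero deciding sum leaves the sign unchanged
    with a warning.
    """
    WR = np.asarray(rotated_weights, dtype=float)
    if WR.ndim == 1:
        WR = WR[:, None]
    WR = WR.copy()
    K, M = WR.shape

    def flip(col: int, total: float, what: str) -> None:
        if total < 0:
            WR[:, col] = -WR[:, col]
        elif total == 0:
            warnings.warn(
                f"{what} sum for factor {col + 1} is exactly zero; sign left unchanged",
                stacklevel=3,
            )

    flip(0, float(WR[:, 0].sum()), "tempo-weight")
    if M > 1:
        if interval_labels is None:
            raise ValueError("interval_labels are required to sign higher factors")
        syl = np.asarray([lab == "syllable" for lab in interval_labels])
        for j in range(1, M):
            flip(j, float(WR[syl, j].sum()), "syllable-weight")
    return WR
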