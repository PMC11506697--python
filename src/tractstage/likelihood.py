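"""Stage-marginalized Gaussian likelihood of the linear z-score model.

Subjects are modelled as Gaussian around the stage trajectory: given a
sequence with trajectories g_b(k) and noise scale sigma_b, a subject at
stage k has x_b ~ Normal(g_b(k), sigma_b) independently across biomarkers.
The stage is latent with a uniform prior over {0, ..., N}, so the subject
marginal is log[(1/(N+1)) * sum_k prod_b Normal(x_b; g_b(k), sigma_b)],
evaluated with log-sum-exp.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

from .events import ZScoreEventSet, trajectory_matrix

__all__ = [
    "as_sigma",
    "stage_log_densities",
    "subject_log_marginal",
    "sequence_log_likelihood",
    "mixture_log_likelihood",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


def as_sigma(sigma, n_biomarkers: int) -> np.ndarray:
    s = np.broadcast_to(np.asarray(sigma, dtype=float), (n_biomarkers,)).copy()
    if np.any(s <= 0) or not np.all(np.isfinite(s)):
        raise ValueError("sigma must be positive and finite")
    return s


def stage_log_densities(X: np.ndarray, g: np.ndarray, sigma) -> np.ndarray:
    """Per-subject, per-stage Gaussian log density, shape (P, N + 1).

    Entry (i, k) = sum_b log Normal(x_ib; g_kb, sigma_b). Computed via the
    expanded quadratic so the stage axis is a single matrix product.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not np.all(np.isfinite(X)):
        raise ValueError("abnormality matrix contains non-finite values")
    s = as_sigma(sigma, g.shape[1])
    inv2 = 1.0 / s**2
    Xs = X * inv2
    const = -0.5 * (g.shape[1] * _LOG_2PI) - np.sum(np.log(s))
    xx = 0.5 * np.sum(X * Xs, axis=1)            # (P,)
    gg = 0.5 * np.sum(g * g * inv2, axis=1)      # (N+1,)
    return const + Xs @ g.T - xx[:, None] - gg[None, :]


def subject_log_marginal(x, order, events: ZScoreEventSet, sigma=1.0) -> float:
    """Stage-marginalized log likelihood of one subject (uniform stage prior)."""
    g = trajectory_matrix(order, events)
    A = stage_log_densities(np.atleast_2d(x), g, sigma)
    return float(logsumexp(A[0]) - np.log(events.n_events + 1))


def sequence_log_likelihood(X, order, events: ZScoreEventSet, sigma=1.0) -> float:
    """Total stage-marginalized log likelihood over all subjects.

    Empty cohorts return 0 (an empty sum); subject order is irrelevant.
    """
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        return 0.0
    g = trajectory_matrix(order, events)
    A = stage_log_densities(X, g, sigma)
    return float(np.sum(logsumexp(A, axis=1)) - X.shape[0] * np.log(events.n_events + 1))


def mixture_log_likelihood(marginals: np.ndarray, fractions: np.ndarray) -> float:
    """Total log likelihood under a subtype mixture.

    Parameters
    ----------
    marginals : (P, C) array
        Per-subject stage-marginal log likelihood under each subtype's
        sequence.
    fractions : (C,) array
        Mixture fractions, non-negative, summing to 1.
    """
    marginals = np.atleast_2d(marginals)
    fractions = np.asarray(fractions, dtype=float)
    with np.errstate(divide="ignore"):
        logf = np.log(fractions)
    return float(np.sum(logsumexp(marginals + logf[None, :], axis=1)))
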