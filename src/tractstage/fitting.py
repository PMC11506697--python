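"""Sequence optimization and MCMC uncertainty for the z-score event model.

`greedy_fit` is coordinate ascent over event positions: from a starting
sequence, each event is repeatedly moved to its likelihood-optimal position
(within the slots allowed by its biomarker's threshold order) until no move
improves; the best of several starts is returned.

`mcmc_sample` is a Metropolis chain over valid sequences with a uniform
prior: the proposal swaps two uniformly chosen positions and is re-proposed
if the swap would break a biomarker's threshold order; acceptance is
min(1, likelihood ratio). Likelihood updates are incremental — a swap only
changes the trajectories of the (at most two) biomarkers involved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from .events import (
    ZScoreEventSet,
    check_sequence,
    random_valid_sequence,
    ranked_init_sequence,
    trajectory_matrix,
)
from .likelihood import as_sigma

__all__ = ["greedy_fit", "coordinate_ascent", "mcmc_sample",
           "positional_density", "McmcResult"]


class _LLCache:
    """Precomputed per-dataset terms so one sequence evaluation is a single
    matrix product plus a log-sum-exp."""

    def __init__(self, X, events: ZScoreEventSet, sigma):
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.X.size and not np.all(np.isfinite(self.X)):
            raise ValueError("abnormality matrix contains non-finite values")
        self.events = events
        self.sigma = as_sigma(sigma, events.n_biomarkers)
        self.inv2 = 1.0 / self.sigma**2
        self.Xs = self.X * self.inv2
        self.xx = 0.5 * np.sum(self.X * self.Xs, axis=1)
        self.const = (-0.5 * events.n_biomarkers * np.log(2 * np.pi)
                      - np.sum(np.log(self.sigma)))
        self.log_prior = -np.log(events.n_events + 1)
        self.n = self.X.shape[0]

    def stage_dens(self, order) -> np.ndarray:
        g = trajectory_matrix(order, self.events)
        gg = 0.5 * np.sum(g * g * self.inv2, axis=1)
        return self.const + self.Xs @ g.T - self.xx[:, None] - gg[None, :]

    def total_ll(self, order) -> float:
        if self.n == 0:
            return 0.0
        A = self.stage_dens(order)
        return float(np.sum(_row_lse(A)) + self.n * self.log_prior)


def _row_lse(A: np.ndarray) -> np.ndarray:
    m = A.max(axis=1)
    return m + np.log(np.exp(A - m[:, None]).sum(axis=1))


def _interp_column(pos, events: ZScoreEventSet, b: int, ks) -> np.ndarray:
    """Trajectory of one biomarker given current event positions."""
    n = events.n_events
    ev = events.events_of(b)
    p = pos[ev].astype(float)
    v = events.event_value[ev]
    if p[-1] < n:
        xp = np.concatenate(([0.0], p, [float(n)]))
        fp = np.concatenate(([0.0], v, [events.z_max[b]]))
    else:
        xp = np.concatenate(([0.0], p))
        fp = np.concatenate(([0.0], v))
    return np.interp(ks, xp, fp)


def _delta_swap(cache: _LLCache, A, g, pos, ks, changed):
    """Update A and g in place after `pos` changed for biomarkers in
    `changed`; returns the new total log likelihood."""
    gn = np.stack([_interp_column(pos, cache.events, c, ks) for c in changed],
                  axis=1)
    go = g[:, changed]
    if cache.n:
        dgg = 0.5 * np.sum((gn * gn - go * go) * cache.inv2[changed], axis=1)
        A += cache.Xs[:, changed] @ (gn - go).T - dgg[None, :]
        ll = float(np.sum(_row_lse(A)) + cache.n * cache.log_prior)
    else:
        ll = 0.0
    g[:, changed] = gn
    return ll


def _scan_event(order, e, cache: _LLCache):
    """Log likelihood of placing event `e` at every threshold-order-valid
    position, holding the rest of the sequence fixed.

    Returns (base, lo, hi, lls) where `base` is the order without `e`,
    insertion indices lo..hi are the valid slots, and lls[j - lo] is the
    total log likelihood of ``insert(base, j, e)``. The scan walks the
    valid slots by adjacent transpositions so each step only touches the
    two biomarker trajectories involved.
    """
    events = cache.events
    slot = int(np.flatnonzero(order == e)[0])
    base = np.delete(order, slot)
    sibs = events.events_of(events.event_biomarker[e])
    rank = int(np.flatnonzero(sibs == e)[0])
    lo = 0 if rank == 0 else int(np.flatnonzero(base == sibs[rank - 1])[0]) + 1
    hi = len(base) if rank == len(sibs) - 1 else int(
        np.flatnonzero(base == sibs[rank + 1])[0])
    lls = np.zeros(hi - lo + 1)
    if cache.n == 0:
        return base, lo, hi, lls

    n = events.n_events
    ks = np.arange(n + 1, dtype=float)
    cur = np.insert(base, lo, e)
    pos = np.empty(n, dtype=np.intp)
    pos[cur] = np.arange(1, n + 1)
    g = trajectory_matrix(cur, events)
    A = cache.stage_dens(cur)
    lls[0] = float(np.sum(_row_lse(A)) + cache.n * cache.log_prior)
    be = int(events.event_biomarker[e])
    for j in range(lo + 1, hi + 1):
        other = base[j - 1]          # neighbour e swaps past
        bo = int(events.event_biomarker[other])
        pos[e], pos[other] = pos[other], pos[e]
        changed = [be] if bo == be else [be, bo]
        lls[j - lo] = _delta_swap(cache, A, g, pos, ks, changed)
    return base, lo, hi, lls


def _one_greedy_pass(order, cache: _LLCache, cur_ll, rng):
    """One sweep over all events; returns (order, ll, improved)."""
    events = cache.events
    improved = False
    for e in rng.permutation(events.n_events):
        base, lo, hi, lls = _scan_event(order, e, cache)
        j_best = lo + int(np.argmax(lls))
        best_ll = float(lls[j_best - lo])
        if best_ll > cur_ll + 1e-9:
            order = np.insert(base, j_best, e)
            cur_ll = best_ll
            improved = True
    return order, cur_ll, improved


def greedy_fit(X, events: ZScoreEventSet, n_starts: int = 25, seed=None,
               sigma=1.0, max_passes: int | None = None,
               ranked_start: bool = True):
    """Best event sequence over multiple coordinate-ascent starts.

    Parameters
    ----------
    n_starts : int
        Number of starting sequences. When ``ranked_start`` is true the first
        start orders events by cohort exceedance fraction (a cheap data-driven
        guess); the remainder are uniform random valid sequences.
    max_passes : int or None
        Cap on ascent sweeps per start (None = run to convergence).

    Returns
    -------
    order : ndarray
        The best sequence found.
    ll : float
        Its total log likelihood.
    start_lls : list of (float, float)
        Per-start (starting, final) log likelihoods, for convergence audit.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    rng = np.random.default_rng(seed)
    cache = _LLCache(X, events, sigma)
    best_order, best_ll = None, -np.inf
    start_lls = []
    for s in range(n_starts):
        if s == 0 and ranked_start:
            order = ranked_init_sequence(cache.X, events)
        else:
            order = random_valid_sequence(events, rng)
        cur = cache.total_ll(order)
        first = cur
        passes = 0
        improved = True
        while improved and (max_passes is None or passes < max_passes):
            order, cur, improved = _one_greedy_pass(order, cache, cur, rng)
            passes += 1
        start_lls.append((first, cur))
        if cur > best_ll:
            best_order, best_ll = order.copy(), cur
    return best_order, best_ll, start_lls


def coordinate_ascent(X, events: ZScoreEventSet, start, sigma=1.0,
                      max_passes: int | None = None, seed=None):
    """Ascend from an explicit starting sequence; returns (order, ll)."""
    rng = np.random.default_rng(seed)
    cache = _LLCache(X, events, sigma)
    order = check_sequence(start, events).copy()
    cur = cache.total_ll(order)
    passes = 0
    improved = True
    while improved and (max_passes is None or passes < max_passes):
        order, cur, improved = _one_greedy_pass(order, cache, cur, rng)
        passes += 1
    return order, cur


@dataclass
class McmcResult:
    """A Metropolis chain over event sequences.

    Attributes
    ----------
    samples : (n_iter, N) int array
        The sequence at every iteration (event indices by position).
    log_likelihoods : (n_iter,) array
    n_accepted : int
    n_invalid_proposals : int
        Swaps re-proposed because they violated threshold order.
    """

    samples: np.ndarray
    log_likelihoods: np.ndarray
    n_accepted: int
    n_invalid_proposals: int

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / max(len(self.samples), 1)

    def ml_sequence(self):
        i = int(np.argmax(self.log_likelihoods))
        return self.samples[i].astype(np.intp), float(self.log_likelihoods[i])


def _order_ok(pos, events: ZScoreEventSet, b: int) -> bool:
    return bool(np.all(np.diff(pos[events.events_of(b)]) > 0))


def mcmc_sample(X, events: ZScoreEventSet, start, n_iter: int, seed=None,
                sigma=1.0, max_reproposals: int = 10_000) -> McmcResult:
    """Run the Metropolis chain from `start` for `n_iter` iterations."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    order = check_sequence(start, events).copy()
    rng = np.random.default_rng(seed)
    cache = _LLCache(X, events, sigma)
    n = events.n_events
    ks = np.arange(n + 1, dtype=float)
    pos = np.empty(n, dtype=np.intp)
    pos[order] = np.arange(1, n + 1)
    g = trajectory_matrix(order, events)
    if cache.n:
        A = cache.stage_dens(order)
        cur_ll = float(np.sum(_row_lse(A)) + cache.n * cache.log_prior)
    else:
        A, cur_ll = None, 0.0

    dtype = np.int16 if n < np.iinfo(np.int16).max else np.intp
    samples = np.empty((n_iter, n), dtype=dtype)
    lls = np.empty(n_iter)
    n_acc = 0
    n_invalid = 0

    for it in range(n_iter):
        # draw a valid swap (invalid draws are re-proposals, not rejections)
        for _ in range(max_reproposals):
            i, j = rng.integers(0, n, size=2)
            if i == j:
                continue
            a, b = order[i], order[j]
            ba = int(events.event_biomarker[a])
            bb = int(events.event_biomarker[b])
            pos[a], pos[b] = pos[b], pos[a]
            if _order_ok(pos, events, ba) and (ba == bb or _order_ok(pos, events, bb)):
                break
            pos[a], pos[b] = pos[b], pos[a]
            n_invalid += 1
        else:  # pragma: no cover - only reachable on pathological event sets
            raise RuntimeError("no valid swap found")

        cb = [ba] if ba == bb else [ba, bb]
        gn = np.stack([_interp_column(pos, events, c, ks) for c in cb], axis=1)
        go = g[:, cb]
        if cache.n:
            dgg = 0.5 * np.sum((gn * gn - go * go) * cache.inv2[cb], axis=1)
            A_cand = A + cache.Xs[:, cb] @ (gn - go).T - dgg[None, :]
            cand_ll = float(np.sum(_row_lse(A_cand)) + cache.n * cache.log_prior)
        else:
            A_cand, cand_ll = None, 0.0

        if np.log(rng.random()) < cand_ll - cur_ll:
            order[i], order[j] = b, a
            g[:, cb] = gn
            A, cur_ll = A_cand, cand_ll
            n_acc += 1
        else:
            pos[a], pos[b] = pos[b], pos[a]

        samples[it] = order
        lls[it] = cur_ll

    return McmcResult(samples, lls, n_acc, n_invalid)


def positional_density(samples, events: ZScoreEventSet | None = None) -> np.ndarray:
    """Posterior positional-density matrix from a chain of sequences.

    Entry (e, p) is the fraction of samples placing event e at position
    p + 1 (canonical event order on the rows); every row sums to 1. This is
    the matrix behind positional-variance diagrams.
    """
    samples = np.asarray(samples)
    if samples.ndim == 1:
        samples = samples[None, :]
    if samples.size == 0:
        raise ValueError("at least one sample is required")
    s, n = samples.shape
    dens = np.zeros((n, n))
    for p in range(n):
        dens[:, p] = np.bincount(samples[:, p].astype(np.intp), minlength=n)
    dens /= s
    return dens
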