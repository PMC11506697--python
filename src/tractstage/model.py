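"""Subtype-and-stage inference for z-scored biomarkers.

`SubtypeStageModel` is the package's core estimator: an event-based disease
progression model in which every biomarker crosses a ladder of abnormality
thresholds in an unknown order. Fitting recovers, per subtype, the maximum-
likelihood event sequence (greedy ascent over permutations + Metropolis MCMC
for uncertainty); subjects are assigned a subtype and a maximum-likelihood
stage along the sequence. The number of subtypes is chosen externally with
`select_n_subtypes` (cross-validation information criterion).

The estimator follows scikit-learn conventions: hyperparameters in
``__init__``, fitted state in trailing-underscore attributes, `fit` /
`predict` / `score`, and compatibility with `sklearn.base.clone`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import kendalltau
from sklearn.base import BaseEstimator
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

from .events import ZScoreEventSet, trajectory_matrix
from .fitting import (McmcResult, coordinate_ascent, greedy_fit, mcmc_sample,
                      positional_density)
from .likelihood import mixture_log_likelihood, stage_log_densities

__all__ = ["SubtypeStageModel", "StageResult", "select_n_subtypes",
           "subtype_similarity"]


@dataclass
class StageResult:
    """Per-subject staging output.

    ``stage_posterior`` is the posterior over stages conditional on each
    subject's maximum-likelihood subtype (uniform stage prior); ``ml_stage``
    is its argmax, with ties broken toward the smaller stage.
    """

    subject_ids: list
    subtype_posterior: np.ndarray    # (P, C)
    stage_posterior: np.ndarray      # (P, N + 1)
    ml_subtype: np.ndarray           # (P,)
    ml_stage: np.ndarray             # (P,)

    def to_frame(self) -> pd.DataFrame:
        post = self.stage_posterior
        with np.errstate(divide="ignore", invalid="ignore"):
            ent = -np.sum(np.where(post > 0, post * np.log(post), 0.0), axis=1)
        return pd.DataFrame({
            "subject_id": self.subject_ids,
            "ml_subtype": self.ml_subtype,
            "ml_stage": self.ml_stage,
            "stage_posterior_entropy": ent,
        })


class SubtypeStageModel(BaseEstimator):
    """Linear z-score subtype-and-stage event-sequence model.

    Parameters
    ----------
    n_subtypes : int, default 1
        Number of progression subtypes C. Fitted hierarchically: the
        (C-1)-subtype model is fitted first, then each subtype is tentatively
        split in two and the best-scoring split is kept.
    thresholds : sequence of float, default (1, 2, 3)
        Abnormality thresholds per biomarker. Three thresholds over 20 ROIs
        give N = 60 events, hence stages 0..60.
    z_max : float, default 5.0
        Asymptotic abnormality reached at the final stage.
    sigma : float or array, default 1.0
        Gaussian noise scale per biomarker; inputs are z-scores, so 1 is the
        natural default.
    n_starts : int, default 25
        Greedy-ascent starting sequences (first one data-driven, rest random).
    mcmc_iter : int, default 100_000
        Metropolis iterations for sequence uncertainty; 0 disables MCMC
        (point estimate only).
    burn_in : float, default 0.1
        Fraction of the chain discarded before summarising uncertainty.
    n_split_attempts : int, default 2
        Random bipartitions tried when splitting a subtype.
    max_split_rounds : int, default 10
        Cap on alternating refit/reassign rounds per split attempt.
    max_greedy_passes, split_greedy_passes : int or None
        Sweep caps for the main and split-refinement ascents (None = to
        convergence). Lowering them trades fit quality for speed.
    random_state : int or None
        Seed for all randomness in the fit.
    """

    def __init__(self, n_subtypes=1, thresholds=(1.0, 2.0, 3.0), z_max=5.0,
                 sigma=1.0, n_starts=25, mcmc_iter=100_000, burn_in=0.1,
                 n_split_attempts=2, max_split_rounds=10,
                 max_greedy_passes=None, split_greedy_passes=2,
                 random_state=None):
        self.n_subtypes = n_subtypes
        self.thresholds = thresholds
        self.z_max = z_max
        self.sigma = sigma
        self.n_starts = n_starts
        self.mcmc_iter = mcmc_iter
        self.burn_in = burn_in
        self.n_split_attempts = n_split_attempts
        self.max_split_rounds = max_split_rounds
        self.max_greedy_passes = max_greedy_passes
        self.split_greedy_passes = split_greedy_passes
        self.random_state = random_state

    # ------------------------------------------------------------------ io
    def _coerce_X(self, X, fit=False):
        if isinstance(X, pd.DataFrame):
            if fit:
                self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            elif hasattr(self, "feature_names_in_"):
                X = X.loc[:, list(self.feature_names_in_)]
            ids = list(X.index)
            arr = X.to_numpy(dtype=float)
        else:
            arr = np.atleast_2d(np.asarray(X, dtype=float))
            ids = list(range(arr.shape[0]))
        if arr.ndim != 2:
            raise ValueError("X must be 2-dimensional (subjects x biomarkers)")
        if not np.all(np.isfinite(arr)):
            raise ValueError("X contains non-finite values")
        return arr, ids

    def _event_set(self, n_features) -> ZScoreEventSet:
        names = (list(self.feature_names_in_)
                 if hasattr(self, "feature_names_in_")
                 else [f"bm{i}" for i in range(n_features)])
        return ZScoreEventSet.with_defaults(names, self.thresholds, self.z_max)

    # ----------------------------------------------------------------- fit
    def fit(self, X, y=None):
        arr, _ = self._coerce_X(X, fit=True)
        if self.n_subtypes < 1:
            raise ValueError("n_subtypes must be >= 1")
        if self.n_subtypes > arr.shape[0]:
            raise ValueError(
                f"n_subtypes={self.n_subtypes} exceeds the number of "
                f"subjects ({arr.shape[0]})")
        self.n_features_in_ = arr.shape[1]
        events = self._event_set(arr.shape[1])
        rng = np.random.default_rng(self.random_state)

        path, diag = self._fit_path(arr, events, rng, self.n_subtypes)
        sequences, fractions = path[-1]
        sequences = list(sequences)
        fractions, resp = self._em_fractions(arr, events, sequences, fractions)

        # MCMC uncertainty per subtype on its hard-assigned subjects
        self.mcmc_: list[McmcResult | None] = []
        hard = np.argmax(resp, axis=1)
        for c, seq in enumerate(sequences):
            if self.mcmc_iter and self.mcmc_iter > 0:
                sub = arr[hard == c] if len(sequences) > 1 else arr
                res = mcmc_sample(sub, events, seq, self.mcmc_iter,
                                  seed=rng.integers(2**31), sigma=self.sigma)
                ml_seq, ml_ll = res.ml_sequence()
                better, better_ll = coordinate_ascent(
                    sub, events, ml_seq, sigma=self.sigma,
                    max_passes=self.max_greedy_passes,
                    seed=rng.integers(2**31))
                sequences[c] = better
                self.mcmc_.append(res)
            else:
                self.mcmc_.append(None)

        self.event_set_ = events
        self.sequences_ = [np.asarray(s, dtype=np.intp) for s in sequences]
        self.fractions_, resp = self._em_fractions(arr, events, sequences,
                                                   fractions)
        marg = self._subject_marginals(arr, events, sequences)
        self.log_likelihood_ = mixture_log_likelihood(marg, self.fractions_)
        self.greedy_start_lls_ = diag
        return self

    def _fit_path(self, arr, events, rng, c_max):
        """Hierarchical fit yielding every model from C = 1 to `c_max`.

        Returns ([(sequences, fractions) per C], greedy diagnostics). The
        C-subtype model is built by splitting one subtype of the (C-1)
        model, so all intermediate models come out of a single pass —
        which is what CVIC evaluation consumes.
        """
        order, ll, start_lls = greedy_fit(
            arr, events, n_starts=self.n_starts, seed=rng.integers(2**31),
            sigma=self.sigma, max_passes=self.max_greedy_passes)
        sequences, fractions = [order], np.array([1.0])
        path = [( [s.copy() for s in sequences], fractions.copy() )]
        for C in range(2, c_max + 1):
            sequences, fractions = self._split_best(
                arr, events, sequences, fractions, rng)
            fractions, _ = self._em_fractions(arr, events, sequences,
                                              fractions)
            path.append(([s.copy() for s in sequences], fractions.copy()))
        return path, start_lls

    def _subject_marginals(self, arr, events, sequences):
        """(P, C) stage-marginal log likelihood per subtype sequence."""
        n = events.n_events
        cols = []
        for seq in sequences:
            g = trajectory_matrix(seq, events)
            A = stage_log_densities(arr, g, self.sigma)
            cols.append(logsumexp(A, axis=1) - np.log(n + 1))
        return np.column_stack(cols)

    def _em_fractions(self, arr, events, sequences, fractions, n_iter=200,
                      tol=1e-10):
        """MLE of mixture fractions with sequences held fixed."""
        marg = self._subject_marginals(arr, events, sequences)
        f = np.asarray(fractions, dtype=float)
        f = f / f.sum()
        for _ in range(n_iter):
            with np.errstate(divide="ignore"):
                w = marg + np.log(f)[None, :]
            w -= logsumexp(w, axis=1, keepdims=True)
            resp = np.exp(w)
            new = resp.mean(axis=0)
            if np.max(np.abs(new - f)) < tol:
                f = new
                break
            f = new
        return f / f.sum(), resp

    def _split_best(self, arr, events, sequences, fractions, rng):
        """Try splitting each current subtype in two; keep the best model."""
        marg = self._subject_marginals(arr, events, sequences)
        with np.errstate(divide="ignore"):
            hard = np.argmax(marg + np.log(fractions)[None, :], axis=1)
        best_score, best = -np.inf, None
        for c in range(len(sequences)):
            idx = np.flatnonzero(hard == c)
            if idx.size < 4:
                continue
            for _ in range(self.n_split_attempts):
                cand = self._refine_split(arr, events, sequences[c], idx, rng)
                if cand is None:
                    continue
                seq_a, seq_b = cand
                new_seqs = ([s for k, s in enumerate(sequences) if k != c]
                            + [seq_a, seq_b])
                new_f = np.full(len(new_seqs), 1.0 / len(new_seqs))
                new_f, _ = self._em_fractions(arr, events, new_seqs, new_f,
                                              n_iter=50)
                m = self._subject_marginals(arr, events, new_seqs)
                score = mixture_log_likelihood(m, new_f)
                if score > best_score:
                    best_score, best = score, (new_seqs, new_f)
        if best is None:
            # no split improved or was feasible: fall back to duplicating the
            # largest subtype; the extra component is redundant and CVIC will
            # penalize it out
            c = int(np.argmax(fractions))
            new_seqs = list(sequences) + [sequences[c].copy()]
            f = np.asarray(fractions, dtype=float).copy()
            extra = f[c] / 2
            f[c] -= extra
            return new_seqs, np.append(f, extra)
        return best

    def _refine_split(self, arr, events, parent_seq, idx, rng):
        """Alternating refit/reassign refinement of one random bipartition."""
        mask = rng.random(idx.size) < 0.5
        if mask.all() or not mask.any():
            mask[rng.integers(idx.size)] = ~mask[rng.integers(idx.size)]
        seq_a, seq_b = parent_seq.copy(), parent_seq.copy()
        for _ in range(self.max_split_rounds):
            a_idx, b_idx = idx[mask], idx[~mask]
            if a_idx.size == 0 or b_idx.size == 0:
                return None
            seq_a, _ = coordinate_ascent(arr[a_idx], events, seq_a,
                                         sigma=self.sigma,
                                         max_passes=self.split_greedy_passes,
                                         seed=rng.integers(2**31))
            seq_b, _ = coordinate_ascent(arr[b_idx], events, seq_b,
                                         sigma=self.sigma,
                                         max_passes=self.split_greedy_passes,
                                         seed=rng.integers(2**31))
            m = self._subject_marginals(arr[idx], events, [seq_a, seq_b])
            new_mask = m[:, 0] >= m[:, 1]
            if new_mask.all() or not new_mask.any():
                return None
            if np.array_equal(new_mask, mask):
                break
            mask = new_mask
        return seq_a, seq_b

    # ------------------------------------------------------------- predict
    def predict_stages(self, X) -> StageResult:
        """Full posterior staging: subtype posterior, stage posterior under
        the ML subtype, and ML subtype/stage per subject."""
        check_is_fitted(self, "sequences_")
        arr, ids = self._coerce_X(X)
        events = self.event_set_
        C = len(self.sequences_)
        marg = self._subject_marginals(arr, events, self.sequences_)
        with np.errstate(divide="ignore"):
            w = marg + np.log(self.fractions_)[None, :]
        w -= logsumexp(w, axis=1, keepdims=True)
        subtype_post = np.exp(w)
        ml_subtype = np.argmax(subtype_post, axis=1)

        stage_post = np.empty((arr.shape[0], events.n_events + 1))
        for c in range(C):
            rows = np.flatnonzero(ml_subtype == c)
            if rows.size == 0:
                continue
            g = trajectory_matrix(self.sequences_[c], events)
            A = stage_log_densities(arr[rows], g, self.sigma)
            A -= logsumexp(A, axis=1, keepdims=True)
            stage_post[rows] = np.exp(A)
        ml_stage = np.argmax(stage_post, axis=1)  # argmax → smallest on ties
        return StageResult(ids, subtype_post, stage_post, ml_subtype, ml_stage)

    def predict(self, X) -> np.ndarray:
        """Maximum-likelihood stage per subject."""
        return self.predict_stages(X).ml_stage

    def score(self, X, y=None) -> float:
        """Mean per-subject mixture log likelihood."""
        check_is_fitted(self, "sequences_")
        arr, _ = self._coerce_X(X)
        marg = self._subject_marginals(arr, self.event_set_, self.sequences_)
        return mixture_log_likelihood(marg, self.fractions_) / max(arr.shape[0], 1)

    def total_log_likelihood(self, X) -> float:
        check_is_fitted(self, "sequences_")
        arr, _ = self._coerce_X(X)
        marg = self._subject_marginals(arr, self.event_set_, self.sequences_)
        return mixture_log_likelihood(marg, self.fractions_)

    # ------------------------------------------------------------ summaries
    def positional_density(self, subtype: int = 0) -> np.ndarray:
        """Positional-density matrix from the post-burn-in chain (rows in
        canonical event order, rows sum to 1)."""
        check_is_fitted(self, "mcmc_")
        res = self.mcmc_[subtype]
        if res is None:
            raise ValueError("model was fitted with mcmc_iter=0; no chain")
        k = int(self.burn_in * len(res.samples))
        return positional_density(res.samples[k:], self.event_set_)

    def subtype_similarity(self) -> np.ndarray:
        check_is_fitted(self, "sequences_")
        return subtype_similarity(self.sequences_)

    def sequence_labels(self, subtype: int = 0) -> list:
        """The ML sequence as ordered human-readable event labels."""
        check_is_fitted(self, "sequences_")
        labels = self.event_set_.event_labels()
        return [labels[e] for e in self.sequences_[subtype]]


def subtype_similarity(sequences) -> np.ndarray:
    """Kendall-tau similarity between subtype sequences.

    Tau is computed over event positions; the matrix is symmetric with a
    unit diagonal, and a sequence versus its reversal gives -1.
    """
    C = len(sequences)
    pos = []
    for seq in sequences:
        p = np.empty(len(seq), dtype=np.intp)
        p[np.asarray(seq)] = np.arange(len(seq))
        pos.append(p)
    sim = np.eye(C)
    for i in range(C):
        for j in range(i + 1, C):
            tau = kendalltau(pos[i], pos[j]).statistic
            sim[i, j] = sim[j, i] = tau
    return sim


def select_n_subtypes(X, max_subtypes: int, folds: int = 10, seed=None,
                      **model_kwargs):
    """Choose the number of subtypes by the cross-validation information
    criterion.

    For each C in 1..max_subtypes, a K-fold split of subjects (seeded,
    shuffled) is fitted on the training folds and scored on the held-out
    subjects (each contributes the log of the fraction-weighted mixture of
    its per-subtype stage marginals). CVIC(C) = -2 x summed held-out log
    likelihood; the C minimising CVIC is chosen, ties toward the smaller C.

    Returns
    -------
    chosen : int
    cvic : dict mapping C -> CVIC value
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if max_subtypes < 1:
        raise ValueError("max_subtypes must be >= 1")
    if isinstance(X, pd.DataFrame):
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.atleast_2d(np.asarray(X, dtype=float))
    n = arr.shape[0]
    if n // folds < 2:
        raise ValueError(f"{folds}-fold split of {n} subjects leaves folds "
                         "with fewer than 2 subjects")
    rng = np.random.default_rng(seed)
    kf = KFold(n_splits=folds, shuffle=True,
               random_state=int(rng.integers(2**31)))
    heldout = np.zeros(max_subtypes)
    for train, test in kf.split(arr):
        est = SubtypeStageModel(n_subtypes=max_subtypes,
                                random_state=int(rng.integers(2**31)),
                                **model_kwargs)
        events = est._event_set(arr.shape[1])
        est.n_features_in_ = arr.shape[1]
        fold_rng = np.random.default_rng(est.random_state)
        path, _ = est._fit_path(arr[train], events, fold_rng, max_subtypes)
        for C, (seqs, fracs) in enumerate(path, start=1):
            marg = est._subject_marginals(arr[test], events, seqs)
            heldout[C - 1] += mixture_log_likelihood(marg, fracs)
    cvic = {C: float(-2.0 * heldout[C - 1])
            for C in range(1, max_subtypes + 1)}
    chosen = min(cvic, key=lambda c: (round(cvic[c], 12), c))
    return chosen, cvic
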