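"""Z-score events and piecewise-linear biomarker trajectories.

An *event* is one biomarker crossing one abnormality threshold (e.g. the
ipsilateral UF reaching z = 2). A model with B biomarkers and per-biomarker
thresholds z1 < z2 < ... has N = sum of threshold counts events in total; a
disease *sequence* is a permutation of all N events, and a subject's *stage*
k in {0, ..., N} means the first k events have occurred.

Under the linear z-score model, biomarker b's expected abnormality as a
function of stage is the piecewise-linear curve through (0, 0), one control
point (position of each of b's events, its threshold), and (N, z_max_b).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ZScoreEventSet",
    "is_valid_sequence",
    "check_sequence",
    "random_valid_sequence",
    "ranked_init_sequence",
    "trajectory_matrix",
    "expected_value",
]


@dataclass(frozen=True)
class ZScoreEventSet:
    """The full set of (biomarker, threshold) events for one model.

    Parameters
    ----------
    biomarkers : tuple of str
        Biomarker labels (e.g. the 20 lateralized ROI names).
    thresholds : tuple of tuple of float
        Per-biomarker abnormality thresholds, each strictly increasing and
        positive. Default set by :meth:`with_defaults`.
    z_max : tuple of float
        Per-biomarker asymptotic abnormality, reached at stage N; must be at
        least the last threshold.
    """

    biomarkers: tuple
    thresholds: tuple
    z_max: tuple
    # canonical event order: biomarker-major, thresholds ascending
    event_biomarker: np.ndarray = field(init=False, repr=False, compare=False)
    event_value: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if len(self.thresholds) != len(self.biomarkers):
            raise ValueError("one threshold tuple per biomarker required")
        if len(self.z_max) != len(self.biomarkers):
            raise ValueError("one z_max per biomarker required")
        bm, val = [], []
        for b, (thr, zm) in enumerate(zip(self.thresholds, self.z_max)):
            thr = tuple(float(t) for t in thr)
            if len(thr) == 0:
                raise ValueError(f"biomarker {self.biomarkers[b]!r} has no events")
            if any(t <= 0 for t in thr) or any(
                t2 <= t1 for t1, t2 in zip(thr, thr[1:])
            ):
                raise ValueError(
                    f"thresholds for {self.biomarkers[b]!r} must be positive "
                    f"and strictly increasing, got {thr}"
                )
            if zm < thr[-1]:
                raise ValueError(
                    f"z_max for {self.biomarkers[b]!r} ({zm}) below last "
                    f"threshold ({thr[-1]})"
                )
            bm.extend([b] * len(thr))
            val.extend(thr)
        object.__setattr__(self, "event_biomarker", np.asarray(bm, dtype=np.intp))
        object.__setattr__(self, "event_value", np.asarray(val, dtype=float))

    @classmethod
    def with_defaults(cls, biomarkers, thresholds=(1.0, 2.0, 3.0), z_max=5.0):
        """Same thresholds and z_max for every biomarker."""
        biomarkers = tuple(biomarkers)
        return cls(
            biomarkers=biomarkers,
            thresholds=tuple(tuple(thresholds) for _ in biomarkers),
            z_max=tuple(float(z_max) for _ in biomarkers),
        )

    @property
    def n_biomarkers(self) -> int:
        return len(self.biomarkers)

    @property
    def n_events(self) -> int:
        return self.event_value.size

    def events_of(self, b: int) -> np.ndarray:
        """Canonical event indices of biomarker b, thresholds ascending."""
        return np.flatnonzero(self.event_biomarker == b)

    def event_labels(self) -> list:
        """Human-readable event labels like ``"UF_ipsi:z2"``."""
        return [
            f"{self.biomarkers[b]}:z{v:g}"
            for b, v in zip(self.event_biomarker, self.event_value)
        ]


def is_valid_sequence(order: np.ndarray, events: ZScoreEventSet) -> bool:
    """True iff `order` is a permutation of all events with each biomarker's
    thresholds appearing in increasing order."""
    order = np.asarray(order)
    n = events.n_events
    if order.shape != (n,) or not np.array_equal(np.sort(order), np.arange(n)):
        return False
    vals_along = events.event_value[order]
    bms_along = events.event_biomarker[order]
    for b in range(events.n_biomarkers):
        v = vals_along[bms_along == b]
        if np.any(np.diff(v) <= 0):
            return False
    return True


def check_sequence(order: np.ndarray, events: ZScoreEventSet) -> np.ndarray:
    order = np.asarray(order, dtype=np.intp)
    if not is_valid_sequence(order, events):
        raise ValueError("invalid event sequence (not a permutation respecting "
                         "intra-biomarker threshold order)")
    return order


def random_valid_sequence(events: ZScoreEventSet, rng: np.random.Generator) -> np.ndarray:
    """Uniform random valid sequence: shuffle all events, then sort each
    biomarker's slots by threshold (a uniform draw over valid orderings)."""
    order = rng.permutation(events.n_events)
    for b in range(events.n_biomarkers):
        slots = np.flatnonzero(events.event_biomarker[order] == b)
        order[slots] = events.events_of(b)
    return order


def ranked_init_sequence(X: np.ndarray, events: ZScoreEventSet) -> np.ndarray:
    """Data-driven starting sequence: order events by how commonly their
    threshold is already exceeded in the cohort (most-exceeded first).

    Within a biomarker the exceedance fraction is non-increasing in the
    threshold, so the result is always a valid sequence; ties are broken by
    canonical event index for determinism.
    """
    X = np.asarray(X, dtype=float)
    frac = np.array([
        np.mean(X[:, b] >= v) if X.shape[0] else 0.0
        for b, v in zip(events.event_biomarker, events.event_value)
    ])
    order = np.lexsort((np.arange(events.n_events), events.event_value, -frac))
    # enforce validity in degenerate tie cases
    for b in range(events.n_biomarkers):
        slots = np.flatnonzero(events.event_biomarker[order] == b)
        order[slots] = events.events_of(b)
    return np.asarray(order, dtype=np.intp)


def trajectory_matrix(order: np.ndarray, events: ZScoreEventSet) -> np.ndarray:
    """Expected abnormality at every stage, shape (N + 1, B).

    Row k is the model's expected z-score vector at stage k: piecewise-linear
    through (0, 0), (position of event, threshold) for each event, and
    (N, z_max). Monotone non-decreasing down each column.
    """
    order = np.asarray(order)
    n = events.n_events
    pos = np.empty(n, dtype=np.intp)
    pos[order] = np.arange(1, n + 1)  # 1-based sequence position per event
    ks = np.arange(n + 1, dtype=float)
    g = np.empty((n + 1, events.n_biomarkers))
    for b in range(events.n_biomarkers):
        ev = events.events_of(b)
        p = pos[ev].astype(float)
        v = events.event_value[ev]
        if p[-1] < n:
            xp = np.concatenate(([0.0], p, [float(n)]))
            fp = np.concatenate(([0.0], v, [events.z_max[b]]))
        else:  # last event sits at stage N; the z_max anchor is vacuous
            xp = np.concatenate(([0.0], p))
            fp = np.concatenate(([0.0], v))
        g[:, b] = np.interp(ks, xp, fp)
    return g


def expected_value(biomarker: int, stage: int, order: np.ndarray,
                   events: ZScoreEventSet) -> float:
    """Expected abnormality of one biomarker at one stage (scalar form)."""
    if not 0 <= stage <= events.n_events:
        raise ValueError(f"stage must be in [0, {events.n_events}]")
    return float(trajectory_matrix(order, events)[stage, biomarker])
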