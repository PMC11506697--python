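"""Shared fixtures: synthetic cohorts, fitted models, and toy instances.

The expensive fits are session-scoped so that recovery properties and the
acceptance checks share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

import tractstage as ts
from tractstage.events import ZScoreEventSet, trajectory_matrix


def preprocess_cohort(table):
    """Cohort table -> (lateralized z-matrix, patient rows)."""
    hc = table[table["group"] == "HC"]
    patients = table[table["group"] == "TLE"]
    norm = ts.CovariateNormalizer().fit(hc)
    return ts.lateralize(norm.transform(patients), patients), patients


def make_toy(n_biomarkers=3, n_subjects=50, noise_sd=0.5, seed=0,
             threshold=2.0, z_max=5.0):
    """Tiny single-threshold instance with a planted sequence and stages."""
    rng = np.random.default_rng(seed)
    events = ZScoreEventSet.with_defaults(
        [f"bm{i}" for i in range(n_biomarkers)], (threshold,), z_max)
    order = ts.random_valid_sequence(events, rng)
    stages = rng.integers(0, events.n_events + 1, n_subjects)
    g = trajectory_matrix(order, events)
    X = g[stages] + rng.normal(0.0, noise_sd, (n_subjects, n_biomarkers))
    return events, order, stages, X


@pytest.fixture(scope="session")
def default_cohort():
    """Default-condition cohort: 270 HC, 155 TLE, 60 events, noise SD 1."""
    cfg = ts.CohortConfig(seed=7)
    table, gt = ts.generate_cohort(cfg)
    zmat, patients = preprocess_cohort(table)
    return {"config": cfg, "table": table, "gt": gt, "zmat": zmat,
            "patients": patients}


@pytest.fixture(scope="session")
def default_fit(default_cohort):
    """Single-subtype fit of the default cohort (with MCMC uncertainty)."""
    model = ts.SubtypeStageModel(n_subtypes=1, n_starts=4, mcmc_iter=20_000,
                                 random_state=101)
    model.fit(default_cohort["zmat"])
    stages = model.predict_stages(default_cohort["zmat"])
    return {"model": model, "stages": stages, **default_cohort}


@pytest.fixture(scope="session")
def two_subtype_fit():
    """Two maximally dissimilar planted sequences, n = 300, low noise."""
    cfg = ts.CohortConfig(n_patients=300, n_subtypes_true=2,
                          sequence_mode="reversed_pair", noise_sd=0.5,
                          seed=12)
    table, gt = ts.generate_cohort(cfg)
    zmat, patients = preprocess_cohort(table)
    model = ts.SubtypeStageModel(n_subtypes=2, n_starts=3, mcmc_iter=0,
                                 n_split_attempts=3, random_state=3)
    model.fit(zmat)
    return {"config": cfg, "gt": gt, "zmat": zmat, "model": model,
            "stages": model.predict_stages(zmat)}


def position_vector(order):
    order = np.asarray(order)
    pos = np.empty(order.size, dtype=np.intp)
    pos[order] = np.arange(order.size)
    return pos


def kendall_between(seq_a, seq_b):
    from scipy.stats import kendalltau
    return kendalltau(position_vector(seq_a), position_vector(seq_b)).statistic
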