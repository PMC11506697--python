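"""Synthetic TLE/control cohorts with known progression ground truth.

No tract-level FA dataset is distributed with the package, so testing the
whole pipeline requires a generator that inverts the inference model: plant
one or more event sequences, sample a latent stage per patient, draw each
patient's lateralized abnormality vector around the stage trajectory, and
map it back to FA space through the same age/sex normative model the
preprocessing step assumes. Clinical covariates (disease duration, ASM
count, hippocampal-sclerosis status) are coupled to the latent stage at
effect sizes comparable to published TLE cohorts, so the downstream
association battery has realistic signal to recover.

Default cohort structure mirrors a single-centre unilateral-TLE study:
270 controls; 155 patients of whom ~32% have hippocampal sclerosis and
~69% a left-sided focus.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .events import ZScoreEventSet, check_sequence, random_valid_sequence, \
    trajectory_matrix
from .preprocess import delateralize
from .tracts import MIDLINE_TRACTS, PAIRED_TRACTS, ROI_LABELS, TRACT_LABELS

__all__ = ["ClinicalCoupling", "CohortConfig", "CohortGroundTruth",
           "generate_cohort", "tle_like_sequence", "blocked_sequence",
           "reversed_valid", "save_cohort", "load_cohort"]

# Typical tract-level FA means (directionally realistic; exact demographics
# and tract means of any specific cohort are not matched).
_BASE_FA = {"ATR": 0.45, "CST": 0.56, "Cing_C": 0.50, "Cing_H": 0.40,
            "IFOF": 0.48, "ILF": 0.47, "SLF": 0.45, "SLF_T": 0.50,
            "UF": 0.44, "Forceps_major": 0.58, "Forceps_minor": 0.50}


def _default_fa_means() -> dict:
    out = {}
    for t in PAIRED_TRACTS:
        out[f"{t}_L"] = _BASE_FA[t]
        out[f"{t}_R"] = _BASE_FA[t]
    for t in MIDLINE_TRACTS:
        out[t] = _BASE_FA[t]
    return out


@dataclass
class ClinicalCoupling:
    """Linear-in-stage clinical covariates, floored at 0 and rounded.

    Defaults were calibrated once by Monte Carlo so that at n = 155 with
    uniform stages the stage-duration rank correlation centres near 0.33
    and stage-ASM near 0.27.
    """

    duration_intercept: float = 10.0
    duration_slope: float = 0.24     # years per stage
    duration_noise_sd: float = 12.0
    asm_intercept: float = 1.5
    asm_slope: float = 0.025         # medications per stage
    asm_noise_sd: float = 1.5
    asm_missing_rate: float = 5 / 155


@dataclass
class CohortConfig:
    """Generator configuration; defaults are the package's study conditions."""

    n_hc: int = 270
    n_patients: int = 155
    tract_labels: tuple = TRACT_LABELS
    fa_baseline_mean: dict = field(default_factory=_default_fa_means)
    fa_baseline_sd: float = 0.025        # FA units; also the HC residual SD
    age_slope: float = -0.0005           # FA units per year
    sex_offset: float = 0.005            # FA units (F minus M)
    age_range: tuple = (18.0, 70.0)
    n_subtypes_true: int = 1
    sequence_mode: str = "tle_like"      # tle_like | random | reversed_pair
    z_thresholds: tuple = (1.0, 2.0, 3.0)
    z_max: float = 5.0
    noise_sd: float = 1.0                # z units around the stage trajectory
    stage_distribution: tuple = ("uniform",)   # or ("beta", a, b)
    coupling: ClinicalCoupling = field(default_factory=ClinicalCoupling)
    hs_fraction: float = 50 / 155
    hs_stage_slope: float = 0.06         # logistic slope of P(HS) in stage
    left_fraction: float = 107 / 155
    seizure_free_rate: float = 14 / 155
    seed: int = 0

    def validate(self) -> None:
        def bad(name, msg):
            raise ValueError(f"invalid CohortConfig.{name}: {msg}")
        if self.n_hc < 0:
            bad("n_hc", "must be >= 0")
        if self.n_patients < 0:
            bad("n_patients", "must be >= 0")
        if set(self.tract_labels) != set(TRACT_LABELS):
            bad("tract_labels", "must be the 18 paired + 2 midline JHU set")
        for t, m in self.fa_baseline_mean.items():
            if not 0.0 < m < 1.0:
                bad("fa_baseline_mean", f"{t} = {m} not in (0,1)")
        if self.fa_baseline_sd <= 0:
            bad("fa_baseline_sd", "must be > 0")
        thr = tuple(self.z_thresholds)
        if any(t <= 0 for t in thr) or any(b <= a for a, b in zip(thr, thr[1:])):
            bad("z_thresholds", "must be positive and strictly increasing")
        if self.z_max < thr[-1]:
            bad("z_max", "must be >= last threshold")
        if self.noise_sd < 0:
            bad("noise_sd", "must be >= 0")
        if self.n_subtypes_true < 1:
            bad("n_subtypes_true", "must be >= 1")
        if self.sequence_mode not in ("tle_like", "random", "reversed_pair"):
            bad("sequence_mode", f"unknown mode {self.sequence_mode!r}")
        if self.sequence_mode == "reversed_pair" and self.n_subtypes_true != 2:
            bad("sequence_mode", "reversed_pair requires n_subtypes_true = 2")
        if self.stage_distribution[0] not in ("uniform", "beta"):
            bad("stage_distribution", "must be ('uniform',) or ('beta', a, b)")
        if self.stage_distribution[0] == "beta" and (
                len(self.stage_distribution) != 3
                or any(a <= 0 for a in self.stage_distribution[1:])):
            bad("stage_distribution", "beta needs two positive shape params")
        for name in ("hs_fraction", "left_fraction", "seizure_free_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                bad(name, "must be in [0,1]")

    def event_set(self) -> ZScoreEventSet:
        """The lateralized-ROI event set implied by this configuration."""
        return ZScoreEventSet.with_defaults(ROI_LABELS, self.z_thresholds,
                                            self.z_max)

    # --------------------------------------------------------- (de)serialise
    def to_dict(self) -> dict:
        d = asdict(self)
        d["tract_labels"] = list(self.tract_labels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "coupling" in d and isinstance(d["coupling"], dict):
            d["coupling"] = ClinicalCoupling(**d["coupling"])
        if "tract_labels" in d:
            d["tract_labels"] = tuple(d["tract_labels"])
        for k in ("z_thresholds", "stage_distribution", "age_range"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


# ROI ranking of the canonical planted trajectory: focus-side limbic tracts
# first (UF), then forceps / SLF / ATR, association tracts mid-course,
# contralateral homologues late.
_TLE_ROI_RANK = (
    "UF_ipsi", "Forceps_minor", "Forceps_major", "SLF_ipsi", "ATR_ipsi",
    "SLF_T_ipsi", "UF_contra", "Cing_C_ipsi", "ILF_ipsi", "IFOF_ipsi",
    "Cing_H_ipsi", "CST_ipsi", "ATR_contra", "SLF_contra", "ILF_contra",
    "IFOF_contra", "Cing_C_contra", "Cing_H_contra", "SLF_T_contra",
    "CST_contra",
)


def tle_like_sequence(events: ZScoreEventSet) -> np.ndarray:
    """A fixed valid sequence with the qualitative TLE trajectory (UF first,
    forceps/SLF/ATR early, contralateral tracts late), staggered so that
    successive thresholds of one tract interleave with other tracts."""
    rank = {r: i for i, r in enumerate(_TLE_ROI_RANK)}
    keys = []
    for e in range(events.n_events):
        b = int(events.event_biomarker[e])
        name = events.biomarkers[b]
        sibs = events.events_of(b)
        thr_idx = int(np.flatnonzero(sibs == e)[0])
        keys.append(rank.get(name, len(rank)) + 12.0 * thr_idx)
    order = np.asarray(np.lexsort((np.arange(events.n_events),
                                   np.asarray(keys))), dtype=np.intp)
    return check_sequence(order, events)


def blocked_sequence(events: ZScoreEventSet) -> np.ndarray:
    """A valid sequence in which each ROI's thresholds are consecutive
    ("one tract at a time"), ROIs in the canonical TLE rank order. Its
    `reversed_valid` image is the most dissimilar valid sequence attainable
    (Kendall tau close to the -1 bound that threshold order permits), which
    is what the two-subtype separation experiments plant."""
    rank = {r: i for i, r in enumerate(_TLE_ROI_RANK)}
    keys = []
    for e in range(events.n_events):
        b = int(events.event_biomarker[e])
        name = events.biomarkers[b]
        sibs = events.events_of(b)
        thr_idx = int(np.flatnonzero(sibs == e)[0])
        keys.append(rank.get(name, len(rank)) * (events.n_events + 1) + thr_idx)
    order = np.asarray(np.lexsort((np.arange(events.n_events),
                                   np.asarray(keys))), dtype=np.intp)
    return check_sequence(order, events)


def reversed_valid(order: np.ndarray, events: ZScoreEventSet) -> np.ndarray:
    """Reverse a sequence, then restore intra-biomarker threshold order —
    the most dissimilar valid ordering (Kendall tau close to -1)."""
    rev = np.asarray(order)[::-1].copy()
    for b in range(events.n_biomarkers):
        slots = np.flatnonzero(events.event_biomarker[rev] == b)
        rev[slots] = events.events_of(b)
    return check_sequence(rev, events)


@dataclass
class CohortGroundTruth:
    """What the generator planted, for recovery tests and scoring."""

    event_set: ZScoreEventSet
    true_sequences: list            # one order array per true subtype
    true_subtype: np.ndarray        # (n_patients,)
    true_stage: np.ndarray          # (n_patients,) in [0, N]
    coupling: ClinicalCoupling
    n_clipped_fa: int               # FA cells clipped into (0,1)

    def to_dict(self) -> dict:
        labels = self.event_set.event_labels()
        return {
            "event_labels": labels,
            "true_sequences": [[labels[e] for e in seq]
                               for seq in self.true_sequences],
            "true_sequence_orders": [np.asarray(s).tolist()
                                     for s in self.true_sequences],
            "true_subtype": self.true_subtype.tolist(),
            "true_stage": self.true_stage.tolist(),
            "coupling": asdict(self.coupling),
            "n_clipped_fa": self.n_clipped_fa,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _sample_stages(cfg: CohortConfig, n_events: int, size: int,
                   rng: np.random.Generator) -> np.ndarray:
    kind = cfg.stage_distribution[0]
    if kind == "uniform":
        return rng.integers(0, n_events + 1, size=size)
    a, b = cfg.stage_distribution[1:]
    u = rng.beta(a, b, size=size)
    return np.minimum((u * (n_events + 1)).astype(int), n_events)


def _calibrate_hs_offset(stages: np.ndarray, slope: float,
                         target: float) -> float:
    """Location s0 such that mean sigmoid(slope*(stage-s0)) == target."""
    if target <= 0.0 or target >= 1.0 or slope == 0.0 or stages.size == 0:
        return np.nan

    def f(s0):
        return float(np.mean(1.0 / (1.0 + np.exp(-slope * (stages - s0))))
                     - target)
    lo, hi = -1e4, 1e4
    return brentq(f, lo, hi)


def generate_cohort(cfg: CohortConfig):
    """Generate (cohort_table, ground_truth) under `cfg`.

    The cohort table has one row per subject (controls first) with the
    metadata columns followed by the 20 FA columns; identical config and
    seed give identical output.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    events = cfg.event_set()
    n_events = events.n_events
    means = np.array([cfg.fa_baseline_mean[t] for t in TRACT_LABELS])
    age_lo, age_hi = cfg.age_range
    age_mid = 0.5 * (age_lo + age_hi)

    def covariate_fa(age, sex_f):
        return (means[None, :] + cfg.age_slope * (age - age_mid)[:, None]
                + cfg.sex_offset * sex_f[:, None])

    # ---------------------------------------------------------- controls
    hc_age = rng.uniform(age_lo, age_hi, cfg.n_hc)
    hc_sex = rng.integers(0, 2, cfg.n_hc).astype(float)
    hc_fa = covariate_fa(hc_age, hc_sex) + rng.normal(
        0.0, cfg.fa_baseline_sd, (cfg.n_hc, len(TRACT_LABELS)))

    # ---------------------------------------------------------- sequences
    if cfg.sequence_mode == "tle_like":
        base = tle_like_sequence(events)
        seqs = [base]
        for _ in range(1, cfg.n_subtypes_true):
            seqs.append(random_valid_sequence(events, rng))
    elif cfg.sequence_mode == "reversed_pair":
        base = blocked_sequence(events)
        seqs = [base, reversed_valid(base, events)]
    else:
        seqs = [random_valid_sequence(events, rng)
                for _ in range(cfg.n_subtypes_true)]

    # ---------------------------------------------------------- patients
    n_p = cfg.n_patients
    subtype = rng.integers(0, cfg.n_subtypes_true, n_p)
    stage = _sample_stages(cfg, n_events, n_p, rng)
    p_age = rng.uniform(age_lo, age_hi, n_p)
    p_sex = rng.integers(0, 2, n_p).astype(float)
    side = np.where(rng.random(n_p) < cfg.left_fraction, "left", "right")

    trajs = [trajectory_matrix(s, events) for s in seqs]
    z_roi = np.empty((n_p, len(ROI_LABELS)))
    for i in range(n_p):
        mean_z = trajs[subtype[i]][stage[i]]
        z_roi[i] = mean_z + (rng.normal(0.0, cfg.noise_sd, len(ROI_LABELS))
                             if cfg.noise_sd > 0 else 0.0)

    # back to left/right tract space per sampled focus side, then FA space
    z_df = pd.DataFrame(z_roi, index=pd.Index([f"TLE{i + 1:03d}"
                                               for i in range(n_p)],
                                              name="subject_id"),
                        columns=list(ROI_LABELS))
    side_df = pd.DataFrame({"subject_id": z_df.index, "focus_side": side})
    z_lr = delateralize(z_df, side_df)
    p_fa = covariate_fa(p_age, p_sex) - z_lr.to_numpy() * cfg.fa_baseline_sd

    eps = 1e-3
    all_fa = np.vstack([hc_fa, p_fa])
    n_clipped = int(np.sum((all_fa <= 0.0 + eps) | (all_fa >= 1.0 - eps)))
    all_fa = np.clip(all_fa, eps, 1.0 - eps)

    # ---------------------------------------------------------- clinicals
    cp = cfg.coupling
    duration = np.round(np.maximum(
        0.0, cp.duration_intercept + cp.duration_slope * stage
        + rng.normal(0.0, cp.duration_noise_sd, n_p)))
    duration = np.minimum(duration, np.floor(p_age) - 1)  # onset age >= 1
    onset = np.floor(p_age) - duration
    asms = np.round(np.maximum(
        0.0, cp.asm_intercept + cp.asm_slope * stage
        + rng.normal(0.0, cp.asm_noise_sd, n_p)))
    asms = asms.astype(object)
    miss = rng.random(n_p) < cp.asm_missing_rate
    asms[miss] = np.nan

    s0 = _calibrate_hs_offset(stage, cfg.hs_stage_slope, cfg.hs_fraction)
    if np.isnan(s0):
        p_hs = np.full(n_p, cfg.hs_fraction)
    else:
        p_hs = 1.0 / (1.0 + np.exp(-cfg.hs_stage_slope * (stage - s0)))
    hs = rng.random(n_p) < p_hs
    seizure_free = rng.random(n_p) < cfg.seizure_free_rate

    # ---------------------------------------------------------- assemble
    hc = pd.DataFrame({
        "subject_id": [f"HC{i + 1:03d}" for i in range(cfg.n_hc)],
        "group": "HC", "age": hc_age,
        "sex": np.where(hc_sex == 1, "F", "M"),
        "focus_side": "none", "etiology": "none",
        "onset_age": np.nan, "duration_years": np.nan,
        "n_asms": np.nan, "seizure_free": np.nan,
    })
    pt = pd.DataFrame({
        "subject_id": list(z_df.index),
        "group": "TLE", "age": p_age,
        "sex": np.where(p_sex == 1, "F", "M"),
        "focus_side": side,
        "etiology": np.where(hs, "HS", "NL"),
        "onset_age": onset, "duration_years": duration,
        "n_asms": asms,
        "seizure_free": seizure_free.astype(object),
    })
    meta = pd.concat([hc, pt], ignore_index=True)
    fa = pd.DataFrame(all_fa, columns=list(TRACT_LABELS))
    table = pd.concat([meta, fa], axis=1)

    gt = CohortGroundTruth(event_set=events, true_sequences=seqs,
                           true_subtype=subtype, true_stage=stage,
                           coupling=cp, n_clipped_fa=n_clipped)
    return table, gt


def save_cohort(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format="%.10g")


def load_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "seizure_free" in df:
        df["seizure_free"] = df["seizure_free"].map(
            {True: True, False: False, "True": True, "False": False})
    return df
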