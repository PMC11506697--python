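"""From raw tract FA to the lateralized abnormality matrix.

The normative reference is the healthy-control cohort: per tract, FA is
regressed on age and sex (OLS) in controls only, and patients are expressed
as z-scores of their residual against that fit. Because FA *falls* with
white-matter damage, the abnormality score is the sign-flipped z
(abnormality = -(observed - predicted)/residual SD), so larger always means
more damaged. Paired tracts are then relabelled into focus-relative
(ipsilateral/contralateral) space; the midline forceps keep their names.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .tracts import (MIDLINE_TRACTS, PAIRED_TRACTS, ROI_LABELS, TRACT_LABELS,
                     validate_tract_labels)

__all__ = ["CovariateNormalizer", "lateralize", "validate_cohort",
           "METADATA_COLUMNS"]

METADATA_COLUMNS = ("subject_id", "group", "age", "sex", "focus_side",
                    "etiology", "onset_age", "duration_years", "n_asms",
                    "seizure_free")

_SEX_CODE = {"M": 0.0, "F": 1.0}  # absorbed by the intercept; documented


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Schema check for a cohort table (controls and/or patients).

    FA cells must be present and in [0, 1]; this is a hard reject, not an
    imputation. Control rows must carry no focus side or etiology; patient
    rows must have a left/right focus side.
    """
    missing = [c for c in ("subject_id", "group", "age", "sex") if c not in df]
    if missing:
        raise ValueError(f"cohort table missing required columns: {missing}")
    fa_cols = [c for c in df.columns if c in TRACT_LABELS]
    validate_tract_labels(fa_cols)
    fa = df[list(TRACT_LABELS)]
    bad = fa.isna().any(axis=1) | ((fa < 0) | (fa > 1)).any(axis=1)
    if bad.any():
        raise ValueError(
            f"FA values missing or outside [0,1] for subjects: "
            f"{df.loc[bad, 'subject_id'].tolist()[:10]}")
    if not df["group"].isin(["HC", "TLE"]).all():
        raise ValueError("group must be 'HC' or 'TLE'")
    if not df["sex"].isin(list(_SEX_CODE)).all():
        raise ValueError("sex must be 'M' or 'F'")
    hc = df["group"] == "HC"
    if "focus_side" in df:
        side = df["focus_side"].fillna("none")
        if not side[hc].isin(["none"]).all():
            raise ValueError("control rows must have focus_side = 'none'")
        if not side[~hc].isin(["left", "right"]).all():
            raise ValueError("patient rows must have focus_side left/right")
    return df


class CovariateNormalizer(BaseEstimator, TransformerMixin):
    """Normative age/sex correction and abnormality z-scoring.

    Fit on healthy controls only: per tract, OLS of FA on [1, age, sex]
    (sex coded M=0, F=1) with the residual SD stored under the unbiased
    n - 3 denominator. `transform` maps any cohort to abnormality z-scores
    ``-(FA - predicted) / residual SD`` (still in left/right tract space).

    Parameters
    ----------
    flip_sign : bool, default True
        Emit abnormality (= negated residual z) rather than the raw z.
    min_residual_sd : float, default 1e-8
        Tracts with residual SD at or below this are degenerate and raise.
    """

    def __init__(self, flip_sign: bool = True, min_residual_sd: float = 1e-8):
        self.flip_sign = flip_sign
        self.min_residual_sd = min_residual_sd

    def _design(self, df: pd.DataFrame) -> np.ndarray:
        age = df["age"].to_numpy(dtype=float)
        sex = df["sex"].map(_SEX_CODE).to_numpy(dtype=float)
        return np.column_stack([np.ones(len(df)), age, sex])

    def fit(self, X: pd.DataFrame, y=None):
        """`X` is a cohort table of healthy controls (>= 10 rows)."""
        df = validate_cohort(X)
        if not (df["group"] == "HC").all():
            raise ValueError("covariate model must be fitted on HC rows only")
        if len(df) < 10:
            raise ValueError("need at least 10 controls to fit the "
                             "covariate model")
        D = self._design(df)
        if np.linalg.matrix_rank(D) < 3:
            raise ValueError("degenerate design: age/sex columns are not "
                             "linearly independent (single sex cohort?)")
        Y = df[list(TRACT_LABELS)].to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(D, Y, rcond=None)
        resid = Y - D @ beta
        dof = len(df) - 3
        sd = np.sqrt(np.sum(resid**2, axis=0) / dof)
        self.coef_ = beta                  # (3, 20): intercept, age, sex
        self.residual_sd_ = sd             # (20,)
        self.residual_mean_ = resid.mean(axis=0)
        self.tract_labels_ = list(TRACT_LABELS)
        self.n_controls_ = len(df)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Abnormality z per tract (rows indexed by subject_id)."""
        check_is_fitted(self, "coef_")
        df = validate_cohort(X)
        low = self.residual_sd_ <= self.min_residual_sd
        if np.any(low):
            names = [t for t, b in zip(self.tract_labels_, low) if b]
            raise ValueError(f"degenerate tracts with ~zero control residual "
                             f"SD: {names}")
        D = self._design(df)
        Y = df[self.tract_labels_].to_numpy(dtype=float)
        z = (Y - D @ self.coef_) / self.residual_sd_
        if self.flip_sign:
            z = -z
        return pd.DataFrame(z, index=pd.Index(df["subject_id"],
                                              name="subject_id"),
                            columns=self.tract_labels_)

    # -------------------------------------------------------- persistence
    def to_dict(self) -> dict:
        check_is_fitted(self, "coef_")
        return {
            "tract_labels": self.tract_labels_,
            "coefficients": {t: {"intercept": self.coef_[0, i],
                                 "age": self.coef_[1, i],
                                 "sex_F": self.coef_[2, i]}
                             for i, t in enumerate(self.tract_labels_)},
            "residual_sd": dict(zip(self.tract_labels_,
                                    self.residual_sd_.tolist())),
            "n_controls": self.n_controls_,
            "sex_coding": {"M": 0, "F": 1},
            "flip_sign": self.flip_sign,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "CovariateNormalizer":
        est = cls(flip_sign=d.get("flip_sign", True))
        labels = d["tract_labels"]
        est.tract_labels_ = labels
        est.coef_ = np.array([[d["coefficients"][t][k] for t in labels]
                              for k in ("intercept", "age", "sex_F")])
        est.residual_sd_ = np.array([d["residual_sd"][t] for t in labels])
        est.residual_mean_ = np.zeros(len(labels))
        est.n_controls_ = d.get("n_controls", 0)
        return est

    @classmethod
    def load(cls, path) -> "CovariateNormalizer":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def lateralize(z: pd.DataFrame, records: pd.DataFrame) -> pd.DataFrame:
    """Relabel left/right tract z-scores into focus-relative ROI space.

    For a left-focus patient the left tract of each pair becomes the
    ipsilateral ROI and the right becomes contralateral; mirrored for
    right-focus patients. The forceps are copied unchanged. This is a pure
    per-row column permutation: the multiset of values per patient is
    preserved, and relabelling back with the stored focus side recovers the
    original matrix exactly.

    Parameters
    ----------
    z : DataFrame indexed by subject_id with the 20 left/right tract columns.
    records : cohort table (or any frame) with subject_id and focus_side.

    Returns
    -------
    DataFrame indexed by subject_id with columns in the fixed order
    ``tractstage.tracts.ROI_LABELS``.
    """
    side = (records.set_index("subject_id")["focus_side"]
            if "subject_id" in records else records["focus_side"])
    side = side.reindex(z.index)
    if side.isna().any() or not side.isin(["left", "right"]).all():
        bad = z.index[~side.isin(["left", "right"])].tolist()[:10]
        raise ValueError(f"missing or invalid focus_side for subjects {bad}; "
                         "lateralization requires a left/right focus")
    out = pd.DataFrame(index=z.index, columns=list(ROI_LABELS), dtype=float)
    left = (side == "left").to_numpy()
    for t in PAIRED_TRACTS:
        zl = z[f"{t}_L"].to_numpy()
        zr = z[f"{t}_R"].to_numpy()
        out[f"{t}_ipsi"] = np.where(left, zl, zr)
        out[f"{t}_contra"] = np.where(left, zr, zl)
    for t in MIDLINE_TRACTS:
        out[t] = z[t].to_numpy()
    return out


def delateralize(roi: pd.DataFrame, records: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`lateralize` given the same focus sides."""
    side = (records.set_index("subject_id")["focus_side"]
            if "subject_id" in records else records["focus_side"])
    side = side.reindex(roi.index)
    out = pd.DataFrame(index=roi.index, columns=list(TRACT_LABELS),
                       dtype=float)
    left = (side == "left").to_numpy()
    for t in PAIRED_TRACTS:
        zi = roi[f"{t}_ipsi"].to_numpy()
        zc = roi[f"{t}_contra"].to_numpy()
        out[f"{t}_L"] = np.where(left, zi, zc)
        out[f"{t}_R"] = np.where(left, zc, zi)
    for t in MIDLINE_TRACTS:
        out[t] = roi[t].to_numpy()
    return out
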