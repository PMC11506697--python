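"""Nonparametric association battery for stages vs. clinical variables.

The conventions are fixed so that results are reproducible against the
tables such analyses print: Pearson chi-square without continuity
correction for 2x2 categorical comparisons; two-sided Mann-Whitney U from
the tie-corrected normal approximation without continuity correction for
group comparisons of stage; Spearman's rank correlation with the
t-distribution p-value for stage vs. continuous covariates. No multiple-
testing adjustment is applied; raw p-values are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["pearson_chi2", "mann_whitney", "spearman",
           "AssociationReport", "build_association_report"]


def pearson_chi2(table, continuity: bool = False):
    """Pearson chi-square on a 2x2 table.

    Parameters
    ----------
    table : 2x2 array of non-negative counts (rows = groups).
    continuity : bool, default False
        Apply the Yates correction. Off by default: the uncorrected
        statistic is the convention this package reports.

    Returns
    -------
    (chi2, p, df=1)
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.floor(t)):
        raise ValueError("table must be 2x2 non-negative integer counts")
    if t.sum() == 0 or np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("chi-square undefined: a row or column margin is zero")
    chi2, p, df, _ = sps.chi2_contingency(t, correction=continuity)
    return float(chi2), float(p), int(df)


def mann_whitney(x, y, exact: bool = False):
    """Two-sided Mann-Whitney U for two independent samples.

    U is reported for the first sample (midrank ties). The p-value uses the
    tie-corrected normal approximation without continuity correction; with
    ``exact=True`` (small samples, n1*n2 <= 400) the exact permutation null
    is used instead.

    Returns
    -------
    (U, p)
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if exact and x.size * y.size > 400:
        raise ValueError("exact Mann-Whitney limited to n1*n2 <= 400")
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=False)
    return float(res.statistic), float(res.pvalue)


def spearman(x, y):
    """Spearman rank correlation with pairwise deletion of missing values.

    Returns
    -------
    (rs, p, n_used, n_missing)
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired (same length)")
    keep = ~(np.isnan(x) | np.isnan(y))
    n_missing = int(np.sum(~keep))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs for Spearman")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue), int(x.size), n_missing


def _median_iqr(v: np.ndarray) -> str:
    v = v[~np.isnan(v)]
    if v.size == 0:
        return "NA"
    med = np.median(v)
    iqr = np.percentile(v, 75) - np.percentile(v, 25)
    return f"{med:g} ({iqr:g})"


@dataclass
class AssociationReport:
    """Stage-vs-clinical association results (group block + correlation block)."""

    group_comparisons: pd.DataFrame = field(default_factory=pd.DataFrame)
    correlations: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_text(self) -> str:
        lines = ["Categorical comparison of ML stage",
                 "-" * 64]
        for _, r in self.group_comparisons.iterrows():
            lines.append(
                f"{r['variable']:>16}: {r['group1']} {r['median_iqr1']}"
                f" vs {r['group2']} {r['median_iqr2']}"
                f"  U={r['U']:g}  p={r['p']:.3g}  (n={r['n']}"
                + (f", missing={r['n_missing']}" if r["n_missing"] else "")
                + ")")
        lines += ["", "Correlation of ML stage with clinical variables",
                  "-" * 64]
        for _, r in self.correlations.iterrows():
            lines.append(
                f"{r['variable']:>16}: rs={r['rs']:+.3f}  p={r['p']:.3g}"
                f"  (n={r['n']}"
                + (f", missing={r['n_missing']}" if r["n_missing"] else "")
                + ")")
        return "\n".join(lines)

    def save(self, csv_path, text_path=None) -> None:
        g = self.group_comparisons.assign(block="group_comparison")
        c = self.correlations.assign(block="correlation")
        pd.concat([g, c], ignore_index=True).to_csv(csv_path, index=False)
        if text_path is not None:
            with open(text_path, "w") as fh:
                fh.write(self.to_text() + "\n")


_GROUP_VARS = (
    ("sex", "M", "F"),
    ("etiology", "HS", "NL"),
    ("focus_side", "left", "right"),
    ("seizure_free", True, False),
)
_CORR_VARS = ("age", "onset_age", "duration_years", "n_asms")


def build_association_report(stages, records: pd.DataFrame,
                             group_vars=_GROUP_VARS,
                             corr_vars=_CORR_VARS) -> AssociationReport:
    """Relate ML stages to clinical variables.

    Parameters
    ----------
    stages : StageResult or DataFrame with subject_id and ml_stage.
    records : cohort table (patient rows; extra rows are ignored by the
        subject_id join).

    Group comparisons use the Mann-Whitney U test on stage; continuous
    covariates use Spearman's rank correlation. Missing clinical values are
    dropped pairwise and counted.
    """
    if hasattr(stages, "to_frame"):
        stages = stages.to_frame()
    merged = stages.merge(records, on="subject_id", how="inner")
    if merged.empty:
        raise ValueError("no overlapping subject_ids between stages and "
                         "clinical records")
    stage = merged["ml_stage"].to_numpy(dtype=float)

    grows = []
    for var, lvl1, lvl2 in group_vars:
        if var not in merged:
            continue
        col = merged[var]
        m1 = (col == lvl1).to_numpy()
        m2 = (col == lvl2).to_numpy()
        n_missing = int(len(merged) - m1.sum() - m2.sum())
        if m1.sum() == 0 or m2.sum() == 0:
            continue
        U, p = mann_whitney(stage[m1], stage[m2])
        grows.append({
            "variable": var, "group1": str(lvl1), "group2": str(lvl2),
            "median_iqr1": _median_iqr(stage[m1]),
            "median_iqr2": _median_iqr(stage[m2]),
            "U": U, "p": p, "n": int(m1.sum() + m2.sum()),
            "n_missing": n_missing, "test": "mann-whitney",
        })

    crows = []
    for var in corr_vars:
        if var not in merged:
            continue
        rs, p, n, n_missing = spearman(stage,
                                       merged[var].to_numpy(dtype=float))
        crows.append({"variable": var, "rs": rs, "p": p, "n": n,
                      "n_missing": n_missing, "test": "spearman"})

    return AssociationReport(pd.DataFrame(grows), pd.DataFrame(crows))
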