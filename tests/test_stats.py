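"""Statistical kernels against closed-form and permutation oracles, and
the stage-vs-clinical association report."""

import itertools

import numpy as np
import pandas as pd
import pytest

import tractstage as ts
from tractstage.stats import (build_association_report, mann_whitney,
                              pearson_chi2, spearman)

from conftest import preprocess_cohort


# --------------------------------------------------------------- chi-square

# 2x2 tables readable from a published unilateral-TLE demographic table,
# with the p-values that table prints
PRINTED_TABLES = [
    ("gender_tle_vs_hc", [[68, 87], [119, 151]], 0.968, 3),
    ("gender_hs_vs_nl", [[18, 32], [50, 55]], 0.173, 3),
    ("laterality_hs_vs_nl", [[32, 18], [75, 30]], 0.35, 2),
    ("seizure_freedom_hs_vs_nl", [[2, 48], [12, 93]], 0.131, 3),
]


@pytest.mark.parametrize("name,table,printed_p,digits", PRINTED_TABLES)
def test_chi2_reproduces_printed_pvalues(name, table, printed_p, digits):
    chi2, p, df = pearson_chi2(table)
    assert df == 1
    assert round(p, digits) == printed_p


def test_chi2_closed_form_margin_oracle():
    # (ad - bc)^2 * N / (r1 r2 c1 c2), independently of scipy
    a, b, c, d = 68, 87, 119, 151
    n = a + b + c + d
    expect = (a * d - b * c) ** 2 * n / ((a + b) * (c + d) * (a + c) * (b + d))
    chi2, p, _ = pearson_chi2([[a, b], [c, d]])
    assert chi2 == pytest.approx(expect, abs=1e-12)
    assert chi2 == pytest.approx(0.0016, abs=5e-4)


def test_chi2_identical_proportions_gives_zero():
    chi2, p, _ = pearson_chi2([[10, 10], [20, 20]])
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_chi2_invariances():
    t = np.array([[7, 21], [13, 5]])
    base = pearson_chi2(t)
    assert pearson_chi2(t.T)[0] == pytest.approx(base[0], abs=1e-12)
    assert pearson_chi2(t[::-1, ::-1])[0] == pytest.approx(base[0], abs=1e-12)


def test_chi2_zero_margin_is_undefined():
    with pytest.raises(ValueError, match="margin"):
        pearson_chi2([[0, 0], [5, 7]])


def test_chi2_continuity_option_is_more_conservative():
    p_plain = pearson_chi2([[2, 48], [12, 93]])[1]
    p_yates = pearson_chi2([[2, 48], [12, 93]], continuity=True)[1]
    assert p_yates > p_plain


# ------------------------------------------------------------- mann-whitney

def test_mw_balanced_midranks():
    x, y = [1, 4, 5, 8], [2, 3, 6, 7]
    U, p = mann_whitney(x, y)
    assert U == pytest.approx(8.0)  # n1*n2/2
    assert p == pytest.approx(1.0)


def test_mw_complete_separation():
    x, y = [1, 2, 3], [10, 11, 12, 13]
    U1, _ = mann_whitney(x, y)
    U2, _ = mann_whitney(y, x)
    assert U1 == 0.0
    assert U2 == 12.0  # n1*n2
    assert U1 + U2 == len(x) * len(y)


def test_mw_symmetric_in_arguments():
    rng = np.random.default_rng(0)
    x, y = rng.integers(0, 10, 9).astype(float), rng.integers(0, 10, 12)
    assert mann_whitney(x, y)[1] == pytest.approx(mann_whitney(y, x)[1])


def exact_mw_pvalue(x, y):
    """Exhaustive permutation oracle for the two-sided Mann-Whitney test."""
    pooled = np.concatenate([x, y])
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j < len(pooled) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = 0.5 * (i + j - 1) + 1  # midranks, 1-based
        i = j
    n1, n2 = len(x), len(y)
    mu = n1 * n2 / 2

    def u_of(idx):
        return ranks[list(idx)].sum() - n1 * (n1 + 1) / 2

    u_obs = u_of(range(n1))
    dev = abs(u_obs - mu)
    hits = total = 0
    for comb in itertools.combinations(range(n1 + n2), n1):
        total += 1
        if abs(u_of(comb) - mu) >= dev - 1e-9:
            hits += 1
    return hits / total


def test_mw_asymptotic_close_to_exact_permutation_with_ties():
    # tie-corrected normal approximation vs exhaustive permutation null on
    # shifted integer samples (many ties); in the decision-relevant small-p
    # regime the two agree to 0.01 at n1 = n2 = 8
    rng = np.random.default_rng(7)
    checked = 0
    while checked < 3:
        x = rng.integers(0, 6, 8).astype(float)
        y = rng.integers(3, 9, 8).astype(float)
        _, p_asym = mann_whitney(x, y)
        if p_asym > 0.2:
            continue
        checked += 1
        assert abs(p_asym - exact_mw_pvalue(x, y)) < 0.01


def test_mw_exact_option_matches_oracle_without_ties():
    rng = np.random.default_rng(8)
    x = rng.normal(size=6)
    y = rng.normal(0.8, 1, 7)
    _, p = mann_whitney(x, y, exact=True)
    assert p == pytest.approx(exact_mw_pvalue(x, y), abs=1e-9)


def test_mw_empty_group_is_an_error():
    with pytest.raises(ValueError, match="non-empty"):
        mann_whitney([], [1.0, 2.0])


# ----------------------------------------------------------------- spearman

def test_spearman_monotone_and_reversal():
    x = np.array([1.0, 2.5, 4.0, 9.0, 20.0])
    assert spearman(x, np.exp(x / 10))[0] == pytest.approx(1.0)
    assert spearman(x, -x)[0] == pytest.approx(-1.0)


def test_spearman_midrank_formula_oracle_with_ties():
    rng = np.random.default_rng(9)
    x = rng.integers(0, 8, 30).astype(float)
    y = 0.5 * x + rng.integers(0, 5, 30)
    rs, p, n, miss = spearman(x, y)

    def midranks(v):
        order = np.argsort(v, kind="mergesort")
        r = np.empty(len(v))
        sv = v[order]
        i = 0
        while i < len(v):
            j = i
            while j < len(v) and sv[j] == sv[i]:
                j += 1
            r[order[i:j]] = 0.5 * (i + j - 1) + 1
            i = j
        return r

    rx, ry = midranks(x), midranks(y)
    expect = np.corrcoef(rx, ry)[0, 1]
    assert rs == pytest.approx(expect, abs=1e-10)
    assert n == 30 and miss == 0


def test_spearman_monotone_transform_invariance():
    rng = np.random.default_rng(10)
    x = rng.normal(size=25)
    y = rng.normal(size=25)
    base = spearman(x, y)[0]
    assert spearman(np.exp(x), y)[0] == pytest.approx(base, abs=1e-12)
    assert spearman(x, y**3)[0] == pytest.approx(base, abs=1e-12)


def test_spearman_missing_pairs_dropped_and_counted():
    x = np.array([1, 2, 3, 4, np.nan, 6.0])
    y = np.array([2, 1, 4, np.nan, 5, 8.0])
    rs, p, n, miss = spearman(x, y)
    assert n == 4 and miss == 2
    with pytest.raises(ValueError, match="at least 3"):
        spearman([1, 2, np.nan], [1, np.nan, 3])


# --------------------------------------------------------- association report

def _report_for(cfg_kwargs, use_true_stage=True, seed=31):
    cfg = ts.CohortConfig(seed=seed, **cfg_kwargs)
    table, gt = ts.generate_cohort(cfg)
    pat = table[table["group"] == "TLE"].reset_index(drop=True)
    stages = pd.DataFrame({"subject_id": pat["subject_id"],
                           "ml_stage": gt.true_stage})
    return build_association_report(stages, pat), pat


def test_report_null_coupling_stays_in_null_band():
    cp = ts.ClinicalCoupling(duration_slope=0.0, asm_slope=0.0)
    report, _ = _report_for({"coupling": cp, "hs_stage_slope": 0.0})
    corr = report.correlations.set_index("variable")
    # 95% null band for rank correlation at n = 155 is about +/-0.16
    assert abs(corr.loc["duration_years", "rs"]) < 0.16
    assert abs(corr.loc["n_asms", "rs"]) < 0.16


def test_report_recovers_planted_duration_coupling():
    report, _ = _report_for({})
    corr = report.correlations.set_index("variable")
    rs = corr.loc["duration_years", "rs"]
    assert 0.23 <= rs <= 0.43
    assert corr.loc["duration_years", "p"] < 0.05
    assert corr.loc["n_asms", "n_missing"] > 0


def test_report_hs_group_shows_later_stages():
    report, _ = _report_for({})
    grp = report.group_comparisons.set_index("variable")
    assert grp.loc["etiology", "p"] < 0.05
    med_hs = float(grp.loc["etiology", "median_iqr1"].split(" ")[0])
    med_nl = float(grp.loc["etiology", "median_iqr2"].split(" ")[0])
    assert med_hs > med_nl


def test_report_requires_overlapping_ids():
    stages = pd.DataFrame({"subject_id": ["nope"], "ml_stage": [3]})
    _, pat = _report_for({"n_patients": 10, "n_hc": 0}, seed=2)
    with pytest.raises(ValueError, match="overlap"):
        build_association_report(stages, pat)


def test_report_text_and_csv_render(tmp_path):
    report, _ = _report_for({"n_patients": 60, "n_hc": 0}, seed=3)
    text = report.to_text()
    assert "Correlation" in text and "duration_years" in text
    report.save(tmp_path / "r.csv", tmp_path / "r.txt")
    back = pd.read_csv(tmp_path / "r.csv")
    assert {"group_comparison", "correlation"} == set(back["block"])
    assert back["p"].between(0, 1).all()
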