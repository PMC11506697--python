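"""Normative covariate model, abnormality z-scores, and lateralization."""

import numpy as np
import pandas as pd
import pytest

import tractstage as ts
from tractstage.preprocess import (CovariateNormalizer, delateralize,
                                   lateralize, validate_cohort)
from tractstage.tracts import TRACT_LABELS


def hc_frame(n=200, seed=0, noise=0.02, age_coef=-0.0008, sex_coef=0.01,
             intercept=0.52):
    rng = np.random.default_rng(seed)
    age = rng.uniform(18, 70, n)
    sex = rng.integers(0, 2, n)
    df = pd.DataFrame({
        "subject_id": [f"HC{i}" for i in range(n)],
        "group": "HC", "age": age, "sex": np.where(sex == 1, "F", "M"),
        "focus_side": "none", "etiology": "none",
    })
    for t in TRACT_LABELS:
        df[t] = (intercept + age_coef * age + sex_coef * sex
                 + rng.normal(0, noise, n))
    return df


def test_ols_matches_normal_equations_oracle():
    df = hc_frame(n=200, seed=1)
    norm = CovariateNormalizer().fit(df)
    D = np.column_stack([np.ones(len(df)), df["age"],
                         (df["sex"] == "F").astype(float)])
    for i, t in enumerate(TRACT_LABELS):
        beta = np.linalg.solve(D.T @ D, D.T @ df[t].to_numpy())
        np.testing.assert_allclose(norm.coef_[:, i], beta, atol=1e-8)
        resid = df[t].to_numpy() - D @ beta
        sd = np.sqrt(np.sum(resid**2) / (len(df) - 3))
        assert norm.residual_sd_[i] == pytest.approx(sd, abs=1e-10)


def test_noiseless_linear_model_recovered_to_machine_precision():
    df = hc_frame(n=60, seed=2, noise=0.0)
    # zero residual SD is degenerate: fitting works, transform refuses
    norm = CovariateNormalizer().fit(df)
    np.testing.assert_allclose(norm.coef_[0], 0.52, atol=1e-10)
    np.testing.assert_allclose(norm.coef_[1], -0.0008, atol=1e-12)
    np.testing.assert_allclose(norm.coef_[2], 0.01, atol=1e-10)
    with pytest.raises(ValueError, match="degenerate tracts"):
        norm.transform(df)


def test_single_sex_design_is_degenerate():
    df = hc_frame(n=50, seed=3)
    df["sex"] = "F"
    with pytest.raises(ValueError, match="degenerate design"):
        CovariateNormalizer().fit(df)


def test_z_definition_and_sign_convention():
    df = hc_frame(n=120, seed=4)
    norm = CovariateNormalizer().fit(df)
    # a patient whose FA equals the model prediction everywhere -> z = 0;
    # one residual SD *below* prediction in left UF -> abnormality +1 there
    age, sexf = 40.0, 0.0
    pred = norm.coef_[0] + norm.coef_[1] * age + norm.coef_[2] * sexf
    pat = pd.DataFrame({"subject_id": ["P1", "P2"], "group": "TLE",
                        "age": age, "sex": "M", "focus_side": "left",
                        "etiology": "NL"})
    for i, t in enumerate(TRACT_LABELS):
        pat[t] = [pred[i], pred[i]]
    iuf = list(TRACT_LABELS).index("UF_L")
    pat.loc[1, "UF_L"] = pred[iuf] - norm.residual_sd_[iuf]
    z = norm.transform(pat)
    np.testing.assert_allclose(z.loc["P1"].to_numpy(), 0.0, atol=1e-10)
    assert z.loc["P2", "UF_L"] == pytest.approx(1.0, abs=1e-10)
    assert z.loc["P2"].drop("UF_L").abs().max() < 1e-10


def test_transform_matches_from_scratch_recomputation():
    df = hc_frame(n=150, seed=5)
    rng = np.random.default_rng(6)
    pat = hc_frame(n=30, seed=7)
    pat["group"] = "TLE"
    pat["focus_side"] = rng.choice(["left", "right"], 30)
    pat["subject_id"] = [f"P{i}" for i in range(30)]
    norm = CovariateNormalizer().fit(df)
    z = norm.transform(pat)
    # independent re-derivation from scratch
    D = np.column_stack([np.ones(len(df)), df["age"],
                         (df["sex"] == "F").astype(float)])
    Dp = np.column_stack([np.ones(len(pat)), pat["age"],
                          (pat["sex"] == "F").astype(float)])
    for i, t in enumerate(TRACT_LABELS):
        beta = np.linalg.solve(D.T @ D, D.T @ df[t].to_numpy())
        r = df[t].to_numpy() - D @ beta
        s = np.sqrt(r @ r / (len(df) - 3))
        expect = -(pat[t].to_numpy() - Dp @ beta) / s
        np.testing.assert_allclose(z[t].to_numpy(), expect, atol=1e-8)


def test_hc_in_sample_mean_zero_and_unit_scale():
    df = hc_frame(n=200, seed=8)
    norm = CovariateNormalizer(flip_sign=False).fit(df)
    z = norm.transform(df).to_numpy()
    np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-9)
    # with the n-3 denominator, sum z^2 / (n-3) is exactly 1 in-sample
    np.testing.assert_allclose((z**2).sum(axis=0) / (len(df) - 3), 1.0,
                               atol=1e-9)


def test_fa_out_of_range_or_missing_is_hard_reject():
    df = hc_frame(n=20, seed=9)
    df.loc[3, "ATR_L"] = 1.2
    with pytest.raises(ValueError, match="outside"):
        validate_cohort(df)
    df = hc_frame(n=20, seed=9)
    df.loc[5, "CST_R"] = np.nan
    with pytest.raises(ValueError, match="missing"):
        validate_cohort(df)


def test_requires_at_least_ten_controls():
    with pytest.raises(ValueError, match="at least 10"):
        CovariateNormalizer().fit(hc_frame(n=8))


def test_covariate_model_json_roundtrip(tmp_path):
    norm = CovariateNormalizer().fit(hc_frame(n=80, seed=10))
    norm.save(tmp_path / "cov.json")
    back = CovariateNormalizer.load(tmp_path / "cov.json")
    np.testing.assert_allclose(back.coef_, norm.coef_)
    np.testing.assert_allclose(back.residual_sd_, norm.residual_sd_)


# ----------------------------------------------------------- lateralization

def _z_frame(rows):
    return pd.DataFrame(rows, columns=list(TRACT_LABELS))


def test_lateralize_reclassification_rule():
    rng = np.random.default_rng(11)
    z = _z_frame(rng.normal(size=(2, 20)))
    z.index = pd.Index(["L1", "R1"], name="subject_id")
    z.loc["R1", "UF_R"] = 2.0
    z.loc["R1", "UF_L"] = 0.5
    rec = pd.DataFrame({"subject_id": ["L1", "R1"],
                        "focus_side": ["left", "right"]})
    out = lateralize(z, rec)
    # right-focus: right tract -> ipsilateral
    assert out.loc["R1", "UF_ipsi"] == 2.0
    assert out.loc["R1", "UF_contra"] == 0.5
    # left-focus: left tract -> ipsilateral
    assert out.loc["L1", "ATR_ipsi"] == z.loc["L1", "ATR_L"]
    assert out.loc["L1", "ATR_contra"] == z.loc["L1", "ATR_R"]
    # midline structures pass through unchanged
    assert out.loc["R1", "Forceps_major"] == z.loc["R1", "Forceps_major"]


def test_lateralize_symmetric_patient_is_side_invariant():
    vals = {t: 0.3 for t in TRACT_LABELS}
    z = pd.DataFrame([vals, vals], index=pd.Index(["a", "b"],
                                                  name="subject_id"))
    rec = pd.DataFrame({"subject_id": ["a", "b"],
                        "focus_side": ["left", "right"]})
    out = lateralize(z, rec)
    for t in ts.PAIRED_TRACTS:
        np.testing.assert_allclose(out[f"{t}_ipsi"], out[f"{t}_contra"])


def test_lateralize_roundtrip_and_multiset_preservation():
    rng = np.random.default_rng(12)
    z = _z_frame(rng.normal(size=(40, 20)))
    z.index = pd.Index([f"P{i}" for i in range(40)], name="subject_id")
    rec = pd.DataFrame({"subject_id": z.index,
                        "focus_side": rng.choice(["left", "right"], 40)})
    out = lateralize(z, rec)
    # pure per-row relabelling: value multisets preserved
    np.testing.assert_allclose(np.sort(out.to_numpy(), axis=1),
                               np.sort(z.to_numpy(), axis=1))
    back = delateralize(out, rec)
    np.testing.assert_allclose(back.to_numpy(), z[back.columns].to_numpy())


def test_lateralize_requires_focus_side():
    z = _z_frame(np.zeros((1, 20)))
    z.index = pd.Index(["x"], name="subject_id")
    rec = pd.DataFrame({"subject_id": ["x"], "focus_side": ["none"]})
    with pytest.raises(ValueError, match="focus_side"):
        lateralize(z, rec)
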