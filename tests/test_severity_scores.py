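"""Scoring-engine tests: point-table cells, closed forms, monotonicity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sevscore import (
    age_band, prism3_breakdown, prism3_logit, prism3_probability,
    Pim3Covariates, pim3_linear_predictor, pim3_probability,
    pim3_covariates_from_record, classify_risk_diagnosis, RiskDiagnosisMap,
    score_cohort, MissingVariableError,
)
from sevscore.severity_scores import (
    prism3_components_frame, PIM3_COEFFS, PIM3_INTERCEPT,
)

from conftest import normal_record

AGE_BY_BAND = {"neonate": 0.5, "infant": 6.0, "child": 60.0,
               "adolescent": 180.0}
# zero-point values that are age-band safe for every band
BAND_SAFE = {"sbp": 120.0, "heart_rate": 120.0, "creatinine": 0.4,
             "urea": 10.0, "pt": 12.0, "ptt": 30.0}


# ---------------------------------------------------------------------------
# age bands
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("age,band", [
    (0.0, "neonate"), (0.5, "neonate"), (0.999, "neonate"),
    (1.0, "infant"), (6.0, "infant"), (12.0, "infant"),
    (12.001, "child"), (60.0, "child"), (144.0, "child"),
    (144.001, "adolescent"), (150.0, "adolescent"), (216.0, "adolescent"),
])
def test_age_band_boundaries(age, band):
    assert age_band(age) == band


def test_negative_age_rejected():
    with pytest.raises(ValueError):
        age_band(-0.1)


# ---------------------------------------------------------------------------
# point table: one row per printed cell, boundary-straddling values
# (closed range rows win on shared boundaries)
# ---------------------------------------------------------------------------

POINT_TABLE = [
    # (band, component, overrides, expected points)
    ("neonate", "sbp", {"sbp": 56.0}, 0),
    ("neonate", "sbp", {"sbp": 55.0}, 3),
    ("neonate", "sbp", {"sbp": 40.0}, 3),
    ("neonate", "sbp", {"sbp": 39.9}, 7),
    ("neonate", "sbp", {"sbp": 35.0}, 7),
    ("infant", "sbp", {"sbp": 66.0}, 0),
    ("infant", "sbp", {"sbp": 65.0}, 3),
    ("infant", "sbp", {"sbp": 45.0}, 3),
    ("infant", "sbp", {"sbp": 44.9}, 7),
    ("child", "sbp", {"sbp": 76.0}, 0),
    ("child", "sbp", {"sbp": 75.0}, 3),
    ("child", "sbp", {"sbp": 55.0}, 3),
    ("child", "sbp", {"sbp": 54.9}, 7),
    ("adolescent", "sbp", {"sbp": 86.0}, 0),
    ("adolescent", "sbp", {"sbp": 85.0}, 3),
    ("adolescent", "sbp", {"sbp": 65.0}, 3),
    ("adolescent", "sbp", {"sbp": 64.9}, 7),
    ("neonate", "heart_rate", {"heart_rate": 214.0}, 0),
    ("neonate", "heart_rate", {"heart_rate": 215.0}, 3),
    ("neonate", "heart_rate", {"heart_rate": 225.0}, 3),
    ("neonate", "heart_rate", {"heart_rate": 226.0}, 4),
    ("infant", "heart_rate", {"heart_rate": 215.0}, 3),
    ("child", "heart_rate", {"heart_rate": 184.0}, 0),
    ("child", "heart_rate", {"heart_rate": 185.0}, 3),
    ("child", "heart_rate", {"heart_rate": 205.0}, 3),
    ("child", "heart_rate", {"heart_rate": 206.0}, 4),
    ("adolescent", "heart_rate", {"heart_rate": 144.0}, 0),
    ("adolescent", "heart_rate", {"heart_rate": 145.0}, 3),
    ("adolescent", "heart_rate", {"heart_rate": 155.0}, 3),
    ("adolescent", "heart_rate", {"heart_rate": 156.0}, 4),
    ("infant", "temperature", {"temperature": 32.9}, 3),
    ("infant", "temperature", {"temperature": 33.0}, 0),
    ("infant", "temperature", {"temperature": 40.0}, 0),
    ("infant", "temperature", {"temperature": 40.1}, 3),
    ("infant", "mental_status", {"gcs": 8}, 0),
    ("infant", "mental_status", {"gcs": 7}, 5),
    ("infant", "mental_status", {"gcs": 3}, 5),
    ("infant", "pupils", {"pupils": "both_reactive"}, 0),
    ("infant", "pupils", {"pupils": "one_fixed"}, 7),
    ("infant", "pupils", {"pupils": "both_fixed"}, 11),
    ("infant", "acidosis", {"ph": 6.99}, 6),
    ("infant", "acidosis", {"ph": 6.95}, 6),
    ("infant", "acidosis", {"tco2": 4.9}, 6),
    ("infant", "acidosis", {"ph": 7.0}, 2),
    ("infant", "acidosis", {"ph": 7.28}, 2),
    ("infant", "acidosis", {"tco2": 5.0}, 2),
    ("infant", "acidosis", {"tco2": 16.9}, 2),
    ("infant", "acidosis", {"ph": 7.29, "tco2": 17.0}, 0),
    ("infant", "pco2", {"pco2": 49.9}, 0),
    ("infant", "pco2", {"pco2": 50.0}, 1),
    ("infant", "pco2", {"pco2": 75.0}, 1),
    ("infant", "pco2", {"pco2": 75.1}, 3),
    ("infant", "ph_alkalosis", {"ph": 7.47}, 0),
    ("infant", "ph_alkalosis", {"ph": 7.48}, 2),
    ("infant", "ph_alkalosis", {"ph": 7.55}, 2),
    ("infant", "ph_alkalosis", {"ph": 7.56}, 3),
    ("infant", "tco2_high", {"tco2": 34.0}, 0),
    ("infant", "tco2_high", {"tco2": 34.1}, 4),
    ("infant", "pao2", {"pao2": 50.0}, 0),
    ("infant", "pao2", {"pao2": 49.9}, 3),
    ("infant", "pao2", {"pao2": 42.0}, 3),
    ("infant", "pao2", {"pao2": 41.9}, 6),
    ("neonate", "creatinine", {"creatinine": 0.85}, 0),
    ("neonate", "creatinine", {"creatinine": 0.86}, 2),
    ("infant", "creatinine", {"creatinine": 0.90}, 0),
    ("infant", "creatinine", {"creatinine": 0.91}, 2),
    ("child", "creatinine", {"creatinine": 0.91}, 2),
    ("adolescent", "creatinine", {"creatinine": 1.30}, 0),
    ("adolescent", "creatinine", {"creatinine": 1.31}, 2),
    ("infant", "potassium", {"potassium": 6.9}, 0),
    ("infant", "potassium", {"potassium": 7.0}, 3),
    ("infant", "glucose", {"glucose": 200.0}, 0),
    ("infant", "glucose", {"glucose": 200.1}, 2),
    ("neonate", "bun", {"urea": 11.9}, 0),
    ("neonate", "bun", {"urea": 12.0}, 3),
    ("infant", "bun", {"urea": 14.9}, 0),
    ("infant", "bun", {"urea": 15.0}, 3),
    ("neonate", "coagulation", {"pt": 22.0, "ptt": 85.0}, 0),
    ("neonate", "coagulation", {"pt": 22.1}, 3),
    ("neonate", "coagulation", {"ptt": 85.1}, 3),
    ("infant", "coagulation", {"pt": 22.0, "ptt": 57.0}, 0),
    ("infant", "coagulation", {"ptt": 57.1}, 3),
    ("infant", "coagulation", {"pt": 22.1}, 3),
    ("infant", "platelets", {"platelets": 201.0}, 0),
    ("infant", "platelets", {"platelets": 200.0}, 2),
    ("infant", "platelets", {"platelets": 100.0}, 2),
    ("infant", "platelets", {"platelets": 99.9}, 4),
    ("infant", "platelets", {"platelets": 50.0}, 4),
    ("infant", "platelets", {"platelets": 49.9}, 5),
    ("infant", "wbc", {"wbc": 3.0}, 0),
    ("infant", "wbc", {"wbc": 2.9}, 4),
]


@pytest.mark.parametrize("band,component,overrides,expected", POINT_TABLE)
def test_point_table_cell(band, component, overrides, expected):
    rec = normal_record(age_months=AGE_BY_BAND[band], **BAND_SAFE)
    rec.update(overrides)
    bd = prism3_breakdown(rec)
    assert getattr(bd, component) == expected


def test_all_normal_record_scores_zero(record_factory):
    bd = prism3_breakdown(record_factory())
    assert bd.total == 0
    assert all(v == 0 for v in bd.components().values())


def test_gcs6_fixed_pupils_total_16(record_factory):
    bd = prism3_breakdown(record_factory(gcs=6, pupils="both_fixed"))
    assert bd.mental_status == 5
    assert bd.pupils == 11
    assert bd.total == 16


def test_total_is_component_sum(default_cohort):
    frame = prism3_components_frame(default_cohort.df)
    comp = frame.drop(columns="total")
    assert (comp.sum(axis=1) == frame["total"]).all()
    assert (comp >= 0).all().all()


def test_scalar_and_vector_paths_agree(default_cohort):
    df = default_cohort.df.head(40)
    frame = prism3_components_frame(df)
    for i in range(len(df)):
        bd = prism3_breakdown(df.iloc[i].to_dict())
        assert bd.total == frame["total"].iloc[i]


def test_missing_variable_raises_without_policy(record_factory):
    rec = record_factory()
    rec["potassium"] = None
    with pytest.raises(MissingVariableError):
        prism3_breakdown(rec)
    # missing-as-normal mode scores the absent variable as zero points
    bd = prism3_breakdown(rec, missing_as_normal=True)
    assert bd.potassium == 0


@settings(max_examples=60, deadline=None)
@given(age=st.floats(0, 216), sbp_hi=st.floats(20, 200),
       drop=st.floats(0, 100))
def test_lowering_sbp_never_decreases_points(age, sbp_hi, drop):
    rec_hi = normal_record(age_months=age, **BAND_SAFE)
    rec_hi["sbp"] = sbp_hi
    rec_lo = dict(rec_hi, sbp=sbp_hi - drop)
    assert prism3_breakdown(rec_lo).sbp >= prism3_breakdown(rec_hi).sbp


@settings(max_examples=40, deadline=None)
@given(gcs_hi=st.integers(3, 15), d=st.integers(0, 12))
def test_lowering_gcs_never_decreases_points(gcs_hi, d):
    lo = max(gcs_hi - d, 3)
    rec_hi = normal_record(gcs=gcs_hi)
    rec_lo = normal_record(gcs=lo)
    assert prism3_breakdown(rec_lo).mental_status >= \
        prism3_breakdown(rec_hi).mental_status


def test_worsening_pupils_strictly_increases():
    pts = [prism3_breakdown(normal_record(pupils=p)).pupils
           for p in ("both_reactive", "one_fixed", "both_fixed")]
    assert pts == [0, 7, 11]


# ---------------------------------------------------------------------------
# closed-form probabilities
# ---------------------------------------------------------------------------

def test_prism3_logit_worked_values():
    assert prism3_logit(0, 0, False) == pytest.approx(-4.782, abs=1e-12)
    assert prism3_logit(10, 0, False) == pytest.approx(-2.712, abs=1e-12)
    assert prism3_logit(0, 100, True) == pytest.approx(-5.715, abs=1e-12)


def test_prism3_logit_monotone_in_score():
    scores = np.arange(0, 40)
    logits = prism3_logit(scores, 6.0, False)
    assert np.all(np.diff(logits) > 0)
    probs = prism3_probability(scores, 6.0, False)
    assert np.all(np.diff(probs) > 0)
    assert np.all((probs > 0) & (probs < 1))


def test_pim3_lp_intercept_only():
    assert pim3_linear_predictor(Pim3Covariates()) == \
        pytest.approx(-1.7928, abs=1e-12)


def test_pim3_lp_single_covariates():
    assert pim3_linear_predictor(Pim3Covariates(pupils_fixed=1)) == \
        pytest.approx(2.0305, abs=1e-12)
    assert pim3_linear_predictor(Pim3Covariates(sbp=100.0)) == \
        pytest.approx(-4.3868, abs=1e-10)


def test_pim3_lp_matches_term_by_term_oracle(rng):
    # independent summation oracle over 1000 random covariate vectors
    for _ in range(1000):
        cov = Pim3Covariates(
            pupils_fixed=int(rng.random() < 0.5),
            elective=int(rng.random() < 0.5),
            ventilated=int(rng.random() < 0.5),
            abs_base_excess=float(rng.uniform(0, 30)),
            sbp=float(rng.uniform(0, 200)),
            fio2_over_pao2_term=float(rng.uniform(0, 3)),
            bypass=1 if rng.random() < 0.3 else 0,
            very_high_risk=1 if rng.random() < 0.3 else 0,
        )
        expected = (3.8233 * cov.pupils_fixed
                    - 0.5378 * cov.elective
                    + 0.9763 * cov.ventilated
                    + 0.0671 * cov.abs_base_excess
                    - 0.0431 * cov.sbp
                    + 0.1716 * cov.sbp * cov.sbp / 1000.0
                    + 0.4214 * cov.fio2_over_pao2_term
                    - 1.2246 * cov.bypass
                    + 1.6225 * cov.very_high_risk
                    - 1.7928)
        assert pim3_linear_predictor(cov) == pytest.approx(expected,
                                                           abs=1e-12)


def test_pim3_probability_identities():
    assert pim3_probability(0.0) == pytest.approx(0.5, abs=1e-15)
    expected = np.exp(-1.7928) / (1 + np.exp(-1.7928))
    assert pim3_probability(-1.7928) == pytest.approx(expected, abs=1e-15)
    assert pim3_probability(-1.7928) == pytest.approx(0.1427, abs=5e-4)
    for lp in (-3.0, -0.7, 1.2):
        assert pim3_probability(lp) + pim3_probability(-lp) == \
            pytest.approx(1.0, abs=1e-12)
    lps = np.linspace(-6, 6, 50)
    assert np.all(np.diff(pim3_probability(lps)) > 0)


def test_pim3_covariate_mapping(record_factory):
    rec = record_factory(pupils="both_fixed", admission_type="elective",
                         mechanical_ventilation=True, base_excess=-5.0,
                         fio2=0.40, pao2=80.0, procedure="bypass_cardiac",
                         risk_diagnosis="very_high")
    cov = pim3_covariates_from_record(rec)
    assert cov.pupils_fixed == 1 and cov.elective == 1 and cov.ventilated == 1
    assert cov.abs_base_excess == pytest.approx(5.0)
    assert cov.fio2_over_pao2_term == pytest.approx(0.40 * 100 / 80.0)
    assert cov.bypass == 1 and cov.very_high_risk == 1
    # one fixed pupil is not "fixed pupils" in the PIM-3 sense
    assert pim3_covariates_from_record(
        record_factory(pupils="one_fixed")).pupils_fixed == 0


def test_mutually_exclusive_flags_rejected():
    with pytest.raises(ValueError):
        Pim3Covariates(bypass=1, noncardiac_proc=1)
    with pytest.raises(ValueError):
        Pim3Covariates(low_risk=1, high_risk=1)


# ---------------------------------------------------------------------------
# risk diagnosis classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("label,expected", [
    ("asthma", "low"), ("Asthma", "low"), ("bronchiolitis", "low"),
    ("cardiac arrest", "very_high"), ("Leukemia or Lymphoma", "very_high"),
    ("necrotizing enterocolitis", "high"), ("appendicitis", "none"),
])
def test_classify_risk_diagnosis(label, expected):
    assert classify_risk_diagnosis(label) == expected


def test_risk_map_disjointness_enforced():
    with pytest.raises(ValueError):
        RiskDiagnosisMap(low={"asthma"}, high={"asthma"}, very_high=set())


# ---------------------------------------------------------------------------
# batch scoring
# ---------------------------------------------------------------------------

def test_score_cohort_columns_and_breakdown(default_cohort):
    out = score_cohort(default_cohort, breakdown=True)
    assert {"prism3_total", "prism3_prob", "pim3_lp", "pim3_prob"} <= \
        set(out.columns)
    assert "prism3_pupils" in out.columns
    assert np.all((out["prism3_prob"] > 0) & (out["prism3_prob"] < 1))
    assert np.all((out["pim3_prob"] > 0) & (out["pim3_prob"] < 1))
    # probability columns are the logistic of their linear predictors
    np.testing.assert_allclose(
        out["pim3_prob"], 1 / (1 + np.exp(-out["pim3_lp"])), rtol=1e-12)
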