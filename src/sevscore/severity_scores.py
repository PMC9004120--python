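"""PRISM-3 and PIM-3 severity-of-illness scoring engines.

PRISM-3 (Pediatric Risk of Mortality, 3rd version) is an additive point
score over 17 physiological/laboratory variables with age-band-specific
thresholds, converted to a death probability through a published logit.
PIM-3 (Pediatric Index of Mortality, 3rd version) is a 13-term logistic
linear predictor over admission covariates.

Both engines are deterministic table/formula lookups.  The point table is
encoded once, in vectorized form; the scalar record API wraps the
vectorized kernels so there is a single source of truth.

Boundary semantics
------------------
Printed inequalities are followed verbatim.  Where a value falls on a
boundary shared by a closed range row and an open row (e.g. neonatal SBP
exactly 40 or 55), the closed range row wins: SBP 55 for a neonate scores
3 points ("40-55 mmHg -> 3"), not 0.  Age-band edges: 1 month and
12 months are infant, 144 months is child.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .cohort_io import Cohort, PatientRecord

__all__ = [
    "AGE_BANDS", "age_band", "age_band_vector",
    "Prism3Breakdown", "prism3_breakdown", "prism3_components_frame",
    "prism3_logit", "prism3_probability",
    "Pim3Covariates", "pim3_covariates_from_record",
    "pim3_linear_predictor", "pim3_probability",
    "RiskDiagnosisMap", "DEFAULT_RISK_MAP", "classify_risk_diagnosis",
    "score_cohort", "MissingVariableError",
]

AGE_BANDS = ("neonate", "infant", "child", "adolescent")

# variables required by the PRISM-3 point table
PRISM3_VARIABLES = (
    "sbp", "heart_rate", "temperature", "gcs", "pupils",
    "ph", "tco2", "pco2", "pao2",
    "creatinine", "potassium", "glucose", "urea",
    "pt", "ptt", "platelets", "wbc",
)

PIM3_VARIABLES = (
    "pupils", "admission_type", "mechanical_ventilation", "base_excess",
    "sbp", "fio2", "pao2", "procedure", "risk_diagnosis",
)


class MissingVariableError(ValueError):
    """A scoring input is missing and missing-as-normal is disabled."""


# --------------------------------------------------------------------------
# Age bands
# --------------------------------------------------------------------------

def age_band_vector(age_months: np.ndarray) -> np.ndarray:
    """Band index 0=neonate, 1=infant, 2=child, 3=adolescent.

    Neonate [0, 1) month, infant [1, 12], child (12, 144],
    adolescent > 144 months.
    """
    age = np.asarray(age_months, dtype=float)
    if np.any(age < 0):
        raise ValueError("age_months must be non-negative")
    band = np.full(age.shape, 3, dtype=np.int64)
    band[age <= 144] = 2
    band[age <= 12] = 1
    band[age < 1] = 0
    return band


def age_band(age_months: float) -> str:
    """Age band name for a single age in months."""
    return AGE_BANDS[int(age_band_vector(np.array([age_months]))[0])]


# --------------------------------------------------------------------------
# PRISM-3 point table (vectorized kernels)
# --------------------------------------------------------------------------
# Thresholds indexed by band: neonate, infant, child, adolescent.

_SBP_LOW = np.array([40.0, 45.0, 55.0, 65.0])    # < low -> 7
_SBP_MID = np.array([55.0, 65.0, 75.0, 85.0])    # [low, mid] -> 3, > mid -> 0
_HR_MID_LO = np.array([215.0, 215.0, 185.0, 145.0])  # [lo, hi] -> 3
_HR_MID_HI = np.array([225.0, 225.0, 205.0, 155.0])  # > hi -> 4
_CREAT_MAX = np.array([0.85, 0.90, 0.90, 1.30])  # > max -> 2
_BUN_MAX = np.array([11.9, 14.9, 14.9, 14.9])    # > max -> 3
_PTT_MAX = np.array([85.0, 57.0, 57.0, 57.0])    # PT > 22 or PTT > max -> 3

_PUPIL_POINTS = {"both_reactive": 0, "one_fixed": 7, "both_fixed": 11}


def _pts_sbp(band, sbp):
    return np.where(sbp < _SBP_LOW[band], 7,
                    np.where(sbp <= _SBP_MID[band], 3, 0))


def _pts_heart_rate(band, hr):
    return np.where(hr > _HR_MID_HI[band], 4,
                    np.where(hr >= _HR_MID_LO[band], 3, 0))


def _pts_temperature(band, temp):
    return np.where((temp < 33.0) | (temp > 40.0), 3, 0)


def _pts_mental_status(band, gcs):
    return np.where(gcs < 8, 5, 0)


def _pts_pupils(band, pupil_code):
    # pupil_code: 0 both reactive, 1 one fixed (>3 mm), 2 both fixed (>3 mm)
    return np.choose(pupil_code, [0, 7, 11])


def _pts_acidosis(band, ph, tco2):
    severe = (ph < 7.0) | (tco2 < 5.0)
    moderate = ((ph >= 7.0) & (ph <= 7.28)) | ((tco2 >= 5.0) & (tco2 <= 16.9))
    return np.where(severe, 6, np.where(moderate, 2, 0))


def _pts_pco2(band, pco2):
    return np.where(pco2 > 75.0, 3, np.where(pco2 >= 50.0, 1, 0))


def _pts_ph_alkalosis(band, ph):
    return np.where(ph > 7.55, 3, np.where(ph >= 7.48, 2, 0))


def _pts_tco2_high(band, tco2):
    return np.where(tco2 > 34.0, 4, 0)


def _pts_pao2(band, pao2):
    return np.where(pao2 < 42.0, 6, np.where(pao2 < 50.0, 3, 0))


def _pts_creatinine(band, creat):
    return np.where(creat > _CREAT_MAX[band], 2, 0)


def _pts_potassium(band, k):
    return np.where(k > 6.9, 3, 0)


def _pts_glucose(band, glucose):
    return np.where(glucose > 200.0, 2, 0)


def _pts_bun(band, urea):
    return np.where(urea > _BUN_MAX[band], 3, 0)


def _pts_coagulation(band, pt, ptt):
    return np.where((pt > 22.0) | (ptt > _PTT_MAX[band]), 3, 0)


def _pts_platelets(band, plate):
    # platelets in 10^3 cells/mm^3
    return np.where(plate < 50.0, 5,
                    np.where(plate < 100.0, 4,
                             np.where(plate <= 200.0, 2, 0)))


def _pts_wbc(band, wbc):
    # wbc in 10^3 cells/mm^3
    return np.where(wbc < 3.0, 4, 0)


_COMPONENT_KERNELS = {
    "sbp": (_pts_sbp, ("sbp",)),
    "heart_rate": (_pts_heart_rate, ("heart_rate",)),
    "temperature": (_pts_temperature, ("temperature",)),
    "mental_status": (_pts_mental_status, ("gcs",)),
    "pupils": (_pts_pupils, ("pupils",)),
    "acidosis": (_pts_acidosis, ("ph", "tco2")),
    "pco2": (_pts_pco2, ("pco2",)),
    "ph_alkalosis": (_pts_ph_alkalosis, ("ph",)),
    "tco2_high": (_pts_tco2_high, ("tco2",)),
    "pao2": (_pts_pao2, ("pao2",)),
    "creatinine": (_pts_creatinine, ("creatinine",)),
    "potassium": (_pts_potassium, ("potassium",)),
    "glucose": (_pts_glucose, ("glucose",)),
    "bun": (_pts_bun, ("urea",)),
    "coagulation": (_pts_coagulation, ("pt", "ptt")),
    "platelets": (_pts_platelets, ("platelets",)),
    "wbc": (_pts_wbc, ("wbc",)),
}

PRISM3_COMPONENTS = tuple(_COMPONENT_KERNELS)


@dataclass
class Prism3Breakdown:
    """Per-component PRISM-3 points and their total."""

    sbp: int
    heart_rate: int
    temperature: int
    mental_status: int
    pupils: int
    acidosis: int
    pco2: int
    ph_alkalosis: int
    tco2_high: int
    pao2: int
    creatinine: int
    potassium: int
    glucose: int
    bun: int
    coagulation: int
    platelets: int
    wbc: int
    total: int

    def components(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)
                if f.name != "total"}


def _prism3_inputs_from_frame(df: pd.DataFrame, missing_as_normal: bool):
    """Extract and check the numeric input arrays for the point table."""
    n = len(df)
    missing_report: dict[str, np.ndarray] = {}
    arrays: dict[str, np.ndarray] = {}

    for var in PRISM3_VARIABLES:
        if var == "pupils":
            codes = df["pupils"] if "pupils" in df else pd.Series([None] * n)
            miss = codes.isna().to_numpy()
            code_idx = np.zeros(n, dtype=np.int64)
            known = ~miss
            mapped = codes[known].map(
                {"both_reactive": 0, "one_fixed": 1, "both_fixed": 2})
            if mapped.isna().any():
                raise ValueError("unparseable pupils code in cohort")
            code_idx[known] = mapped.to_numpy(dtype=np.int64)
            arrays["pupils"] = code_idx
            missing_report["pupils"] = miss
        else:
            col = pd.to_numeric(df[var], errors="coerce") if var in df \
                else pd.Series(np.nan, index=df.index)
            vals = col.to_numpy(dtype=float)
            missing_report[var] = np.isnan(vals)
            arrays[var] = vals

    any_missing = {v: m for v, m in missing_report.items() if m.any()}
    if any_missing and not missing_as_normal:
        names = ", ".join(sorted(any_missing))
        raise MissingVariableError(
            f"records have missing scoring variables ({names}); impute "
            "first or enable missing_as_normal")
    return arrays, missing_report


def prism3_components_frame(df: pd.DataFrame,
                            missing_as_normal: bool = False) -> pd.DataFrame:
    """Vectorized PRISM-3 per-component points for a cohort table.

    Returns a DataFrame with one integer column per component plus
    ``total``.  With ``missing_as_normal`` a missing input contributes 0
    points to every component it feeds (the common PRISM convention);
    otherwise missing inputs raise :class:`MissingVariableError`.
    """
    band = age_band_vector(pd.to_numeric(df["age_months"]).to_numpy(float))
    arrays, missing = _prism3_inputs_from_frame(df, missing_as_normal)

    out = {}
    for comp, (kernel, inputs) in _COMPONENT_KERNELS.items():
        args = []
        miss_mask = np.zeros(len(df), dtype=bool)
        for var in inputs:
            vals = arrays[var]
            miss_mask |= missing[var]
            if var != "pupils":
                # neutral placeholders keep the kernels NaN-free; the mask
                # zeroes these rows afterwards
                vals = np.where(missing[var], _NEUTRAL[var], vals)
            args.append(vals)
        pts = kernel(band, *args)
        if comp == "acidosis":
            # with one of (ph, tco2) missing, score on the observed one
            ph = np.where(missing["ph"], np.inf, arrays["ph"])
            tco2 = np.where(missing["tco2"], np.inf, arrays["tco2"])
            pts = _pts_acidosis(band, ph, tco2)
            miss_mask = missing["ph"] & missing["tco2"]
        if comp == "coagulation":
            pt = np.where(missing["pt"], -np.inf, arrays["pt"])
            ptt = np.where(missing["ptt"], -np.inf, arrays["ptt"])
            pts = _pts_coagulation(band, pt, ptt)
            miss_mask = missing["pt"] & missing["ptt"]
        pts = np.where(miss_mask, 0, pts)
        out[comp] = pts.astype(np.int64)

    frame = pd.DataFrame(out, index=df.index)
    frame["total"] = frame.sum(axis=1)
    return frame


# neutral (zero-point) placeholder values used for masked missing inputs
_NEUTRAL = {
    "sbp": 1e6, "heart_rate": 0.0, "temperature": 37.0, "gcs": 15.0,
    "ph": 7.38, "tco2": 22.0, "pco2": 0.0, "pao2": 100.0,
    "creatinine": 0.0, "potassium": 0.0, "glucose": 0.0, "urea": 0.0,
    "pt": 0.0, "ptt": 0.0, "platelets": 1e6, "wbc": 1e6,
}


def prism3_breakdown(record: PatientRecord | Mapping,
                     missing_as_normal: bool = False) -> Prism3Breakdown:
    """PRISM-3 per-component points for a single admission."""
    if isinstance(record, PatientRecord):
        data = {f.name: getattr(record, f.name) for f in dc_fields(record)}
    else:
        data = dict(record)
    df = pd.DataFrame([data])
    frame = prism3_components_frame(df, missing_as_normal=missing_as_normal)
    row = frame.iloc[0]
    return Prism3Breakdown(**{k: int(row[k]) for k in frame.columns})


# --------------------------------------------------------------------------
# Published closed-form probabilities
# --------------------------------------------------------------------------

def prism3_logit(score, age_months, postoperative):
    """Published PRISM-3 mortality logit.

    logit = 0.207*score - 0.005*age_months - 0.433*[postoperative] - 4.782
    (all non-score terms subtractive).
    """
    score = np.asarray(score, dtype=float)
    if np.any(score < 0):
        raise ValueError("PRISM-3 score must be non-negative")
    post = np.asarray(postoperative).astype(float)
    return (0.207 * score - 0.005 * np.asarray(age_months, dtype=float)
            - 0.433 * post - 4.782)


def _logistic(x):
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out if out.ndim else float(out)


def prism3_probability(score, age_months, postoperative):
    """Published PRISM-3 probability of death (logistic of the logit)."""
    return _logistic(prism3_logit(score, age_months, postoperative))


PIM3_COEFFS = {
    "pupils_fixed": 3.8233,
    "elective": -0.5378,
    "ventilated": 0.9763,
    "abs_base_excess": 0.0671,
    "sbp": -0.0431,
    "sbp_sq_over_1000": 0.1716,
    "fio2_over_pao2_term": 0.4214,
    "bypass": -1.2246,
    "nonbypass_cardiac": -0.8762,
    "noncardiac_proc": -1.5164,
    "very_high_risk": 1.6225,
    "high_risk": 1.0725,
    "low_risk": -2.1766,
}
PIM3_INTERCEPT = -1.7928


@dataclass
class Pim3Covariates:
    """The 12 covariates of the PIM-3 linear predictor."""

    pupils_fixed: int = 0
    elective: int = 0
    ventilated: int = 0
    abs_base_excess: float = 0.0
    sbp: float = 0.0
    fio2_over_pao2_term: float = 0.0   # (FiO2 * 100) / PaO2
    bypass: int = 0
    nonbypass_cardiac: int = 0
    noncardiac_proc: int = 0
    very_high_risk: int = 0
    high_risk: int = 0
    low_risk: int = 0

    def __post_init__(self):
        if self.bypass + self.nonbypass_cardiac + self.noncardiac_proc > 1:
            raise ValueError("procedure flags are mutually exclusive")
        if self.very_high_risk + self.high_risk + self.low_risk > 1:
            raise ValueError("risk-diagnosis flags are mutually exclusive")
        if self.abs_base_excess < 0:
            raise ValueError("abs_base_excess must be non-negative")


def pim3_linear_predictor(cov: Pim3Covariates) -> float:
    """PIM-3 linear predictor: 13 published terms plus intercept -1.7928."""
    c = PIM3_COEFFS
    return (
        c["pupils_fixed"] * cov.pupils_fixed
        + c["elective"] * cov.elective
        + c["ventilated"] * cov.ventilated
        + c["abs_base_excess"] * cov.abs_base_excess
        + c["sbp"] * cov.sbp
        + c["sbp_sq_over_1000"] * (cov.sbp ** 2) / 1000.0
        + c["fio2_over_pao2_term"] * cov.fio2_over_pao2_term
        + c["bypass"] * cov.bypass
        + c["nonbypass_cardiac"] * cov.nonbypass_cardiac
        + c["noncardiac_proc"] * cov.noncardiac_proc
        + c["very_high_risk"] * cov.very_high_risk
        + c["high_risk"] * cov.high_risk
        + c["low_risk"] * cov.low_risk
        + PIM3_INTERCEPT
    )


def pim3_probability(lp) -> float:
    """Probability of death: exp(lp) / (1 + exp(lp))."""
    lp = np.asarray(lp, dtype=float)
    if not np.all(np.isfinite(lp)):
        raise ValueError("PIM-3 linear predictor must be finite")
    return _logistic(lp)


def pim3_covariates_from_record(record: PatientRecord | Mapping) -> Pim3Covariates:
    """Map raw admission variables to PIM-3 covariates.

    Fixed pupils means both pupils fixed and dilated; the three procedure
    flags and three risk-diagnosis flags are one-hot encodings of the
    ``procedure`` and ``risk_diagnosis`` categoricals.
    """
    if isinstance(record, PatientRecord):
        get = lambda k: getattr(record, k)  # noqa: E731
    else:
        get = lambda k: record.get(k)  # noqa: E731
    required = [v for v in PIM3_VARIABLES if get(v) is None or
                (isinstance(get(v), float) and np.isnan(get(v)))]
    if required:
        raise MissingVariableError(
            f"missing PIM-3 variables: {', '.join(required)}")
    proc = get("procedure")
    risk = get("risk_diagnosis")
    return Pim3Covariates(
        pupils_fixed=int(get("pupils") == "both_fixed"),
        elective=int(get("admission_type") == "elective"),
        ventilated=int(bool(get("mechanical_ventilation"))),
        abs_base_excess=abs(float(get("base_excess"))),
        sbp=float(get("sbp")),
        fio2_over_pao2_term=float(get("fio2")) * 100.0 / float(get("pao2")),
        bypass=int(proc == "bypass_cardiac"),
        nonbypass_cardiac=int(proc == "nonbypass_cardiac"),
        noncardiac_proc=int(proc == "noncardiac"),
        very_high_risk=int(risk == "very_high"),
        high_risk=int(risk == "high"),
        low_risk=int(risk == "low"),
    )


def _pim3_lp_frame(df: pd.DataFrame) -> np.ndarray:
    """Vectorized PIM-3 linear predictor over a complete cohort table."""
    for var in PIM3_VARIABLES:
        if var not in df.columns or df[var].isna().any():
            raise MissingVariableError(f"missing PIM-3 variable: {var}")
    c = PIM3_COEFFS
    sbp = pd.to_numeric(df["sbp"]).to_numpy(float)
    lp = (
        c["pupils_fixed"] * (df["pupils"] == "both_fixed").to_numpy(float)
        + c["elective"] * (df["admission_type"] == "elective").to_numpy(float)
        + c["ventilated"] * df["mechanical_ventilation"].astype(bool).to_numpy().astype(float)
        + c["abs_base_excess"] * np.abs(pd.to_numeric(df["base_excess"]).to_numpy(float))
        + c["sbp"] * sbp
        + c["sbp_sq_over_1000"] * sbp ** 2 / 1000.0
        + c["fio2_over_pao2_term"] * (pd.to_numeric(df["fio2"]).to_numpy(float) * 100.0
                                      / pd.to_numeric(df["pao2"]).to_numpy(float))
        + c["bypass"] * (df["procedure"] == "bypass_cardiac").to_numpy(float)
        + c["nonbypass_cardiac"] * (df["procedure"] == "nonbypass_cardiac").to_numpy(float)
        + c["noncardiac_proc"] * (df["procedure"] == "noncardiac").to_numpy(float)
        + c["very_high_risk"] * (df["risk_diagnosis"] == "very_high").to_numpy(float)
        + c["high_risk"] * (df["risk_diagnosis"] == "high").to_numpy(float)
        + c["low_risk"] * (df["risk_diagnosis"] == "low").to_numpy(float)
        + PIM3_INTERCEPT
    )
    return lp


# --------------------------------------------------------------------------
# Risk-diagnosis classification
# --------------------------------------------------------------------------

@dataclass
class RiskDiagnosisMap:
    """Disjoint label sets defining PIM-3 risk-diagnosis categories."""

    low: frozenset
    high: frozenset
    very_high: frozenset

    def __post_init__(self):
        self.low = frozenset(s.lower() for s in self.low)
        self.high = frozenset(s.lower() for s in self.high)
        self.very_high = frozenset(s.lower() for s in self.very_high)
        if (self.low & self.high) or (self.low & self.very_high) \
                or (self.high & self.very_high):
            raise ValueError("risk-diagnosis sets must be pairwise disjoint")


DEFAULT_RISK_MAP = RiskDiagnosisMap(
    low=frozenset({
        "asthma", "bronchiolitis", "croup", "obstructive sleep apnea",
        "diabetic ketoacidosis", "seizure",
    }),
    high=frozenset({
        "spontaneous cerebral hemorrhage", "cardiomyopathy or myocarditis",
        "hypoplastic left heart syndrome", "neurodegenerative disorder",
        "necrotizing enterocolitis",
    }),
    very_high=frozenset({
        "cardiac arrest", "severe combined immune deficiency",
        "leukemia or lymphoma", "bone marrow transplant recipient",
        "liver failure",
    }),
)


def classify_risk_diagnosis(label: str,
                            risk_map: RiskDiagnosisMap = DEFAULT_RISK_MAP) -> str:
    """Case-folded membership lookup; unmatched labels map to 'none'."""
    key = label.strip().lower()
    if key in risk_map.very_high:
        return "very_high"
    if key in risk_map.high:
        return "high"
    if key in risk_map.low:
        return "low"
    return "none"


# --------------------------------------------------------------------------
# Batch scoring
# --------------------------------------------------------------------------

def score_cohort(cohort: Cohort | pd.DataFrame,
                 missing_as_normal: bool = False,
                 breakdown: bool = False) -> pd.DataFrame:
    """Score every admission with both engines.

    Returns a DataFrame with patient_id, prism3_total, prism3_logit,
    prism3_prob, pim3_lp, pim3_prob (and the per-component PRISM-3 point
    columns when ``breakdown`` is set).
    """
    df = cohort.df if isinstance(cohort, Cohort) else cohort
    comp = prism3_components_frame(df, missing_as_normal=missing_as_normal)
    post = df["postoperative"].astype(bool).to_numpy() \
        if "postoperative" in df else np.zeros(len(df), dtype=bool)
    logit = prism3_logit(comp["total"].to_numpy(float),
                         pd.to_numeric(df["age_months"]).to_numpy(float),
                         post)
    pim_lp = _pim3_lp_frame(df)
    out = pd.DataFrame({
        "patient_id": df["patient_id"] if "patient_id" in df
        else np.arange(len(df)),
        "prism3_total": comp["total"].to_numpy(),
        "prism3_logit": logit,
        "prism3_prob": _logistic(logit),
        "pim3_lp": pim_lp,
        "pim3_prob": _logistic(pim_lp),
    }, index=df.index)
    if breakdown:
        for col in PRISM3_COMPONENTS:
            out[f"prism3_{col}"] = comp[col].to_numpy()
    return out
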