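"""Reading, validating and writing patient-level PICU cohort tables.

This module is the single source of truth for the cohort CSV schema: column
names, units and categorical codings.  One row is one PICU admission
(re-admissions are new rows with new ids).  Cells left empty are missing.

Units
-----
age_months      months
sbp, dbp        mmHg
heart_rate      beats/min
resp_rate       breaths/min
temperature     degrees Celsius
gcs             Glasgow Coma Score, integer 3-15
ph              pH units
pco2, pao2      mmHg
tco2            mEq/L
fio2            fraction of inspired oxygen in [0.21, 1.0]
base_excess     mEq/L
glucose         mg/dL
creatinine      mg/dL
urea            mg/dL (BUN)
potassium       mEq/L
wbc, platelets  10^3 cells/mm^3
pt, ptt         seconds
los_*_days      days
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger("sevscore")

# --------------------------------------------------------------------------
# Schema
# --------------------------------------------------------------------------

SEX_CODES = ("male", "female")
PUPIL_CODES = ("both_reactive", "one_fixed", "both_fixed")
ADMISSION_CODES = ("emergency", "referral", "elective")
PROCEDURE_CODES = ("none", "bypass_cardiac", "nonbypass_cardiac", "noncardiac")
RISK_DX_CODES = ("none", "low", "high", "very_high")

#: continuous physiological / laboratory variables eligible for imputation
PHYSIOLOGIC_VARS = (
    "sbp", "dbp", "heart_rate", "resp_rate", "temperature", "gcs",
    "ph", "pco2", "tco2", "pao2", "fio2", "base_excess",
    "glucose", "creatinine", "urea", "potassium",
    "wbc", "platelets", "pt", "ptt",
)

#: categorical clinical variables eligible for imputation
CATEGORICAL_CLINICAL_VARS = ("pupils",)

BOOLEAN_COLUMNS = (
    "postoperative", "mechanical_ventilation", "death_picu", "death_hospital",
)
OPTIONAL_BOOLEAN_COLUMNS = ("brain_death", "subspecialty_referral")

CATEGORICAL_COLUMNS = {
    "sex": SEX_CODES,
    "pupils": PUPIL_CODES,
    "admission_type": ADMISSION_CODES,
    "procedure": PROCEDURE_CODES,
    "risk_diagnosis": RISK_DX_CODES,
}

SCHEMA_COLUMNS = (
    "patient_id", "age_months", "sex",
    "sbp", "dbp", "heart_rate", "resp_rate", "temperature", "gcs", "pupils",
    "ph", "pco2", "tco2", "pao2", "fio2", "base_excess",
    "glucose", "creatinine", "urea", "potassium", "wbc", "platelets",
    "pt", "ptt",
    "admission_type", "postoperative", "mechanical_ventilation",
    "procedure", "risk_diagnosis",
    "death_picu", "death_hospital",
    "los_picu_days", "los_hospital_days", "hospital",
)

MANDATORY_COLUMNS = ("patient_id", "age_months", "death_picu", "death_hospital")


class SchemaError(ValueError):
    """The CSV header does not match the documented cohort schema."""


class CohortValidationError(ValueError):
    """One or more rows violate a hard record invariant."""

    def __init__(self, diagnostics: list[str]):
        self.diagnostics = diagnostics
        super().__init__(
            "cohort validation failed:\n" + "\n".join(diagnostics)
        )


@dataclass
class PatientRecord:
    """One PICU admission: raw variables, flags and outcomes."""

    patient_id: str
    age_months: float
    sex: Optional[str] = None
    sbp: Optional[float] = None
    dbp: Optional[float] = None
    heart_rate: Optional[float] = None
    resp_rate: Optional[float] = None
    temperature: Optional[float] = None
    gcs: Optional[float] = None
    pupils: Optional[str] = None
    ph: Optional[float] = None
    pco2: Optional[float] = None
    tco2: Optional[float] = None
    pao2: Optional[float] = None
    fio2: Optional[float] = None
    base_excess: Optional[float] = None
    glucose: Optional[float] = None
    creatinine: Optional[float] = None
    urea: Optional[float] = None
    potassium: Optional[float] = None
    wbc: Optional[float] = None
    platelets: Optional[float] = None
    pt: Optional[float] = None
    ptt: Optional[float] = None
    admission_type: Optional[str] = None
    postoperative: Optional[bool] = None
    mechanical_ventilation: Optional[bool] = None
    procedure: Optional[str] = None
    risk_diagnosis: Optional[str] = None
    death_picu: Optional[bool] = None
    death_hospital: Optional[bool] = None
    los_picu_days: Optional[float] = None
    los_hospital_days: Optional[float] = None
    hospital: Optional[str] = None


@dataclass
class Cohort:
    """An ordered collection of admissions plus free-text provenance."""

    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[PatientRecord]:
        names = [f.name for f in dc_fields(PatientRecord)]
        for _, row in self.df.iterrows():
            kwargs = {}
            for name in names:
                if name not in self.df.columns:
                    continue
                v = row[name]
                kwargs[name] = None if pd.isna(v) else v
            yield PatientRecord(**kwargs)

    def copy(self) -> "Cohort":
        return Cohort(self.df.copy(), dict(self.provenance))


# --------------------------------------------------------------------------
# Row validation
# --------------------------------------------------------------------------

def _validate_rows(df: pd.DataFrame) -> list[str]:
    """Return row-indexed diagnostics for hard invariant violations."""
    diags: list[str] = []

    def flag(mask: pd.Series, message: str) -> None:
        for idx in df.index[mask.fillna(False)]:
            diags.append(f"row {idx}: {message}")

    if "patient_id" in df:
        dup = df["patient_id"].duplicated(keep=False) & df["patient_id"].notna()
        flag(dup, "duplicate patient_id (re-admissions need new ids)")
    if "age_months" in df:
        flag(df["age_months"] < 0, "age_months is negative")
    if "gcs" in df:
        flag((df["gcs"] < 3) | (df["gcs"] > 15), "gcs outside [3, 15]")
    if "fio2" in df:
        flag((df["fio2"] < 0.21) | (df["fio2"] > 1.0),
             "fio2 outside [0.21, 1.0] after unit conversion")
    if "death_picu" in df and "death_hospital" in df:
        bad = (df["death_picu"] == True) & (df["death_hospital"] == False)  # noqa: E712
        flag(bad, "death_picu=true but death_hospital=false")
    if "los_picu_days" in df and "los_hospital_days" in df:
        both = df["los_picu_days"].notna() & df["los_hospital_days"].notna()
        flag(both & (df["los_hospital_days"] < df["los_picu_days"] - 1e-9),
             "los_hospital_days < los_picu_days")
    for col, codes in CATEGORICAL_COLUMNS.items():
        if col in df:
            bad = df[col].notna() & ~df[col].isin(codes)
            flag(bad, f"unparseable {col} code")
    return diags


def _parse_boolean(series: pd.Series, col: str) -> pd.Series:
    mapping = {"1": True, "0": False, "true": True, "false": False,
               "yes": True, "no": False, 1: True, 0: False,
               True: True, False: False, 1.0: True, 0.0: False}
    out = []
    for v in series:
        if pd.isna(v):
            out.append(np.nan)
            continue
        key = v.strip().lower() if isinstance(v, str) else v
        if key not in mapping:
            raise CohortValidationError(
                [f"column {col}: unparseable boolean value {v!r}"]
            )
        out.append(mapping[key])
    return pd.Series(out, index=series.index, dtype="object")


# --------------------------------------------------------------------------
# Operations
# --------------------------------------------------------------------------

def read_cohort(path, unit_dialect: str = "si_fraction",
                on_invalid: str = "drop") -> Cohort:
    """Read a cohort CSV, validate invariants and normalise units.

    Parameters
    ----------
    path : str or Path
        CSV file following the documented schema (UTF-8, '.' decimals,
        empty cell = missing).
    unit_dialect : {'si_fraction', 'percent_fio2'}
        Under ``percent_fio2`` the FiO2 column holds percentages 21-100 and
        is converted to a fraction; values > 1.0 are always treated as
        percentages (mislabeled-unit tolerance).
    on_invalid : {'drop', 'raise'}
        Rows violating hard invariants are either dropped (with row-indexed
        diagnostics logged and kept in provenance) or cause a
        :class:`CohortValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if unit_dialect not in ("si_fraction", "percent_fio2"):
        raise ValueError(f"unknown unit dialect {unit_dialect!r}")

    df = pd.read_csv(path, dtype={"patient_id": str, "hospital": str})

    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {', '.join(missing)}")

    known = set(SCHEMA_COLUMNS) | set(OPTIONAL_BOOLEAN_COLUMNS)
    extra = [c for c in df.columns if c not in known]
    if extra:
        logger.warning("ignoring unknown columns: %s", ", ".join(extra))
        df = df.drop(columns=extra)

    for col in BOOLEAN_COLUMNS + OPTIONAL_BOOLEAN_COLUMNS:
        if col in df.columns:
            df[col] = _parse_boolean(df[col], col)
    for col in CATEGORICAL_COLUMNS:
        if col in df.columns:
            df[col] = df[col].where(df[col].isna(), df[col].astype(str).str.strip().str.lower())

    if "fio2" in df.columns:
        vals = pd.to_numeric(df["fio2"], errors="coerce")
        if unit_dialect == "percent_fio2":
            vals = vals / 100.0
        # tolerance for mislabeled percent values under either dialect
        vals = vals.where(~(vals > 1.0), vals / 100.0)
        df["fio2"] = vals

    diags = _validate_rows(df)
    if diags:
        if on_invalid == "raise":
            raise CohortValidationError(diags)
        bad_rows = sorted({int(d.split()[1].rstrip(":")) for d in diags
                           if d.startswith("row ")})
        logger.warning("rejecting %d invalid rows:\n%s",
                       len(bad_rows), "\n".join(diags))
        df = df.drop(index=bad_rows).reset_index(drop=True)

    return Cohort(df, provenance={
        "source": str(path),
        "unit_dialect": unit_dialect,
        "rejected_rows": diags,
        "imputed": False,
    })


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort back to the schema CSV (round-trips with read_cohort)."""
    df = cohort.df.copy()
    for col in BOOLEAN_COLUMNS + OPTIONAL_BOOLEAN_COLUMNS:
        if col in df.columns:
            df[col] = df[col].map(
                lambda v: "" if pd.isna(v) else ("1" if v else "0"))
    cols = [c for c in SCHEMA_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df[cols].to_csv(path, index=False)


def apply_eligibility(cohort: Cohort,
                      min_picu_hours: float = 2.0,
                      min_followup_hours: float = 24.0,
                      followup_field: str = "los_hospital_days",
                      ) -> tuple[Cohort, dict]:
    """Apply the study's eligibility rules and return (cohort, tally).

    Rules, applied in order (each excluded admission is tallied under the
    first rule it violates):

    1. ``picu_stay_lt_min``      los_picu_days * 24 < min_picu_hours
    2. ``followup_lt_min``       followup LOS * 24 < min_followup_hours
       (discharged or died before the follow-up window; which LOS column
       defines "discharge" is configurable via ``followup_field``)
    3. ``brain_death``           optional boolean column, when present
    4. ``subspecialty_referral`` optional boolean column, when present
    """
    if min_picu_hours <= 0 or min_followup_hours <= 0:
        raise ValueError("eligibility thresholds must be positive")
    df = cohort.df
    n = len(df)
    excluded = np.zeros(n, dtype=bool)
    tally: dict[str, int] = {}

    def apply_rule(name: str, mask: np.ndarray) -> None:
        nonlocal excluded
        new = mask & ~excluded
        tally[name] = int(new.sum())
        excluded |= new

    picu_h = pd.to_numeric(df.get("los_picu_days"), errors="coerce") * 24.0
    apply_rule("picu_stay_lt_min", (picu_h < min_picu_hours).fillna(False).to_numpy())

    fup_h = pd.to_numeric(df.get(followup_field), errors="coerce") * 24.0
    apply_rule("followup_lt_min", (fup_h < min_followup_hours).fillna(False).to_numpy())

    for col in OPTIONAL_BOOLEAN_COLUMNS:
        if col in df.columns:
            apply_rule(col, (df[col] == True).to_numpy())  # noqa: E712

    kept = df.loc[~excluded].reset_index(drop=True)

    # every analyzed admission must carry both outcomes
    for col in ("death_picu", "death_hospital"):
        if kept[col].isna().any():
            bad = kept.index[kept[col].isna()].tolist()
            raise CohortValidationError(
                [f"row {i}: missing {col} after eligibility filtering"
                 for i in bad])

    out = Cohort(kept, dict(cohort.provenance))
    out.provenance["exclusions"] = tally
    return out, tally


def write_exclusion_tally(tally: dict, path) -> None:
    Path(path).write_text(json.dumps(tally, indent=2))
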