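"""Chained-equations imputation of physiological and laboratory values.

Missing cells are filled by iterating per-variable conditional models over
the currently-completed data (the "fully conditional specification" /
chained-equations scheme): continuous variables get stochastic predictive
draws from a linear model (fitted coefficients plus Gaussian residual
noise), categorical variables get draws from a multinomial logistic model.
Continuous draws are clamped to the observed range of the variable so the
downstream scoring engines always see physiological values.

One completed dataset is produced (m = 1): the downstream analysis mirrors
single-cohort reporting, not pooled multiple-imputation estimates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort_io import (
    Cohort, PHYSIOLOGIC_VARS, CATEGORICAL_CLINICAL_VARS, CATEGORICAL_COLUMNS,
)

logger = logging.getLogger("sevscore")

__all__ = ["ImputationSpec", "ImputationReport", "impute_chained",
           "UnimputableError"]

DEFAULT_IMPUTE_VARS = PHYSIOLOGIC_VARS + CATEGORICAL_CLINICAL_VARS


class UnimputableError(ValueError):
    """A variable has no observed values to condition on."""


@dataclass
class ImputationSpec:
    """Configuration of the chained-equations imputer."""

    variables: Sequence[str] = DEFAULT_IMPUTE_VARS
    n_cycles: int = 10
    n_imputations: int = 1
    seed: Optional[int] = None

    def __post_init__(self):
        forbidden = {"patient_id", "death_picu", "death_hospital",
                     "los_picu_days", "los_hospital_days", "hospital"}
        bad = forbidden & set(self.variables)
        if bad:
            raise ValueError(f"cannot impute outcome/id/admin fields: {bad}")
        if self.n_cycles < 1 or self.n_imputations < 1:
            raise ValueError("n_cycles and n_imputations must be positive")


@dataclass
class ImputationReport:
    """Per-variable missing counts and imputer settings."""

    missing_before: dict
    missing_after: dict
    n_cycles: int
    seed: Optional[int]
    warnings: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({
            "missing_before": self.missing_before,
            "missing_after": self.missing_after,
            "n_cycles": self.n_cycles,
            "seed": self.seed,
            "warnings": self.warnings,
        }, indent=2)


def _design_matrix(df: pd.DataFrame, predictors: list[str]) -> np.ndarray:
    """Numeric design matrix (categoricals dummy-coded) with intercept."""
    cols = [np.ones(len(df))]
    for var in predictors:
        if var in CATEGORICAL_COLUMNS:
            codes = CATEGORICAL_COLUMNS[var]
            for code in codes[1:]:
                cols.append((df[var] == code).to_numpy(float))
        else:
            cols.append(pd.to_numeric(df[var]).to_numpy(float))
    return np.column_stack(cols)


def _draw_continuous(rng, X_obs, y_obs, X_mis):
    """Predictive draw from a linear model with residual noise."""
    beta, *_ = np.linalg.lstsq(X_obs, y_obs, rcond=None)
    resid = y_obs - X_obs @ beta
    dof = max(len(y_obs) - X_obs.shape[1], 1)
    sigma = float(np.sqrt((resid ** 2).sum() / dof))
    return X_mis @ beta + rng.normal(0.0, sigma, len(X_mis))


def _draw_categorical(rng, X_obs, y_obs_codes, X_mis, n_classes, warnings):
    """Draw from a multinomial logistic conditional, marginal fallback."""
    from sklearn.linear_model import LogisticRegression

    classes = np.unique(y_obs_codes)
    if len(classes) == 1:
        return np.full(len(X_mis), classes[0])
    try:
        # standardize for the lbfgs solver; sklearn adds its own intercept
        mu = X_obs[:, 1:].mean(axis=0)
        sd = X_obs[:, 1:].std(axis=0)
        sd[sd == 0] = 1.0
        clf = LogisticRegression(max_iter=1000)
        clf.fit((X_obs[:, 1:] - mu) / sd, y_obs_codes)
        probs = clf.predict_proba((X_mis[:, 1:] - mu) / sd)
        cum = probs.cumsum(axis=1)
        u = rng.random((len(X_mis), 1))
        picks = (u < cum).argmax(axis=1)
        return clf.classes_[picks]
    except Exception as exc:  # pragma: no cover - defensive fallback
        warnings.append(f"categorical model failed ({exc}); marginal draw")
        logger.warning("categorical imputation model failed; marginal draw")
        counts = np.bincount(y_obs_codes, minlength=n_classes).astype(float)
        p = counts / counts.sum()
        return rng.choice(n_classes, size=len(X_mis), p=p)


def impute_chained(cohort: Cohort, spec: ImputationSpec | None = None,
                   ) -> tuple[Cohort, ImputationReport]:
    """Fill missing cells among spec.variables; observed cells unchanged.

    Visit sequence is ascending missingness count.  Initial fills are
    random draws from the observed values of each variable; each cycle
    then re-draws every originally-missing cell from its conditional
    model given all other variables in the spec.
    """
    spec = spec or ImputationSpec()
    rng = np.random.default_rng(spec.seed)
    df = cohort.df.copy()
    warnings: list[str] = []

    variables = [v for v in spec.variables if v in df.columns]
    miss_masks = {v: df[v].isna().to_numpy() for v in variables}
    missing_before = {v: int(m.sum()) for v, m in miss_masks.items()}

    for v, m in miss_masks.items():
        if m.all():
            raise UnimputableError(
                f"variable {v!r} is missing in every record")

    to_impute = [v for v in variables if miss_masks[v].any()]
    # visit sequence: ascending missingness
    to_impute.sort(key=lambda v: (missing_before[v], v))

    if not to_impute:
        report = ImputationReport(missing_before, dict(missing_before),
                                  spec.n_cycles, spec.seed, warnings)
        out = cohort.copy()
        out.provenance["imputed"] = True
        return out, report

    # observed ranges for clamping; categorical code books
    obs_range = {}
    cat_codes = {}
    for v in variables:
        if v in CATEGORICAL_COLUMNS:
            cat_codes[v] = list(CATEGORICAL_COLUMNS[v])
        else:
            obs = pd.to_numeric(df[v][~miss_masks[v]])
            obs_range[v] = (float(obs.min()), float(obs.max()))

    # initial fill: marginal draws from observed values
    for v in to_impute:
        m = miss_masks[v]
        obs_vals = df.loc[~m, v].to_numpy()
        df.loc[m, v] = rng.choice(obs_vals, size=int(m.sum()))

    integer_like = {"gcs"}

    for _cycle in range(spec.n_cycles):
        for v in to_impute:
            m = miss_masks[v]
            predictors = [p for p in variables if p != v]
            X = _design_matrix(df, predictors)
            if v in CATEGORICAL_COLUMNS:
                codes = cat_codes[v]
                y_obs = df.loc[~m, v].map({c: i for i, c in enumerate(codes)})
                drawn = _draw_categorical(
                    rng, X[~m], y_obs.to_numpy(int), X[m], len(codes),
                    warnings)
                df.loc[m, v] = [codes[int(k)] for k in drawn]
            else:
                y_obs = pd.to_numeric(df.loc[~m, v]).to_numpy(float)
                drawn = _draw_continuous(rng, X[~m], y_obs, X[m])
                lo, hi = obs_range[v]
                drawn = np.clip(drawn, lo, hi)
                if v in integer_like:
                    drawn = np.round(drawn)
                df.loc[m, v] = drawn

    missing_after = {v: int(df[v].isna().sum()) for v in variables}
    report = ImputationReport(missing_before, missing_after,
                              spec.n_cycles, spec.seed, warnings)
    out = Cohort(df, dict(cohort.provenance))
    out.provenance["imputed"] = True
    out.provenance["imputation_seed"] = spec.seed
    return out, report
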