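"""Prognostic-model validation metrics.

Overall accuracy (Brier score, standardized mortality ratio), discrimination
(Mann-Whitney AUC, DeLong paired comparison, optimism-corrected bootstrap)
and calibration (Hosmer-Lemeshow grouped chi-square, calibration tables and
curves, Youden-index operating point).

Conventions
-----------
* higher score / probability means predicted death;
* the SMR uses the score's original published probabilities (the expected
  deaths come from the development model), while Brier score and the
  Hosmer-Lemeshow test default to locally recalibrated probabilities —
  both choices are overridable at the pipeline level;
* all bootstrap operations are deterministic given their seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .recalibration import fit_score_logit, predict_probability, \
    DegenerateOutcomeError

logger = logging.getLogger("sevscore")

__all__ = [
    "SmrResult", "CalibrationTable", "DiscriminationResult",
    "OperatingPoint", "ValidationReport",
    "brier_score", "smr", "auc_empirical", "bootstrap_internal_validation",
    "delong_compare", "hosmer_lemeshow", "youden_operating_point",
    "calibration_curve",
]


def _check_binary(outcomes) -> np.ndarray:
    y = np.asarray(outcomes, dtype=float)
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("outcomes must be binary 0/1")
    return y


def _check_both_classes(y: np.ndarray) -> None:
    if y.min() == y.max():
        raise DegenerateOutcomeError("both outcome classes must be present")


# --------------------------------------------------------------------------
# Overall accuracy
# --------------------------------------------------------------------------

def brier_score(probs, outcomes) -> float:
    """Mean squared difference between predicted probability and outcome."""
    p = np.asarray(probs, dtype=float)
    y = _check_binary(outcomes)
    if p.shape != y.shape:
        raise ValueError("probs and outcomes must have equal length")
    if len(p) < 1:
        raise ValueError("need at least one observation")
    return float(np.mean((p - y) ** 2))


@dataclass
class SmrResult:
    """Observed/expected deaths ratio with a 95% CI."""

    observed: int
    expected: float
    smr: float
    ci95: tuple
    method: str = "byar"


def _byar_poisson_ci(obs: int, level: float = 0.95) -> tuple:
    """Byar's approximation to the Poisson count CI."""
    z = stats.norm.ppf(0.5 + level / 2.0)
    if obs == 0:
        low = 0.0
    else:
        low = obs * (1.0 - 1.0 / (9.0 * obs) - z / (3.0 * np.sqrt(obs))) ** 3
    op1 = obs + 1.0
    high = op1 * (1.0 - 1.0 / (9.0 * op1) + z / (3.0 * np.sqrt(op1))) ** 3
    return low, high


def smr(probs, outcomes, method: str = "byar",
        n_boot: int = 1000, seed: Optional[int] = None) -> SmrResult:
    """Standardized mortality ratio: observed deaths / sum of probabilities.

    The probabilities should come from the original published model (the
    "development set" expectation).  The default CI treats the observed
    count as Poisson with mean equal to the expected count (Byar's
    approximation); ``method='bootstrap'`` resamples patients instead.
    """
    p = np.asarray(probs, dtype=float)
    y = _check_binary(outcomes)
    if p.shape != y.shape:
        raise ValueError("probs and outcomes must have equal length")
    expected = float(p.sum())
    if expected <= 0:
        raise ZeroDivisionError("expected deaths is zero; SMR undefined")
    observed = int(y.sum())
    ratio = observed / expected

    if method == "byar":
        lo_cnt, hi_cnt = _byar_poisson_ci(observed)
        ci = (lo_cnt / expected, hi_cnt / expected)
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        n = len(p)
        ratios = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, n, n)
            e = p[idx].sum()
            ratios[b] = y[idx].sum() / e if e > 0 else np.nan
        ci = tuple(np.nanpercentile(ratios, [2.5, 97.5]))
    else:
        raise ValueError(f"unknown SMR CI method {method!r}")
    return SmrResult(observed, expected, ratio, ci, method)


# --------------------------------------------------------------------------
# Discrimination
# --------------------------------------------------------------------------

def auc_empirical(scores, outcomes) -> float:
    """Mann-Whitney AUC: (concordant + tied/2) / (n1 * n0) via midranks."""
    x = np.asarray(scores, dtype=float)
    y = _check_binary(outcomes)
    _check_both_classes(y)
    n1 = int(y.sum())
    n0 = len(y) - n1
    ranks = stats.rankdata(x)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


@dataclass
class DiscriminationResult:
    """Apparent and optimism-corrected AUC with a bootstrap CI."""

    auc: float
    ci95: tuple
    method: str
    n_boot: int
    seed: Optional[int]
    apparent_auc: float = np.nan
    optimism: float = np.nan


def bootstrap_internal_validation(scores, outcomes, n_boot: int = 1000,
                                  seed: Optional[int] = None,
                                  ) -> DiscriminationResult:
    """Harrell optimism-corrected bootstrap AUC for a score-logit model.

    For each resample the univariable logistic model is refit; optimism is
    the mean gap between the resample AUC and the refit model's AUC on the
    original sample.  Corrected AUC = apparent - optimism.  The CI is the
    percentile interval of the resample AUCs.  Single-class resamples are
    redrawn (logged).
    """
    x = np.asarray(scores, dtype=float)
    y = _check_binary(outcomes)
    _check_both_classes(y)
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    rng = np.random.default_rng(seed)
    n = len(x)
    apparent = auc_empirical(x, y)

    boot_aucs = np.empty(n_boot)
    optimisms = np.empty(n_boot)
    redrawn = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, n)
            yb = y[idx]
            if yb.min() != yb.max():
                break
            redrawn += 1
        xb = x[idx]
        model = fit_score_logit(xb, yb)
        auc_b = auc_empirical(xb, yb)
        # refit model evaluated on the original sample
        auc_orig = auc_empirical(predict_probability(model, x), y)
        boot_aucs[b] = auc_b
        optimisms[b] = auc_b - auc_orig
    if redrawn:
        logger.warning("redrew %d single-class bootstrap resamples", redrawn)

    optimism = float(optimisms.mean())
    corrected = apparent - optimism
    ci = tuple(np.percentile(boot_aucs, [2.5, 97.5]))
    return DiscriminationResult(
        auc=corrected, ci95=ci, method="bootstrap_bias_corrected",
        n_boot=n_boot, seed=seed, apparent_auc=apparent, optimism=optimism,
    )


def _delong_components(x: np.ndarray, y: np.ndarray):
    """DeLong structural components (V10 for cases, V01 for controls)."""
    cases = x[y == 1]
    controls = x[y == 0]
    m, n = len(cases), len(controls)
    all_ranks = stats.rankdata(np.concatenate([cases, controls]))
    case_ranks = stats.rankdata(cases)
    control_ranks = stats.rankdata(controls)
    v10 = (all_ranks[:m] - case_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - control_ranks) / m
    return v10, v01


def delong_compare(scores_a, scores_b, outcomes):
    """DeLong's test for two paired (same patients) AUCs.

    Returns (auc_a, auc_b, z, two-sided p).  When the estimated variance of
    the AUC difference is zero (e.g. identical or rank-equivalent
    predictors) z = 0 and p = 1.
    """
    xa = np.asarray(scores_a, dtype=float)
    xb = np.asarray(scores_b, dtype=float)
    y = _check_binary(outcomes)
    _check_both_classes(y)
    if not (xa.shape == xb.shape == y.shape):
        raise ValueError("paired score vectors must match outcomes in length")

    v10_a, v01_a = _delong_components(xa, y)
    v10_b, v01_b = _delong_components(xb, y)
    auc_a = float(v10_a.mean())
    auc_b = float(v10_b.mean())
    m, n = len(v10_a), len(v01_a)

    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    if var_diff <= 1e-16:
        return auc_a, auc_b, 0.0, 1.0
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return auc_a, auc_b, float(z), float(p)


def delong_variance(scores, outcomes) -> float:
    """DeLong variance of a single empirical AUC."""
    x = np.asarray(scores, dtype=float)
    y = _check_binary(outcomes)
    _check_both_classes(y)
    v10, v01 = _delong_components(x, y)
    return float(np.var(v10, ddof=1) / len(v10)
                 + np.var(v01, ddof=1) / len(v01))


# --------------------------------------------------------------------------
# Calibration
# --------------------------------------------------------------------------

@dataclass
class CalibrationTable:
    """Risk-group expected/observed deaths and the Hosmer-Lemeshow test."""

    #: rows of (total, expected, observed, mean predicted risk)
    groups: list
    hl_statistic: float
    hl_dof: int
    hl_pvalue: float
    n_groups: int


def _quantile_groups(p: np.ndarray, n_groups: int) -> list[np.ndarray]:
    """Equal-frequency groups by predicted risk, ties kept together."""
    order = np.argsort(p, kind="mergesort")
    edges = np.linspace(0, len(p), n_groups + 1).round().astype(int)
    groups = []
    start = 0
    for k in range(n_groups):
        end = edges[k + 1]
        if end <= start:
            continue
        # extend the cut so tied predictions stay in one group
        while end < len(p) and p[order[end - 1]] == p[order[end]]:
            end += 1
        groups.append(order[start:end])
        start = end
        if start >= len(p):
            break
    return [g for g in groups if len(g)]


def hosmer_lemeshow(probs, outcomes, n_groups: int = 10,
                    dof_offset: int = 2) -> CalibrationTable:
    """Hosmer-Lemeshow grouped chi-square goodness-of-fit test.

    Groups are quantiles of predicted risk (ties kept together);
    chi2 = sum (O-E)^2/E + ((T-O)-(T-E))^2/(T-E); dof = g - dof_offset
    (offset 2 for a model fit on the same data, 1 for external validation).
    Groups with degenerate expectations are merged into their neighbor.
    """
    p = np.asarray(probs, dtype=float)
    y = _check_binary(outcomes)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("probabilities must lie strictly in (0, 1)")
    if len(p) < 2 * n_groups:
        raise ValueError("need at least 2 observations per risk group")

    groups = _quantile_groups(p, n_groups)
    rows = []
    for g in groups:
        total = len(g)
        e = float(p[g].sum())
        o = float(y[g].sum())
        rows.append([total, e, o, float(p[g].mean())])

    # merge degenerate groups (all-but-impossible with p in (0,1), kept for
    # robustness against near-zero expectations)
    merged = []
    for row in rows:
        total, e, o, _ = row
        if merged and (e < 1e-12 or (total - e) < 1e-12):
            prev = merged[-1]
            logger.warning("merging degenerate Hosmer-Lemeshow group")
            tot = prev[0] + total
            ee = prev[1] + e
            oo = prev[2] + o
            mean_p = ee / tot
            merged[-1] = [tot, ee, oo, mean_p]
        else:
            merged.append(row)

    chi2 = 0.0
    for total, e, o, _ in merged:
        chi2 += (o - e) ** 2 / e
        chi2 += ((total - o) - (total - e)) ** 2 / (total - e)
    g = len(merged)
    dof = max(g - dof_offset, 1)
    pval = float(stats.chi2.sf(chi2, dof))
    return CalibrationTable(
        groups=[tuple(r) for r in merged], hl_statistic=float(chi2),
        hl_dof=dof, hl_pvalue=pval, n_groups=g,
    )


def calibration_curve(probs, outcomes, n_bins: int = 10) -> list:
    """Equal-frequency calibration bins.

    Returns rows of (mean predicted, observed event rate, count).
    """
    p = np.asarray(probs, dtype=float)
    y = _check_binary(outcomes)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    groups = _quantile_groups(p, n_bins)
    return [(float(p[g].mean()), float(y[g].mean()), len(g)) for g in groups]


# --------------------------------------------------------------------------
# Operating point
# --------------------------------------------------------------------------

@dataclass
class OperatingPoint:
    """Classification characteristics at the Youden-index cutoff."""

    cutoff: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    youden_j: float


def youden_operating_point(scores, outcomes) -> OperatingPoint:
    """Cutoff maximizing J = sensitivity + specificity - 1.

    Candidate cutoffs are midpoints between consecutive distinct sorted
    score values (half-integers for integer scores); score >= cutoff
    predicts death; ties in J break toward the smallest cutoff.
    """
    x = np.asarray(scores, dtype=float)
    y = _check_binary(outcomes)
    _check_both_classes(y)

    distinct = np.unique(x)
    if len(distinct) < 2:
        raise ValueError("all scores identical; no cutoff exists")
    cutoffs = (distinct[:-1] + distinct[1:]) / 2.0

    n1 = y.sum()
    n0 = len(y) - n1
    best = None
    for c in cutoffs:
        pred = x >= c
        tp = float(np.sum(pred & (y == 1)))
        fp = float(np.sum(pred & (y == 0)))
        sens = tp / n1
        spec = (n0 - fp) / n0
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, c, tp, fp)
    j, c, tp, fp = best
    fn = n1 - tp
    tn = n0 - fp
    pos = tp + fp
    neg = tn + fn
    return OperatingPoint(
        cutoff=float(c),
        sensitivity=tp / n1,
        specificity=tn / n0,
        ppv=tp / pos if pos else np.nan,
        npv=tn / neg if neg else np.nan,
        accuracy=(tp + tn) / len(y),
        youden_j=float(j),
    )


# --------------------------------------------------------------------------
# Combined report
# --------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """The full metric battery for one (score, outcome, subgroup) cell."""

    subgroup: str
    n: int
    brier: float
    smr: SmrResult
    discrimination: DiscriminationResult
    calibration: CalibrationTable
    operating_point: OperatingPoint
    extras: dict = field(default_factory=dict)
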