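"""Univariable logistic recalibration of a severity score to mortality.

A severity score X developed elsewhere is mapped to the local outcome Y by
refitting the two-parameter logistic model

    P(Y = 1 | X) = 1 / (1 + exp(-(b0 + b1 * X)))

by maximum likelihood.  Because the recalibrated probability is a monotone
transform of the score (for b1 > 0), discrimination (AUC) is unchanged;
recalibration only moves the probability scale, enabling calibration and
Brier-score assessment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np

__all__ = [
    "RecalibratedModel", "fit_score_logit", "predict_probability",
    "DegenerateOutcomeError", "SeparationError",
]


class DegenerateOutcomeError(ValueError):
    """Only one outcome class present; the slope is not identifiable."""


class SeparationError(ValueError):
    """(Quasi-)complete separation: the MLE diverges."""


@dataclass
class RecalibratedModel:
    """Intercept/slope of a fitted score -> outcome logistic model."""

    score_name: str
    outcome_name: str
    beta0: float
    beta1: float
    n: int
    converged: bool
    log_likelihood: float
    #: Wald standard errors (beta0, beta1) from the observed information
    se: tuple = (np.nan, np.nan)

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        """Wald confidence intervals, rows (beta0, beta1)."""
        from scipy.stats import norm
        z = norm.ppf(0.5 + level / 2.0)
        est = np.array([self.beta0, self.beta1])
        se = np.asarray(self.se)
        return np.column_stack([est - z * se, est + z * se])

    def to_json(self) -> str:
        d = asdict(self)
        d["se"] = list(d["se"])
        return json.dumps(d, indent=2)


def _logistic(x):
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _log_likelihood(eta, y):
    # sum(y*eta - log(1+exp(eta))) computed stably
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_score_logit(scores, outcomes,
                    score_name: str = "score",
                    outcome_name: str = "outcome",
                    tol: float = 1e-8,
                    max_iter: int = 100) -> RecalibratedModel:
    """Maximum-likelihood fit of outcome ~ score by Newton/IRLS.

    Convergence is declared when the log-likelihood improves by less than
    ``tol`` and the score equations are satisfied to the same order.
    Complete separation is reported as :class:`SeparationError` once the
    slope exceeds 50 in absolute value (a logistic slope of 50 per score
    unit is far beyond any plausible clinical association).
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("scores and outcomes must be equal-length vectors")
    if len(x) < 10:
        raise ValueError("need at least 10 observations")
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("outcomes must be binary 0/1")
    if y.min() == y.max():
        raise DegenerateOutcomeError(
            f"all outcomes are {int(y[0])}; cannot fit a logistic model")

    # center the score for conditioning; transform back afterwards
    x_mean = x.mean()
    xc = x - x_mean
    X = np.column_stack([np.ones_like(xc), xc])

    beta = np.zeros(2)
    ll_old = _log_likelihood(X @ beta, y)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        p = _logistic(eta)
        w = p * (1.0 - p)
        grad = X.T @ (y - p)
        hess = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            raise SeparationError("singular information matrix")
        beta_new = beta + step
        ll_new = _log_likelihood(X @ beta_new, y)
        # step-halving when Newton overshoots
        halvings = 0
        while ll_new < ll_old - 1e-12 and halvings < 30:
            step /= 2.0
            beta_new = beta + step
            ll_new = _log_likelihood(X @ beta_new, y)
            halvings += 1
        beta = beta_new
        if abs(beta[1]) > 50.0:
            raise SeparationError(
                "slope diverged (|beta1| > 50); complete separation")
        grad_new = X.T @ (y - _logistic(X @ beta))
        # the gradient condition keeps the score equations satisfied to
        # machine order, so mean fitted probability matches prevalence
        if abs(ll_new - ll_old) < tol and np.max(np.abs(grad_new)) < 1e-9 * len(x):
            ll_old = ll_new
            converged = True
            break
        ll_old = ll_new

    # final gradient polish check
    eta = X @ beta
    p = _logistic(eta)
    w = p * (1.0 - p)
    hess = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.full((2, 2), np.nan)

    beta1 = beta[1]
    beta0 = beta[0] - beta1 * x_mean
    # delta method for the uncentered intercept SE
    se0 = float(np.sqrt(max(cov[0, 0] - 2 * x_mean * cov[0, 1]
                            + x_mean ** 2 * cov[1, 1], 0.0)))
    se1 = float(np.sqrt(max(cov[1, 1], 0.0)))

    return RecalibratedModel(
        score_name=score_name, outcome_name=outcome_name,
        beta0=float(beta0), beta1=float(beta1), n=len(x),
        converged=converged, log_likelihood=ll_old, se=(se0, se1),
    )


def predict_probability(model: RecalibratedModel, score):
    """Recalibrated probability 1 / (1 + exp(-(b0 + b1*score)))."""
    if not model.converged:
        raise ValueError("model did not converge; refusing to predict")
    eta = model.beta0 + model.beta1 * np.asarray(score, dtype=float)
    out = _logistic(np.atleast_1d(eta))
    return float(out[0]) if np.isscalar(score) or np.ndim(score) == 0 else out
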