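"""One-command orchestration of the severity-score validation study.

Pipeline: ingest (or simulate) -> eligibility filter -> chained-equations
imputation -> PRISM-3/PIM-3 scoring -> logistic recalibration -> metric
battery, for both scores x both outcomes x optional subgroups (age band,
hospital), with a tabular report, JSON bundle and ROC/calibration figures.

Score scales
------------
PRISM-3 enters recalibration and reporting as its integer point total.
PIM-3 enters as its published probability expressed in percent (the
"PIM-3 score" convention of severity-score reporting: a score of 2 means
2% predicted mortality); this is a monotone transform of the linear
predictor, so discrimination is unaffected.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .cohort_io import Cohort, read_cohort, apply_eligibility, write_cohort
from .imputation import ImputationSpec, impute_chained
from .severity_scores import score_cohort, age_band_vector, AGE_BANDS
from .recalibration import (fit_score_logit, predict_probability,
                            DegenerateOutcomeError)
from . import validation_metrics as vm
from .synthetic_cohort import CohortScenario, simulate_cohort, \
    inject_missingness

logger = logging.getLogger("sevscore")

__all__ = ["PipelineConfig", "run_study", "derive_seed"]

OUTCOMES = {"picu_death": "death_picu", "hospital_death": "death_hospital"}
SCORES = ("prism3", "pim3")


def derive_seed(master: Optional[int], label: str) -> Optional[int]:
    """Expand one master seed into per-stage seeds (stable across runs)."""
    if master is None:
        return None
    return int(np.random.SeedSequence(
        [int(master), zlib.crc32(label.encode())]).generate_state(1)[0]
        % (2 ** 31))


@dataclass
class PipelineConfig:
    """Everything run_study needs; either input_path or scenario."""

    input_path: Optional[str] = None
    scenario: Optional[CohortScenario] = None
    unit_dialect: str = "si_fraction"
    out_dir: str = "report"
    seed: Optional[int] = 0
    # eligibility
    min_picu_hours: float = 2.0
    min_followup_hours: float = 24.0
    # imputation
    imputation_cycles: int = 10
    # metrics
    hl_groups: int = 10
    report_hl_groups: int = 5      # quintiles-of-risk report layout
    smr_ci_method: str = "byar"
    n_boot: int = 1000
    brier_on: str = "recalibrated"   # or "original"
    hl_on: str = "recalibrated"      # or "original"
    subgroups: tuple = ("age_band", "hospital")
    make_plots: bool = True

    def __post_init__(self):
        if self.n_boot < 100:
            raise ValueError("bootstrap n must be at least 100")
        if self.input_path is None and self.scenario is None:
            raise ValueError("either input_path or scenario is required")
        bad = set(self.subgroups) - {"age_band", "hospital", "none"}
        if bad:
            raise ValueError(f"unknown subgroup keys: {bad}")


def _score_vectors(scored: pd.DataFrame) -> dict:
    return {
        "prism3": scored["prism3_total"].to_numpy(float),
        "pim3": scored["pim3_prob"].to_numpy(float) * 100.0,
    }


def _original_probs(scored: pd.DataFrame) -> dict:
    return {
        "prism3": scored["prism3_prob"].to_numpy(float),
        "pim3": scored["pim3_prob"].to_numpy(float),
    }


def _cell_report(scores, orig_probs, recal_probs, outcomes, cfg,
                 seed) -> Optional[vm.ValidationReport]:
    """Metric battery on one (score, outcome, subgroup) slice."""
    y = np.asarray(outcomes, dtype=float)
    if len(y) == 0 or y.min() == y.max():
        return None
    brier_probs = recal_probs if cfg.brier_on == "recalibrated" else orig_probs
    hl_probs = recal_probs if cfg.hl_on == "recalibrated" else orig_probs
    try:
        disc = vm.bootstrap_internal_validation(
            scores, y, n_boot=cfg.n_boot, seed=seed)
        calib = vm.hosmer_lemeshow(hl_probs, y,
                                   n_groups=min(cfg.report_hl_groups,
                                                len(y) // 2) or 2)
        op = vm.youden_operating_point(scores, y)
        return vm.ValidationReport(
            subgroup="", n=len(y),
            brier=vm.brier_score(brier_probs, y),
            smr=vm.smr(orig_probs, y, method=cfg.smr_ci_method, seed=seed),
            discrimination=disc, calibration=calib, operating_point=op,
        )
    except (DegenerateOutcomeError, ValueError) as exc:
        logger.warning("cell not estimable: %s", exc)
        return None


def _report_row(outcome, subgroup, model, rep: Optional[vm.ValidationReport]):
    if rep is None:
        return {"Outcome": outcome, "Subgroup": subgroup, "Model": model,
                "Total": None, "estimable": False}
    return {
        "Outcome": outcome, "Subgroup": subgroup, "Model": model,
        "estimable": True,
        "AUC": round(rep.discrimination.auc, 4),
        "AUC_CI_low": round(rep.discrimination.ci95[0], 4),
        "AUC_CI_high": round(rep.discrimination.ci95[1], 4),
        "AUC_apparent": round(rep.discrimination.apparent_auc, 4),
        "Total": rep.n,
        "Exp": round(rep.smr.expected, 2),
        "Obs": rep.smr.observed,
        "SMR": round(rep.smr.smr, 3),
        "SMR_CI_low": round(rep.smr.ci95[0], 3),
        "SMR_CI_high": round(rep.smr.ci95[1], 3),
        "HL_stat": round(rep.calibration.hl_statistic, 3),
        "HL_p": round(rep.calibration.hl_pvalue, 5),
        "BS": round(rep.brier, 4),
        "Cutoff": rep.operating_point.cutoff,
        "Sen": round(rep.operating_point.sensitivity, 3),
        "Spe": round(rep.operating_point.specificity, 3),
        "PPV": round(rep.operating_point.ppv, 3),
        "NPV": round(rep.operating_point.npv, 3),
        "Acc": round(rep.operating_point.accuracy, 3),
    }


def _plot_roc(scores_by_model, y, path, title):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from sklearn.metrics import roc_curve

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, s in scores_by_model.items():
        fpr, tpr, _ = roc_curve(y, s)
        auc = vm.auc_empirical(s, y)
        ax.plot(fpr, tpr, label=f"{name.upper()} (AUC {auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(title)
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def _plot_calibration(probs, y, path, title):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    bins = vm.calibration_curve(probs, y, n_bins=10)
    pred = [b[0] for b in bins]
    obs = [b[1] for b in bins]
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot([0, max(pred + obs) * 1.05 + 1e-6],
            [0, max(pred + obs) * 1.05 + 1e-6], "k--", lw=0.8)
    ax.plot(pred, obs, "o-")
    ax.set_xlabel("predicted risk")
    ax.set_ylabel("observed mortality")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def run_study(config: PipelineConfig) -> dict:
    """Run the full validation study; returns the report bundle dict.

    Writes report.json, table4.csv, exclusions.json, models.json, run.log
    and (optionally) ROC / calibration SVGs into config.out_dir.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    try:
        return _run_study_inner(config, out_dir)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run_study_inner(config: PipelineConfig, out_dir: Path) -> dict:
    # --- ingest -----------------------------------------------------------
    if config.scenario is not None:
        sc = dataclasses.replace(
            config.scenario, seed=derive_seed(config.seed, "simulate")
            if config.scenario.seed is None else config.scenario.seed)
        cohort = simulate_cohort(sc)
        if sc.missing_fraction > 0:
            cohort = inject_missingness(
                cohort, sc.missing_fraction,
                seed=derive_seed(config.seed, "missingness"))
        logger.info("simulated cohort of %d admissions", len(cohort))
    else:
        cohort = read_cohort(config.input_path, config.unit_dialect)
        logger.info("read %d admissions from %s", len(cohort),
                    config.input_path)

    # --- eligibility --------------------------------------------------------
    cohort, tally = apply_eligibility(
        cohort, config.min_picu_hours, config.min_followup_hours)
    logger.info("eligible admissions: %d (exclusions: %s)", len(cohort), tally)
    (out_dir / "exclusions.json").write_text(json.dumps(tally, indent=2))

    # --- imputation ---------------------------------------------------------
    spec = ImputationSpec(n_cycles=config.imputation_cycles,
                          seed=derive_seed(config.seed, "imputation"))
    cohort, imp_report = impute_chained(cohort, spec)
    (out_dir / "imputation.json").write_text(imp_report.to_json())

    # --- scoring -------------------------------------------------------------
    scored = score_cohort(cohort)
    write_cohort(cohort, out_dir / "analysis_cohort.csv")
    scored.to_csv(out_dir / "scores.csv", index=False)

    score_vecs = _score_vectors(scored)
    orig_probs = _original_probs(scored)

    # --- recalibration (full cohort, reused in subgroup slices) -------------
    models = {}
    recal_probs: dict[tuple, np.ndarray] = {}
    for outcome_name, col in OUTCOMES.items():
        y = cohort.df[col].astype(bool).to_numpy().astype(float)
        for score_name in SCORES:
            m = fit_score_logit(score_vecs[score_name], y,
                                score_name=score_name,
                                outcome_name=outcome_name)
            models[f"{score_name}|{outcome_name}"] = m
            recal_probs[(score_name, outcome_name)] = predict_probability(
                m, score_vecs[score_name])
    (out_dir / "models.json").write_text(json.dumps(
        {k: {"score_name": m.score_name, "outcome_name": m.outcome_name,
             "beta0": m.beta0, "beta1": m.beta1, "n": m.n,
             "log_likelihood": m.log_likelihood}
         for k, m in models.items()}, indent=2))

    # --- subgroup labels ------------------------------------------------------
    slices: list[tuple[str, np.ndarray]] = [
        ("Total", np.ones(len(cohort), dtype=bool))]
    if "age_band" in config.subgroups:
        bands = age_band_vector(
            cohort.df["age_months"].to_numpy(float))
        for i, name in enumerate(AGE_BANDS):
            slices.append((name.capitalize(), bands == i))
    if "hospital" in config.subgroups and "hospital" in cohort.df:
        for h in sorted(cohort.df["hospital"].dropna().unique()):
            slices.append((f"Hospital {h}",
                           (cohort.df["hospital"] == h).to_numpy()))

    # --- metric battery ---------------------------------------------------------
    rows = []
    cells = {}
    for outcome_name, col in OUTCOMES.items():
        y_all = cohort.df[col].astype(bool).to_numpy().astype(float)
        for score_name in SCORES:
            for label, mask in slices:
                rep = _cell_report(
                    score_vecs[score_name][mask],
                    orig_probs[score_name][mask],
                    recal_probs[(score_name, outcome_name)][mask],
                    y_all[mask], config,
                    derive_seed(config.seed,
                                f"boot|{score_name}|{outcome_name}|{label}"))
                cells[(outcome_name, label, score_name)] = rep
                rows.append(_report_row(outcome_name, label, score_name, rep))

    table4 = pd.DataFrame(rows)
    table4.to_csv(out_dir / "table4.csv", index=False)

    # --- DeLong comparison on the full cohort per outcome -------------------
    delong = {}
    for outcome_name, col in OUTCOMES.items():
        y = cohort.df[col].astype(bool).to_numpy().astype(float)
        auc_a, auc_b, z, p = vm.delong_compare(
            score_vecs["prism3"], score_vecs["pim3"], y)
        delong[outcome_name] = {"auc_prism3": auc_a, "auc_pim3": auc_b,
                                "z": z, "pvalue": p}

    # --- figures ----------------------------------------------------------------
    if config.make_plots:
        for outcome_name, col in OUTCOMES.items():
            y = cohort.df[col].astype(bool).to_numpy().astype(float)
            _plot_roc(score_vecs, y, out_dir / f"roc_{outcome_name}.svg",
                      f"ROC - {outcome_name.replace('_', ' ')}")
            for score_name in SCORES:
                _plot_calibration(
                    recal_probs[(score_name, outcome_name)], y,
                    out_dir / f"calibration_{outcome_name}_{score_name}.svg",
                    f"{score_name.upper()} - {outcome_name.replace('_', ' ')}")

    bundle = {
        "n_analyzed": len(cohort),
        "exclusions": tally,
        "imputation": json.loads(imp_report.to_json()),
        "models": json.loads((out_dir / "models.json").read_text()),
        "delong": delong,
        "cells": rows,
        "seed": config.seed,
    }
    (out_dir / "report.json").write_text(json.dumps(bundle, indent=2))
    logger.info("report bundle written to %s", out_dir)
    bundle["_cells"] = cells
    bundle["_cohort"] = cohort
    bundle["_scored"] = scored
    return bundle
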