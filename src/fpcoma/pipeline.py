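"""End-to-end analysis: feature table → prognostic model report.

Mirrors the full-cohort analysis chain: dichotomize the 60-day GOS, compare
all 48 features between outcome groups with BH correction, prune
amplitude-driven redundancy by RMS-controlled partial correlation, summarize
Spearman correlations with GOS, run MCA on the surviving features, and build
single-feature and stepwise-combined logistic predictors evaluated by
stratified 3-fold cross-validation with a merged-fold ROC/AUC.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, epoch_features, aggregate_patient_features
from .preprocess import preprocess_recording
from .stats import (ModelResult, compare_groups, cross_validate_model,
                    dichotomize_outcome, fit_logistic_stepwise_lr,
                    mca_discriminate, partial_correlation, spearman_with_gos,
                    UNFAVORABLE)


def cohort_feature_table(recordings, metadata: pd.DataFrame,
                         epoch_s=120.0) -> pd.DataFrame:
    """Preprocess and extract the 48-feature vector for every recording.

    ``metadata`` must carry ``subject_id`` plus clinical columns (gos,
    etiology, ...); the result has one row per patient with feature columns
    followed by the metadata.
    """
    meta = metadata.set_index("subject_id")
    rows = []
    for rec in recordings:
        retained, _ = preprocess_recording(rec, epoch_s=epoch_s)
        pf = aggregate_patient_features(
            [epoch_features(e) for e in retained],
            subject_id=rec.subject_id,
            metadata=meta.loc[rec.subject_id].to_dict())
        rows.append(pf.to_series())
    return pd.DataFrame(rows).reset_index(drop=True)


@dataclass
class CohortAnalysis:
    """All tables produced by the full-cohort prognostic analysis."""

    outcome: np.ndarray
    comparison: pd.DataFrame
    significant: list
    partial: pd.DataFrame
    pruned: list                     # features surviving partial correlation
    spearman: pd.DataFrame
    mca: object
    single_models: dict = field(default_factory=dict)   # name -> ModelResult
    stepwise_terms: list = field(default_factory=list)
    combined: ModelResult | None = None


def analyze_cohort(features: pd.DataFrame, k=3, seed=0, alpha=0.05,
                   cutoff=0.5, feature_names=FEATURE_NAMES) -> CohortAnalysis:
    """Run the complete statistical pipeline on a patient feature table.

    ``features`` needs the 48 feature columns plus ``gos`` and ``etiology``.
    """
    outcome = np.array([dichotomize_outcome(g) for g in features["gos"]])
    y = (outcome == UNFAVORABLE).astype(int)
    etiology = features["etiology"].to_numpy() if "etiology" in features \
        else None

    comparison = compare_groups(features, outcome, feature_names, alpha)
    significant = comparison.loc[comparison["p_adj"] < alpha,
                                 "feature"].tolist()

    # RMS-controlled partial correlation with GOS prunes amplitude proxies
    gos = features["gos"].to_numpy(float)
    rms = features["rms"].to_numpy(float)
    partial_rows = []
    for name in significant:
        if name == "rms":
            continue
        rho, p = partial_correlation(features[name].to_numpy(float), gos, rms)
        partial_rows.append({"feature": name, "rho": rho, "p": p})
    partial = pd.DataFrame(partial_rows, columns=["feature", "rho", "p"])
    kept = set(partial.loc[partial["p"] < alpha, "feature"])
    if "rms" in significant:
        kept.add("rms")   # RMS was the control variable, not a candidate
    pruned = [n for n in feature_names if n in kept]

    spearman = pd.DataFrame(
        [{"feature": name,
          **dict(zip(("rho", "p"),
                     spearman_with_gos(features[name].to_numpy(float), gos)))}
         for name in pruned], columns=["feature", "rho", "p"])

    mca = mca_discriminate(features[pruned], outcome) if len(pruned) >= 1 \
        else None

    analysis = CohortAnalysis(outcome, comparison, significant, partial,
                              pruned, spearman, mca)
    if not pruned:
        return analysis

    for name in pruned:
        analysis.single_models[name] = cross_validate_model(
            features, y, [name], k=k, seed=seed, etiology=etiology,
            cutoff=cutoff)

    step = fit_logistic_stepwise_lr(features[pruned].astype(float), y)
    analysis.stepwise_terms = step.terms["term"].tolist() \
        if not step.intercept_only else []
    if analysis.stepwise_terms:
        analysis.combined = cross_validate_model(
            features, y, analysis.stepwise_terms, k=k, seed=seed,
            etiology=etiology, cutoff=cutoff)
    return analysis


def report_tables(analysis: CohortAnalysis) -> dict:
    """Flatten a CohortAnalysis into named DataFrames for writing to disk."""
    out = {"comparison": analysis.comparison, "partial": analysis.partial,
           "spearman": analysis.spearman}
    if analysis.mca is not None:
        out["mca_coords"] = analysis.mca.category_coords
        out["mca_discrimination"] = analysis.mca.discrimination
    rows = []
    for name, model in analysis.single_models.items():
        for m in model.fold_metrics:
            rows.append({"predictor": name, "fold": m["fold"],
                         "sensitivity": m["sensitivity"],
                         "specificity": m["specificity"],
                         "ppv": m["ppv"], "npv": m["npv"], "fpr": m["fpr"]})
        rows.append({"predictor": name, "fold": "merged",
                     "auc": model.auc, "auc_lo": model.auc_ci[0],
                     "auc_hi": model.auc_ci[1]})
    if analysis.combined is not None:
        name = "+".join(analysis.stepwise_terms)
        for m in analysis.combined.fold_metrics:
            rows.append({"predictor": name, "fold": m["fold"],
                         "sensitivity": m["sensitivity"],
                         "specificity": m["specificity"],
                         "ppv": m["ppv"], "npv": m["npv"], "fpr": m["fpr"]})
        rows.append({"predictor": name, "fold": "merged",
                     "auc": analysis.combined.auc,
                     "auc_lo": analysis.combined.auc_ci[0],
                     "auc_hi": analysis.combined.auc_ci[1]})
    out["cv_performance"] = pd.DataFrame(rows)
    return out
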