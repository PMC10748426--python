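"""Prognostic statistics for the coma-EEG cohort.

Implements the analysis chain applied to the 48-feature table: outcome
dichotomization by 60-day GOS, group comparison with normality-gated test
selection and Benjamini-Hochberg correction, RMS-controlled partial
correlation, Spearman correlation with GOS, multiple correspondence analysis
of median-split features, logistic prognostic models with likelihood-ratio
stepwise selection, stratified 3-fold cross-validation, prognostic
characteristics at a probability cutoff, and merged-fold ROC/AUC with a
DeLong confidence interval.  The positive class is the unfavorable outcome
throughout.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.api import Logit, add_constant
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

FAVORABLE, UNFAVORABLE = "favorable", "unfavorable"


def dichotomize_outcome(gos) -> str:
    """60-day Glasgow Outcome Scale → favorable (GOS ≥ 3) / unfavorable (≤ 2)."""
    gos = int(gos)
    if gos not in (1, 2, 3, 4, 5):
        raise ValueError(f"GOS must be in 1..5, got {gos}")
    return FAVORABLE if gos >= 3 else UNFAVORABLE


def bh_adjust(pvals):
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    NaN entries are passed through and excluded from the correction.
    """
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def ttest_from_summary(m1, s1, n1, m2, s2, n2):
    """Pooled-variance two-sample t-test from printed summary statistics."""
    res = sps.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=True)
    return float(res.statistic), n1 + n2 - 2, float(res.pvalue)


def chi2_contingency(table):
    """Pearson χ² (no continuity correction) on a contingency table."""
    table = np.asarray(table, dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero marginal")
    res = sps.chi2_contingency(table, correction=False)
    return float(res[0]), int(res[2]), float(res[1])


def _mannwhitney_z(x, y):
    """Signed standardized Mann-Whitney statistic with tie correction.

    Positive when the first sample tends to take larger values.  The
    two-sided p comes from the normal approximation.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    ranks = sps.rankdata(np.concatenate([x, y]))
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    n = n1 + n2
    _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))
    sigma2 = n1 * n2 / 12 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return np.nan, np.nan
    z = (u1 - mu) / np.sqrt(sigma2)
    return float(z), float(2 * sps.norm.sf(abs(z)))


def compare_groups(features: pd.DataFrame, outcome, feature_names=None,
                   alpha=0.05) -> pd.DataFrame:
    """Per-feature two-group comparison with normality-gated test choice.

    For each feature, Shapiro-Wilk runs per group and Levene (mean-centred)
    across groups at ``alpha``; when both groups are normal with homogeneous
    variance a pooled t-test is used and groups are summarized as mean ± SD,
    otherwise a Mann-Whitney U test (standardized z, tie-corrected) with
    median (IQR) summaries.  Benjamini-Hochberg correction is applied across
    all features.  Group 1 is the favorable-outcome group.
    """
    outcome = np.asarray(outcome)
    feature_names = list(feature_names or features.columns)
    rows = []
    for name in feature_names:
        v = features[name].to_numpy(dtype=float)
        g1 = v[(outcome == FAVORABLE) & np.isfinite(v)]
        g2 = v[(outcome == UNFAVORABLE) & np.isfinite(v)]
        row = {"feature": name, "n1": len(g1), "n2": len(g2)}
        if len(g1) < 3 or len(g2) < 3 or np.concatenate([g1, g2]).var() == 0:
            row.update(test=None, statistic=np.nan, p_raw=np.nan,
                       group1=np.nan, group2=np.nan,
                       normal1=np.nan, normal2=np.nan, homoscedastic=np.nan,
                       summary1="", summary2="")
            rows.append(row)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            norm1 = g1.var() > 0 and sps.shapiro(g1).pvalue > alpha
            norm2 = g2.var() > 0 and sps.shapiro(g2).pvalue > alpha
            homo = sps.levene(g1, g2, center="mean").pvalue > alpha
        if norm1 and norm2 and homo:
            res = sps.ttest_ind(g1, g2, equal_var=True)
            row.update(test="t", statistic=float(res.statistic),
                       p_raw=float(res.pvalue),
                       summary1=f"{g1.mean():.3f} ± {g1.std(ddof=1):.3f}",
                       summary2=f"{g2.mean():.3f} ± {g2.std(ddof=1):.3f}")
        else:
            z, p = _mannwhitney_z(g1, g2)
            iqr1 = np.percentile(g1, 75) - np.percentile(g1, 25)
            iqr2 = np.percentile(g2, 75) - np.percentile(g2, 25)
            row.update(test="U", statistic=z, p_raw=p,
                       summary1=f"{np.median(g1):.3f} ({iqr1:.3f})",
                       summary2=f"{np.median(g2):.3f} ({iqr2:.3f})")
        row.update(group1=np.median(g1), group2=np.median(g2),
                   normal1=norm1, normal2=norm2, homoscedastic=homo)
        rows.append(row)
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    return out


# ------------------------------------------------------------ correlations

def partial_correlation(x, y, z, method="spearman"):
    """First-order partial correlation of x and y controlling z.

    Rank-based (Spearman flavour) by default since the outcome scale is
    ordinal; ``method="pearson"`` uses raw scores.  p from the t
    approximation on n − 3 degrees of freedom.
    """
    x, y, z = (np.asarray(a, float) for a in (x, y, z))
    n = len(x)
    if not (len(y) == len(z) == n) or n < 5:
        raise ValueError("need equal-length inputs with n >= 5")
    if method == "spearman":
        x, y, z = (sps.rankdata(a) for a in (x, y, z))
    rxy = np.corrcoef(x, y)[0, 1]
    rxz = np.corrcoef(x, z)[0, 1]
    ryz = np.corrcoef(y, z)[0, 1]
    denom = (1 - rxz ** 2) * (1 - ryz ** 2)
    if denom <= 0:
        return np.nan, np.nan
    rho = (rxy - rxz * ryz) / np.sqrt(denom)
    rho = float(np.clip(rho, -1.0, 1.0))
    df = n - 3
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt(df / (1 - rho ** 2))
    return rho, float(2 * sps.t.sf(abs(t), df))


def spearman_with_gos(values, gos):
    """Spearman rank correlation between a feature and 60-day GOS."""
    values = np.asarray(values, float)
    gos = np.asarray(gos, float)
    if len(values) < 5:
        raise ValueError("need n >= 5")
    if values.var() == 0 or gos.var() == 0:
        return np.nan, np.nan
    res = sps.spearmanr(values, gos)
    return float(res.statistic), float(res.pvalue)


# --------------------------------------------------------------------- MCA

@dataclass
class MCAResult:
    """Indicator-matrix correspondence analysis output (2 dimensions)."""

    category_coords: pd.DataFrame   # variable, category, dim1, dim2
    discrimination: pd.DataFrame    # per-variable eta^2 on dim1/dim2
    object_scores: np.ndarray       # (n, 2) standardized row scores
    inertia: np.ndarray             # principal inertias (eigenvalues)
    dropped: list = field(default_factory=list)


def mca_discriminate(features: pd.DataFrame, outcome, n_dims=2) -> MCAResult:
    """MCA of median-split features together with the outcome variable.

    Continuous columns are discretized at their within-cohort median
    (``low``/``high``); the outcome enters as its own categorical variable.
    Correspondence analysis of the resulting indicator matrix yields 2-D
    category coordinates; discrimination measures are the per-variable η² of
    the standardized object scores across that variable's categories.  The
    sign of each axis is fixed so the ``outcome=unfavorable`` category has a
    positive dimension-1 coordinate.
    """
    cats = {}
    dropped = []
    for name in features.columns:
        col = features[name]
        if col.dtype.kind in "fiu" and col.nunique() > 2:
            med = col.median()
            lab = np.where(col.to_numpy(float) > med, "high", "low")
        else:
            lab = col.astype(str).to_numpy()
        if len(pd.unique(lab)) < 2:
            dropped.append(name)
            warnings.warn(f"MCA: variable {name!r} has one category; dropped")
            continue
        cats[name] = lab
    cats["outcome"] = np.asarray(outcome, dtype=object)
    if len(cats) < 2:
        raise ValueError("MCA needs at least 2 categorical variables")

    n = len(next(iter(cats.values())))
    blocks, labels = [], []
    for name, lab in cats.items():
        dummies = pd.get_dummies(pd.Series(lab), dtype=float)
        blocks.append(dummies.to_numpy())
        labels += [(name, c) for c in dummies.columns]
    Z = np.hstack(blocks)
    Q = len(cats)
    P = Z / (n * Q)
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, s, Vt = np.linalg.svd(S, full_matrices=False)
    k = min(n_dims, (s > 1e-12).sum())
    U, s, Vt = U[:, :k], s[:k], Vt[:k]

    obj = U / np.sqrt(r)[:, None]               # standardized row scores
    cat_coords = (Vt.T / np.sqrt(c)[:, None]) * s   # principal column coords

    # fix axis signs: unfavorable outcome positive on each dimension
    unf_idx = labels.index(("outcome", UNFAVORABLE))
    for d in range(k):
        if cat_coords[unf_idx, d] < 0:
            cat_coords[:, d] *= -1
            obj[:, d] *= -1

    disc_rows = []
    for name, lab in cats.items():
        row = {"variable": name}
        for d in range(k):
            score = obj[:, d]
            tot = np.sum((score - score.mean()) ** 2)
            between = sum(
                (lab == cval).sum() * (score[lab == cval].mean() - score.mean()) ** 2
                for cval in pd.unique(lab))
            row[f"dim{d + 1}"] = float(between / tot) if tot > 0 else np.nan
        disc_rows.append(row)

    coords = pd.DataFrame(
        [{"variable": v, "category": cval,
          **{f"dim{d + 1}": cat_coords[i, d] for d in range(k)}}
         for i, (v, cval) in enumerate(labels)])
    return MCAResult(coords, pd.DataFrame(disc_rows), obj, s ** 2, dropped)


# ---------------------------------------------------------------- logistic

@dataclass
class LogisticFit:
    """A fitted logistic model reported as odds ratios with Wald 95% CIs."""

    terms: pd.DataFrame          # term, coef, or, ci_low, ci_high, p
    llf: float
    separation: bool = False
    intercept_only: bool = False
    model: object = None


def _fit_logit(X: pd.DataFrame, y):
    """Maximum-likelihood logistic fit; returns (result, separation_flag)."""
    Xc = add_constant(X.astype(float), has_constant="add")
    sep = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = Logit(np.asarray(y, float), Xc).fit(disp=0, maxiter=200)
        except Exception:
            # Newton fails under (near-)perfect separation; L-BFGS still
            # yields a usable fit with diverging-but-finite coefficients.
            try:
                res = Logit(np.asarray(y, float), Xc).fit(
                    disp=0, method="lbfgs", maxiter=500)
                sep = True
            except Exception:
                return None, True
        for w in caught:
            if "separation" in str(w.message).lower() \
                    or "convergence" in str(w.message).lower():
                sep = True
    if not np.all(np.isfinite(res.bse)) or np.any(np.abs(res.params) > 30):
        sep = True
    return res, sep


def _ridge_logit_predict(X_train, y_train, X_test, alpha=0.5):
    """Predictions from an L2-penalized logistic fit (standardized features,
    unpenalized intercept), solved by Newton iteration.

    Used to stabilize fold predictions under (near-)perfect separation,
    where the ML coefficients diverge and out-of-fold probabilities saturate
    at 0/1, destroying the rank information the merged ROC needs.
    """
    Xtr = np.asarray(X_train, float)
    Xte = np.asarray(X_test, float)
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0)
    sd[sd == 0] = 1.0
    Ztr = np.column_stack([np.ones(len(Xtr)), (Xtr - mu) / sd])
    Zte = np.column_stack([np.ones(len(Xte)), (Xte - mu) / sd])
    y = np.asarray(y_train, float)
    k = Ztr.shape[1]
    pen = alpha * np.eye(k)
    pen[0, 0] = 0.0
    beta = np.zeros(k)
    for _ in range(100):
        eta = np.clip(Ztr @ beta, -30, 30)
        p = 1 / (1 + np.exp(-eta))
        w = np.maximum(p * (1 - p), 1e-12)
        grad = Ztr.T @ (y - p) - pen @ beta
        hess = (Ztr * w[:, None]).T @ Ztr + pen
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return 1 / (1 + np.exp(-np.clip(Zte @ beta, -30, 30)))


def _terms_table(res, names):
    ci = res.conf_int()
    rows = []
    for name in names:
        coef = res.params[name]
        rows.append({"term": name, "coef": float(coef),
                     "or": float(np.exp(coef)),
                     "ci_low": float(np.exp(ci.loc[name, 0])),
                     "ci_high": float(np.exp(ci.loc[name, 1])),
                     "p": float(res.pvalues[name])})
    return pd.DataFrame(rows)


def fit_logistic_single(x, y, name="feature") -> LogisticFit:
    """Logistic regression of unfavorable outcome on one feature."""
    y = np.asarray(y, float)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    X = pd.DataFrame({name: np.asarray(x, float)})
    res, sep = _fit_logit(X, y)
    if res is None:
        return LogisticFit(pd.DataFrame([{"term": name, "coef": np.nan,
                                          "or": np.nan, "ci_low": 0.0,
                                          "ci_high": np.inf, "p": np.nan}]),
                           np.nan, separation=True)
    table = _terms_table(res, [name])
    if sep:
        table.loc[:, ["ci_low", "ci_high"]] = [0.0, np.inf]
    return LogisticFit(table, float(res.llf), separation=sep, model=res)


def fit_logistic_stepwise_lr(X: pd.DataFrame, y, p_enter=0.05,
                             p_remove=0.10) -> LogisticFit:
    """Forward stepwise logistic regression driven by likelihood-ratio tests.

    At each step the candidate whose addition gives the smallest LR-χ²
    p-value enters if p < ``p_enter`` (ties broken by input order); included
    terms whose removal LR p exceeds ``p_remove`` are pruned.  Deterministic
    given the column order of ``X``.
    """
    y = np.asarray(y, float)
    candidates = list(X.columns)
    included: list[str] = []

    def llf_of(cols):
        if not cols:
            p1 = y.mean()
            return float(len(y) * (p1 * np.log(p1) + (1 - p1) * np.log(1 - p1))) \
                if 0 < p1 < 1 else 0.0
        res, sep = _fit_logit(X[cols], y)
        return None if res is None else float(res.llf)

    current_llf = llf_of(included)
    changed = True
    while changed:
        changed = False
        # forward step
        best_p, best_var, best_llf = None, None, None
        for var in candidates:
            if var in included:
                continue
            llf = llf_of(included + [var])
            if llf is None:
                continue
            lr = max(0.0, 2 * (llf - current_llf))
            p = float(sps.chi2.sf(lr, 1))
            if best_p is None or p < best_p - 1e-12:
                best_p, best_var, best_llf = p, var, llf
        if best_var is not None and best_p < p_enter:
            included.append(best_var)
            current_llf = best_llf
            changed = True
        # backward step
        removed = True
        while removed and len(included) > 1:
            removed = False
            worst_p, worst_var, worst_llf = None, None, None
            for var in included:
                rest = [v for v in included if v != var]
                llf = llf_of(rest)
                if llf is None:
                    continue
                lr = max(0.0, 2 * (current_llf - llf))
                p = float(sps.chi2.sf(lr, 1))
                if worst_p is None or p > worst_p + 1e-12:
                    worst_p, worst_var, worst_llf = p, var, llf
            if worst_var is not None and worst_p > p_remove:
                included.remove(worst_var)
                current_llf = worst_llf
                removed = changed = True

    if not included:
        return LogisticFit(pd.DataFrame(columns=["term", "coef", "or",
                                                 "ci_low", "ci_high", "p"]),
                           current_llf, intercept_only=True)
    res, sep = _fit_logit(X[included], y)
    return LogisticFit(_terms_table(res, included), float(res.llf),
                       separation=sep, model=res)


# ---------------------------------------------------- cross-validation

def stratified_kfold(outcome, etiology=None, k=3, seed=0):
    """Greedy stratified fold assignment on outcome × etiology cells.

    Cells are processed largest first; within a cell, shuffled members are
    dealt cyclically over the folds ordered by current load, so per-cell
    counts across folds differ by at most 1 and overall fold sizes differ by
    at most 1.  Reproducible from ``seed``.
    """
    outcome = np.asarray(outcome)
    n = len(outcome)
    if n < k:
        raise ValueError("need at least k subjects")
    etiology = np.asarray(etiology) if etiology is not None else np.zeros(n)
    rng = np.random.default_rng(seed)
    cells = pd.DataFrame({"o": outcome, "e": etiology}).groupby(
        ["o", "e"], sort=True).indices
    order = sorted(cells, key=lambda key: (-len(cells[key]), str(key)))
    folds = np.empty(n, dtype=int)
    loads = np.zeros(k, dtype=int)
    for key in order:
        members = np.array(cells[key])
        rng.shuffle(members)
        fold_order = np.lexsort((rng.random(k), loads))
        for j, idx in enumerate(members):
            f = fold_order[j % k]
            folds[idx] = f
            loads[f] += 1
        # re-balance ordering after each full deal
    return folds


# ------------------------------------------- prognostic characteristics

def _wilson(count, nobs):
    if nobs == 0:
        return np.nan, (np.nan, np.nan)
    lo, hi = proportion_confint(count, nobs, alpha=0.05, method="wilson")
    return count / nobs, (float(lo), float(hi))


def prognostic_characteristics(probs, labels, cutoff=0.5) -> dict:
    """Confusion-matrix metrics of the unfavorable-outcome predictor.

    ``labels`` are 1 for unfavorable (positive class).  Predictions are
    positive when probability ≥ ``cutoff``.  Each proportion carries a Wilson
    score 95% CI; metrics with an empty denominator are NaN.
    """
    probs = np.asarray(probs, float)
    labels = np.asarray(labels, int)
    if probs.size == 0:
        raise ValueError("empty prediction set")
    pred = (probs >= cutoff).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    sen, sen_ci = _wilson(tp, tp + fn)
    spec, spec_ci = _wilson(tn, tn + fp)
    ppv, ppv_ci = _wilson(tp, tp + fp)
    npv, npv_ci = _wilson(tn, tn + fn)
    fpr, fpr_ci = _wilson(fp, fp + tn)
    return {"sensitivity": sen, "sensitivity_ci": sen_ci,
            "specificity": spec, "specificity_ci": spec_ci,
            "ppv": ppv, "ppv_ci": ppv_ci, "npv": npv, "npv_ci": npv_ci,
            "fpr": fpr, "fpr_ci": fpr_ci,
            "tp": tp, "fn": fn, "tn": tn, "fp": fp}


def _delong_auc_variance(probs, labels):
    """AUC and its DeLong variance via midranks."""
    probs = np.asarray(probs, float)
    labels = np.asarray(labels, int)
    pos = probs[labels == 1]
    neg = probs[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    tz = sps.rankdata(np.concatenate([pos, neg]))
    tx = sps.rankdata(pos)
    ty = sps.rankdata(neg)
    auc = (tz[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    return float(auc), float(var)


def roc_auc_merged(probs, labels):
    """Pooled out-of-fold AUC (rank formulation) with DeLong 95% CI."""
    auc, var = _delong_auc_variance(probs, labels)
    half = 1.959963984540054 * np.sqrt(var)
    return auc, (float(np.clip(auc - half, 0, 1)),
                 float(np.clip(auc + half, 0, 1)))


def roc_curve_points(probs, labels):
    """ROC coordinates (FPR, TPR) at every distinct threshold."""
    probs = np.asarray(probs, float)
    labels = np.asarray(labels, int)
    thresholds = np.r_[np.inf, np.unique(probs)[::-1]]
    pts = []
    for thr in thresholds:
        pred = probs >= thr
        tp = (pred & (labels == 1)).sum()
        fp = (pred & (labels == 0)).sum()
        pts.append({"threshold": thr,
                    "fpr": fp / max(1, (labels == 0).sum()),
                    "tpr": tp / max(1, (labels == 1).sum())})
    return pd.DataFrame(pts)


@dataclass
class ModelResult:
    """A prognostic model with cross-validated performance."""

    terms: pd.DataFrame
    folds: np.ndarray
    fold_metrics: list
    oof_probs: np.ndarray
    labels: np.ndarray
    auc: float
    auc_ci: tuple
    seed: int
    separation: bool = False


def cross_validate_model(features: pd.DataFrame, y, terms, k=3, seed=0,
                         etiology=None, cutoff=0.5) -> ModelResult:
    """Stratified k-fold cross-validation of a fixed-term logistic model.

    The model ``unfavorable ~ terms`` is refit on each training set; held-out
    probabilities give per-fold prognostic characteristics and are pooled
    across folds for the merged ROC/AUC (DeLong CI).  The reported term table
    comes from the all-data fit, as in a combined-cohort model report.
    """
    y = np.asarray(y, float)
    terms = list(terms)
    folds = stratified_kfold(y, etiology, k=k, seed=seed)
    oof = np.full(len(y), np.nan)
    fold_metrics = []
    any_sep = False
    for f in range(k):
        test = folds == f
        res, sep = _fit_logit(features.loc[~test, terms], y[~test])
        any_sep = any_sep or sep
        Xt = add_constant(features.loc[test, terms].astype(float),
                          has_constant="add")
        if res is None or sep:
            # separated training fold: ridge-stabilized predictions keep
            # the probability ranking informative after pooling
            oof[test] = _ridge_logit_predict(features.loc[~test, terms],
                                             y[~test],
                                             features.loc[test, terms])
        else:
            oof[test] = res.predict(Xt)
        m = prognostic_characteristics(oof[test], y[test].astype(int), cutoff)
        m["fold"] = f
        fold_metrics.append(m)
    auc, ci = roc_auc_merged(oof, y.astype(int))
    full, sep = _fit_logit(features[terms], y)
    return ModelResult(_terms_table(full, terms) if full is not None else
                       pd.DataFrame(), folds, fold_metrics, oof,
                       y.astype(int), auc, ci, seed,
                       separation=any_sep or sep)
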