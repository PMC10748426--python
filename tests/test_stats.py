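"""Statistical pipeline: test gating, FDR, correlations, MCA, logistic
models, stratified folds, prognostic characteristics and ROC/AUC."""
import numpy as np
import pandas as pd
import pytest

import oracles
from fpcoma import (bh_adjust, chi2_contingency, compare_groups,
                    cross_validate_model, dichotomize_outcome,
                    fit_logistic_single, fit_logistic_stepwise_lr,
                    mca_discriminate, partial_correlation,
                    prognostic_characteristics, roc_auc_merged,
                    spearman_with_gos, stratified_kfold, ttest_from_summary,
                    FAVORABLE, UNFAVORABLE)


class TestDichotomize:
    def test_boundaries(self):
        assert dichotomize_outcome(3) == FAVORABLE
        assert dichotomize_outcome(2) == UNFAVORABLE

    def test_cohort_distribution(self):
        """GOS counts 39/20/10/7/5 split into 22 favorable / 59 unfavorable."""
        gos = np.repeat([1, 2, 3, 4, 5], [39, 20, 10, 7, 5])
        labels = np.array([dichotomize_outcome(g) for g in gos])
        assert (labels == FAVORABLE).sum() == 22
        assert (labels == UNFAVORABLE).sum() == 59

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            dichotomize_outcome(6)


class TestBH:
    def test_stepup_hand_values(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                           [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_ties_preserved(self):
        assert np.allclose(bh_adjust([0.5] * 10), 0.5)

    def test_matches_stepup_recursion(self, rng):
        p = rng.uniform(size=30)
        assert np.allclose(bh_adjust(p), oracles.bh_stepup(list(p)))

    def test_adjusted_at_least_raw(self, rng):
        p = rng.uniform(size=25)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-12) and np.all(adj <= 1.0)

    def test_rejection_set_matches_classical_rule(self, rng):
        """adjusted p ≤ α reproduces the classical step-up rejection set."""
        p = rng.uniform(size=40) ** 2
        alpha = 0.05
        adj = bh_adjust(p)
        order = np.argsort(p)
        m = len(p)
        k = 0
        for rank, i in enumerate(order, start=1):
            if p[i] <= rank / m * alpha:
                k = rank
        classical = set(order[:k])
        assert set(np.flatnonzero(adj <= alpha)) == classical


class TestSummaryTests:
    def test_age_row_recomputation(self):
        """Printed cohort age summaries give t ≈ 0.026, p ≈ 0.980."""
        t, df, p = ttest_from_summary(49.32, 17.844, 22, 49.20, 17.966, 59)
        assert t == pytest.approx(0.026, abs=0.001)
        assert df == 79
        assert p == pytest.approx(0.980, abs=0.005)

    def test_equal_means_zero_t(self):
        t, _, p = ttest_from_summary(5.0, 1.0, 10, 5.0, 2.0, 12)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_closed_form_oracle(self):
        m1, s1, n1, m2, s2, n2 = 1.0, 1.0, 10, 0.0, 1.0, 10
        sp2 = ((n1 - 1) * s1 ** 2 + (n2 - 1) * s2 ** 2) / (n1 + n2 - 2)
        expect = (m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        t, _, _ = ttest_from_summary(m1, s1, n1, m2, s2, n2)
        assert t == pytest.approx(expect, rel=1e-12)

    def test_etiology_contingency(self):
        """Printed etiology counts give Pearson χ² ≈ 5.101 on 4 df."""
        chi2, df, _ = chi2_contingency([[6, 0, 11, 1, 4], [19, 4, 22, 9, 5]])
        assert chi2 == pytest.approx(5.101, abs=0.001)
        assert df == 4

    def test_proportional_table_zero(self):
        chi2, _, p = chi2_contingency([[10, 20], [5, 10]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_diagonal_table(self):
        chi2, df, _ = chi2_contingency([[10, 0], [0, 10]])
        assert chi2 == pytest.approx(20.0)
        assert df == 1

    def test_zero_marginal_fatal(self):
        with pytest.raises(ValueError, match="marginal"):
            chi2_contingency([[0, 5], [0, 7]])


class TestCompareGroups:
    def _frame(self, g1, g2):
        values = np.concatenate([g1, g2])
        outcome = np.array([FAVORABLE] * len(g1) + [UNFAVORABLE] * len(g2))
        return pd.DataFrame({"x": values}), outcome

    def test_normal_shift_uses_t(self):
        rng = np.random.default_rng(0)
        df, outcome = self._frame(rng.normal(0, 1, 30), rng.normal(2, 1, 30))
        out = compare_groups(df, outcome, ["x"])
        assert out.loc[0, "test"] == "t"
        assert out.loc[0, "p_adj"] < 0.05

    def test_skewed_uses_mannwhitney(self, rng):
        df, outcome = self._frame(rng.lognormal(0, 1.5, 30),
                                  rng.lognormal(0, 1.5, 30))
        out = compare_groups(df, outcome, ["x"])
        assert out.loc[0, "test"] == "U"

    def test_mannwhitney_sign_convention(self, rng):
        """Positive standardized U when the favorable group runs larger."""
        df, outcome = self._frame(rng.normal(10, 1, 25) ** 2,
                                  rng.normal(5, 1, 25) ** 2)
        out = compare_groups(df, outcome, ["x"])
        assert out.loc[0, "statistic"] > 0

    def test_null_type_i_error_controlled(self):
        """Identical groups: BH-significant calls are rare across replicates."""
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            df, outcome = self._frame(rng.normal(0, 1, 25),
                                      rng.normal(0, 1, 25))
            out = compare_groups(df, outcome, ["x"])
            hits += int(out.loc[0, "p_adj"] < 0.05)
        assert hits <= 4

    def test_zero_variance_reported_missing(self):
        df = pd.DataFrame({"x": np.ones(20)})
        outcome = np.array([FAVORABLE] * 10 + [UNFAVORABLE] * 10)
        out = compare_groups(df, outcome, ["x"])
        assert out.loc[0, "test"] is None
        assert np.isnan(out.loc[0, "p_raw"])


class TestCorrelations:
    def test_partial_identity(self, rng):
        x = rng.standard_normal(200)
        z = rng.standard_normal(200)
        rho, p = partial_correlation(x, x, z)
        assert rho == pytest.approx(1.0, abs=0.01)

    def test_partial_self_control(self, rng):
        """Controlling for (almost) itself leaves no association; the exact
        degenerate case |r_xz| = 1 is reported as missing."""
        z = rng.standard_normal(500)
        y = rng.standard_normal(500)
        x = z + 0.01 * rng.standard_normal(500)
        rho, _ = partial_correlation(x, y, z)
        assert abs(rho) < 0.1
        rho, p = partial_correlation(z, y, z)
        assert np.isnan(rho) and np.isnan(p)

    def test_partial_removes_shared_driver(self):
        rng = np.random.default_rng(4)
        z = rng.standard_normal(500)
        x = z + rng.standard_normal(500)
        y = z + rng.standard_normal(500)
        rho, _ = partial_correlation(x, y, z)
        assert abs(rho) < 0.1

    def test_partial_matches_pingouin(self, rng):
        """Cross-check both flavours against an independent implementation."""
        pingouin = pytest.importorskip("pingouin")
        x = rng.standard_normal(100)
        y = 0.5 * x + rng.standard_normal(100)
        z = 0.3 * x + rng.standard_normal(100)
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        for method in ("spearman", "pearson"):
            rho, p = partial_correlation(x, y, z, method=method)
            ref = pingouin.partial_corr(df, "x", "y", covar="z", method=method)
            assert rho == pytest.approx(ref["r"].iloc[0], abs=1e-9)
            assert p == pytest.approx(ref["p_val"].iloc[0], abs=1e-6)

    def test_spearman_monotone(self):
        rho, p = spearman_with_gos(np.arange(20.0), np.arange(20.0))
        assert rho == 1.0
        rho, _ = spearman_with_gos(np.arange(20.0), -np.arange(20.0))
        assert rho == -1.0

    def test_spearman_bivariate_normal(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(200)
        y = 0.5 * x + np.sqrt(1 - 0.25) * rng.standard_normal(200)
        rho, _ = spearman_with_gos(x, y)
        # Spearman of a Gaussian with ρ = 0.5 is (6/π) asin(ρ/2) ≈ 0.483
        assert rho == pytest.approx(0.483, abs=0.12)


class TestMCA:
    def test_perfect_association(self, rng):
        outcome = np.array([FAVORABLE] * 20 + [UNFAVORABLE] * 20)
        df = pd.DataFrame({
            "a": (outcome == UNFAVORABLE) + rng.normal(0, 1e-9, 40),
            "b": (outcome == UNFAVORABLE) + rng.normal(0, 1e-9, 40)})
        res = mca_discriminate(df, outcome)
        disc = res.discrimination.set_index("variable")["dim1"]
        assert disc["a"] == pytest.approx(1.0, abs=1e-6)
        assert disc["b"] == pytest.approx(1.0, abs=1e-6)
        unf = res.category_coords.query(
            "variable == 'outcome' and category == @UNFAVORABLE")
        assert unf["dim1"].iloc[0] > 0   # fixed sign convention

    def test_independent_variable_low_discrimination(self):
        rng = np.random.default_rng(3)
        outcome = np.array([FAVORABLE, UNFAVORABLE] * 30)
        df = pd.DataFrame({
            "signal": (outcome == UNFAVORABLE) + rng.normal(0, 1e-9, 60),
            "noise": rng.standard_normal(60)})
        res = mca_discriminate(df, outcome)
        disc = res.discrimination.set_index("variable")["dim1"]
        assert disc["signal"] > 0.9
        assert disc["noise"] < 0.3

    def test_duplicated_variable_identical_coordinates(self, rng):
        outcome = np.array([FAVORABLE, UNFAVORABLE] * 25)
        v = rng.standard_normal(50)
        df = pd.DataFrame({"a": v, "b": v.copy()})
        res = mca_discriminate(df, outcome)
        ca = res.category_coords[res.category_coords["variable"] == "a"]
        cb = res.category_coords[res.category_coords["variable"] == "b"]
        assert np.allclose(ca[["dim1", "dim2"]].to_numpy(),
                           cb[["dim1", "dim2"]].to_numpy(), atol=1e-9)

    def test_single_category_variable_dropped(self, rng):
        outcome = np.array([FAVORABLE, UNFAVORABLE] * 20)
        df = pd.DataFrame({"flat": np.ones(40),
                           "ok": rng.standard_normal(40)})
        with pytest.warns(UserWarning, match="flat"):
            res = mca_discriminate(df, outcome)
        assert res.dropped == ["flat"]


class TestLogistic:
    def test_null_feature(self, rng):
        y = np.array([0, 1] * 100)
        x = rng.standard_normal(200)
        fit = fit_logistic_single(x, y)
        assert fit.terms["or"].iloc[0] == pytest.approx(1.0, abs=0.35)
        assert fit.terms["p"].iloc[0] > 0.05

    def test_parameter_recovery(self):
        """Data from logit p = −1 + 2x recovers the slope within ±0.15."""
        rng = np.random.default_rng(42)
        x = rng.standard_normal(2000)
        prob = 1 / (1 + np.exp(-(-1 + 2 * x)))
        y = (rng.random(2000) < prob).astype(int)
        fit = fit_logistic_single(x, y)
        assert fit.terms["coef"].iloc[0] == pytest.approx(2.0, abs=0.15)
        lo, hi = fit.terms["ci_low"].iloc[0], fit.terms["ci_high"].iloc[0]
        assert lo < fit.terms["or"].iloc[0] < hi

    def test_perfect_separation_flagged(self):
        x = np.r_[np.zeros(10), np.ones(10)]
        y = np.r_[np.zeros(10), np.ones(10)].astype(int)
        fit = fit_logistic_single(x, y)
        assert fit.separation
        assert fit.terms["ci_high"].iloc[0] == np.inf

    def test_one_class_fatal(self):
        with pytest.raises(ValueError, match="both outcome classes"):
            fit_logistic_single(np.arange(10.0), np.ones(10))


class TestStepwise:
    def _signal_noise(self, seed, n=400):
        rng = np.random.default_rng(seed)
        sig = rng.standard_normal(n)
        noise = rng.standard_normal(n)
        prob = 1 / (1 + np.exp(-(-0.5 + 1.5 * sig)))
        y = (rng.random(n) < prob).astype(int)
        return pd.DataFrame({"noise": noise, "signal": sig}), y

    def test_selects_signal_not_noise(self):
        hits = 0
        for seed in range(20):
            X, y = self._signal_noise(seed)
            fit = fit_logistic_stepwise_lr(X, y)
            hits += int(fit.terms["term"].tolist() == ["signal"])
        assert hits >= 19

    def test_duplicate_feature_enters_once(self):
        X, y = self._signal_noise(0)
        X["signal_copy"] = X["signal"]
        fit = fit_logistic_stepwise_lr(X, y)
        terms = fit.terms["term"].tolist()
        assert terms.count("signal") + terms.count("signal_copy") == 1

    def test_all_noise_mostly_intercept_only(self):
        """A single noise candidate enters in ≈5% of replicates, so the
        intercept-only model is returned in ≈95%."""
        intercept_only = 0
        for seed in range(30):
            rng = np.random.default_rng(1000 + seed)
            X = pd.DataFrame({"a": rng.standard_normal(300)})
            y = (rng.random(300) < 0.5).astype(int)
            fit = fit_logistic_stepwise_lr(X, y)
            intercept_only += int(fit.intercept_only)
        assert intercept_only >= 26


class TestStratifiedKFold:
    def test_cohort_fold_sizes(self, rng):
        outcome = np.repeat([UNFAVORABLE, FAVORABLE], [59, 22])
        etiology = rng.choice(list("ABCDE"), 81)
        folds = stratified_kfold(outcome, etiology, k=3, seed=9)
        assert sorted(np.bincount(folds)) == [27, 27, 27]
        fav = np.bincount(folds[outcome == FAVORABLE], minlength=3)
        assert sorted(fav) == [7, 7, 8]

    def test_per_cell_spread_at_most_one(self, rng):
        for seed in range(5):
            n = int(rng.integers(20, 120))
            outcome = rng.choice([FAVORABLE, UNFAVORABLE], n)
            etiology = rng.choice(list("ABC"), n)
            folds = stratified_kfold(outcome, etiology, k=3, seed=seed)
            df = pd.DataFrame({"o": outcome, "e": etiology, "f": folds})
            for _, grp in df.groupby(["o", "e"]):
                counts = np.bincount(grp["f"], minlength=3)
                assert counts.max() - counts.min() <= 1
            sizes = np.bincount(folds, minlength=3)
            assert sizes.max() - sizes.min() <= 1

    def test_reproducible_from_seed(self, rng):
        outcome = rng.choice([FAVORABLE, UNFAVORABLE], 50)
        a = stratified_kfold(outcome, None, k=3, seed=7)
        b = stratified_kfold(outcome, None, k=3, seed=7)
        assert np.array_equal(a, b)


class TestPrognosticCharacteristics:
    def test_perfect_predictions(self):
        m = prognostic_characteristics([1.0, 1.0, 0.0, 0.0], [1, 1, 0, 0])
        assert m["sensitivity"] == 1.0 and m["specificity"] == 1.0
        assert m["fpr"] == 0.0

    def test_hand_counted_case(self):
        m = prognostic_characteristics([0.9, 0.6, 0.4, 0.2], [1, 1, 0, 0])
        assert (m["sensitivity"], m["specificity"], m["ppv"], m["npv"]) == \
            (1.0, 1.0, 1.0, 1.0)

    def test_constant_classifier(self):
        m = prognostic_characteristics([0.6] * 10, [1] * 5 + [0] * 5)
        assert m["sensitivity"] == 1.0
        assert m["specificity"] == 0.0
        assert m["fpr"] == 1.0

    def test_wilson_ci_contains_point(self, rng):
        probs = rng.random(50)
        labels = (rng.random(50) < 0.6).astype(int)
        m = prognostic_characteristics(probs, labels)
        for key in ("sensitivity", "specificity", "ppv", "npv", "fpr"):
            lo, hi = m[f"{key}_ci"]
            assert 0.0 <= lo <= m[key] <= hi <= 1.0
        assert m["fpr"] == pytest.approx(1 - m["specificity"])

    def test_empty_fatal(self):
        with pytest.raises(ValueError):
            prognostic_characteristics([], [])


class TestAUC:
    def test_perfect_ranking(self):
        auc, _ = roc_auc_merged([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_null_predictions(self):
        rng = np.random.default_rng(10)
        probs = rng.random(2000)
        labels = (rng.random(2000) < 0.5).astype(int)
        auc, (lo, hi) = roc_auc_merged(probs, labels)
        assert auc == pytest.approx(0.5, abs=0.03)
        assert lo < 0.5 < hi

    def test_matches_concordance_oracle(self):
        """AUC equals the concordant-pair fraction on 50 random fixtures."""
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(10, 60))
            probs = np.round(rng.random(n), 2)   # force some ties
            labels = (rng.random(n) < 0.5).astype(int)
            if labels.min() == labels.max():
                continue
            auc, _ = roc_auc_merged(probs, labels)
            assert auc == pytest.approx(
                oracles.auc_concordance(probs, labels), abs=1e-12)

    def test_complement_sums_to_one(self, rng):
        probs = rng.random(100)
        labels = (rng.random(100) < 0.4).astype(int)
        a1, _ = roc_auc_merged(probs, labels)
        a2, _ = roc_auc_merged(1 - probs, labels)
        assert a1 + a2 == pytest.approx(1.0, abs=1e-12)

    def test_matches_sklearn(self, rng):
        sk = pytest.importorskip("sklearn.metrics")
        probs = rng.random(300)
        labels = (probs + rng.normal(0, 0.3, 300) > 0.5).astype(int)
        auc, _ = roc_auc_merged(probs, labels)
        assert auc == pytest.approx(sk.roc_auc_score(labels, probs), abs=1e-12)


def test_cross_validation_smoke(rng):
    """CV of a fixed-term model returns coherent fold metrics and AUC."""
    n = 90
    x = rng.standard_normal(n)
    prob = 1 / (1 + np.exp(-1.5 * x))
    y = (rng.random(n) < prob).astype(int)
    feats = pd.DataFrame({"x": x, "z": rng.standard_normal(n)})
    res = cross_validate_model(feats, y, ["x"], k=3, seed=1)
    assert len(res.fold_metrics) == 3
    assert np.isfinite(res.oof_probs).all()
    assert 0.5 < res.auc <= 1.0
    assert res.auc_ci[0] <= res.auc <= res.auc_ci[1]
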