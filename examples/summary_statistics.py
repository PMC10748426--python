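"""Recompute cohort-level summary statistics from printed table inputs.

Demonstrates the summary-statistic utilities on the baseline characteristics
of an 81-patient comatose cohort (22 favorable / 59 unfavorable outcomes).
"""
import numpy as np

from fpcoma import chi2_contingency, dichotomize_outcome, ttest_from_summary

# pooled t-test from printed mean ± SD age summaries
t, df, p = ttest_from_summary(49.32, 17.844, 22, 49.20, 17.966, 59)
print(f"age: t = {t:.3f} on {df} df, p = {p:.3f}  (groups indistinguishable)")

# Pearson chi-square on the etiology contingency counts
chi2, df, p = chi2_contingency([[6, 0, 11, 1, 4], [19, 4, 22, 9, 5]])
print(f"etiology: chi2 = {chi2:.3f} on {df} df, p = {p:.3f}")

# dichotomize a printed outcome-scale distribution
gos = np.repeat([1, 2, 3, 4, 5], [39, 20, 10, 7, 5])
labels = [dichotomize_outcome(g) for g in gos]
print(f"outcome split: {labels.count('favorable')} favorable / "
      f"{labels.count('unfavorable')} unfavorable")
print(f"favorable-group female share: {100 * 6 / 22:.1f}%  (6 of 22)")
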