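"""Re-analyze published clinical tables from their printed summaries.

Clinical papers print group mean +- SD and n; the classic pooled one-way
ANOVA F and two-sample t are exact functions of those numbers, so the
reported statistics can be recomputed — and checked — without
subject-level data.
"""

from ssmpca import (
    GroupSummary, anova_from_summary, t_from_summary, chi_square_independence,
)

# Demographics of an essential-tremor FDG-PET cohort: healthy controls,
# a derivation patient group and a validation patient group.
age = GroupSummary(["HC", "ET1", "ET2"],
                   means=[61.1, 63.6, 68.1], sds=[6.3, 9.1, 8.2], ns=[18, 16, 8])
res = anova_from_summary(age)
print(f"age:              F({res.df[0]:.0f},{res.df[1]:.0f}) = {res.value:.3f}, "
      f"p = {res.p_value:.3f}")

tremor = GroupSummary(["HC", "ET1", "ET2"],
                      means=[0.9, 26.6, 54.9], sds=[1.8, 13.5, 21.4], ns=[12, 16, 8])
res = anova_from_summary(tremor)
print(f"tremor severity:  F({res.df[0]:.0f},{res.df[1]:.0f}) = {res.value:.3f}, "
      f"p = {res.p_value:.2g}")
# A huge F: tremor scores separate the groups, as they must.

duration = GroupSummary(["ET1", "ET2"],
                        means=[22.4, 36.1], sds=[17.9, 17.9], ns=[16, 8])
res = t_from_summary(duration)
print(f"disease duration: t({res.df[0]:.0f}) = {res.value:.3f} "
      f"(F = {res.value**2:.3f}), p = {res.p_value:.3f}")

res = chi_square_independence([[9, 9], [8, 8], [4, 4]])
print(f"gender balance:   chi2({res.df[0]:.0f}) = {res.value:.2f}, "
      f"p = {res.p_value:.2f}")
# Perfectly balanced male/female counts give chi2 = 0 exactly.
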