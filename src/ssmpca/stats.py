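"""Cohort-level inference: group tests from raw data and from printed summaries.

Clinical tables in imaging studies report group means, SDs (n-1
denominator) and sizes; the summary-statistics routines here reconstruct
the classic pooled one-way ANOVA F and two-sample t exactly from those
quantities, so printed tables can be re-analyzed without subject-level
data. Raw-data counterparts (ANOVA, Kruskal-Wallis, chi-square, paired
tests, correlations, normality checks, Bonferroni/Dunn post-hocs) wrap
the standard scipy/statsmodels machinery behind one result type.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "StatResult",
    "anova_from_summary",
    "t_from_summary",
    "chi_square_independence",
    "one_way_anova",
    "kruskal_wallis",
    "posthoc_bonferroni",
    "posthoc_dunn",
    "paired_tests",
    "correlate",
    "normality_tests",
    "summarize",
]


@dataclass
class GroupSummary:
    """Per-group mean, SD (n-1 denominator) and size, as printed in tables."""

    labels: list[str]
    means: np.ndarray
    sds: np.ndarray
    ns: np.ndarray

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=np.float64)
        self.sds = np.asarray(self.sds, dtype=np.float64)
        self.ns = np.asarray(self.ns, dtype=int)
        k = len(self.labels)
        if not (self.means.size == self.sds.size == self.ns.size == k):
            raise ValueError("labels, means, sds, ns must have equal length")
        if np.any(self.ns < 2):
            raise ValueError("every group needs n >= 2")
        if np.any(self.sds < 0):
            raise ValueError("SDs must be non-negative")


@dataclass
class StatResult:
    statistic_name: str  # F, H, t, chi2, r, rho, W, ...
    value: float
    df: tuple[float, ...] = ()
    p_value: float = np.nan

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must be in [0, 1]")


def summarize(groups: Sequence[np.ndarray], labels: Sequence[str] | None = None) -> GroupSummary:
    """GroupSummary of raw per-group data (n-1 SDs)."""
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    labels = list(labels) if labels is not None else [f"g{i}" for i in range(len(groups))]
    return GroupSummary(
        labels=labels,
        means=np.array([g.mean() for g in groups]),
        sds=np.array([g.std(ddof=1) for g in groups]),
        ns=np.array([g.size for g in groups]),
    )


def anova_from_summary(s: GroupSummary) -> StatResult:
    """Classic one-way ANOVA F from group means, SDs and sizes.

    Between-groups SS from group means around the size-weighted grand
    mean; within-groups SS = sum (n_g - 1) sd_g^2; df = (k-1, N-k).
    Identical to the raw-data pooled ANOVA when the summary is exact.
    """
    if len(s.labels) < 2:
        raise ValueError("need at least 2 groups")
    ns = s.ns.astype(np.float64)
    n_total = ns.sum()
    k = len(s.labels)
    grand = (ns * s.means).sum() / n_total
    ss_between = (ns * (s.means - grand) ** 2).sum()
    ss_within = ((ns - 1.0) * s.sds**2).sum()
    df1, df2 = k - 1.0, n_total - k
    if ss_within == 0:
        f = np.inf if ss_between > 0 else 0.0
    else:
        f = (ss_between / df1) / (ss_within / df2)
    p = float(sps.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    return StatResult("F", float(f), (df1, df2), p)


def t_from_summary(s: GroupSummary) -> StatResult:
    """Pooled-variance two-sample t from two group summaries.

    The returned result carries t with df N-2; ``F = t**2`` with df
    (1, N-2) is recoverable for comparison with ANOVA-style reporting.
    """
    if len(s.labels) != 2:
        raise ValueError("t_from_summary needs exactly 2 groups")
    n1, n2 = s.ns.astype(np.float64)
    sp2 = ((n1 - 1) * s.sds[0] ** 2 + (n2 - 1) * s.sds[1] ** 2) / (n1 + n2 - 2)
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    if se == 0:
        t = 0.0 if s.means[0] == s.means[1] else np.inf
    else:
        t = (s.means[0] - s.means[1]) / se
    df = n1 + n2 - 2.0
    p = float(2.0 * sps.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    return StatResult("t", float(t), (df,), p)


def chi_square_independence(table: np.ndarray) -> StatResult:
    """Pearson chi-square of independence, no continuity correction."""
    table = np.asarray(table, dtype=np.float64)
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise ValueError("counts must be non-negative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("degenerate margins (empty row or column)")
    res = sps.chi2_contingency(table, correction=False)
    return StatResult("chi2", float(res.statistic), (float(res.dof),), float(res.pvalue))


def one_way_anova(groups: Sequence[np.ndarray]) -> StatResult:
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs n >= 2")
    f, p = sps.f_oneway(*groups)
    n_total = sum(len(g) for g in groups)
    return StatResult("F", float(f), (len(groups) - 1.0, float(n_total - len(groups))), float(p))


def kruskal_wallis(groups: Sequence[np.ndarray]) -> StatResult:
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    h, p = sps.kruskal(*groups)
    return StatResult("H", float(h), (len(groups) - 1.0,), float(p))


def posthoc_bonferroni(
    groups: Sequence[np.ndarray],
    labels: Sequence[str] | None = None,
    test: str = "t",
) -> list[dict]:
    """All pairwise comparisons with Bonferroni-adjusted p-values.

    ``test`` is 't' (pooled two-sample t) or 'mannwhitney'. Adjusted
    p = min(1, m * raw p) with m the number of pairs.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    labels = list(labels) if labels is not None else [f"g{i}" for i in range(len(groups))]
    pairs = [(i, j) for i in range(len(groups)) for j in range(i + 1, len(groups))]
    m = len(pairs)
    out = []
    for i, j in pairs:
        if test == "t":
            stat, p = sps.ttest_ind(groups[i], groups[j], equal_var=True)
            name = "t"
        elif test == "mannwhitney":
            stat, p = sps.mannwhitneyu(groups[i], groups[j], alternative="two-sided")
            name = "U"
        else:
            raise ValueError(f"unknown test {test!r}")
        out.append(
            {
                "pair": (labels[i], labels[j]),
                "statistic_name": name,
                "statistic": float(stat),
                "p_raw": float(p),
                "p_adjusted": float(min(1.0, m * p)),
            }
        )
    return out


def posthoc_dunn(
    groups: Sequence[np.ndarray], labels: Sequence[str] | None = None
) -> list[dict]:
    """Dunn's pairwise rank tests after Kruskal-Wallis, Bonferroni corrected.

    z_ij = (Rbar_i - Rbar_j) / sqrt( (N(N+1)/12 - T) (1/n_i + 1/n_j) ),
    with tie correction T = sum(t^3 - t) / (12 (N-1)) over tie groups.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    labels = list(labels) if labels is not None else [f"g{i}" for i in range(len(groups))]
    pooled = np.concatenate([np.asarray(g, dtype=np.float64) for g in groups])
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    # Mean rank per group.
    sizes = [len(g) for g in groups]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[bounds[i] : bounds[i + 1]].mean() for i in range(len(groups))]
    _, counts = np.unique(pooled, return_counts=True)
    tie_corr = float(((counts**3 - counts).sum()) / (12.0 * (n_total - 1)))
    var_base = n_total * (n_total + 1) / 12.0 - tie_corr
    pairs = [(i, j) for i in range(len(groups)) for j in range(i + 1, len(groups))]
    m = len(pairs)
    out = []
    for i, j in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p = float(2.0 * sps.norm.sf(abs(z)))
        out.append(
            {
                "pair": (labels[i], labels[j]),
                "statistic_name": "z",
                "statistic": float(z),
                "p_raw": p,
                "p_adjusted": float(min(1.0, m * p)),
            }
        )
    return out


def paired_tests(before: np.ndarray, after: np.ndarray) -> dict[str, StatResult]:
    """Paired t-test and Wilcoxon signed-rank test on matched vectors.

    With all differences zero the signed-rank statistic is undefined;
    that case is reported as W=0 with p=1 (no evidence of change).
    """
    before = np.asarray(before, dtype=np.float64)
    after = np.asarray(after, dtype=np.float64)
    if before.size != after.size or before.size < 3:
        raise ValueError("paired vectors of equal length >= 3 required")
    t, tp = sps.ttest_rel(before, after)
    if np.isnan(t):  # zero-variance differences
        t, tp = 0.0, 1.0
    diffs = after - before
    if np.all(diffs == 0):
        w_res = StatResult("W", 0.0, (), 1.0)
    else:
        w, wp = sps.wilcoxon(before, after)
        w_res = StatResult("W", float(w), (), float(wp))
    return {
        "paired_t": StatResult("t", float(t), (float(before.size - 1),), float(tp)),
        "wilcoxon": w_res,
    }


def correlate(x: np.ndarray, y: np.ndarray, method: str = "pearson") -> StatResult:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise ValueError("vectors of equal length >= 3 required")
    if method == "pearson":
        res = sps.pearsonr(x, y)
        return StatResult("r", float(res.statistic), (float(x.size - 2),), float(res.pvalue))
    if method == "spearman":
        rho, p = sps.spearmanr(x, y)
        return StatResult("rho", float(rho), (float(x.size - 2),), float(p))
    raise ValueError("method must be 'pearson' or 'spearman'")


def normality_tests(x: np.ndarray) -> dict[str, StatResult]:
    """Shapiro-Wilk and (Lilliefors-style) Kolmogorov-Smirnov normality checks.

    Used to route group comparisons to ANOVA (normal) or Kruskal-Wallis.
    The KS test standardizes by the sample mean/SD.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 3:
        raise ValueError("n >= 3 required")
    if x.std() == 0:
        raise ValueError("constant input: normality undefined")
    sw_stat, sw_p = sps.shapiro(x)
    ks_stat, ks_p = sps.kstest((x - x.mean()) / x.std(ddof=1), "norm")
    return {
        "shapiro": StatResult("W", float(sw_stat), (), float(sw_p)),
        "ks": StatResult("D", float(ks_stat), (), float(ks_p)),
    }
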