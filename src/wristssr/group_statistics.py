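"""Group comparisons on the outcome metrics.

SNR-based metrics are compared across the four sensory-impairment groups
(severe, mild, none, control) with a classical one-way ANOVA; Tukey's honest
significant difference criterion is applied post hoc only when the omnibus
test is significant.  The within-group task effect ΔE is tested against a
zero median with a Wilcoxon signed-rank test.  All tests are two-tailed at
α = 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

ALPHA = 0.05


@dataclass
class GroupTestResult:
    metric_name: str
    test_name: str
    statistic: float
    p_value: float
    group_labels: tuple[str, ...] = ()
    pairwise_significant: list[tuple[str, str]] = field(default_factory=list)
    alpha: float = ALPHA
    n: int = 0

    def __post_init__(self):
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")


def anova_with_tukey(values_by_group: dict, alpha: float = ALPHA,
                     metric_name: str = "") -> GroupTestResult:
    """One-way ANOVA across groups; Tukey HSD pairs only when omnibus p < α.

    Groups with fewer than two observations are excluded with a warning.  A
    fully degenerate input (all values identical) reports F = 0, p = 1.
    """
    groups = {}
    for name, vals in values_by_group.items():
        vals = np.asarray(vals, float)
        vals = vals[~np.isnan(vals)]
        if len(vals) < 2:
            warnings.warn(f"group {name!r} has fewer than 2 observations; excluded")
            continue
        groups[name] = vals
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups with >= 2 observations")
    names = tuple(groups)
    arrays = [groups[n] for n in names]
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return GroupTestResult(metric_name, "one-way ANOVA", 0.0, 1.0,
                               group_labels=names, alpha=alpha, n=len(pooled))
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f_stat, p = stats.f_oneway(*arrays)
    if np.isnan(f_stat):  # zero within-group variance etc.
        f_stat, p = 0.0, 1.0
    pairs = []
    if p < alpha:
        from itertools import combinations

        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        labels = np.concatenate([[n] * len(groups[n]) for n in names])
        tk = pairwise_tukeyhsd(pooled, labels, alpha=alpha)
        # statsmodels orders rows as combinations of the sorted unique groups
        for (g1, g2), rej in zip(combinations(tk.groupsunique, 2), tk.reject):
            if rej:
                pairs.append((str(g1), str(g2)))
    return GroupTestResult(metric_name, "one-way ANOVA", float(f_stat), float(p),
                           group_labels=names, pairwise_significant=pairs,
                           alpha=alpha, n=len(pooled))


def wilcoxon_signed_rank(values, null_center: float = 0.0,
                         metric_name: str = "") -> GroupTestResult:
    """Two-tailed signed-rank test of a zero-median difference.

    Uses the exact null distribution for n ≤ 25 (no ties or zeros), otherwise
    the continuity-corrected normal approximation.  All-zero input leaves the
    test undefined (NaN p).
    """
    vals = np.asarray(values, float)
    vals = vals[~np.isnan(vals)] - null_center
    nonzero = vals[vals != 0]
    if len(nonzero) == 0:
        return GroupTestResult(metric_name, "Wilcoxon signed-rank",
                               float("nan"), float("nan"), n=len(vals))
    if len(nonzero) < 5:
        warnings.warn("fewer than 5 non-zero differences; signed-rank test weak")
    method = "exact" if len(nonzero) <= 25 else "approx"
    res = stats.wilcoxon(nonzero, alternative="two-sided", method=method,
                         correction=(method == "approx"))
    return GroupTestResult(metric_name, "Wilcoxon signed-rank",
                           float(res.statistic), float(res.pvalue), n=len(vals))


def spearman_rank(x, y, metric_name: str = "") -> GroupTestResult:
    """Tie-corrected Spearman rank correlation with a two-tailed p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    if len(x) < 5:
        warnings.warn("Spearman correlation with n < 5 is uninformative")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return GroupTestResult(metric_name, "Spearman rank correlation",
                               float("nan"), float("nan"), n=len(x))
    rho, p = stats.spearmanr(x, y)
    return GroupTestResult(metric_name, "Spearman rank correlation",
                           float(rho), float(p), n=len(x))


def paired_ttest(a, b, metric_name: str = "") -> GroupTestResult:
    """Two-tailed paired t-test on the differences a - b."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) != len(b):
        raise ValueError("paired samples must have equal length")
    if len(a) < 3:
        raise ValueError("paired t-test needs n >= 3")
    d = a - b
    if np.ptp(d) == 0:
        if np.all(d == 0):
            return GroupTestResult(metric_name, "paired t-test", 0.0, 1.0, n=len(a))
        return GroupTestResult(metric_name, "paired t-test",
                               float("nan"), float("nan"), n=len(a))
    t, p = stats.ttest_rel(a, b)
    return GroupTestResult(metric_name, "paired t-test", float(t), float(p), n=len(a))
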