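"""Group comparisons used throughout the figures.

Two-group comparisons use the unpaired t-test, defaulting to the
Welch (unequal-variance) form; three or more groups use one-way ANOVA
followed by Tukey's HSD on the studentized-range distribution.
Significance is reported both as an exact p-value and in the figure star
convention (* p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class GroupSample:
    label: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be 1-D")

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass
class TestResult:
    procedure: str
    statistic: float
    df: object
    p_value: float
    stars: str
    pairwise: Optional[Dict[Tuple[str, str], float]] = None


def stars(p: float) -> str:
    """Figure star convention for a p-value."""
    for threshold, mark in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")):
        if p < threshold:
            return mark
    return "ns"


def summarize(group: GroupSample):
    """Mean, sample (n-1) SD, and n.  SD is None at n = 1."""
    if group.n == 0:
        raise ValueError("empty group")
    mean = float(group.values.mean())
    sd = float(group.values.std(ddof=1)) if group.n > 1 else None
    return mean, sd, group.n


def unpaired_t_test(
    a: GroupSample, b: GroupSample, equal_variance: bool = False
) -> TestResult:
    """Two-sided unpaired t-test: Student form when ``equal_variance``,
    Welch-Satterthwaite otherwise (the default)."""
    if a.n < 2 or b.n < 2:
        raise ValueError("each group needs n >= 2 for a t-test")
    va, vb = a.values.var(ddof=1), b.values.var(ddof=1)
    if va == 0 and vb == 0:
        if a.values.mean() == b.values.mean():
            df = a.n + b.n - 2
            return TestResult("student-t" if equal_variance else "welch-t", 0.0, df, 1.0, "ns")
        raise ValueError("degrees of freedom undefined: both groups have zero variance")
    res = sps.ttest_ind(a.values, b.values, equal_var=equal_variance)
    name = "student-t" if equal_variance else "welch-t"
    return TestResult(name, float(res.statistic), float(res.df), float(res.pvalue), stars(res.pvalue))


def anova_tukey(groups: Sequence[GroupSample]) -> TestResult:
    """One-way ANOVA with Tukey's HSD multiple-comparison procedure.

    Returns the omnibus F with (k-1, N-k) degrees of freedom plus one
    adjusted p-value per unordered group pair.
    """
    if len(groups) < 3:
        raise ValueError("fewer than 3 groups: use unpaired_t_test instead")
    for g in groups:
        if g.n < 2:
            raise ValueError(f"group {g.label!r} needs n >= 2")
    values = [g.values for g in groups]
    k = len(groups)
    n_total = sum(g.n for g in groups)

    if all(np.ptp(v) == 0 for v in values) and np.ptp([v[0] for v in values]) == 0:
        f_stat, p = 0.0, 1.0
        pairwise = {
            (groups[i].label, groups[j].label): 1.0
            for i in range(k)
            for j in range(i + 1, k)
        }
        return TestResult("anova-tukey", f_stat, (k - 1, n_total - k), p, "ns", pairwise)

    f_stat, p = sps.f_oneway(*values)
    hsd = sps.tukey_hsd(*values)
    pairwise = {
        (groups[i].label, groups[j].label): float(hsd.pvalue[i, j])
        for i in range(k)
        for j in range(i + 1, k)
    }
    return TestResult(
        "anova-tukey", float(f_stat), (k - 1, n_total - k), float(p), stars(p), pairwise
    )


def compare_groups(
    groups: Sequence[GroupSample], equal_variance: bool = False
) -> Tuple[TestResult, pd.DataFrame]:
    """Dispatch to the t-test (2 groups) or ANOVA + Tukey (>= 3) and emit a
    tidy comparison table (group_a, group_b, procedure, statistic, df, p,
    stars)."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if len(groups) == 2:
        res = unpaired_t_test(groups[0], groups[1], equal_variance)
        rows = [
            {
                "group_a": groups[0].label,
                "group_b": groups[1].label,
                "procedure": res.procedure,
                "statistic": res.statistic,
                "df": res.df,
                "p": res.p_value,
                "stars": res.stars,
            }
        ]
    else:
        res = anova_tukey(groups)
        rows = [
            {
                "group_a": "all",
                "group_b": "all",
                "procedure": "anova-F",
                "statistic": res.statistic,
                "df": f"{res.df[0]},{res.df[1]}",
                "p": res.p_value,
                "stars": res.stars,
            }
        ]
        for (la, lb), padj in res.pairwise.items():
            rows.append(
                {
                    "group_a": la,
                    "group_b": lb,
                    "procedure": "tukey-hsd",
                    "statistic": np.nan,
                    "df": "",
                    "p": padj,
                    "stars": stars(padj),
                }
            )
    return res, pd.DataFrame(rows)
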