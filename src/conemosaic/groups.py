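"""Group summaries (mean ± SEM over fields) and two-group comparison.

The experimental unit is the animal / sampling field, not the cell: each
field contributes one value of a statistic (density, g1, CC) and groups of
3-4 fields are compared with a two-sided two-sample Student's t-test at
alpha = 0.05.  The classical pooled-variance test is the default; the
Welch variant is exposed for sensitivity when group variances are very
unequal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["GroupSummary", "ComparisonResult", "summarize", "compare_groups"]


@dataclass
class GroupSummary:
    group_label: str
    n_fields: int
    mean: float
    sem: float
    per_field_values: np.ndarray

    def __str__(self) -> str:
        return f"{self.group_label}: {self.mean:.4g} ± {self.sem:.4g} (n={self.n_fields})"


@dataclass
class ComparisonResult:
    t_statistic: float
    p_value: float
    df: float
    significant: bool
    alpha: float = 0.05
    variant: str = "pooled"


def summarize(values, label: str = "") -> GroupSummary:
    """Mean ± SEM of per-field values; SEM uses the sample (n-1) SD.

    A single field gives SEM 0 with a warning (no dispersion estimate).
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("cannot summarize an empty group")
    if x.size == 1:
        warnings.warn("group has a single field; SEM reported as 0", stacklevel=2)
        sem = 0.0
    else:
        sem = float(x.std(ddof=1) / np.sqrt(x.size))
    return GroupSummary(label, int(x.size), float(x.mean()), sem, x)


def compare_groups(
    a: GroupSummary,
    b: GroupSummary,
    alpha: float = 0.05,
    variant: str = "pooled",
) -> ComparisonResult:
    """Two-sided two-sample t-test between the per-field values of two groups.

    ``variant="pooled"`` is the classical equal-variance Student's test;
    ``"welch"`` drops the equal-variance assumption.  The t statistic is
    signed as mean(a) - mean(b).
    """
    if variant not in {"pooled", "welch"}:
        raise ValueError(f"unknown t-test variant {variant!r}")
    xa, xb = a.per_field_values, b.per_field_values
    if len(xa) < 2 or len(xb) < 2:
        raise ValueError("t-test needs at least 2 fields per group")
    res = stats.ttest_ind(xa, xb, equal_var=(variant == "pooled"))
    p = float(res.pvalue)
    return ComparisonResult(
        t_statistic=float(res.statistic),
        p_value=p,
        df=float(res.df),
        significant=bool(p < alpha),
        alpha=alpha,
        variant=variant,
    )
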