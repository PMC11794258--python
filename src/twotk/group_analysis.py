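"""Two-group comparisons from summary statistics (mean, SD, n).

Published cohort tables often report only per-group means, sample standard
deviations and sizes.  For two groups those suffice for the independent
two-sample t-test, either pooled (equal-variance; the default) or Welch.
With two groups the one-way ANOVA is the same test (F = t^2, identical p),
so one operation serves rows labelled either way and reports both
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

from scipy import stats

__all__ = ["GroupSummary", "TTestResult", "summary_ttest"]


@dataclass(frozen=True)
class GroupSummary:
    """One group's label, mean, sample SD and size."""

    label: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 2:
            raise ValueError("n must be >= 2")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    method: str  # "pooled" or "welch"

    @property
    def F(self) -> float:
        """Equivalent one-way ANOVA F statistic (two groups): t squared."""
        return self.t * self.t


def summary_ttest(a: GroupSummary, b: GroupSummary, method: str = "pooled") -> TTestResult:
    """Two-sided independent t-test from summary statistics.

    ``method="pooled"`` uses the pooled-variance statistic with
    df = n_a + n_b - 2; ``method="welch"`` uses the Welch statistic with
    Satterthwaite degrees of freedom.

    Raises
    ------
    ValueError
        On an unknown method, or when both SDs are zero (degenerate
        variance: the statistic is undefined).
    """
    if method not in ("pooled", "welch"):
        raise ValueError(f"method must be 'pooled' or 'welch', got {method!r}")
    if a.sd == 0 and b.sd == 0:
        raise ValueError("degenerate comparison: both groups have zero variance")
    res = stats.ttest_ind_from_stats(
        mean1=a.mean, std1=a.sd, nobs1=a.n,
        mean2=b.mean, std2=b.sd, nobs2=b.n,
        equal_var=(method == "pooled"),
    )
    if method == "pooled":
        df = a.n + b.n - 2
    else:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return TTestResult(t=float(res.statistic), df=float(df), p=float(res.pvalue), method=method)
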