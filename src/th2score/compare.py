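"""Two-group comparisons: t-tests, Mann-Whitney U, and automatic selection.

The automatic policy mirrors common practice for summary tables: a
Shapiro-Wilk normality gate at alpha = 0.05 on each group picks the unpaired
t-test when both groups pass, and the Mann-Whitney U-test otherwise. The
chosen test is always recorded in the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort import GroupSummary, summarize_group

__all__ = ["ComparisonResult", "t_test", "mann_whitney_u", "select_and_compare"]

#: Exact Mann-Whitney enumeration is used when n_a * n_b is at most this and
#: the pooled data has no ties.
EXACT_MW_BOUND = 400

SHAPIRO_ALPHA = 0.05


@dataclass(frozen=True)
class ComparisonResult:
    test_name: str  # student_t | welch_t | mann_whitney
    statistic: float
    p: float
    group_summaries: tuple[GroupSummary, GroupSummary]

    def __post_init__(self) -> None:
        if not 0 <= self.p <= 1:
            raise ValueError("p must be in [0, 1]")


def _arrays(a, b) -> tuple[np.ndarray, np.ndarray]:
    return np.asarray(a, dtype=float), np.asarray(b, dtype=float)


def t_test(a, b, variant: str = "welch") -> ComparisonResult:
    """Unpaired two-sided t-test (Welch by default, Student via variant)."""
    x, y = _arrays(a, b)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2 for a t-test")
    if variant == "student":
        res = stats.ttest_ind(x, y, equal_var=True)
        name = "student_t"
    elif variant == "welch":
        res = stats.ttest_ind(x, y, equal_var=False)
        name = "welch_t"
    else:
        raise ValueError(f"unknown t-test variant {variant!r}")
    return ComparisonResult(
        test_name=name,
        statistic=float(res.statistic),
        p=float(res.pvalue),
        group_summaries=(summarize_group(x), summarize_group(y)),
    )


def mann_whitney_u(a, b, mode: str = "auto") -> ComparisonResult:
    """Mann-Whitney U with mid-rank ties.

    ``exact`` enumerates the permutation distribution (requires no ties);
    ``normal_approx`` uses the tie-corrected normal approximation with
    continuity correction; ``auto`` picks exact when the data are tie-free
    and n_a * n_b <= EXACT_MW_BOUND.
    """
    x, y = _arrays(a, b)
    if x.size < 1 or y.size < 1:
        raise ValueError("each group needs n >= 1")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if mode == "auto":
        method = (
            "exact" if (not has_ties and x.size * y.size <= EXACT_MW_BOUND)
            else "asymptotic"
        )
    elif mode == "exact":
        if has_ties:
            raise ValueError("exact Mann-Whitney requires tie-free data")
        method = "exact"
    elif mode == "normal_approx":
        method = "asymptotic"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return ComparisonResult(
        test_name="mann_whitney",
        statistic=float(res.statistic),
        p=float(res.pvalue),
        group_summaries=(summarize_group(x), summarize_group(y)),
    )


def select_and_compare(
    a, b, policy: str = "auto_shapiro", t_variant: str = "welch"
) -> ComparisonResult:
    """Pick and run the comparison according to the stated policy."""
    x, y = _arrays(a, b)
    if policy == "force_t":
        return t_test(x, y, variant=t_variant)
    if policy == "force_mw":
        return mann_whitney_u(x, y)
    if policy != "auto_shapiro":
        raise ValueError(f"unknown policy {policy!r}")
    # Shapiro-Wilk needs n >= 3 and non-constant data; anything else is
    # treated as non-normal and routed to the rank test.
    def _normal(g: np.ndarray) -> bool:
        if g.size < 3 or np.ptp(g) == 0:
            return False
        return stats.shapiro(g).pvalue > SHAPIRO_ALPHA

    if _normal(x) and _normal(y):
        return t_test(x, y, variant=t_variant)
    return mann_whitney_u(x, y)
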