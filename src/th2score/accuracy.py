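"""2x2 diagnostic-accuracy machinery.

Confusion tables, the full sensitivity/specificity/PPV/NPV/likelihood-ratio
panel with confidence intervals, reconstruction of an integer 2x2 table from
published sensitivity/specificity, an exact Fisher test by full hypergeometric
enumeration, and the Pearson chi-square test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateTableError
from .render import fmt_pct, fmt_ratio, round_half_up

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionTable",
    "Metric",
    "DiagnosticMetrics",
    "confusion_table",
    "diagnostic_metrics",
    "metrics_from_rates",
    "fisher_exact",
    "chi_square_test",
    "wilson_interval",
    "clopper_pearson_interval",
]

# Relative tolerance for "at most as probable" float ties in the exact test.
_FISHER_TIE_RTOL = 1e-7


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 counts: prediction (rows) vs reference truth (columns)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n < 1:
            raise ValueError("table must contain at least one observation")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_pos(self) -> int:
        """Truth-positive margin."""
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.fp + self.tn

    @property
    def prevalence(self) -> float:
        return self.n_pos / self.n

    def as_array(self) -> np.ndarray:
        """Rows = predicted -,+ ; columns = truth -,+ (report layout)."""
        return np.array([[self.tn, self.fn], [self.fp, self.tp]], dtype=int)


@dataclass(frozen=True)
class Metric:
    """A point estimate with CI; ``value`` is None when undefined."""

    value: float | None
    ci: tuple[float, float] | None = None
    undefined_reason: str | None = None

    @property
    def defined(self) -> bool:
        return self.value is not None

    def render_pct(self, decimals: int = 1) -> str:
        if self.value is None:
            return "undef"
        return fmt_pct(self.value, decimals)

    def render(self, decimals: int = 1) -> str:
        if self.value is None:
            return "undef"
        return fmt_ratio(self.value, decimals)


@dataclass(frozen=True)
class DiagnosticMetrics:
    sensitivity: Metric
    specificity: Metric
    ppv: Metric
    npv: Metric
    lr_pos: Metric
    lr_neg: Metric
    accuracy: Metric
    youden_j: float | None
    table: ConfusionTable


def confusion_table(
    predictions: Sequence[bool] | np.ndarray, truths: Sequence[bool] | np.ndarray
) -> ConfusionTable:
    """Cross-tabulate boolean predictions against boolean truths."""
    pred = np.asarray(predictions, dtype=bool)
    truth = np.asarray(truths, dtype=bool)
    if pred.shape != truth.shape or pred.ndim != 1:
        raise ValueError(
            f"predictions and truths must be equal-length 1-D, got "
            f"{pred.shape} vs {truth.shape}"
        )
    if pred.size == 0:
        raise ValueError("need at least one observation")
    return ConfusionTable(
        tp=int(np.sum(pred & truth)),
        fp=int(np.sum(pred & ~truth)),
        fn=int(np.sum(~pred & truth)),
        tn=int(np.sum(~pred & ~truth)),
    )


def wilson_interval(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n == 0:
        return (0.0, 1.0)
    z = stats.norm.ppf(1 - alpha / 2)
    phat = k / n
    denom = 1 + z**2 / n
    centre = (phat + z**2 / (2 * n)) / denom
    half = z * np.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2)) / denom
    return (max(0.0, centre - half), min(1.0, centre + half))


def clopper_pearson_interval(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Clopper-Pearson) interval for a binomial proportion."""
    if n == 0:
        return (0.0, 1.0)
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return (lo, hi)


def _proportion(k: int, n: int, ci_method: str, alpha: float, what: str) -> Metric:
    if n == 0:
        return Metric(None, None, f"{what}: zero denominator")
    if ci_method == "wilson":
        ci = wilson_interval(k, n, alpha)
    elif ci_method == "clopper_pearson":
        ci = clopper_pearson_interval(k, n, alpha)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return Metric(k / n, ci)


def _lr_ci(
    lr: float, a: int, m: int, b: int, n: int, alpha: float
) -> tuple[float, float] | None:
    """Log-method CI for a likelihood ratio (a/m)/(b/n)."""
    if a == 0 or b == 0:
        return None  # log-method breaks down on zero cells
    z = stats.norm.ppf(1 - alpha / 2)
    se = np.sqrt(1 / a - 1 / m + 1 / b - 1 / n)
    return (float(lr * np.exp(-z * se)), float(lr * np.exp(z * se)))


def diagnostic_metrics(
    ct: ConfusionTable, ci_method: str = "wilson", alpha: float = 0.05
) -> DiagnosticMetrics:
    """Full accuracy panel from a confusion table.

    Any metric with a zero denominator (or LR with a degenerate complement)
    is returned as undefined with a reason instead of NaN.
    """
    sens = _proportion(ct.tp, ct.tp + ct.fn, ci_method, alpha, "sensitivity")
    spec = _proportion(ct.tn, ct.tn + ct.fp, ci_method, alpha, "specificity")
    ppv = _proportion(ct.tp, ct.tp + ct.fp, ci_method, alpha, "ppv")
    npv = _proportion(ct.tn, ct.tn + ct.fn, ci_method, alpha, "npv")
    acc = _proportion(ct.tp + ct.tn, ct.n, ci_method, alpha, "accuracy")

    if not (sens.defined and spec.defined):
        lr_pos = Metric(None, None, "needs both sensitivity and specificity")
        lr_neg = Metric(None, None, "needs both sensitivity and specificity")
        youden = None
    else:
        youden = sens.value + spec.value - 1.0
        if spec.value == 1.0:
            lr_pos = Metric(None, None, "specificity is 1: LR+ infinite")
        else:
            v = sens.value / (1 - spec.value)
            lr_pos = Metric(
                v, _lr_ci(v, ct.tp, ct.n_pos, ct.fp, ct.n_neg, alpha)
            )
        if spec.value == 0.0:
            lr_neg = Metric(None, None, "specificity is 0: LR- undefined")
        else:
            v = (1 - sens.value) / spec.value
            lr_neg = Metric(
                v, _lr_ci(v, ct.fn, ct.n_pos, ct.tn, ct.n_neg, alpha)
            )
    return DiagnosticMetrics(
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        accuracy=acc,
        youden_j=youden,
        table=ct,
    )


def metrics_from_rates(
    sens: float, spec: float, n_pos: int, n_neg: int,
    ci_method: str = "wilson", alpha: float = 0.05,
) -> tuple[ConfusionTable, DiagnosticMetrics]:
    """Reconstruct the integer 2x2 table implied by published rates.

    ``tp = round(sens * n_pos)`` and ``tn = round(spec * n_neg)`` with
    half-up rounding; complements fill fn/fp. The metric panel is then
    computed from the implied integer table.
    """
    if not (0 <= sens <= 1 and 0 <= spec <= 1):
        raise ValueError("sens and spec must lie in [0, 1]")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("n_pos and n_neg must be >= 1")
    tp = int(round_half_up(sens * n_pos))
    tn = int(round_half_up(spec * n_neg))
    ct = ConfusionTable(tp=tp, fp=n_neg - tn, fn=n_pos - tp, tn=tn)
    return ct, diagnostic_metrics(ct, ci_method=ci_method, alpha=alpha)


def _as_2x2(table) -> np.ndarray:
    if isinstance(table, ConfusionTable):
        arr = table.as_array()
    else:
        arr = np.asarray(table, dtype=int)
    if arr.shape != (2, 2) or np.any(arr < 0):
        raise ValueError("need a 2x2 table of non-negative counts")
    return arr


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table by full enumeration.

    With margins fixed, every feasible table is indexed by its (0,0) cell;
    the p-value sums the hypergeometric probabilities of all tables at most
    as probable as the observed one (small relative tolerance for float
    ties). A zero margin returns p = 1 with a warning.
    """
    t = _as_2x2(table)
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n = a + b + c + d
    row0, col0 = a + b, a + c
    if row0 == 0 or row0 == n or col0 == 0 or col0 == n:
        warnings.warn("fisher_exact: degenerate margin, returning p = 1")
        return 1.0
    lo = max(0, row0 + col0 - n)
    hi = min(row0, col0)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, col0, row0)
    p_obs = pmf[a - lo]
    p = float(np.sum(pmf[pmf <= p_obs * (1 + _FISHER_TIE_RTOL)]))
    if p >= 1.0 - 1e-12:  # full support included: exactly 1 up to float sum
        return 1.0
    return p


def chi_square_test(table, correction: bool = False) -> dict:
    """Pearson chi-square test of independence for an r x c count table.

    No continuity correction by default; Yates correction (2x2 only) via the
    ``correction`` flag.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or np.any(obs < 0):
        raise ValueError("need a 2-D table of non-negative counts")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise DegenerateTableError("chi_square_test: zero row or column margin")
    expected = np.outer(rows, cols) / obs.sum()
    diff = np.abs(obs - expected)
    if correction:
        if obs.shape != (2, 2):
            raise ValueError("continuity correction applies to 2x2 tables only")
        diff = np.maximum(diff - 0.5, 0.0)
    statistic = float(np.sum(diff**2 / expected))
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return {
        "statistic": statistic,
        "df": df,
        "p": float(stats.chi2.sf(statistic, df)),
    }
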