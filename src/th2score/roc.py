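"""Empirical ROC curves, AUC with DeLong/bootstrap CIs, and Youden cutoffs.

Candidate cutoffs are the unique observed values (classification rule
``value >= threshold`` under the higher-positive orientation) plus a +inf
sentinel, so the curve always contains the (0,1) and (1,0) endpoints in
(1-spec, sens) space. Tied values collapse to a single operating point.
The AUC is computed by trapezoidal integration and cross-checked against
the Mann-Whitney pair statistic (ties count 1/2); the two must agree to
machine precision on every input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["RocCurve", "AucResult", "empirical_roc", "auc", "youden_optimal"]


@dataclass(frozen=True)
class RocCurve:
    thresholds: np.ndarray  # descending, thresholds[0] = +inf sentinel
    sens: np.ndarray
    spec: np.ndarray
    orientation: str = "higher_positive"

    def operating_point(self, threshold: float) -> tuple[float, float]:
        """(sens, spec) at a given threshold (must be on the curve)."""
        idx = np.where(np.isclose(self.thresholds, threshold))[0]
        if idx.size == 0:
            raise ValueError(f"threshold {threshold} not on the curve")
        return float(self.sens[idx[0]]), float(self.spec[idx[0]])


@dataclass(frozen=True)
class AucResult:
    auc: float
    ci: tuple[float, float]
    se: float
    p_value: float  # H0: AUC = 0.5, normal reference on the DeLong SE
    method: str = "trapezoid"
    ci_method: str = "delong"


def _validate(values, labels) -> tuple[np.ndarray, np.ndarray]:
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if v.shape != y.shape or v.ndim != 1:
        raise ValueError("values and labels must be equal-length 1-D")
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    return v, y


def empirical_roc(
    values, labels, orientation: str = "higher_positive"
) -> RocCurve:
    """Empirical ROC over the unique observed values as candidate cutoffs."""
    v, y = _validate(values, labels)
    if orientation == "lower_positive":
        inner = empirical_roc(-v, y, "higher_positive")
        return RocCurve(-inner.thresholds, inner.sens, inner.spec, orientation)
    if orientation != "higher_positive":
        raise ValueError(f"unknown orientation {orientation!r}")

    uniq = np.unique(v)[::-1]  # descending
    thresholds = np.concatenate(([np.inf], uniq))
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    # value >= t for each candidate t: cumulative class counts down the sort
    pos_sorted = np.sort(v[y])[::-1]
    neg_sorted = np.sort(v[~y])[::-1]
    tp = np.searchsorted(-pos_sorted, -thresholds, side="right")
    fp = np.searchsorted(-neg_sorted, -thresholds, side="right")
    sens = tp / n_pos
    spec = 1.0 - fp / n_neg
    return RocCurve(thresholds, sens, spec, orientation)


def _mann_whitney_auc(v: np.ndarray, y: np.ndarray) -> float:
    """Rank-based AUC: P(pos > neg) + 0.5 P(pos = neg)."""
    ranks = stats.rankdata(v)  # mid-ranks handle ties
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def _delong_variance(v: np.ndarray, y: np.ndarray) -> float:
    """DeLong variance of the empirical AUC via placement values."""
    pos, neg = v[y], v[~y]
    m, n = pos.size, neg.size
    # V10_i = fraction of negatives beaten by pos_i (ties 1/2); V01 symmetric
    neg_sorted = np.sort(neg)
    below = np.searchsorted(neg_sorted, pos, side="left")
    at_or_below = np.searchsorted(neg_sorted, pos, side="right")
    v10 = (below + 0.5 * (at_or_below - below)) / n
    pos_sorted = np.sort(pos)
    above = m - np.searchsorted(pos_sorted, neg, side="right")
    at = np.searchsorted(pos_sorted, neg, side="right") - np.searchsorted(
        pos_sorted, neg, side="left"
    )
    v01 = (above + 0.5 * at) / m
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return float(s10 / m + s01 / n)


def auc(
    values,
    labels,
    orientation: str = "higher_positive",
    ci_method: str = "delong",
    alpha: float = 0.05,
    n_boot: int = 2000,
    rng: np.random.Generator | None = None,
) -> AucResult:
    """Empirical AUC with a DeLong (default) or stratified-bootstrap CI."""
    v, y = _validate(values, labels)
    if orientation == "lower_positive":
        v = -v
    elif orientation != "higher_positive":
        raise ValueError(f"unknown orientation {orientation!r}")

    curve = empirical_roc(v, y)
    fpr = 1.0 - curve.spec
    a_trap = float(np.trapezoid(curve.sens, fpr))
    a_mw = _mann_whitney_auc(v, y)
    if not np.isclose(a_trap, a_mw, rtol=0, atol=1e-10):
        raise AssertionError(
            f"internal AUC cross-check failed: trapezoid {a_trap} vs MW {a_mw}"
        )

    var = _delong_variance(v, y)
    se = float(np.sqrt(var))
    z = stats.norm.ppf(1 - alpha / 2)
    if ci_method == "delong":
        ci = (max(0.0, a_mw - z * se), min(1.0, a_mw + z * se))
    elif ci_method == "bootstrap":
        rng = rng or np.random.default_rng()
        pos, neg = v[y], v[~y]
        reps = np.empty(n_boot)
        for i in range(n_boot):
            bp = rng.choice(pos, pos.size, replace=True)
            bn = rng.choice(neg, neg.size, replace=True)
            reps[i] = _mann_whitney_auc(
                np.concatenate([bp, bn]),
                np.concatenate(
                    [np.ones(bp.size, bool), np.zeros(bn.size, bool)]
                ),
            )
        ci = (
            float(np.quantile(reps, alpha / 2)),
            float(np.quantile(reps, 1 - alpha / 2)),
        )
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    p_value = 1.0 if se == 0 and a_mw == 0.5 else (
        0.0 if se == 0 else float(2 * stats.norm.sf(abs(a_mw - 0.5) / se))
    )
    return AucResult(
        auc=a_mw, ci=ci, se=se, p_value=p_value, method="trapezoid",
        ci_method=ci_method,
    )


def youden_optimal(roc: RocCurve) -> dict:
    """Threshold maximizing J = sens + spec - 1.

    Ties are broken toward higher specificity, then toward the lower
    threshold, deterministically.
    """
    j = roc.sens + roc.spec - 1.0
    best = j.max()
    candidates = np.where(np.isclose(j, best, rtol=0, atol=1e-12))[0]
    # highest specificity first, then lowest threshold
    order = sorted(
        candidates, key=lambda i: (-roc.spec[i], roc.thresholds[i])
    )
    i = order[0]
    return {
        "cutoff": float(roc.thresholds[i]),
        "j": float(j[i]),
        "sens": float(roc.sens[i]),
        "spec": float(roc.spec[i]),
    }
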