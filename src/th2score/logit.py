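"""Binomial logistic regression by IRLS, written from first principles.

Newton-Raphson on the binomial log-likelihood with step-halving, Wald
inference from the inverse observed information, odds ratios with CIs,
Nagelkerke's pseudo-R-squared, the likelihood-ratio model chi-square, and
classification accuracy at probability 0.5. Quasi-separation is detected
and reported as non-convergence rather than crashing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "LogisticFit",
    "fit_logistic",
    "nagelkerke_r2",
    "classification_accuracy",
    "predict_proba",
]

# |beta| beyond this on a standardized-ish scale signals quasi-separation
_SEPARATION_COEF_BOUND = 30.0


@dataclass(frozen=True)
class LogisticFit:
    names: tuple[str, ...]          # includes "intercept" first
    coefficients: np.ndarray        # log-odds scale
    standard_errors: np.ndarray
    odds_ratios: np.ndarray
    or_ci: np.ndarray               # shape (k, 2)
    wald_z: np.ndarray
    wald_p: np.ndarray
    log_likelihood: float
    null_log_likelihood: float
    model_chi2: float
    model_df: int
    model_p: float
    nagelkerke: float
    pct_correct: float
    converged: bool
    n_iter: int
    n_obs: int


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))


def _log_likelihood(y: np.ndarray, p: np.ndarray) -> float:
    eps = 1e-300
    return float(np.sum(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))


def _design(X, names, add_intercept: bool) -> tuple[np.ndarray, list[str]]:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    if names is None:
        names = [f"x{j + 1}" for j in range(X.shape[1])]
    names = list(names)
    if len(names) != X.shape[1]:
        raise ValueError("names length must match number of predictors")
    if add_intercept:
        X = np.column_stack([np.ones(X.shape[0]), X])
        names = ["intercept"] + names
    return X, names


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    start = 1 if names and names[0] == "intercept" else 0
    for j in range(start, X.shape[1]):
        if np.ptp(X[:, j]) == 0:
            raise ValueError(f"predictor {names[j]!r} is constant")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via QR pivoting on the gram matrix
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = [names[j] for j in range(X.shape[1]) if diag[j] < 1e-8 * diag.max()]
        raise ValueError(
            f"design matrix is rank-deficient (rank {rank} < {X.shape[1]}); "
            f"collinear column(s): {bad or 'undetermined'}"
        )


def fit_logistic(
    y,
    X,
    names: list[str] | None = None,
    *,
    add_intercept: bool = True,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> LogisticFit:
    """Maximum-likelihood logistic fit of boolean ``y`` on predictors ``X``.

    Iterates Newton steps on the log-likelihood with step-halving when a
    step would decrease it; stops when the score norm or the coefficient
    change falls below ``tol``. Standard errors come from the inverse
    observed information at the optimum.
    """
    y = np.asarray(y, dtype=float).ravel()
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("y must be binary 0/1 (or boolean)")
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("y must contain both classes")
    Xd, allnames = _design(X, names, add_intercept)
    n, k = Xd.shape
    if n <= k:
        raise ValueError(f"need n > number of parameters ({n} <= {k})")
    _check_rank(Xd, allnames)

    beta = np.zeros(k)
    p = _sigmoid(Xd @ beta)
    ll = _log_likelihood(y, p)
    converged = False
    separated = False
    it = 0
    for it in range(1, max_iter + 1):
        w = p * (1 - p)
        score = Xd.T @ (y - p)
        info = (Xd * w[:, None]).T @ Xd
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            separated = True
            break
        # step-halving: never accept a likelihood decrease
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            p_cand = _sigmoid(Xd @ cand)
            ll_cand = _log_likelihood(y, p_cand)
            if ll_cand >= ll - 1e-12:
                break
            factor /= 2.0
        delta = cand - beta
        beta, p, ll = cand, p_cand, ll_cand
        if np.max(np.abs(beta)) > _SEPARATION_COEF_BOUND:
            separated = True
            break
        if np.max(np.abs(score)) < tol or np.max(np.abs(delta)) < tol:
            converged = True
            break
    if separated:
        warnings.warn(
            "fit_logistic: coefficients diverging — data are (quasi-)separated; "
            "reporting the last iterate with converged=False"
        )

    w = p * (1 - p)
    info = (Xd * w[:, None]).T @ Xd
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)

    z975 = stats.norm.ppf(0.975)
    wald_z = beta / se
    wald_p = 2 * stats.norm.sf(np.abs(wald_z))
    or_ci = np.column_stack(
        [np.exp(beta - z975 * se), np.exp(beta + z975 * se)]
    )

    # intercept-only null model has closed-form MLE at the base rate
    pbar = y.mean()
    ll0 = float(y.size * (pbar * np.log(pbar) + (1 - pbar) * np.log(1 - pbar)))
    chi2 = max(0.0, 2 * (ll - ll0))
    model_df = k - 1
    model_p = float(stats.chi2.sf(chi2, model_df)) if model_df > 0 else 1.0

    yhat = (p >= 0.5).astype(float)
    pct_correct = float(np.mean(yhat == y))

    return LogisticFit(
        names=tuple(allnames),
        coefficients=beta,
        standard_errors=se,
        odds_ratios=np.exp(beta),
        or_ci=or_ci,
        wald_z=wald_z,
        wald_p=wald_p,
        log_likelihood=ll,
        null_log_likelihood=ll0,
        model_chi2=chi2,
        model_df=model_df,
        model_p=model_p,
        nagelkerke=nagelkerke_r2(ll, ll0, n),
        pct_correct=pct_correct,
        converged=converged,
        n_iter=it,
        n_obs=n,
    )


def nagelkerke_r2(ll: float, ll0: float, n: int) -> float:
    """Nagelkerke's rescaling of the Cox-Snell pseudo-R-squared."""
    if ll < ll0 - 1e-9:
        raise ValueError("ll must be >= ll0 (fit is not at the MLE)")
    r2_cs = 1.0 - np.exp(2.0 * (ll0 - ll) / n)
    denom = 1.0 - np.exp(2.0 * ll0 / n)
    if denom == 0:
        return 0.0
    return float(min(1.0, max(0.0, r2_cs / denom)))


def predict_proba(fit: LogisticFit, X, *, add_intercept: bool = True) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    if add_intercept:
        X = np.column_stack([np.ones(X.shape[0]), X])
    if X.shape[1] != fit.coefficients.size:
        raise ValueError("X has the wrong number of columns for this fit")
    return _sigmoid(X @ fit.coefficients)


def classification_accuracy(
    fit: LogisticFit, X, y, threshold: float = 0.5, *, add_intercept: bool = True
) -> float:
    """Fraction of observations whose 0.5-thresholded prediction matches y."""
    y = np.asarray(y, dtype=float).ravel()
    p = predict_proba(fit, X, add_intercept=add_intercept)
    return float(np.mean((p >= threshold).astype(float) == y))
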