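"""End-to-end analysis orchestration with reproducible run manifests.

One run writes one output directory: the scored cohort, a two-group
comparison table, the score/diagnosis cross-tabulation with its Fisher
exact p, the per-threshold diagnostic-metric panel, per-marker AUC table,
and a logistic-model summary, plus a manifest from which the whole report
can be regenerated bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .accuracy import confusion_table, diagnostic_metrics, fisher_exact
from .cohort import Cohort, cohort_counts, read_cohort, summarize_group
from .compare import select_and_compare
from .errors import Th2ScoreError
from .logit import fit_logistic
from .roc import auc as roc_auc
from .roc import empirical_roc, youden_optimal
from .scoring import CutoffConfig, classify, score_cohort
from .simulate import (
    GroupSpec,
    SyntheticCohortSpec,
    default_spec,
    generate_cohort,
    lognormal_from_quartiles,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "AnalysisReport", "run_analysis"]

_CONTINUOUS_MARKERS = ("feno", "ige", "bec")


@dataclass(frozen=True)
class RunConfig:
    """Declarative description of one analysis run."""

    input_csv: str | None = None
    synthetic: SyntheticCohortSpec | None = None
    cutoffs: CutoffConfig = field(default_factory=CutoffConfig)
    thresholds: tuple[int, ...] = (1, 2, 3, 4)
    crosstab_threshold: int = 3
    ci_method: str = "wilson"
    alpha: float = 0.05
    compare_policy: str = "auto_shapiro"
    roc_markers: tuple[str, ...] = ("feno", "ige", "bec", "composite_score")
    logit_predictors: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.input_csv is None) == (self.synthetic is None):
            raise ValueError(
                "exactly one input source (input_csv or synthetic) is required"
            )
        known = set(_CONTINUOUS_MARKERS) | {"composite_score"}
        bad = [m for m in self.roc_markers if m not in known]
        if bad:
            raise ValueError(f"unknown ROC marker(s): {bad}")
        for t in self.thresholds:
            if t not in (1, 2, 3, 4):
                raise ValueError(f"score threshold out of range: {t}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        synthetic = d.pop("synthetic", None)
        if synthetic is not None:
            if synthetic == "defaults":
                synthetic = default_spec(seed=int(d.get("seed", 0)))
            else:
                synthetic = _spec_from_dict(synthetic)
        cutoffs = d.pop("cutoffs", None)
        kwargs = dict(
            input_csv=d.pop("input_csv", None),
            synthetic=synthetic,
        )
        if cutoffs:
            kwargs["cutoffs"] = CutoffConfig(**cutoffs)
        for key in (
            "thresholds", "crosstab_threshold", "ci_method", "alpha",
            "compare_policy", "roc_markers", "logit_predictors", "seed",
        ):
            if key in d:
                v = d.pop(key)
                if key in ("thresholds", "roc_markers", "logit_predictors") and v is not None:
                    v = tuple(v)
                kwargs[key] = v
        if d:
            raise ValueError(f"unknown config keys: {sorted(d)}")
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _spec_from_dict(d: dict) -> SyntheticCohortSpec:
    def group(g: dict) -> GroupSpec:
        g = dict(g)
        for marker in _CONTINUOUS_MARKERS:
            m = g[marker]
            if isinstance(m, dict) and "median" in m:
                g[marker] = lognormal_from_quartiles(m["median"], m["q1"], m["q3"])
            elif isinstance(m, dict):
                from .simulate import LognormalSpec

                g[marker] = LognormalSpec(**m)
        return GroupSpec(**g)

    d = dict(d)
    return SyntheticCohortSpec(
        no_asthma=group(d.pop("no_asthma")),
        asthma=group(d.pop("asthma")),
        **d,
    )


@dataclass
class AnalysisReport:
    counts: dict
    group_compare: pd.DataFrame
    crosstab: pd.DataFrame
    fisher_p: float
    diagnostics: pd.DataFrame
    auc_table: pd.DataFrame
    logit_summary: pd.DataFrame | None
    logit_stats: dict | None
    manifest: dict
    scored: pd.DataFrame


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _load_cohort(cfg: RunConfig) -> Cohort:
    if cfg.input_csv is not None:
        return read_cohort(cfg.input_csv)
    return generate_cohort(cfg.synthetic)


def _group_compare_table(cohort: Cohort, scored: pd.DataFrame, policy: str) -> pd.DataFrame:
    neg_mask = scored["asthma"] == 0
    rows = []
    variables = list(_CONTINUOUS_MARKERS) + ["composite_score"]
    for opt in ("weight", "fev1_pct"):
        col = pd.to_numeric(scored[opt], errors="coerce")
        if col.notna().all():
            variables.insert(3, opt)
    for var in variables:
        col = pd.to_numeric(scored[var], errors="coerce")
        a = col[neg_mask].to_numpy(float)
        b = col[~neg_mask].to_numpy(float)
        res = select_and_compare(a, b, policy=policy)
        s0, s1 = res.group_summaries
        if res.test_name == "mann_whitney":
            r0, r1 = s0.render_median_iqr(), s1.render_median_iqr()
        else:
            r0, r1 = s0.render_mean_sd(), s1.render_mean_sd()
        rows.append(
            {
                "variable": var,
                "no_asthma": r0,
                "asthma": r1,
                "test": res.test_name,
                "statistic": round(res.statistic, 6),
                "p": round(res.p, 6),
            }
        )
    # prick positivity is categorical: Fisher exact on the 2x2 counts
    prick = scored["prick"].astype(int)
    n0, n1 = int(neg_mask.sum()), int((~neg_mask).sum())
    k0, k1 = int(prick[neg_mask].sum()), int(prick[~neg_mask].sum())
    p_fisher = fisher_exact([[k0, k1], [n0 - k0, n1 - k1]])
    rows.append(
        {
            "variable": "prick_positive",
            "no_asthma": f"{k0}/{n0}",
            "asthma": f"{k1}/{n1}",
            "test": "fisher",
            "statistic": float("nan"),
            "p": round(p_fisher, 6),
        }
    )
    return pd.DataFrame(rows)


def _crosstab(scored: pd.DataFrame, threshold: int) -> tuple[pd.DataFrame, float]:
    score = scored["composite_score"].astype(int)
    asthma = scored["asthma"].astype(bool)
    pos_rule = score >= threshold
    tab = pd.DataFrame(
        {
            "no_asthma": [
                int((~pos_rule & ~asthma).sum()),
                int((pos_rule & ~asthma).sum()),
            ],
            "asthma": [
                int((~pos_rule & asthma).sum()),
                int((pos_rule & asthma).sum()),
            ],
        },
        index=[f"score<={threshold - 1}", f"score>={threshold}"],
    )
    p = fisher_exact(tab.to_numpy())
    return tab, p


def _diagnostics_table(
    scored: pd.DataFrame, thresholds, ci_method: str, alpha: float
) -> pd.DataFrame:
    asthma = scored["asthma"].astype(bool).to_numpy()
    score = scored["composite_score"].astype(int).to_numpy()
    rows = []
    for t in thresholds:
        pred = np.array([classify(int(s), t) for s in score])
        dm = diagnostic_metrics(
            confusion_table(pred, asthma), ci_method=ci_method, alpha=alpha
        )
        ct = dm.table
        rows.append(
            {
                "threshold": t,
                "tp": ct.tp,
                "fp": ct.fp,
                "fn": ct.fn,
                "tn": ct.tn,
                "sensitivity": dm.sensitivity.render_pct(),
                "specificity": dm.specificity.render_pct(),
                "ppv": dm.ppv.render_pct(),
                "npv": dm.npv.render_pct(),
                "lr_pos": dm.lr_pos.render(),
                "lr_neg": dm.lr_neg.render(),
                "accuracy": dm.accuracy.render_pct(),
                "youden_j": round(dm.youden_j, 4) if dm.youden_j is not None else "",
            }
        )
    return pd.DataFrame(rows)


def _auc_table(scored: pd.DataFrame, markers, seed: int) -> pd.DataFrame:
    asthma = scored["asthma"].astype(bool).to_numpy()
    rows = []
    for marker in markers:
        values = pd.to_numeric(scored[marker]).to_numpy(float)
        res = roc_auc(values, asthma, rng=np.random.default_rng(seed))
        opt = youden_optimal(empirical_roc(values, asthma))
        rows.append(
            {
                "marker": marker,
                "auc": round(res.auc, 4),
                "ci_lo": round(res.ci[0], 4),
                "ci_hi": round(res.ci[1], 4),
                "p_vs_chance": round(res.p_value, 6),
                "youden_cutoff": opt["cutoff"],
                "youden_j": round(opt["j"], 4),
                "youden_sens": round(opt["sens"], 4),
                "youden_spec": round(opt["spec"], 4),
            }
        )
    return pd.DataFrame(rows)


def _default_logit_predictors(scored: pd.DataFrame) -> tuple[str, ...]:
    full = ("sex_female", "weight", "fev1_pct", "composite_score")
    sex_ok = scored["sex"].isin(["male", "female"]).all()
    weight_ok = pd.to_numeric(scored["weight"], errors="coerce").notna().all()
    fev_ok = pd.to_numeric(scored["fev1_pct"], errors="coerce").notna().all()
    if sex_ok and weight_ok and fev_ok:
        return full
    logger.info(
        "covariates incomplete; logistic model uses the composite score only"
    )
    return ("composite_score",)


def _logit_design(scored: pd.DataFrame, predictors) -> np.ndarray:
    cols = []
    for name in predictors:
        if name == "sex_female":
            if not scored["sex"].isin(["male", "female"]).all():
                raise Th2ScoreError(
                    "predictor 'sex_female' requested but sex is missing for "
                    "some participants"
                )
            cols.append((scored["sex"] == "female").astype(float).to_numpy())
        else:
            col = pd.to_numeric(scored[name], errors="coerce")
            if col.isna().any():
                raise Th2ScoreError(
                    f"predictor {name!r} requested but missing for some rows"
                )
            cols.append(col.to_numpy(float))
    return np.column_stack(cols)


def _logit_tables(
    scored: pd.DataFrame, predictors
) -> tuple[pd.DataFrame, dict]:
    y = scored["asthma"].astype(int).to_numpy()
    X = _logit_design(scored, predictors)
    fit = fit_logistic(y, X, names=list(predictors))
    table = pd.DataFrame(
        {
            "predictor": fit.names,
            "coef": np.round(fit.coefficients, 6),
            "se": np.round(fit.standard_errors, 6),
            "odds_ratio": np.round(fit.odds_ratios, 4),
            "or_ci_lo": np.round(fit.or_ci[:, 0], 4),
            "or_ci_hi": np.round(fit.or_ci[:, 1], 4),
            "wald_p": np.round(fit.wald_p, 6),
        }
    )
    fit_stats = {
        "model_chi2": round(fit.model_chi2, 4),
        "model_df": fit.model_df,
        "model_p": round(fit.model_p, 6),
        "nagelkerke_r2": round(fit.nagelkerke, 4),
        "pct_correct": round(fit.pct_correct, 4),
        "converged": fit.converged,
        "n_iter": fit.n_iter,
        "n_obs": fit.n_obs,
    }
    return table, fit_stats


def run_analysis(cfg: RunConfig, out_dir: str | Path | None = None) -> AnalysisReport:
    """Execute the full pipeline; optionally write all outputs to ``out_dir``.

    Outputs are deterministic functions of the config (including its seed),
    so rerunning with the same config regenerates every file bit-identically.
    On failure any partially written files are removed.
    """
    cohort = _load_cohort(cfg)
    logger.info("loaded cohort: %d participants", len(cohort))
    counts = cohort_counts(cohort)
    if counts["n_pos"] == 0 or counts["n_neg"] == 0:
        raise Th2ScoreError("both diagnosis classes are required for analysis")

    scored = score_cohort(cohort, cfg.cutoffs)
    group_tbl = _group_compare_table(cohort, scored, cfg.compare_policy)
    crosstab, fisher_p = _crosstab(scored, cfg.crosstab_threshold)
    diag_tbl = _diagnostics_table(scored, cfg.thresholds, cfg.ci_method, cfg.alpha)
    auc_tbl = _auc_table(scored, cfg.roc_markers, cfg.seed)

    predictors = cfg.logit_predictors or _default_logit_predictors(scored)
    logit_tbl, logit_stats = _logit_tables(scored, predictors)

    manifest = {
        "package": "th2score",
        "version": __version__,
        "config": cfg.to_dict(),
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "n_participants": counts["n_total"],
        "logit_predictors": list(predictors),
    }
    report = AnalysisReport(
        counts=counts,
        group_compare=group_tbl,
        crosstab=crosstab,
        fisher_p=fisher_p,
        diagnostics=diag_tbl,
        auc_table=auc_tbl,
        logit_summary=logit_tbl,
        logit_stats=logit_stats,
        manifest=manifest,
        scored=scored,
    )
    if out_dir is not None:
        _write_report(report, Path(out_dir))
    return report


def _write_report(report: AnalysisReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _w(name: str, writer) -> None:
        path = out_dir / name
        writer(path)
        written.append(path)

    try:
        _w("scored.csv", lambda p: report.scored.to_csv(p, index=False))
        _w(
            "group_compare.csv",
            lambda p: report.group_compare.to_csv(p, index=False),
        )
        _w("crosstab.csv", lambda p: report.crosstab.to_csv(p))
        _w(
            "diagnostics.csv",
            lambda p: report.diagnostics.to_csv(p, index=False),
        )
        _w("auc.csv", lambda p: report.auc_table.to_csv(p, index=False))
        if report.logit_summary is not None:
            _w(
                "logit.csv",
                lambda p: report.logit_summary.to_csv(p, index=False),
            )
        summary = {
            "counts": report.counts,
            "fisher_p_crosstab": report.fisher_p,
            "logit_stats": report.logit_stats,
        }
        _w(
            "summary.json",
            lambda p: p.write_text(
                json.dumps(summary, indent=2, sort_keys=True, default=str) + "\n"
            ),
        )
        _w(
            "manifest.json",
            lambda p: p.write_text(
                json.dumps(report.manifest, indent=2, sort_keys=True, default=str)
                + "\n"
            ),
        )
        _w("report.txt", lambda p: p.write_text(_render_text(report)))
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise


def _render_text(report: AnalysisReport) -> str:
    parts = [
        f"cohort: n={report.counts['n_total']} "
        f"({report.counts['n_pos']} asthma, "
        f"{report.counts['prevalence_pct']})",
        "",
        "== group comparison ==",
        report.group_compare.to_string(index=False),
        "",
        "== score cross-tabulation ==",
        report.crosstab.to_string(),
        f"Fisher exact p = {report.fisher_p:.6f}",
        "",
        "== diagnostic metrics per threshold ==",
        report.diagnostics.to_string(index=False),
        "",
        "== ROC / AUC ==",
        report.auc_table.to_string(index=False),
    ]
    if report.logit_summary is not None:
        parts += [
            "",
            "== logistic model ==",
            report.logit_summary.to_string(index=False),
            json.dumps(report.logit_stats, sort_keys=True, default=str),
        ]
    return "\n".join(parts) + "\n"
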