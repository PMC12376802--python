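# th2score

Composite Th2-type inflammation scoring and the full diagnostic-accuracy
pipeline for asthma screening cohorts: four biomarkers (blood eosinophil
count, total IgE, FENO, skin-prick positivity) are dichotomized at
predefined cutoffs (BEC ≥ 150 cells/µL, IgE ≥ 100 IU/mL, FENO ≥ 25 ppb,
prick positive) and summed into a 0–4 score, which is then evaluated
against the reference diagnosis with confusion tables, sensitivity/
specificity/PPV/NPV/likelihood ratios, exact Fisher tests, ROC/AUC with
DeLong intervals, Youden-optimal cutoffs, two-group comparison tables, and
from-scratch IRLS logistic regression. A calibrated synthetic-cohort
generator (log-normal marginals fitted to published median/IQR summaries,
Bernoulli prick rates, optional Gaussian copula dependence) lets every
stage run without real patient data.

## Layout

| module | contents |
|---|---|
| `th2score.cohort` | `Participant`/`Cohort` types, CSV read/write, group summaries, counts |
| `th2score.scoring` | cutoffs, dichotomization, composite score, threshold classification |
| `th2score.accuracy` | confusion tables, metric panel with Wilson/Clopper–Pearson CIs, table reconstruction from published rates, exact Fisher by full enumeration, chi-square |
| `th2score.roc` | empirical ROC, trapezoid/Mann–Whitney AUC with DeLong or bootstrap CI, Youden optimum |
| `th2score.compare` | t-tests, Mann–Whitney U, Shapiro-gated automatic selection |
| `th2score.logit` | IRLS logistic regression, Wald inference, odds ratios, Nagelkerke R², classification accuracy |
| `th2score.simulate` | quartile→log-normal fitter, copula cohort generator, closed-form AUC |
| `th2score.pipeline` / `th2score.cli` | end-to-end orchestration, run manifests, `th2score` CLI |

## CLI

```bash
th2score simulate --defaults --seed 7 --out cohort.csv   # synthetic cohort
th2score score --input cohort.csv --out scored.csv       # append indicators + score
th2score diagnostics --input scored.csv --out diag.csv   # metrics at thresholds 1–4
th2score roc --input scored.csv --out-dir roc/ --plot    # AUC table, points, PNG
th2score compare --input scored.csv --out table1.csv     # two-group comparisons
th2score logit --input scored.csv \
    --predictors sex_female,weight,fev1_pct,composite_score --out or.csv
th2score run --seed 5 --out report/                      # everything + manifest
```

`th2score run` accepts `--config cfg.yaml` with either `input_csv: path`
or a `synthetic:` generator spec (`"defaults"` or explicit per-group
median/q1/q3 marginals). Reports are deterministic functions of the config;
rerunning regenerates every file byte-identically.

Cohort CSVs need a header with `id,asthma,feno,ige,bec,prick` (plus
optional `sex,weight,fev1_pct`); booleans accept 0/1, true/false, yes/no,
and column names can be remapped via `read_cohort(..., schema=...)`.

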