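# lipokine

Race-stratified immunometabolic cohort analysis toolkit. Given a subjects ×
variables table with a balanced 2×2 design (race ∈ {White, AA} × disease ∈
{NoDx, Dx}), clinical markers, a lipid panel and a cytokine panel, it runs:

1. **Composite clinical indices** — Chol/HDL ratio, HOMA-IR, pooled group
   summaries (`lipokine.clinical`).
2. **Per-analyte univariate statistics** — Box-Cox transform (profile-
   likelihood λ, applied "as needed" via residual-normality / Levene
   triggers), balanced two-way ANOVA with interaction, protected Fisher's
   LSD over the four pre-specified group contrasts, and Benjamini–Hochberg
   FDR per panel × factor (`lipokine.anova`).
3. **Variable-attribution PCA** — correlation-matrix eigendecomposition with
   cos2 and percentage contributions (`lipokine.pca`).
4. **Cluster scoring** — K-means over analytes in subject z-score space with
   Tibshirani gap-statistic model selection, and per-subject cluster-center
   scores fed back into the ANOVA engine (`lipokine.cluster`).
5. **OPLS-DA feature selection** — orthogonal signal correction plus a single
   predictive PLS component; LV1 feature ranking, R²cal, leave-one-out
   classification error (`lipokine.oplsda`).
6. **Lipid:cytokine ratio screen** — every L×C per-subject quotient,
   Pearson-correlated with a clinical endpoint within each racial stratum,
   classified unique-White / unique-AA / shared / none, with volcano-ready
   output (`lipokine.ratios`).
7. **Confirmation contrasts** — per-biomarker raw (pooled t) and BMI/age-
   adjusted (OLS) race differences with an eligibility window
   (`lipokine.validate`).
8. **Synthetic cohorts** — a seeded generator emulating the design: balanced
   groups, 50/50 sex, log-normal analytes, planted race/disease/interaction
   effects, planted covariance clusters, and planted stratum-specific
   ratio–HbA1C correlations, with a ground-truth manifest for recovery
   testing (`lipokine.synth`).

## CLI

```bash
# simulate a synthetic cohort (CSV + ground-truth JSON + config echo)
lipokine simulate --seed 1 --n-per-group 10 --out out/

# run ANOVA/PCA/cluster/OPLS-DA stages on a cohort CSV
lipokine analyze --cohort out/cohort.csv --out out/

# just the ratio screen
lipokine screen-ratios --cohort out/cohort.csv --endpoint clin_hba1c --out screen.tsv

# raw + adjusted race contrasts
lipokine validate --cohort out/cohort.csv --out contrasts.tsv

# everything, as one deterministic report bundle
lipokine report --seed 1 --out out/
```

Cohort CSVs use column-name prefixes to mark panels: `clin_` (clinical),
`lip_` (lipids), `cyt_` (cytokines); `race`, `disease`, `sex` and the
covariates (`bmi`, `age`, …) are unprefixed. All outputs are TSV/JSON; the
`manifest.json` written by `report` suffices to replay an identical run.

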