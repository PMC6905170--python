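# methclock

A tested, reusable pipeline for DNA-methylation age ("m-age") analysis in
normal and tumor tissue: screen age-associated CpG sites, train a sparse
LASSO clock, quantify per-cohort gaps between m-age and chronological age,
call gap-associated differential methylation, and stratify cancer survival
by a Cox methylation risk score.  It is aimed at computational
epigenomics researchers working with Illumina 450K-style beta-value
matrices (sites x samples, values in [0, 1]) and per-sample clinical
tables.

## The model

**Screening.** On normal samples, each site's beta values are correlated
with chronological age by Spearman rank correlation; sites with
*P* < 0.05 and |SCC| > 0.3 are age-associated candidates.

**Clock.** Candidate sites are standardized per site across training
samples (zero sum, unit sum of squares) and fed to an L1-penalized linear
model of age,

    mAge = β₀ + Σⱼ βⱼ (xⱼ − μⱼ)/sⱼ ,
    J(β) = Σᵢ (yᵢ − Σⱼ βⱼ xᵢⱼ)² + γ Σⱼ |βⱼ| ,

with β₀ the mean training age (unpenalized).  J is minimized by cyclic
coordinate descent from a zero start — each update is the soft-threshold
step βⱼ ← S(xⱼᵀr + βⱼ, γ/2) — and γ is chosen on a 100-point log grid by
10-fold cross-validation (least mean squared error).  Note the RSS in J is
unscaled, so γ is not numerically comparable to solvers that divide by 2n.

**Calibration.** The clock reports Pearson *r*, tolerance accuracy, and
the "error value": the 75th percentile of |predicted − actual| in years.

**Age gap.** Per tumor sample, gap = mAge − age; per cohort, the age
difference score is the 75th percentile of |gap|.  Samples are classified
up / down / unchanged against the normal-cohort error value, and the 25%
of samples with the largest |gap| per cohort are the "age-related" set.

**Differential methylation.** Welch's t-test of normal vs age-related
samples per site, Benjamini-Hochberg FDR, significance at FDR < 0.01 and
fold change > 2 or < 0.5.

**Survival.** Differential sites are median-dichotomized and screened in
multivariate Cox models (site + stage, gender, age; Efron ties); retained
sites (Wald *P* < 0.05) form one joint model whose coefficients weight the
per-sample risk score.  High/low groups split at the median score are
compared by Kaplan-Meier curves and the log-rank test.

A synthetic-data module generates cohorts with exactly this structure
(monotone age sites, effective-age-shifted tumors, mean-shifted
differential sites, methylation-driven hazards), so every stage is
testable without external data; see `docs/methods.md`.

## Worked example

```python
import methclock as mc

sim = mc.SimConfig(seed=1, missing_rate=0.01)   # default study conditions
config = mc.PipelineConfig(seed=1)
summary = mc.run_all(sim, config, "results/run1")
print(summary["n_selected_sites"], round(summary["frac_positive_pct"], 1))
print(round(summary["train"]["pearson_r"], 4), round(summary["test"]["pearson_r"], 4))
print(round(summary["mean_gap_by_cohort"]["TUMA"], 2))
```

prints

```
300 98.7
0.9999 0.9993
-9.67
```

All 300 planted clock sites pass screening, 98.7% of them positively
age-correlated (matching the planted slope-sign fraction); the trained
clock correlates with chronological age at 0.9999 on the 375 training
normals and 0.9993 on the 125 held-out normals; and the tumor cohort
generated at an effective age 10 years younger shows a mean m-age gap of
−9.67 years.  The run directory contains every intermediate table (screen
results, model JSON, CV curve, predictions, gap scores, differential
calls, risk scores, KM curves).

The same stages are available on files from a shell:

```bash
methclock simulate  --seed 1 --outdir run1
methclock preprocess run1/beta.tsv --outdir run1
methclock screen     run1/beta_processed.tsv run1/clinical.tsv --outdir run1
methclock train      run1/beta_processed.tsv run1/clinical.tsv run1/screen.tsv --outdir run1
methclock run-all    --seed 1 --outdir run1   # everything at once
```

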