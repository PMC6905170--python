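# Methods

## Scope and data model

The pipeline operates on a site-by-sample matrix of methylation beta
values (fractions of methylated signal, in [0, 1], missing values
allowed) and a per-sample clinical table (age in years, cohort, normal or
tumor status, gender, ordinal stage 1–4, right-censored overall survival
in days with an event flag).  The exchange formats are TSV for tables,
JSON for trained models, and YAML for configuration; all numeric output
uses a fixed float format so identical runs produce identical bytes.

## Preprocessing

Sites whose missing fraction across samples is *strictly* greater than
10% (configurable) are removed; a site missing in exactly 10 of 100
samples is retained.  Remaining missing cells are filled by k-nearest-
neighbor imputation with k = 10: distance between two sample columns is
Euclidean over their co-observed sites, scaled up by co-observation
coverage; a missing cell takes the unweighted mean of the k nearest
samples that observe that site (an inverse-distance-weighted mean is
available as an option).  With fewer than k usable donors all available
ones are used; with none, the site median.  Observed cells are never
altered, imputed values are clipped to [0, 1], and filter-then-impute is
idempotent.

Ages map to four WHO-style bins — young (≤ 44), middle (45–59),
older-young (60–74), old (≥ 75).  The boundary ages 45, 60 and 75 open
the next bin upward so the bins partition [0, ∞); the verbal definitions
("under 44", "over 75") leave the boundaries ambiguous, and closed lower
bins are the choice made here.

## Screening age-associated sites

Spearman correlation (mid-ranks for ties) between each site and
chronological age on normal samples.  Two-sided p-values use the
t-approximation t = scc·√((n−2)/(1−scc²)) on n − 2 df — accurate for the
n in the hundreds this stage sees, and vastly cheaper than permutation at
array scale; an exact permutation option exists for n ≤ 8.  Selection
requires p < 0.05 *and* |SCC| > 0.3 on the raw p-values by default; a
Benjamini-Hochberg switch is available.  Constant sites have undefined
correlation and are reported unselected with a flag rather than raising.
A per-group variant recomputes the correlation within each tissue/cohort
(groups under 4 samples skipped) alongside the pooled value, exposing
baseline-confounding where within-group correlations exceed the pooled
one.

## The clock

Selected sites are standardized per site over the training samples to
zero sum and unit sum of squares; the center μ and scale s (root sum of
squared deviations) are stored in the model and re-applied at prediction
time, where new samples need not re-center to zero.  The response is age
in years, centered; the intercept β₀ is therefore the mean training age
and is excluded from the penalty.

Coefficients minimize J(β) = Σ(yᵢ − Σβⱼxᵢⱼ)² + γΣ|βⱼ| — note the
*unscaled* residual sum of squares, so γ values are roughly 2n times the
α of solvers that use (1/2n)·RSS (the unit test against scikit-learn's
`Lasso` uses exactly the mapping γ = 2nα).  The solver is cyclic
coordinate descent from a zero start; each update is the soft-threshold
step βⱼ ← S(xⱼᵀr + ssⱼβⱼ, γ/2)/ssⱼ with ssⱼ the column sum of squares
(not exactly 1 inside cross-validation folds).  Full sweeps over all
coordinates alternate with cheap sweeps over the current active set, a
standard acceleration that leaves the stop condition unchanged.

**Convergence.** The primary stop is the largest coefficient change
between two adjacent full sweeps falling below 1e-7.  Because the
screened features share one latent age factor they are strongly
correlated, and near-duplicate columns let coefficients slide along flat
valleys of J for >10⁵ sweeps with no change in fit; a secondary stop
therefore ends iteration when a full sweep decreases J by less than a
relative 1e-9 (1e-8 on CV paths, where solves also use tolerance 1e-5 —
held-out MSE is insensitive at that level).  KKT residuals at the plateau
stop are at or below those of the pure coefficient rule on our test
instances.  Hitting the sweep cap raises a warning and returns the last
iterate.

**Penalty selection.** 100 log-spaced γ values from γ_max = 2·max|xⱼᵀy|
down to γ_max·10⁻³, folds assigned by a seeded permutation, warm starts
along the descending path; the selected γ minimizes mean held-out MSE
(no one-standard-error rule), with ties resolved to the sparser end.
Model features are the sites with nonzero coefficient at the selected γ.

**Calibration metrics.** Pearson r with its two-sided p; accuracy at a
tolerance (default 5 years, configurable — reported as tolerance accuracy
because no standard definition of a clock "accuracy" percentage exists);
and the error value: the 75th percentile, with linear interpolation, of
the absolute prediction error in years, i.e. the error bound that holds
for over 75% of samples.

## Age gaps and age-related samples

gap = mAge − chronological age per sample.  The per-cohort age difference
score is the 75th percentile of |gap| (cohorts under 4 samples skipped).
Per-sample direction is up (gap > θ), down (gap < −θ) or unchanged, with
θ defaulting to the normal-cohort error value — the natural "prediction
noise" band; the band width is configurable since no canonical choice
exists.  The age-related set per cohort is the ceil(0.25·n) samples with
largest |gap|; ties at the cut break by sample-id lexical order, making
selection deterministic and nested as the fraction grows.

## Differential methylation

Per site: group means, fold change FC = (mean_tumor + ε)/(mean_normal + ε)
with ε = 1e-8 guarding empty denominators (inert for real beta means),
Welch's unequal-variance t (tumor vs normal, so t > 0 ⇔ FC > 1),
Benjamini-Hochberg FDR across the tested universe.  Significance: q < 0.01
and |log₂FC| > 1 (equivalently FC > 2 or < 0.5); FC > 1 is hyper-, FC < 1
hypo-methylated.  The tested universe defaults to all processed sites;
restricting to the screened age-associated set is a config switch
(`diff_universe="screened"`).  The default is "all" because tumor-specific
shifts need not sit on age-tracking sites — the synthetic ground truth
plants them off the clock — while the restricted universe reproduces the
convention of testing only age-associated sites.

## Survival

Candidate (differential) sites are median-dichotomized — high iff value
strictly above the median, ties low — and screened one at a time in a
multivariate Cox model with stage (ordinal), gender (male indicator) and
age (years); Efron tie handling, Newton-type maximization via lifelines.
Sites whose methylation-term Wald p < 0.05 enter one joint Cox model; the
per-sample risk score is the coefficient-weighted sum of the *methylation
terms only* (binary indicators by default; continuous beta weighting is
an option, since conventions differ).  Patients split at the median risk
score; Kaplan-Meier product-limit curves and the two-group log-rank
chi-square (1 df) compare the halves, significant at p < 0.05.  Cohorts
with < 20 survival-complete subjects or < 5 events are skipped, as are
cohorts where no site survives the screen or the joint fit fails —
degenerate fits would otherwise produce unstable scores.  Constant
covariates (e.g. single-gender cohorts) are dropped from designs;
rows with missing covariates are dropped per fit.

## The synthetic cohort generator

The generator emulates, at desk scale, the statistical structure of a
pan-cancer 450K study; its defaults are the package's study conditions.

For clock site i and sample j the mean beta is
μᵢⱼ = sigmoid(bᵢ + sᵢ·(a_eff − 50)/10): a logistic link keeps values in
(0, 1) while preserving monotonicity in age, with age scaled so slopes
are per decade.  a_eff is chronological age for normals and age + Δⱼ,
Δⱼ ~ N(δ_c, τ²), for tumor cohort c — tumors run epigenetically young or
old by δ_c years, which makes the true m-age recoverable by a clock
trained on normals.  Non-clock sites are constant on the logit scale;
each tumor cohort shifts 20 designated differential sites by +2 logits
from baselines near beta ≈ 0.1 (fold change ≈ 4.5).  Observed values are
clip(μ + ε, 0, 1) with ε ~ N(0, σ²), σ = 0.03.

Defaults: 5,000 sites, 300 clock sites with round(0.987·300) = 296
positive slopes (the empirical preponderance of positively
age-correlated CpGs), ages uniform on 14–89 years, 500 normals, three
tumor cohorts (200 at δ = −10, 150 at δ = −15, 150 at δ = +8; τ = 2 y).
Slope magnitudes are uniform on 0.05–0.25 logits/decade, putting
per-site Spearman correlations with age in the ~0.6–0.95 band — the
order observed for strong age-CpGs — rather than making every site a
near-deterministic age readout.

Survival: a subset of 5 differential sites per cohort ("risk sites")
receives extra per-sample logit jitter (sd 1.5; without it all tumors in
a cohort would share one risk level and within-cohort stratification
would be impossible by construction), and tumor survival times are
exponential with rate h₀·exp(θ·Σ risk-site betas), h₀ = 10⁻³/day,
θ = 1 per unit beta, censored at an independent Uniform(0, 2000 days)
draw — the simplest independent-censoring mechanism consistent with the
Cox model.  Normal samples carry no survival data.  Ground truth (clock
sites, slopes, shifts, differential and risk sites) is returned and
serialized for loop-closing tests.

What the generator does *not* emulate: probe-type chemistry, batch
effects, cell-composition confounding, non-monotone age trajectories,
spatially correlated probes, informative censoring, or clinical
covariates that truly affect hazard.  Passing tests therefore demonstrate
correctness of the statistical machinery under the assumed generative
structure, not robustness to real-data artifacts.

## Problem sizes and reproducibility

The test suite exercises cohorts up to 500 normals × 1,200 sites with 300
clock sites (clock recovery over 10 seeds), 2,000 subjects (Cox
recovery), and 500-replicate null calibrations (log-rank type-I error);
the acceptance script runs the full default conditions (5,000 × 1,000
with 1% missing cells, exercising imputation).  A single seed drives
every stochastic component — generation, fold assignment, the train/test
split — and re-running any stage with the same configuration and seed
reproduces its outputs byte for byte.

## Known limitations

- The per-site Cox screen and the joint risk model reuse the same
  samples; retained-site p-values are selection-biased and the log-rank
  p on the same cohort is anti-conservative, as in the emulated protocol.
- Feature standardization precedes cross-validation, so CV error is
  mildly optimistic; penalty *selection* is unaffected in practice.
- The t-approximation for Spearman p-values is inaccurate below ~10
  samples; use the exact option there.
- The solver's γ scaling (unscaled RSS) must be kept in mind when
  comparing penalties across sample sizes or against other software.
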