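# methylshift

Men, on average, die younger than women and develop cardiovascular disease
(CVD) earlier. One epigenetic signature of this dimorphism is that many
age-related DNA methylation changes in blood appear to run *ahead* in men:
at a given age, a man's methylation level at such a CpG site resembles that
of an older woman. `methylshift` is a Python toolkit for detecting and
quantifying this pattern in CpG-by-sample beta-value matrices (Illumina
HM450-style data), aimed at epigenomics researchers analysing aging cohorts
with age and sex metadata.

## What it computes

Given a beta matrix `B` (CpGs × samples, values in [0, 1]) and per-sample
covariates (age, sex, optional drinker/smoker flags), the pipeline:

1. **Preprocesses**: drops CpGs missing in >5 % of samples, fills the rest
   by K-nearest-neighbour imputation over CpG rows, and quantile-normalizes
   sample columns.
2. **Screens for age-related CpGs**: per CpG, fits
   `beta ~ 1 + Age + Age² + Age³` with backward elimination under AIC,
   then gates on the nested F-test vs. `beta ~ 1`
   (Benjamini–Hochberg corrected p < 0.01), adjusted R² > 0.25, and
   Spearman |ρ| > 0.2. A coefficient-of-variation prefilter is available
   for array-scale data.
3. **Detects sex dimorphism**: adds a sex indicator to each CpG's selected
   polynomial and BH-adjusts the sex-term p-values.
4. **Estimates heterochrony**: for each dimorphic CpG, finds the age shift
   *s* minimising

   `Σ_males (b_i − g(a_i))² + Σ_females (b_i − g(a_i + s))²`

   over the shared polynomial `g`, by grid search plus bounded refinement.
   Under this convention **s < 0 means the male curve lies left of the
   female curve — the CpG is *accelerated in men***. A nested F-test
   against `s = 0` gives significance; results are summarised as the
   fraction of accelerated CpGs and the mean years by which methylation
   changes occur earlier in men.
5. **Age-group tables**: between-sex differences per decade bin and
   within-sex comparisons against the youngest control group (Student's t).
6. **Enrichment**: maps CpGs to genes and tests disease gene sets (GMT)
   with the upper-tail hypergeometric test; optional Pearson correlation of
   methylation with paired expression.
7. **Lifestyle concordance**: drinker/smoker differential methylation
   (t-test, raw p < 0.05) and the fraction of differential CpGs whose
   exposure effect points the same way as the age-related change.

A synthetic-cohort generator (`methylshift.simulate`) plants polynomial
trajectories, sex age-shifts, missingness and exposure effects with a full
serializable ground truth, so every stage is testable without array data.

## Worked example

```python
from methylshift.pipeline import run_pipeline

stats = run_pipeline(seed=1, outdir="out")
for k in sorted(stats):
    print(k, stats[k])
```

prints (abridged):

```
fraction_accelerated 0.7692307692307693
mean_years_earlier 7.070346577587091
n_accelerated 40.0
n_age_related 198.0
n_delayed 12.0
cvd_enrichment_p 1.644239656895991e-09
exposure_concordance 0.75
```

Reading: of 500 simulated CpGs the screen recovers 198 age-related ones;
52 are flagged sex-dimorphic, of which 40 are classified accelerated in
men (planted truth: 40 CpGs at shift −7 yr, 10 at +4 yr). The accelerated
CpGs change on average 7.07 years earlier in men, their genes are strongly
enriched in the synthetic CVD set, and 75 % of drinker-differential CpGs
move in the same direction as aging — matching the planted 75 % alignment.
Per-stage TSV outputs land in `out/`.

The same pipeline is scriptable from a shell:

```bash
methylshift simulate --seed 1 --out sim
methylshift preprocess --matrix sim/beta_raw.tsv --out clean.tsv
methylshift screen --matrix clean.tsv --samples sim/samples.tsv --cv-cutoff 0 --out models.tsv
methylshift shift  --matrix clean.tsv --samples sim/samples.tsv --models models.tsv --out shifts.tsv
```

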