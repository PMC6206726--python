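# Methods

## Data model

Methylation is represented as beta values — methylated signal over total
signal at one CpG site, bounded in [0, 1] — in a CpG-by-sample matrix with
`NaN` for missing cells. Covariates are age in years, sex
(`male`/`female`), and optional boolean exposure flags. All analyses
intersect matrix columns with the covariate table and follow the matrix's
column order, so dropping a sample from either input affects results only
through that sample.

## Preprocessing

The pipeline order is **filter → impute → normalize**; normalization
requires a complete matrix, which fixes the ordering.

- **Missingness filter.** CpGs missing in *strictly more than*
  `max_missing_frac` (default 0.05) of samples are dropped; a CpG at
  exactly the threshold is retained.
- **KNN imputation** (default k = 10, the classic microarray default).
  Neighbours are other CpG rows; distance is Euclidean over samples
  observed in both rows, rescaled by the observed fraction
  (scikit-learn's `nan_euclidean`), and the imputed value is the
  distance-weighted neighbour mean, clipped to [0, 1]. Observed cells are
  never altered. Rows without usable donors fall back to their own mean
  with a warning.
- **Quantile normalization.** Every column's sorted values are replaced by
  the across-column mean of sorted values; ties receive the mean of the
  reference values spanning their tied ranks. The transform is idempotent
  and rank-preserving within columns. It is applied once to the full
  matrix, both sexes jointly — normalizing per sex would remove exactly
  the between-sex signal of interest.

## Age screen

Per CpG, the trajectory of beta on age is modelled as a polynomial of
degree ≤ 3. Model choice is backward elimination from the full cubic under
AIC (`n·log(RSS/n) + 2·p`); because only three terms are removable, the
backward-reachable candidate set (every subset of {Age, Age², Age³} plus
the intercept) is searched exhaustively, so the chosen model is the exact
AIC optimum of that set and elimination is not hierarchy-constrained. RSS
is floored at `1e−14 · TSS` inside the AIC so that numerically perfect
fits cannot reward spurious extra terms through log-of-roundoff noise;
ties prefer the smaller model. Ages enter in raw years; design columns are
norm-scaled before the least-squares solve and coefficients mapped back,
which keeps the cubic design well conditioned without changing the model.
With fewer than four distinct ages the candidate degree is truncated to
what is identifiable, with a warning.

Gates, in order:

1. **Variability prefilter**: coefficient of variation (sample sd / mean)
   ≥ `cv_cutoff` (default 0.5, the conventional array-scale cut). An
   alternative `iqr` mode retains CpGs above the lower quartile fence
   Q1 − c·IQR of the cv distribution; the direct cut is the default
   reading. On simulated cohorts the pipeline disables this gate
   (`cv_cutoff = 0`): the generator calibrates trajectories by explained
   variance, not by dispersion-to-mean ratio, and the downstream gates
   carry the error control there.
2. **F-test**: nested F of the selected model against `beta ~ 1`;
   if the selected model *is* the intercept-only model, p = 1 by
   definition. BH correction is applied across all CpGs that reached the
   F-test (the variability-filter survivors), threshold 0.01.
3. **Fit floor**: adjusted R² > 0.25.
4. **Monotonicity**: Spearman |ρ| > 0.2 (average ranks for ties; a
   constant CpG has undefined ρ and fails).

Note that p-values of an AIC-selected model are post-selection quantities:
under a flat null they are not uniform (there is mass at 1 where the null
model is selected, and inflation below it where a term was kept by
chance). The screen does not rely on their uniformity — false positives
are controlled by the joint BH + adjusted-R² + ρ gates, and the planted-
truth recovery tests measure exactly that.

## Sex term and heterochrony

- **Sex term.** For each screened CpG, OLS of beta on the selected age
  terms plus a female indicator; the indicator's two-sided p is
  BH-adjusted across tested CpGs, flagging dimorphic CpGs at adjusted
  p < 0.05.
- **Age shift.** The male trajectory is the reference. Parameterization:
  `beta_female(a) ≈ g(a + s)`, so **s < 0 places the male curve to the
  left** (men reach a given methylation state earlier — "accelerated in
  men"); s > 0 is "delayed in men". The polynomial basis is taken from a
  male-only refit (falling back to the pooled model's terms if the male
  fit degenerates to flat, in which case the CpG is skipped as
  unidentifiable).
- **Estimation.** For fixed s the coefficients of g are profiled out by
  linear least squares on the pooled data (males at their ages, females at
  `age + s`); RSS(s) is scanned on a coarse grid (default 0.5-yr steps
  over ±20 yr) and the best cell refined by bounded scalar minimization
  (tolerance 1e−6 yr). The grid contains s = 0, and the final estimate is
  clamped so `RSS(ŝ) ≤ RSS(0)` always holds.
- **Inference.** Nested F-test with one numerator degree of freedom:
  `F = (RSS(0) − RSS(ŝ)) / (RSS(ŝ)/(n − p − 1))`, p from F(1, n−p−1),
  where n pools both sexes and p counts the polynomial coefficients.
  Profiling the coefficients under both hypotheses is what makes this test
  calibrated: freezing the male curve at its estimate and testing only the
  female residuals double-counts the male fit's sampling error and
  empirically inflates the type-I rate severalfold at equal group sizes,
  so the joint-refit form is used. Measured null rejection at α = 0.05 is
  5 % ± 1 % in the calibration tests.
- **Classification.** Significant (p < α, default 0.05) negative shifts →
  accelerated in men; significant positive → delayed; otherwise no_shift.
  The summary reports the accelerated fraction among significant shifts
  and the mean |s| over accelerated CpGs ("years earlier in men"). Female
  ages shifted outside the male age range are still evaluated by the
  polynomial but the extrapolated fraction is recorded per CpG.

## Group tables

Age bins are half-open `[lo, hi)` intervals (decade presets). Between-sex
tables report mean(male) − mean(female) and a Student's equal-variance
t-test per CpG and bin (Welch behind a flag); within-sex tables compare
each older bin against the youngest bin per sex. Raw p-values are
reported — these are descriptive tables, not discovery gates. An
aggregate variant runs the same contrasts on the across-CpG mean profile.

## Enrichment and lifestyle

Gene-level counting: a selection of CpGs maps to the union of its
annotated genes (each gene once, however many CpGs hit it). Enrichment of
a gene set within a universe is the upper-tail hypergeometric probability
P[X ≥ k] with N = |universe|, K = |set ∩ universe|, n = |selection|; the
universe defaults to all genes annotated to screened CpGs and is
configurable. Methylation–expression coupling uses the Pearson correlation
with the t-transform p-value on ≥ 4 paired samples.

Exposure analysis is a two-sample t-test per CpG (exposed vs. unexposed,
raw p < 0.05 as the differential flag, mirroring common single-cohort
practice; stated in the output). Direction concordance is the fraction of
differential CpGs whose exposed-minus-unexposed delta has the same sign as
the age-related change, operationalized as the sign of the screen's
Spearman ρ (robust and already computed; the fitted slope sign at a
reference age is an available alternative). Zero deltas or undefined
directions are excluded and counted.

## Synthetic cohorts

The generator emulates a blood HM450-style aging cohort:

- ages uniform on [20, 80] (the decade-bin study range), sexes balanced,
  exposures Bernoulli;
- per-CpG polynomial trajectories evaluated at the sample's age (males)
  or `age + shift` (females) — the same convention the estimator uses, so
  sign semantics are locked end to end;
- additive Gaussian noise on the beta scale, default sd 0.02 (typical
  residual scatter for blood beta values), clipped to [0, 1]; trajectories
  are bound-checked pre-noise and clipping is rare by construction
  (< 0.1 % of cells at the defaults);
- uniform missingness plus optional "heavy" CpGs with 10 % missing cells
  to exercise the filter.

The **default scenario** holds 500 CpGs: 300 flat nulls, 150 age-related
non-dimorphic CpGs with linear slopes calibrated to a population R² of
0.4 at the default noise (slope ≈ 9.4e−4 per year), and 50 dimorphic CpGs
with slope |0.004|/yr — 40 planted at shift −7 yr and 10 at +4 yr, an 80 %
accelerated fraction. Cohort size is 150 per sex (300 samples). Each CpG
carries one gene; a synthetic "CVD" set samples dimorphic genes at 5× the
background rate. Drinker effects of |0.05| beta units are planted on 48 of
the 50 dimorphic CpGs, 36 aligned with the age direction and 12 opposed
(exactly 75 % concordant). Larger recovery experiments (200 CpGs at shift
−7 with 350 samples per sex; 1000 null-shift CpGs for calibration) use the
same machinery; these sizes keep the full suite and the acceptance script
in the tens of seconds while leaving the statistical margins wide.

What the generator does **not** emulate: Infinium I/II probe chemistry and
its bimodal beta distributions, batch effects across merged series,
cell-type composition drift with age, spatial correlation among
neighbouring CpGs, and logit-scale (M-value) noise. Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
model, not robustness to those real-data artefacts.

## Numerical and degenerate-input conventions

- Missing tokens accepted on read: `NA`, `NaN`, empty cell; written as
  `NA`. Matrix orientation is fixed CpGs × samples; a transposed matrix is
  detected at alignment and rejected rather than guessed.
- Sex spellings `M/male/Male/1` and `F/female/Female/2` normalize to
  `male`/`female`; the map is configurable.
- Perfect fits (RSS = 0) yield p = 0 with an explicit flag; intercept-only
  selections yield F-test p = 1; constant vectors fail the Spearman gate
  and are rejected by the correlation routines.
- BH adjustment delegates to the standard step-up implementation and is
  verified against the definitional brute force to 1e−12.
- All generator outputs are pure functions of (parameters, seed); ground
  truth serializes to JSON and regenerates bit-exactly.

## Known limitations

- The shift model displaces a *shared* curve shape along the age axis;
  shape differences between sexes (different slopes, not just timing)
  load partly on the sex term and partly on extrapolated shift values.
- The female curve is never refit with free coefficients plus a shift;
  profiling refits coefficients jointly but constrains both sexes to one
  shape.
- Post-selection inference caveat above applies to all reported per-CpG
  F-test p-values; downstream gates, not uniformity, carry error control.
- Exposure concordance joins cohorts on CpG ids only; no harmonisation of
  sample-size imbalance between the aging and exposure cohorts is
  attempted.
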