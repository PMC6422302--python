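# Methods

This note documents the statistical model, the synthetic-data generator,
the numerical choices, and the known limitations of `metabddx`. It states
nothing that the test suite or `scripts/acceptance.py` do not themselves
compute.

## Analysis model

The pipeline analyses a subjects × analytes table of non-negative *scaled
intensities* (each analyte conventionally near median 1) with a boolean
below-limit-of-detection (LOD) mask, plus per-subject clinical metadata:
case/control group, cohort (discovery/test), continuous covariates (BMI
kg/m², HbA1c %, fasting glucose mg/dL, plasma cotinine ng/mL, waist-to-hip
ratio), medication-class flags, comorbid major depression (MDD), smoking,
and CAPS symptom scores.

Per cohort, the canonical chain is

1. **minimum-value imputation** — each below-LOD cell takes the analyte's
   minimum observed value across the cohort;
2. **median scaling** — each analyte divided by its across-subject median
   (post-condition: median exactly 1);
3. **composite ratios** — per-subject sum(numerator)/sum(denominator) on
   the imputed, scaled (raw) intensities; built-ins are the glycolytic
   ratio (pyruvate + lactate)/citrate and GABR
   arginine/(ornithine + citrulline);
4. **Blom transform** — z = Φ⁻¹((r − 3/8)/(n + 1/4)), average ranks for
   ties.

Hypothesis tests run on the Blom scores; group means/SDs and fold changes
are reported on the raw scale, mirroring how such studies print their
tables. Two-tailed α = 0.05 throughout, with p in (0.05, 0.1] labelled a
*trend*.

Design decisions worth spelling out:

- **Pooled-variance t is the default** (Welch behind a flag): the pooled
  form reproduces published demographic t statistics exactly (e.g.
  26.85 for the CAPS-current contrast of 2.90 ± 4.24 vs 68.02 ± 16.80 at
  51/52), which pins down the dialect.
- **Chi-square without continuity correction** for dichotomous baseline
  variables, again because the uncorrected Pearson statistic reproduces
  the printed smoking contrast (3/51 vs 11/52 → χ² ≈ 5.11, p ≈ 0.024); the
  Yates-corrected p (≈ 0.04) is available but not default.
- **Cohen's d is reported as |d| on the Blom scale**. Raw-scale d from
  printed summaries is generally *not* equal to transformed-scale d, so
  exact reproduction of published d columns is not expected.
- **Storey q-values**: π̂₀(λ) = #{p > λ}/(m(1 − λ)) on λ = 0.05…0.95,
  smoothed with a cubic smoothing spline and evaluated at max λ, clipped
  to [1/m, 1]. Panels with m < 100 use π̂₀ = 1, which makes the q-values
  exactly Benjamini–Hochberg (verified against `statsmodels` to 1e−12).
- **Composite ratios are Blom-transformed before testing**, like any other
  analyte; their reported means stay on the interpretable raw ratio scale.
  GABR's component formula follows the standard arginine/(ornithine +
  citrulline) definition.
- **ANCOVA** is one covariate at a time — ordinary least squares
  z ~ 1 + group + covariate, group-coefficient p with df = n − 3, raw
  (untransformed) covariates, subjects with missing covariates dropped and
  counted. MDD enters the same way as a 0/1 regressor. Covariates
  numerically collinear with the group indicator (1 − r² < 1e−10) or the
  intercept are hard errors.
- **Sensitivity analyses recompute preprocessing within the subset**
  (imputation minima and medians), simulating recruitment of the smaller
  cohort, rather than reusing full-cohort preprocessing.
- **Panel harmonization** is exact string matching after whitespace
  trimming, lexicographically ordered, so downstream positional alignment
  is independent of input column order.
- **Replication resampling** is stratified re-splitting *without*
  replacement of the pooled subjects into a pseudo-discovery and
  pseudo-test of the original cohort sizes; "success" in one re-split
  requires p ≤ α with the same effect direction in both halves. Rationale:
  replication without direction agreement is meaningless. A
  with-replacement bootstrap variant exists behind a flag. Per-cohort
  scaling is redone inside every pseudo-cohort.

## Synthetic cohort generator

The generator emulates a two-cohort case-control study whose per-analyte
group summaries match a published table of means/SDs: discovery 51
controls / 52 cases, test 31/31, with 21 differential analytes (lactate,
pyruvate, citrate, 5-oxoproline, several unsaturated fatty acids,
acyl-carnitines, cortisol, hypoxanthine, …), two support analytes, and 20
null analytes (identical group distributions, mean 1.0 SD 0.3) for
type-I-error calibration.

**Distributional family.** Intensities are non-negative; the source
summaries give only means and SDs. Each analyte/group is drawn from a
**zero-truncated normal whose post-truncation mean and SD equal the
configured values**: the parent (μ, σ) is solved from the truncated-moment
equations (inverse-Mills algebra, Brent root-finding on the standardized
truncation point). This is the choice that makes parameter recovery
testable — the generated group means are exactly the configured ones. A
zero-truncated normal cannot have mean/SD ≤ 1, so variables printed with
mean/SD < 1.05 (control CAPS scores, non-smoker cotinine) fall back to
using the requested values as parent parameters; their realised moments
deviate, which only affects heavily skewed metadata, never the analyte
panel.

**Censoring.** Each analyte has an LOD threshold at the `lod_quantile` of
its control distribution; cells below it (in either group) are masked.
Default 0.01. Rationale: named compounds detected by both platform runs
have low missingness, and minimum-value imputation with a common
control-quantile threshold systematically lifts the lower group's mean —
at 5% censoring that bias reaches ~3% of the fold change for analytes
whose case arm sits well below control, at 1% it stays ≤ ~1.6% (the
residual being mostly the ratio-of-means Jensen bias at n ≈ 51, which no
generator choice removes). 1% keeps the below-LOD code path exercised in
every run while keeping fold-change recovery within the 2% band the test
suite asserts.

**Metadata.** Covariates are group-dependent truncated normals matching
the published demographics (BMI, HbA1c, glucose, waist-to-hip), which
induces realistic covariate–group confounding without any explicit
metabolite–covariate link. Cotinine is modelled through the smoker flag
(prevalences 3/51 vs 11/52 discovery; 1/31 vs 0/31 test): non-smokers
~N(1, 1) ng/mL truncated at 0, smokers ~N(250, 100). Medication-class
flags are independent Bernoullis at the printed per-class prevalences
(`any_medication` is their OR, so its marginal rate is close to, not
exactly, the printed any-medication count); MDD occurs only in cases
(27/52 and 20/31). CAPS scores are generated independent of the
metabolites, encoding the null symptom-severity correlation the analysis
is expected to report.

**Optional structure.** A single latent factor (`latent_loading` ρ)
correlates analytes through a Gaussian copula without changing marginals —
composite ratios and ANCOVA behave differently under correlation, and the
default (independence) is the conservative, assumption-light choice since
no correlation structure is published. A linear leakage term
(`leakage[analyte] = (covariate, β)`, value += β·covariate, clipped at 0)
exists to construct covariate-confounded metabolites for testing that
adjustment removes what it should.

**GABR support analytes.** Only the composite GABR is published, not
ornithine/citrulline; the generator carries synthetic support analytes
(means ≈ 1, case arm ≈ +7%) chosen so the composite lands near the
published GABR group means. They are labelled as synthetic support in the
spec tables and carry no acceptance weight.

## What the generator does *not* emulate

No batch effects, drift, heteroscedastic technical noise, lognormal tails,
inter-analyte correlation by default, or metabolite–symptom links. Passing
tests therefore demonstrate that the *statistical machinery* is correct
and calibrated under the stated model — not that real plasma data meet
that model. In particular the type-I calibration (null analytes flagged at
~5%) relies on exchangeability that real batch-structured data can
violate.

## Numerical choices and degenerate inputs

- Blom constant fixed at 3/8 with n + 1/4 denominator (classical variant);
  ties share average ranks, making the transform rank-equivariant.
- Missingness in files is an empty cell only; 0 and −1 parse as data
  (0 is a legal scaled intensity).
- Zero pooled variance: equal means → (t, p) = (0, 1); unequal means →
  hard error. Constant analytes in correlation analyses are flagged
  not-computable instead of propagating NaN.
- q-values are clipped to [0, 1] and forced monotone nondecreasing in p
  via a reverse cumulative minimum over the sorted vector (stable
  mergesort, so tied p share a q).
- Re-splits are seeded by `AnalysisConfig.rng_seed` (NumPy PCG64); fixed
  seed → bit-identical fractions.
- The resampling chain is a vectorized re-implementation of the public
  preprocessing path; a dedicated test asserts both paths agree to 1e−12
  on a full cohort.

## Problem sizes used by the test suite

Calibration properties run over 200 seeded cohorts at the study sizes
(51/52); fold-change parameter recovery uses 1000 seeds because the
200-seed mean has ~0.8% sampling error for the high-CV analytes, which
would dominate a 2% band. The resampling machinery is exercised at 500
re-splits (acceptance) and 100–200 (unit/determinism); the MDD-subgroup
null battery uses 60 seeds with a binomial allowance around the ~5%
per-seed any-rejection rate that an FDR procedure exhibits under a global
null.

## Known limitations

- Published Cohen's d and q columns from subject-level data are not
  reproducible from printed summaries (transformed-scale computation);
  the pipeline's own d/q are internally consistent instead.
- Statistical power at the study sizes is a property of the published
  effect sizes, not of the implementation: analytes printed with raw
  standardized differences around 0.3 (e.g. pyruvate in the discovery
  summaries) have ~35% two-tailed power at 51/52 and cannot be detected
  "almost always" by any faithful re-analysis.
- The with-replacement bootstrap variant duplicates subjects within a
  pseudo-cohort, which mildly inflates within-group ties after the Blom
  step; the default re-splitting design avoids this.
- `read_matrix_xlsx` is a convenience for workbook-shaped inputs and
  assumes the same layout as the CSV reader; it performs no sheet
  auto-detection.
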