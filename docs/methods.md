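# Methods

## Scope and model

`seamehg` estimates seafood methylmercury concentrations bottom-up: from
study-level literature records (one reported mean ± SD per study × species ×
area × period) to a complete area × category × year grid, and from there to
national time series weighted by where each nation fishes. Concentrations
are always ng/g wet weight of muscle tissue. The five seafood categories are
trophic bins of marine fishes (Level 1: TL ∈ [1.5, 2.5) … Level 4:
[4.5, 5.5]) plus OSE (crustaceans and molluscs); MeHg biomagnifies, so the
category ordering is the strongest structural prior in the data.

The estimation chain and its assumptions:

* **Screening** assumes the metadata flags (pollution, tissue, weight
  basis, below-LOD) are reliable; records are dropped, never corrected.
  Records with a weight basis but unspecified tissue are kept — only
  explicit non-muscle tissue is excluded. Below-LOD records are dropped
  rather than substituted (no LOD/2 scheme).
* **Standardization** treats every reported value as exchangeable across
  the years of its sampling period, assumes 80% tissue water for dry→wet
  conversion, 65% of the mean for a missing SD, and publication year − 2
  for a missing sampling year. Missing sample sizes become 1, which
  deliberately down-weights poorly documented studies in the aggregation.
* **Conversion** assumes the group-level log-log relations between THg and
  MeHg (fish: slope 1, intercept −0.23; other seafoods: slope 0.94,
  intercept −0.47) hold across species and areas within a group.
* **Aggregation** assumes studies within a cell estimate a common cell
  mean, heterogeneity entering only through the pooled SD.
* **Imputation** assumes concentrations vary smoothly enough in
  (area, year) for a forest on year + area indicators, and that sparse
  categories co-vary with the dense Level 2/3 surfaces.
* **National aggregation** assumes capture volumes are a fair proxy for
  the origin mix of a nation's seafood supply (trade is ignored).

## Key parameters

| Parameter | Default | Units | Why |
|---|---|---|---|
| water content | 0.8 | fraction | fixed tissue-moisture assumption of the dry→wet rule |
| SD imputation | 0.65·mean | — | dispersion rule for studies reporting only a mean |
| year imputation | publication − 2 | years | typical lag between sampling and publication |
| outlier quota | 0.05 per (group, category) | fraction | IQR-scored removal cap |
| conversion coefficients | (1, −0.23) fish; (0.94, −0.47) OSE | log-scale | default group regressions; refittable from pairs |
| Monte Carlo draws | 10,000 | draws | sampling error of the MC mean ≲ cv/100 |
| MC distribution | log-normal, moment-matched | — | positive support; truncated normal available |
| forest | 100 trees, unlimited depth | — | standard regression-forest defaults, seeded |
| train/test split | 90/10 of observed cells | fraction | held-out accuracy reporting |
| year range | 1995–2022 | years | earlier data too scarce to support the grid |

## Numerical choices

* Trophic bins are left-closed with the top edge included, so the map is
  total on [1.5, 5.5]; the convention is a deterministic choice, not a
  substantive one.
* The outlier rule reconciles a fixed 5% removal quota with the IQR rule:
  records are scored by their exceedance beyond the Tukey fences
  [Q1 − 1.5·IQR, Q3 + 1.5·IQR] and exactly ⌊0.05·n⌋ records with the
  largest scores are removed per (group, category) stratum; ties break by
  distance from the stratum median, then row id, making removal
  deterministic. Applying the quota per stratum (rather than globally or
  per area) keeps the rule scale-free across unevenly sampled categories.
* The cell SD pools within-study variance and between-study dispersion
  with sample-size weights: `var = Σ m_i(sd_i² + (μ_i − μ̄)²)/Σ m_i`. It
  reduces to the study SD for a single-study cell and is invariant to
  splitting a study into identical halves.
* Monte Carlo sampling uses a log-normal matched to the reported
  (mean, SD), guaranteeing positive draws; zero-SD inputs short-circuit to
  the exact closed form, which is what makes noise-free end-to-end
  recovery exact rather than approximate. A zero-truncated normal is
  available (`distribution_family="truncated_normal"`); note truncation
  biases its mean slightly upward.
* When refitting the fish conversion, the slope is constrained to 1
  (intercept = mean log-ratio) to preserve the proportional form; a free
  slope is available behind a flag. OSE refits are ordinary least squares
  of ln MeHg on ln THg; standard errors come from the regression.
* Conversion residuals are defined on the log scale, matching the
  log-space regression; their kernel density is evaluated on a grid padded
  by three bandwidths and integrates to 1.
* Imputation features are calendar year (numeric) and area indicator
  variables, pooled across areas for data efficiency; optional lag-1
  neighbour values are off by default. Cross-category forests add the
  completed Level 2 and Level 3 means at the same (area, year). If one
  predictor surface cannot be completed it is dropped (with a warning)
  rather than aborting the fill; if a category cannot be imputed at all
  its cells stay missing and the national stage falls back. Forest
  predictions are averages of positive training targets, so imputed means
  are positive and within the training range by construction. SDs for
  imputed cells come from a parallel forest on observed SDs, with
  0.65·mean as a last-resort fallback.
* The national fallback is the geometric mean over catch-weighted
  *national* values of same-continent peers (then all nations) for the
  same category and year — national granularity matches the output files.
  The fallback SD is the geometric mean of peer SDs when all are positive,
  otherwise their arithmetic mean (geometric means are undefined at zero).
  Zero-catch nation-years fall back per cell, even if the nation reports
  catch in other years.
* All randomness (Monte Carlo, forests, splits) derives from one master
  seed via seed sequences; outputs are byte-identical across reruns.

## The synthetic generator

The generator emulates the record shapes and the messiness the screening
targets. Truth is log-linear per (area, category): ln C = ln baseline +
area offset + slope·(year − start). Default baselines (30, 50, 80, 150,
300 ng/g for OSE, Level 1–4) span the order-of-magnitude biomagnification
gradient seen in marine food webs; area offsets (log-SD 0.2) are shared
across categories so the trophic ordering holds everywhere; default slopes
are drawn around −0.01/yr (slow declines) with SD 0.008. Between-study
noise is log-normal with log-SD 0.3, and the reported within-study CV
equals the noise SD, so a "noise 0" configuration yields an exactly
noise-free corpus. 70% of records report THg, rendered by exactly
inverting the group conversion; dry-weight records multiply by 5 (the
exact inverse of the 80%-water rule); units are drawn from a six-unit mix.
The five substantive corruptions (polluted ×3–10 inflation, non-muscle,
unknown area, unspecified basis, below-LOD) are mutually exclusive per
record so each filter's rejection set can be compared one-to-one with the
corrupted set; missing-field and dry-weight/unit corruptions are
independent because they are reversible standardizations, not rejections.
Capture tables include a single-area nation (identity-weight check) and an
all-zero nation (fallback check).

What the generator does *not* emulate: real species taxonomies and
Fishbase trophic estimates, correlated reporting biases between studies,
analyte-specific measurement error, trade flows, or realistic global catch
magnitudes. Passing tests therefore certify the pipeline's algebra,
determinism and statistical behaviour under the stated noise model — not
the accuracy of any real-world concentration estimate.

## Problem sizes used in the tests

The clean end-to-end fixture uses 3 FAO areas × 5 categories × 6 years with
four records per cell (so the per-stratum outlier quota can never empty a
cell) and 5 nations at 2,000 Monte Carlo draws; the noisy imputation
scenario uses 4 areas over 1995–2022 with 2,500 studies and 30% of cells
hidden; oracle-equivalence checks run 1,000 random instances of up to 20
studies/areas; conversion-recovery runs 200 replicates of n = 500 noisy
pairs. These sizes were chosen as the smallest at which each property is
meaningfully exercised.

## Known limitations

* The conversion coefficients are group-level; species- or area-specific
  conversion is out of scope.
* The imputation cannot extrapolate beyond the range of observed
  concentrations (a regression-tree property) — genuine novel extremes in
  unobserved cells are flattened.
* Whether the historical corpus applied the outlier quota per category,
  per area, or globally is not determinable from the rules alone; the
  per-(group, category) choice here is documented and configurable.
* FAO-style capture statistics under-report subsistence, recreational and
  illegal fishing; no correction is attempted.
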