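# Methods

`soil2bio` estimates the association between soil-metal contamination and
child blood/urine biomarkers. This note documents the models it implements,
the choices made where the design was genuinely open, what the synthetic
data generator does and does not emulate, and the numerical conventions.

## The analysis chain

A study consists of a point-sampled soil-metal field (projected meters,
mg/kg), a child cohort with home coordinates, ages, residence histories,
body weights and covariates, and one biomarker per (child, metal). The
pipeline:

1. **Interpolation.** Predict the soil surface by ordinary kriging (OK),
   TIN, and three skew-adapted combinations (below); rank methods by k-fold
   cross-validated RMSE at held-out sample locations and select the best.
2. **Exposure assignment.** Per child: the closest sample within 90 m, the
   mean and maximum over 90 m and 275 m buffers, each interpolated surface
   evaluated at the home, and the daily ingestion dose. Children with no
   sample within 275 m are excluded from every downstream table.
3. **Biomarker preparation.** Below-detection values are substituted at
   LOD/2; urinary analytes are creatinine-adjusted (µg/L divided by
   creatinine in g/L, giving µg/g); outcomes are natural-log transformed and
   continuous predictors z-scored (SD with the n−1 denominator; 0/1
   indicators left unstandardized by default).
4. **Regression.** Per (biomarker, exposure method): OLS first; if the
   Moran's I of the OLS residuals is significant at p < 0.2, refit as a
   maximum-likelihood spatial-error model. Coefficients on the log outcome
   are read multiplicatively: a standardized coefficient β means a
   100·(exp(β) − 1) percent change per SD of exposure.

## Skew-adapted interpolation

Urban contamination fields are right-skewed: a smooth lognormal bulk plus a
heavy upper tail of hotspot measurements that behave like draws from a
different distribution. Fitting one smooth surface to both smears spikes
across neighborhoods. The package therefore splits the sample at the upper
Tukey fence (value > Q3 + 1.5·IQR; quartiles by linear interpolation between
order statistics) and offers:

- **split**: TIN fit to the outlier stratum only (its contribution is zero
  outside the outlier convex hull, so spikes stay local) plus OK fit to the
  bulk;
- **log_split**: as split, but the bulk is kriged on the log scale and
  back-transformed by naive exponentiation (an optional lognormal-kriging
  correction exp(ŷ + σ²_K/2) is available behind a flag);
- **full**: TIN and OK each fit to *all* data and summed pointwise. This is
  implemented literally as that method is defined; note it doubles a constant
  field, and the constructor warns accordingly.

The fence is upper-tail only by default (hotspots are a right-tail
phenomenon); a `two_sided` flag restores the symmetric rule. With fewer than
three outliers (or collinear ones) the combined methods fall back to plain
OK on the full data, logged.

Ordinary kriging uses a semivariogram fit by weighted least squares to the
Matheron empirical estimator (weights = pair counts / lag², 15 lags, max
distance = half the maximum pair separation), exponential family by default
with the raw-range convention γ(h) = c·(1 − e^(−h/a)). Prediction solves the
OK system on the 16 nearest samples with the unbiasedness constraint;
duplicate locations are averaged before the solve. TIN is barycentric-linear
interpolation on the Delaunay triangulation, exact for affine fields, with
nearest-sample fallback outside the hull (flagged).

Method comparison uses k-fold CV RMSE rather than in-sample error because
exact interpolators have zero in-sample residual; rows are put in canonical
coordinate order before folding so the result is row-order invariant. Ties
break by a fixed precedence (OK, TIN, split, log_split, full).

## Dose model

Daily dose D = C·IR·EF·CF / BW, reported in µg/kg body weight/day, with
intake rate IR = 60 mg soil/day, CF = 10⁻⁶ kg/mg, and the residence-weighted
exposure factor

EF = (residence_years·C_home + nonresidence_years·C_city) / (age·C_city),

where C_city is the arithmetic mean over all soil samples of the metal and
years lived away from the current home are imputed at C_city. Two
consequences worth knowing:

- EF = 1 exactly when C_home = C_city, and EF = C_home/C_city at full
  residence, so **D is quadratic in C_home** for a full-residence child.
  This is the model as published and is the default; a
  `concentration_linear` flag replaces the EF denominator's reference
  concentration with C_home, which reduces C·EF to the time-weighted mean
  concentration (linear in C_home).
- Over a heavy-tailed field the quadratic makes the *mean* dose
  hotspot-dominated (a single child at a 20,000 mg/kg hotspot contributes a
  dose in the thousands of µg/kg/day); the *median* dose is the robust
  magnitude summary and sits in the sub-µg/kg/day range typical for urban
  soil-Pb.

Ages and residence years are real-valued to avoid rounding artifacts in a
9–11-year-old cohort.

## Spatial-error regression

y = Xβ + u, u = λWu + e, e ~ N(0, σ²I), with W a row-standardized k-nearest-
neighbor weights matrix over home coordinates (k = 1 by default: each
child's single nearest neighbor; duplicate coordinates are jittered by
~10⁻⁶ m). Estimation profiles the concentrated log-likelihood over
λ ∈ (−0.999, 0.999): a 41-point grid locates the mode (the likelihood can be
multimodal near the boundary with k = 1 weights), Brent refines it, and the
log-determinant of (I − λW) is evaluated from the eigenvalues of W (complex
for asymmetric k = 1 weights). The fit is guaranteed no worse than the λ = 0
(OLS) point; a boundary λ is flagged. Standard errors come from the
asymptotic information matrix (the β block separates from (λ, σ²); the λ SE
inverts the 2×2 trace-based block). The reported R² for spatial-error fits
is a pseudo-R²: the squared correlation between y and the trend Xβ̂.

Moran's I uses the normality approximation for inference (two-sided). The
screening rule (OLS → SEM when Moran p < 0.2) deliberately over-triggers:
at that threshold ~20% of truly i.i.d. datasets are refit as SEM, which
costs little (SEM with λ̂ ≈ 0 reproduces OLS), while missing genuine
autocorrelation biases OLS standard errors. No multiple-testing correction
is applied across the (biomarker × method) model grid; estimates are to be
read as a comparison of exposure metrics, not as a hypothesis family.

## Synthetic data generator

The generator is first-class, tested code: it produces datasets with the
exact statistical structure the estimators assume, with ground truth
recorded, so recovery can be verified.

- **Soil field**: samples uniform in the domain; concentrations are
  exp(Gaussian process) with exponential covariance (dense Cholesky; desk
  scale n ≲ 3000), plus a separate outlier stratum — a fraction of samples
  receives Pareto-distributed spikes (shape 1.5, infinite variance) damped
  by a Gaussian kernel around 1–5 random source points, and membership is
  biased toward samples near sources so hotspots cluster. Defaults
  (log-mean 4.85, log-SD 1.2, range 500 m, spike scale 1200 mg/kg, 5%
  outliers) give a soil-Pb-like field: median ≈ 10² mg/kg, mean/median
  ≈ 2.5, maxima in the tens of thousands.
- **Cohort**: ages uniform on [9, 11]; ~73% of children have moved
  (residence years uniform between 1 and age, the rest full residence);
  body weight ~ N(40, 9) kg truncated to [20, 90]; covariate marginals
  (SES index, race/gender/smoking indicators, BMI percentile, diet indices,
  vacancy share, highway distance, air-Hg, draw-day temperature) echo a
  mid-size US city cohort and are fully configurable.
- **Biomarkers**: log Y = β₀ + β_soil·z(exposure) + Σ β_c·z(covariate) + u
  with u = (I − λW)⁻¹e — the same spatial-error process the regression
  assumes. Optional left-censoring at a configured LOD exercises the LOD/2
  path.
- **Seeding**: one master seed, split via `numpy.random.SeedSequence`
  (child 0 soil, 1 cohort, 2 biomarkers); identical truth + seed gives
  byte-identical tables.

What it does **not** emulate: any real city's spatial pattern (land use,
street grids, socially patterned residence), measurement error in the soil
assay, covariate–exposure confounding (covariates are drawn independently
of location), non-lognormal biomarker tails, or informative missingness.
Passing recovery tests therefore show the estimators work *when the model
is true*; they do not validate the exposure model against real cohorts.

## Calibration studies and problem sizes

Three seeded experiments (in `soil2bio.experiments`, also run by
`scripts/acceptance.py`):

- **Parameter recovery**: one 2000-sample soil field on a 4 km domain is
  kriged once; 200 replicates each draw a 281-child cohort, generate the
  biomarker (β_soil = 0.109, λ = 0.6, covariate effects of cohort-typical
  size), and refit by ML. Scored on soil-coefficient bias, 95% Wald-CI
  coverage, and mean λ̂. The field is generated once because a city's soil
  landscape is fixed across cohort draws.
- **Screen routing**: 100 runs at n = 281 under i.i.d. errors (expect ~80%
  kept on OLS at p < 0.2) and under λ = 0.6 (expect nearly all refit as
  SEM).
- **Pipeline null**: full pipeline runs with β_soil = 0 and λ = 0.6; the
  standardized soil term should exceed |z| = 1.96 at roughly the nominal 5%
  rate for every exposure method. The cohort stays at n = 281 (the Wald
  z-statistics are visibly anti-conservative at half that size), while the
  soil field is reduced to 400 samples on a 2 km domain; rates are
  estimated from 150 runs so the maximum over ~11 methods is resolved
  against a 10% bound (binomial SD ~1.8 percentage points per rate).

## Numerical conventions and degenerate inputs

- Quantiles: linear interpolation between order statistics everywhere.
- Kriging: singular local systems (after duplicate averaging) get a
  diagonal jitter; negative combined-method predictions are floored at zero
  and logged; kriging variances are clipped at zero.
- Variogram on a constant field: pure-nugget model with a warning.
- Nearest-sample ties: broken by lowest sample id. Buffer boundaries
  (distance exactly equal to the radius) are inclusive.
- Coordinates must be projected meters; a magnitude heuristic
  (|x| ≤ 180, |y| ≤ 90) warns when inputs look like lon/lat degrees.
- Zero-variance predictors are dropped with a warning; rank-deficient
  designs raise with the collinear column names.
- Creatinine ≤ 0 excludes the record (NaN) with a log entry rather than
  raising, matching how such records are handled in cohort practice.

## Known limitations

- No anisotropic variograms, co-kriging, or propagation of kriging variance
  into the regression stage.
- No spatial-lag or Durbin specifications; the error model is the only
  spatial regression.
- The dose pathway is soil ingestion only (no dermal, drinking-water, or
  bioavailability adjustment).
- Exposure is assigned to a single home point; schools, parks and previous
  residences are out of scope (nonresidence years are mean-imputed).
- Moran's I inference relies on the normality approximation; a permutation
  option exists for weights where that approximation is doubtful.
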