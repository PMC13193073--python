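# soil2bio

Soil-metal exposure assessment and spatial-error biomarker regression for
child cohorts.

Urban soils carry legacy contamination — lead from gasoline and paint,
arsenic from pesticides, mercury and cobalt from industry — and children
ingest and inhale soil and soil dust where they live. `soil2bio` implements
the analysis chain that links point-sampled soil-metal concentrations
(mg/kg at surveyed locations across a city) to blood and urine metal
biomarkers in a cohort of children, for epidemiologists and exposure
scientists who want that chain as tested, reusable, seedable code rather
than a one-off script.

## What it computes

**Exposure metrics.** Per child and metal: the closest soil sample within
90 m; mean and maximum over 90 m and 275 m buffers; interpolated surfaces
evaluated at the home — ordinary kriging (OK), triangulated irregular
network (TIN), and three skew-adapted combinations that split the sample at
the upper Tukey fence (Q3 + 1.5·IQR) and sum a TIN fit to the hotspot
stratum with an OK fit to the bulk (optionally kriged on the log scale).
Methods are ranked by k-fold cross-validated RMSE at held-out sample
locations. And a daily ingestion dose

    D = C · IR · EF · CF / BW        [µg/kg body weight/day]

with intake rate IR = 60 mg/day, CF = 10⁻⁶ kg/mg, body weight BW, and the
residence-weighted exposure factor

    EF = (residence_years · C_home + nonresidence_years · C_city)
         / (age · C_city).

**Regression.** Outcomes are log-transformed and predictors standardized;
each exposure metric enters its own model per biomarker. OLS residuals are
screened with Moran's I over k-nearest-neighbor spatial weights; models
with autocorrelated residuals (p < 0.2) are refit by maximum likelihood as
a spatial-error model

    y = Xβ + u,    u = λWu + e,    e ~ N(0, σ²I).

A standardized coefficient β on the log outcome reads as a
100·(exp(β) − 1) percent change in the biomarker per SD of exposure.

**Synthetic studies.** A first-class generator produces soil fields
(lognormal Gaussian-process background plus a Pareto-spike outlier stratum
clustered around point sources), cohorts (ages 9–11, residence histories,
covariates), and biomarkers from the spatial-error generating model — with
the full ground truth serialized, so estimator recovery is testable. See
`docs/methods.md` for models, defaults, and limitations.

## Worked example

```python
import warnings
from soil2bio.pipeline import PipelineConfig, run
from soil2bio.spatial import percent_change, ci_percent

cfg = PipelineConfig(
    seed=7, n_soil_samples=1200, n_cohort=281, domain_size_m=3000.0,
    simulation={"beta_soil": 0.109, "lambda_true": 0.6},
    select_best=True, k_folds=5, outlier_sensitivity=False,
)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")      # variogram/kriging notices
    res = run(cfg)

print(res.selected_method["Pb"])                 # OK
print(res.rmse_tables["Pb"])
fit = res.fits[("blood_pb", "dose")]
b, se = fit.params["exposure"], fit.bse["exposure"]
print(fit.method, fit.n, round(fit.lam, 3))      # SEM 281 0.613
print(round(percent_change(b), 1),
      [round(x, 1) for x in ci_percent(b, se)])  # 7.3 [0.2, 14.9]
```

This simulates a skewed soil-Pb field (1200 samples on a 3 km domain) and a
281-child cohort whose log blood-Pb is generated with a true standardized
soil effect of 0.109 and spatial error λ = 0.6, then runs the whole chain.
With this seed cross-validation selects ordinary kriging (RMSE 723 vs 821
for TIN; the combined variants trail on this smooth-bulk field). The dose
model's OLS residuals show strong autocorrelation (Moran z = 11.3), so the
screen refits it as a spatial-error model: λ̂ = 0.613 (truth 0.6), and the
estimated soil coefficient 0.070 (SE 0.035) reads as a 7.3% rise in
blood-Pb per SD of dose, 95% CI [0.2%, 14.9%] — attenuated from the
generating 0.109 because the dose metric is a nonlinear transform of the
exposure that generated the biomarker. The cohort's median Pb dose is
0.225 µg/kg/day (the mean, 1.49, is hotspot-dominated — the dose equation
is quadratic in home concentration; see `docs/methods.md`).

There is also a CLI over the same pipeline:

```sh
soil2bio run-all --config config.yaml --seed 7 --outdir out/
soil2bio simulate --config config.yaml --outdir out/   # inputs only
soil2bio report --config config.yaml --outdir out/     # tables + figures
```

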