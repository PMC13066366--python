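# agballoc

Decoupling grassland aboveground biomass (AGB) into its **horizontal**
allocation — fractional vegetation cover (FVC) — and its **vertical**
allocation — community canopy height — from gridded satellite-style data
and plot surveys, with trend mapping, driver attribution and diversity
tipping-point analysis on top.

The package is aimed at remote-sensing vegetation ecologists who want to
track canopy-height change at scales where direct LiDAR retrieval of
herbaceous canopies is unreliable.  The core idea: if biomass is
volumetric,

```
AGB  ≈  ρ_t · H · C            (g m⁻²)
```

with `C` the cover fraction, `H` the canopy height (cm) and `ρ_t` a
type-specific bulk density, then the ratio `AGB / C` isolates the
vertical dimension and a per-type linear quantile regression

```
H  =  a_t · [AGB / C]  +  b_t
```

calibrated on surveyed heights turns gridded biomass and cover into
gridded height.  The components:

* **AGB** — random-forest upscaling of plot biomass under three forcing
  ensembles (satellite metrics, climate variables, combined), with a 10%
  holdout, five-fold cross-validation repeated four times, random
  oversampling of the high-biomass minority, and BIC-approximated
  Bayesian model averaging over the fold models.
* **FVC** — two-endmember linear spectral mixture analysis of NDVI,
  `C = (NDVI − NDVI_soil)/(NDVI_veg − NDVI_soil)`, with per-type
  endmembers optimized by exhaustive grid search against surveyed cover;
  a Beer–Lambert gap-fraction alternative `C = 1 − exp(−k·LAI)` serves as
  an independent cross-check.
* **Trends** — per-pixel OLS trends with two-sided t tests
  (`df = n − 2`), the closed-form identities `p = 2(1 − F_t(|t|))`,
  `R² = t²/(t²+df)`, `r = t/√(t²+df)`, slope CIs, area fractions and
  ensemble-SD maps.
* **Drivers** — piecewise structural equation models of height and cover
  trends on z-scored trends of radiation (R_a), precipitation (P_r),
  temperature (T_a), CO₂ (C_a) and grazing pressure (G_p), stratified by
  the sign of the height trend, plus linear mixed models with pairwise
  interactions (e.g. ΔT_a × ΔG_p) and a random intercept by grassland
  type.
* **Diversity** — binned responses of the height trend to species
  richness and foliage height diversity (FHD), with the tipping point
  where the fitted response crosses zero.
* **Synthetic scenes** — a generator that encodes exactly the structure
  above (volumetric allometry, linear mixing, Beer–Lambert coupling,
  linear driver forcing) with known ground truth, so every stage is
  testable end to end without restricted survey data or satellite
  archives.

## Worked example

```python
from agballoc import (
    asymmetric_allocation_config, generate_scene, sample_surveys,
    SurveyNoise, optimize_endmembers, sma_fvc, AGBEnsembleModel,
    compute_ratio, fit_height_scaler, height_cube, national_trend,
)
from agballoc.agb import scene_feature_cubes

scene = generate_scene(asymmetric_allocation_config(seed=0))
surveys = sample_surveys(scene, 800, noise=SurveyNoise(5.0, 0.02, 1.0), seed=1)

endmembers = optimize_endmembers(surveys)
fvc = sma_fvc(scene.ndvi, endmembers, scene.type_map)

results = AGBEnsembleModel.from_scene(scene, surveys).fit(seed=2)
cubes = scene_feature_cubes(scene)
agb = sum(results.predict_cube(cubes, lbl) for lbl in results.labels) / 3

height = height_cube(compute_ratio(agb, fvc), fit_height_scaler(surveys),
                     scene.type_map)

print(f"true height trend {national_trend(scene.true_height).slope:+.3f} cm/y")
print(f"est. height trend {national_trend(height).slope:+.3f} cm/y")
print(f"est. AGB trend    {national_trend(agb).slope:+.2f} g m-2/y")
print(f"est. FVC trend    {100 * national_trend(fvc).slope:+.2f} %/y")
```

Output (seed 0; a 50×50 grid over 2001–2022):

```
true height trend -0.038 cm/y
est. height trend -0.012 cm/y
est. AGB trend    +0.17 g m-2/y
est. FVC trend    +0.18 %/y
```

The generator's asymmetric-allocation preset encodes a landscape where
cover expands (+0.24 %/y) while canopy height declines (−0.04 cm/y), so
biomass still rises; the estimation chain recovers the direction of all
three national trends (the height amplitude is attenuated because the
survey-noise–affected ratio flattens the calibration slope — see
`docs/methods.md`).  The same chain, plus SEM/LMM driver attribution and
diversity analysis, runs as one command:

```
agballoc run --seed 0 --report report.json
```

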