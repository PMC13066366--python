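# Methods

## The decoupling model

Community biomass in herbaceous vegetation is treated as volumetric:
per-pixel aboveground biomass (AGB, g m⁻²) is the product of a
type-specific bulk density ρ_t (g m⁻² per cm of height per unit cover),
canopy height H (cm) and fractional cover C,

    AGB = ρ_t · H · C · exp(ε),        ε ~ N(0, σ²_AGB,log).

The multiplicative lognormal error reflects that biomass is positive and
right-skewed.  Under this model the ratio AGB/C is proportional to
height, which is what makes the vertical dimension recoverable from two
quantities that optical remote sensing can deliver (gridded biomass and
cover) even though height itself saturates the optical signal.

Assumptions worth stating plainly: ρ_t is constant within a grassland
type and through time (no shift in tissue density or canopy packing);
cover and height capture all systematic biomass variation (no separate
phenology term — everything is a single peak-season composite per year);
and the survey plots are exchangeable with the pixels they fall in.

## Cover: spectral unmixing and the gap-fraction cross-check

Pixel NDVI is modeled as a linear two-endmember mixture,
NDVI = C·NDVI_veg + (1−C)·NDVI_soil, inverted and clipped to [0, 1].
Endmembers are fitted per grassland type by exhaustive grid search (soil
∈ [0, 0.3], vegetation ∈ [0.5, 1.0], step 0.01 — all configurable)
minimizing the RMSE against surveyed cover.  A deterministic grid was
chosen over an iterative optimizer so the fit is exactly reproducible
and testable; ties are broken toward the widest soil–vegetation interval,
which under noise biases the chosen pair outward by at most one grid
step (observed in Monte-Carlo tests and well inside the ±0.02 recovery
band).  Endmembers are time-invariant over the record.

The gap-fraction alternative C = 1 − exp(−k·LAI) uses k = 0.5, the
spherical leaf-angle canopy value; it exists as an independent route to
cover so that trend agreement between the two methods can be checked.

## Biomass: forest ensembles, oversampling, fold-level BMA

Plot biomass is upscaled by random forests under three forcings:
satellite metrics, climate variables, and their combination.  Every
forced variable enters as two features — its per-pixel long-term mean
and the per-year anomaly against that mean.  This mirrors how climate
predictors are built for upscaling (long-term means plus interannual
anomalies) and matters numerically: the mean feature absorbs the steep
cross-sectional (between-site) biomass gradient, while the anomaly
feature carries the within-pixel temporal signal, so interannual trends
in the predictions are not contaminated by space-for-time substitution.
The static grassland-type grid is part of every forcing; it is a known
input of the workflow (endmembers and height scalers are fitted per
type) and stands in for the type-resolving information that richer real
feature sets carry.

Training: 10% of plots are held out untouched; the remaining 90% are
split five-fold, with each fold model trained on the other four folds
after random oversampling of records above the 75th biomass percentile
(duplicated with replacement until they match the count below — the
threshold is configurable).  The five-fold loop is repeated four times
with fresh splits to average the validation error.  The five fold models
are combined by BIC-approximated Bayesian model averaging: with a
Gaussian likelihood for fold k's validation residuals,
BIC_k = n_k·ln(rmse_k²) up to a shared constant, and weights ∝
exp(−BIC_k/2).  Because BIC differences scale with n, the weights are
often close to degenerate — effectively model selection with a smooth
fallback — which is the intended behavior of this approximation.
Production models for gridded prediction are refit on the full plot set
under the same five-fold scheme; the gridded AGB used downstream is the
ensemble average over the three forcings, and the spread of the three
per-forcing trend maps gives the ensemble-SD map.

Random-forest hyperparameters default to 200 trees (100 in the canned
experiments) with scikit-learn defaults otherwise.

## Height: quantile-regression scaling

Surveyed height is regressed on the surveyed AGB/C ratio per type with
linear quantile regression (pinball loss), default τ = 0.5.  The median
was chosen because the ratio's error distribution is heavy-tailed
(biomass noise is multiplicative and the ratio divides by a noisy
cover); τ is a first-class parameter and `percentile_robustness`
verifies that the recovered trend direction is invariant across τ ∈
{0.25, 0.5, 0.75} and an OLS mean fit.  The intercept is retained and
negative predicted heights clip to 0 cm.  Ratios are only formed where
cover ≥ 0.05 (configurable floor) to avoid division blow-up in sparse
vegetation.

A known, accepted bias: measurement error in the survey ratio attenuates
the calibration slope (classical errors-in-variables), so recovered
height *amplitudes* are damped — in the canned experiments the national
height-trend magnitude comes out a factor ~2–3 low while its sign and
the spatial pattern are robust.  Trend direction, not amplitude, is the
quantity this chain is designed to deliver.

## Trends and reported statistics

All trends are OLS on calendar year.  Per-pixel maps carry slope, t,
two-sided p (Student t, df = n−2) and R²; no multiple-testing adjustment
is applied by default (a Benjamini–Hochberg flag exists).  The
closed-form identities p = 2(1−F_t(|t|; df)), R² = t²/(t²+df),
r = t/√(t²+df) and CI = b ± t_{(1+γ)/2,df}·b/t are exposed directly so
any reported (t, df, slope) triple can be expanded into its companions.
Area fractions treat pixels as equal-area, which is exact on the
synthetic grid and an approximation anywhere else.

## Driver attribution

Pixel trends of height, cover and biomass are regressed on z-scored
pixel trends of five drivers (R_a, P_r, T_a, C_a, G_p).  The piecewise
SEM evaluates a DAG as component OLS regressions; the default topology
sends all five drivers into both height and cover and closes with
AGB ← {CH, FVC}, the decoupling premise (the closure edge is
configurable).  Responses are z-scored too, so coefficients are
standardized paths.  Pixels are stratified by the sign of the height
trend; exact-zero trend pixels are excluded and counted.  The linear
mixed model adds pairwise interaction products of driver trends with a
random intercept by grassland type — the grouping factor is an
interpretation (nothing in the analysis chain dictates one) and is
logged as such; with a single group the model degrades to OLS with a
notice.

## Diversity responses

Height trends are binned along a diversity axis — unit-width integer
bins for species richness, 25 equal-width bins for FHD — and a line is
fitted through the bin means.  Correlations are reported at the bin
level (the small printed degrees of freedom of such analyses imply bin-
level fitting); the pixel-level correlation is kept as a secondary
statistic.  The tipping point is −intercept/slope when it falls inside
the observed range, else "none".  Binning means "exact" recovery is
exact only up to the offset between bin centers and within-bin means,
orders of magnitude below one bin width.

## The synthetic generator: what it emulates and what it does not

Scenes are year × row × col cubes built from: per-type base height,
cover, density and endmembers; five driver anomaly cubes, each a
linear-in-time ramp whose slope is spatially modulated by a smooth
zero-mean field (so trends vary regionally and can flip sign), plus a
smooth static field, a common interannual term and iid pixel noise;
linear height/cover responses to the driver anomalies; the allometry,
mixing and Beer–Lambert relations above; Poisson species richness whose
mean falls with local grazing-trend intensity, and an FHD grid tracking
richness.  Measurement noise on surveyed AGB/FVC/height is additive
Gaussian, clipped to each variable's support.

The asymmetric-allocation preset fixes the study conditions: national
cover trend +0.0024 fraction y⁻¹ and height trend −0.04 cm y⁻¹ (so
biomass rises while the canopy dwarfs); height responds − to warming and
grazing, + to radiation, precipitation and CO₂; interannual driver
variability is set comparable to the 22-year trend amplitude, as for
real climate anomalies, which places the national cover series around
t ≈ 4–5 and the biomass series around t ≈ 2.5 over 22 years and lets
the survey window (2009–2016) span most of the anomaly range the models
later predict over.  Mean heights (~16 cm), biomass (~70–80 g m⁻²) and
NDVI endmembers (0.10–0.16 soil, 0.76–0.84 vegetation) are in the range
of temperate/alpine grassland values.

What the generator does *not* emulate: radiative transfer or sensor
physics beyond linear mixing; spatial autocorrelation beyond Gaussian
smoothing (no anisotropy, no terrain); within-season phenology;
plot-location bias; type-map error; and any feedback of vegetation on
the drivers.  Passing tests therefore demonstrate that the estimation
chain recovers the structure it assumes when that structure holds — they
do not validate the allometry or the mixing model against real canopies.

## Numerical choices and degenerate inputs

Constant series get slope 0, t 0, p 1, R² 0 by convention.  Pixels with
fewer than 3 finite years, zero year variance, or any missing feature
are nodata, and nodata propagates through every map operation.  A
perfectly collinear height calibration short-circuits the iterative
quantile solver (the OLS line is exact for every τ).  Zero validation
error gives a fold the whole BMA weight (shared if tied).  Degenerate
cases raise typed errors naming the offending grassland type or column
(`ConfigError`, `DataError`, `NumericalError`), which the CLI maps to
exit codes 2/3/4.

## Problem sizes

The canned experiments use 50×50×22 scenes with 800 plots (4% of
pixel-years — proportionally far denser than a national survey, as a
desk-scale grid is far smaller), 100-tree forests, and seed counts of
10–20 per experiment; SEM sign recovery uses 100×100 scenes (10⁴ pixels
against the millions a national pixel census would provide).  These
sizes keep a full multi-seed experiment within minutes while leaving
every recovery criterion comfortably determined.

## Known limitations

Fold-level (not tree-level) model averaging is one reading of "Bayesian
model averaging over a random forest"; it was chosen because it is
well-defined and testable.  The height-amplitude attenuation discussed
above is inherent to calibrating on noisy survey ratios.  GEDI-style
structural metrics are consumed as given covariates, never derived.  No
spatial blocking is used in cross-validation (splits are random), so
holdout R² on spatially smooth scenes is optimistic about transfer to
unsampled regions.
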