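# Methods

## Geographic referencing

All distance-based indicators are computed in a per-stock Euclidean frame:
the origin is the componentwise minimum over all vertices of the stock's
survey strata, latitude converts at 111.195 km/degree (spherical earth,
mean radius 6371 km), and longitude degrees are scaled by the cosine of the
strata's midpoint latitude. "Midpoint" is the bounding-box latitude midpoint
by default; an area-weighted centroid-latitude alternative is available
(`build_frame(..., midpoint="centroid")`). The two choices differ by well
under the rounding of any reported trend. One frame per stock × season is
built once and reused for every year, so indicator series are comparable
across years. No conformal projection machinery is used — over a stock area
of a few hundred km the cosine correction is the whole story, and the same
frame maps results back to longitude/latitude exactly.

## Areas of influence

Station weights are Voronoi cell areas clipped to the union of the stock's
strata polygons. Implementation: GEOS Voronoi polygons extended over a box
10× the data/boundary extent (so hull cells are finite), matched back to
their generating stations by point-in-polygon, then intersected with the
dissolved strata boundary. Clipped cell areas partition the boundary, so
Σwᵢ equals the strata area to floating-point precision; the unit tests
verify this at 1e-6 relative and also check cells against an independent
nearest-neighbour rasterization oracle (2000×2000 grid, 0.5% per cell).

Degenerate inputs: coincident stations are merged into one pseudo-site whose
cell area is split equally among them (with the biomass-weighted indicators
this is equivalent to giving the merged site the mean biomass); stations
outside the strata keep whatever clipped cell area they have, and a
zero-area cell drops the station with a logged warning. Clipping is to the
dissolved union of strata rather than per stratum; per-year weights use all
stations in the stock's strata, zeros included, since the positive-area
indicator is defined by the zero/non-zero split.

## Indicators and undefined years

CG, inertia (with eigendecomposition of the weighted covariance: axis
standard deviations are square roots of the eigenvalues, the bearing is the
principal-axis angle in [0, π) from east), biomass-weighted depth, positive
area (strict z > 0, no epsilon), and the unweighted sample-location CG. A
year with Σwᵢzᵢ = 0 has no defined CG; such years are emitted with
`defined=False` and NaN indicator values and are excluded from regressions —
the only treatment consistent with the ratio definition.

## Trend analysis

Indicator-on-year by OLS, with a two-sided t-test on the slope. Serial
correlation is detected by the Durbin-Watson statistic with the large-sample
normal approximation z = (1 − DW/2)·√n, one-sided for positive
autocorrelation at α = 0.05; DW is the canonical companion of the AR(1)
correction and the approximation is adequate at the 20–54-year series
lengths involved. Flagged series are refit with AR(1)-correlated errors by
exact Gaussian maximum likelihood: β and σ² are profiled in closed form at
fixed ρ, and the scalar ρ is maximised on (−0.98, 0.98) by bounded search
with ρ = 0 always evaluated as a fallback reference. Filtered (missing)
years are handled as a continuous-time AR(1), correlation ρ^|Δt|. Slope
standard errors use the df-corrected GLS variance and t reference with
df = n − 2; the ML fit matches statsmodels' SARIMAX state-space likelihood
to ~1e-3 on evenly spaced fixtures (tested). The known O(1/n) downward bias
of the ML ρ estimate is documented, bounded in a test (<0.05 at n = 100),
and not corrected. Constant series return a zero slope with a warning
rather than an error.

## Variable importance

For each indicator series the full 2³ model set over {log biomass,
log relative F, temperature} is fit by the same AR(1)-GLS maximum-likelihood
machinery — ML rather than REML because the models differ in fixed effects
and their likelihoods must be comparable. Parameter count k = p + 3
(intercept, ρ, residual variance). AIC is the default criterion; AICc is
available by flag and its correction term is tested. Akaike weights are
exp(−Δᵢ/2) normalized over the 8 models; a predictor's importance is the
summed weight of its 4 containing models; ranks allow ties at 1e-10, and
tied predictors each count as "ranked first" in the cross-stock summary, so
proportions need not sum to one. Model-averaged coefficients are reported
both conditionally (normalized over containing models) and in full (absent
models contributing zero). Predictors enter untransformed beyond the logs
(natural log; zero catch or index excludes the year rather than adding an
offset, since no offset convention is defined for these data), and are not
standardized, so averaged coefficients carry natural units. Rank-deficient
designs (e.g. a constant relative-F column) are fit by least squares with a
pseudoinverse: the log-likelihood equals the reduced model's and the wasted
parameter is penalized by the criterion, which is exactly the behaviour a
degenerate predictor should have.

## Predictor construction and filters

The biomass index and bottom temperature are design-based stratified means
Σ_h (A_h/A)·ȳ_h with A the *total* stock strata area, so a year missing a
stratum is shrunk and its coverage fraction reported. Year filters: trend
analysis keeps years where every stratum has ≥1 station; the importance
analysis additionally requires temperature coverage (default: every stratum
has ≥1 temperature record; the threshold is configurable as a minimum
covered-area fraction, since the original "representative" rule is not
published) and an available, positive catch. Relative F is annual catch
divided by the biomass index; its scale (catch units) only shifts the log
intercept.

## Synthetic survey generator

The generator emulates the features the pipeline relies on: proportional
allocation of stations to strata (largest-remainder rounding, floor of 2 so
within-stratum means exist; counts deviate from exact proportionality by at
most 1), uniform placement within rectangular strata, an isotropic
Gaussian-decay biomass plume with log-normal noise whose center drifts
linearly (default 1 km/yr north over 50 years, nominal inertia 450 km² =
(15 km)² per axis, chosen so the plume sits comfortably inside the 150×150
km domain), zero-inflation with occupancy probability
(1 − zi)^(1+(d/scale)²) decaying with distance d from the center (so
positive area co-varies with concentration, and the zi = 0 / zi = 1 limits
are exact), a north-south temperature gradient plus interannual anomaly,
a planar depth field, and a catch series equal to an exogenous log-AR(1)
relative-F series times the realized survey index — so the fitted
log relative F recovers the exogenous series exactly. A nonzero β displaces
the next year's true east-west CG by β·(log relF anomaly), planting a known
fishing-pressure effect. Station density defaults to 0.0015/km² (~34
stations/year), the order of one station per few hundred km² typical of
groundfish surveys.

What the generator does not emulate: coastline/bathymetry geometry,
gear/vessel changes, anisotropic or multimodal biomass fields, and spatially
targeted fishing. Passing tests therefore demonstrate estimator correctness
and calibration under the stated design, not robustness to those realities.

## Validation studies (scenarios.py, scripts/acceptance.py)

Fixed study conditions, not tuning knobs: (a) trend recovery — default
scenario, 500 (tests) / 100 (script) independent surveys; the mean
pipeline-estimated YCG slope must sit within 0.05 km/yr of the planted 1.0
and the 95% CI cover the truth 92–97% of the time; (b) ranking recovery —
the planted-driver scenario (β = 50 km per unit log relF, ρ_relF = 0.95,
flat temperature anomaly, doubled station density so indicator noise does
not mask the driver) must rank relative F first for XCG in ≥90% of 200
runs, while a constant-relF null stays ≤20%; (c) the design check on a
stationary 20-year scenario must leave ≥93% of sample-location CG trend
tests non-significant at α = 0.05; (d) Voronoi conservation on 200 random
rectangular/L-shaped instances at 1e-6 relative, with the raster oracle run
on a seeded 25-instance subset (0.5% per cell) to keep the suite fast.
Problem sizes in the acceptance script (100/60/100 seeds) are smaller than
the test-suite studies; both are seeded and deterministic.

## Known limitations

- The Durbin-Watson normal approximation is anti-conservative for very
  short series; below n = 4 no correction is attempted.
- AR(1) ρ and trend inference use t with df = n − 2, a common approximation
  that ignores ρ-estimation uncertainty; coverage is verified by simulation
  rather than asserted analytically.
- The importance analysis assumes linear predictor effects and first-order
  error correlation; interactions and mixed multi-stock models are out of
  scope by design.
- Reproduction of the published survey analyses requires the deposited
  survey/catch data files, which are not distributed with the package.
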