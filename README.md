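# stockdist

Spatial distribution analysis for trawl-survey fish stocks: Voronoi-weighted
spatial indicators, AR(1)-corrected time trends, and the relative importance
of population size, fishing pressure and bottom temperature ranked by summed
Akaike weights.

## Who this is for

Fisheries scientists and quantitative ecologists who track where a stock
lives from stratified-random bottom-trawl survey data — e.g. whether a stock
is moving poleward or deeper, expanding or contracting its range, and
whether those changes track abundance, exploitation, or temperature.

## The indicators

Let station *i* have location *x*ᵢ (km, in a Euclidean frame with origin at
the minimum longitude/latitude of the stock's survey strata, longitude scaled
by cos of the midpoint latitude), biomass *z*ᵢ (kg per tow) and area of
influence *w*ᵢ — the area of its Voronoi (Dirichlet) cell clipped to the
strata boundary, so irregularly spaced stations are weighted fairly.

- **Center of gravity** CG = Σ *x*ᵢ*w*ᵢ*z*ᵢ / Σ *w*ᵢ*z*ᵢ — the bivariate
  mean location (XCG east-west, YCG north-south, km). Replacing *x*ᵢ with
  station depth gives the biomass-weighted mean depth (m).
- **Inertia** I = Σ (*x*ᵢ − CG)² *w*ᵢ*z*ᵢ / Σ *w*ᵢ*z*ᵢ — the variance (km²)
  of location around the CG, decomposed into orthogonal maximum/minimum
  axes whose square roots are standard deviations (km).
- **Positive area** PA = Σ *w*ᵢ[*z*ᵢ > 0] — the area (km²) occupied by
  non-zero biomass.

Each indicator series is regressed on year (OLS; refit with AR(1) errors by
exact maximum likelihood when the Durbin-Watson test flags serial
correlation). The CG of sample locations alone (*z*ᵢ ≡ 1) is regressed on
year as a check that apparent movement is not a sampling-design artifact.

For each indicator, all 8 subsets of {log biomass index, log relative F
(catch / stratified mean kg per tow), stratified mean bottom temperature}
are fit as GLS models with AR(1) errors; a predictor's importance is the sum
of Akaike weights of the 4 models containing it, and model-averaged
coefficients are reported.

## Worked example

The numbered scripts under `analysis/` run the whole pipeline on a synthetic
survey with known dynamics (50 years, nine 2500-km² strata, a biomass plume
drifting north at 1 km/yr):

```sh
python analysis/01_simulate.py
python analysis/02_indicators.py
python analysis/03_trends.py
python analysis/04_importance.py
```

`03_trends.py` prints, for seed 1:

```
YCG trend: 1.063 +/- 0.103 km/yr (truth 1.0), p = 9.05e-14, AR(1) applied: False
design check (sample-location CG) p-values: [0.646, 0.193]
```

i.e. the estimated northward drift (1.06 km/yr) recovers the planted 1 km/yr
within one standard error, and the sample-location CG shows no trend — the
movement is in the fish, not the sampling. `04_importance.py` runs a
five-stock suite where fishing pressure drives the east-west CG for three
stocks, and reports relative F ranked first for exactly those three.

The same stages run on real data through the `stockdist` CLI
(`simulate | indicators | trends | importance | all`) given a survey CSV, a
catch CSV and a strata-definition JSON (see `stockdist/io.py` for the
schemas).

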