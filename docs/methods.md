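# Methods

## The analysis model

The package treats site abundance as a linear response to a landscape
covariate measured at an unknown radius: for site *i*, abundance
*y<sub>i</sub>* ≈ β₀ + β₁·*m<sub>i</sub>*(I, r\*) + ε, where
*m<sub>i</sub>*(I, r) is the mean of spectral index *I* inside a circle of
radius *r* around the site and *r*\* is the scale of effect. Nothing in
the scan assumes this form — the scan simply reports the Pearson
correlation surface over (index, radius, date) — but the synthetic ground
truth, the model-selection stage and the recovery experiments all use it.

Assumptions worth stating:

* sites within a stratum are spatially random (checked by the quadrat
  test, not assumed silently) and their abundances are exchangeable given
  the covariates — spatial autocorrelation of residuals is handled by
  stratification only;
* abundance is analysed untransformed with ordinary least squares, which
  suits pooled counts in the hundreds; a Poisson generator option exists
  for users who want count-model behaviour, but the analysis stage is OLS
  throughout;
* no multiple-testing correction is applied across the 60-radius scan by
  default. Neighbouring radii are strongly dependent (nested buffers), so
  per-cell α is interpretable as a per-scale screen, not a familywise
  guarantee; a Benjamini–Hochberg option is available
  (`correlation_scan(..., bh_correct=True)`).

## Spectral indices

Normalized differences (NDVI, NDWI2, MNDWI) are computed per pixel with
zero-denominator pixels masked rather than zeroed — a 0 would be a valid
index value and silently bias buffer means. SATVI uses soil factor
L = 0.5 (the common published default), exposed as a parameter. The
tasseled cap ships the published Landsat-8 OLI at-sensor-reflectance
coefficient set (Baig et al. 2014) as packaged CSV; the coastal band
carries coefficient 0 because the transform is defined on the six
reflective bands. Whether a given product's tasseled cap should use
at-sensor or surface-reflectance coefficients is a genuine ambiguity; the
default is documented and user-overridable. Because the tasseled cap and
SATVI's L are not scale invariant, integer-DN stacks must pass through
`normalize_reflectance(scene, scale)` before any index.

## Buffer extraction

Pixels enter a buffer when their **centre** lies within the circle
(reproducible, fast, and the common zonal-statistics default); an exact
area-weighted rule is available (`rule="area"`, 16×16 subpixel sampling).
At 25 m radius on the 30 m lattice the circle can contain no pixel
centre; the fallback is the single pixel containing the site, so every
cell has ≥ 1 contributing pixel. Circles that leave the raster raise an
error by default (silent truncation changes means undetectably);
`allow_edge=True` averages over available pixels. Geometry convention:
north-up grids, origin at the top-left corner, pixel value at its centre,
coordinates in projected metres. The per-site implementation sorts pixels
by distance once and reads prefix means for all radii, and is tested for
exact equality against a brute-force all-pixels scan.

## Quadrat CSR test

5×5 quadrats by default (df = 24), window defaulting to the points'
bounding box (pass the true generation window when known — a bounding box
shrinks to the data and slightly biases counts). The p-value doubles the
smaller chi-square tail and caps at 1, so both clustered (upper tail) and
overly regular (lower tail) layouts reject. At small counts the chi-square
approximation is conservative: with 15 points in 25 quadrats (expected 0.6
per cell) the true type-I error at nominal α = 0.05 is ≈ 3.4%, rising to
≈ 5% by n = 30 — the calibration experiment makes this measurable rather
than hiding it. The greedy exclusion helper removes, one at a time, the
point whose removal most increases the p-value (ties to the lowest index);
it is a diagnostic for locating the points driving non-randomness and is
never applied automatically in the pipeline.

## Pre-screen, scan and model selection

The inter-index pre-screen computes correlations across sites at a single
stated radius — by default the largest (1500 m), where buffer means are
most stable — per date, and drops indices with |r| > 0.9 against the
reference (NDVI) unless they are on the keep-list. The shipped keep-list
contains all six indices because each carries a distinct ecological
meaning (productivity, albedo, surface moisture, canopy water, open
water, green+senescent cover); users screening larger registries get the
drop behaviour.

`best_scale` returns the significant scan cell with the largest |r|, ties
broken toward the smaller radius then the earlier date label.

The multi-predictor stage builds one candidate column per index (its
best-scale cell per date; max-|r| cell when nothing is significant; an
explicit (index → radius) map can force any candidate set), then
iteratively drops the worst predictor with VIF ≥ 10, then runs
bidirectional stepwise OLS minimizing AIC (BIC and forward/backward are
options). Two honest caveats, both visible in the examples: AIC admits a
pure-noise predictor with probability ≈ 0.16, so occasional decoy terms
are expected behaviour, not a bug; and when all candidates share latent
structure, the VIF filter can drop the true driver in favour of a less
collinear proxy set — the scan, not the regression, is the
scale-of-effect instrument. Significance stars: *** < 0.001, ** < 0.01,
* < 0.05, . < 0.1.

## Synthetic scenes and what they do (not) emulate

Reflectance is built from two latent Gaussian random fields — vegetation
and moisture — obtained by Gaussian-kernel smoothing of white noise
(kernel SD = corr_length/2; default corr_length 300 m, i.e. 10 pixels,
chosen as a realistic patch grain for steppe mosaics) plus smoothed
per-band noise (SD 0.01), mixed into the seven bands with fixed loadings
around semi-arid base reflectances and clipped to [0, 1]. Greenness-type
indices respond mainly to the vegetation latent and moisture-type indices
to the moisture latent, so planted effects can be index-specific. Site
layouts are dart-throwing CSR (or Thomas-style clusters) with a minimum
separation of 150 m in the study fixture, bounded at 10⁵ attempts.
Abundance noise is Gaussian-then-rounded with a zero floor, matching the
OLS analysis stage; the fixture generates 5 traps × 5 visits per site
(2250 trap-samples over 90 sites) and pools by exact summation, with
per-trap zeros allowed.

Not emulated: radiative transfer, topography, phenology beyond an additive
per-date offset of the vegetation latent, sensor noise structure, cloud
patterns (masks can be injected, not simulated). Passing tests therefore
demonstrate that the *machinery* recovers known structure under realistic
spatial autocorrelation and noise — not that any particular real landscape
satisfies the linear single-scale model.

## Numerical and design choices

* Determinism: every generator takes an explicit seed; identical spec +
  seed gives bit-identical output, and the pipeline re-run with the same
  config writes byte-identical CSVs.
* Scan cells with n < 3 or constant variables carry NaN and are never
  significant; the empty best-scale result is an explicit `None`.
* Perfect collinearity reports VIF = ∞ rather than raising.
* Tukey homogeneous groups across radii use scipy's Tukey HSD and an
  insert-and-absorb compact-letter display; letters follow increasing
  group means, making labels invariant to input order.
* The recovery experiment calibrates noise per replicate so that
  |β₁|·SD(m)/σ equals the requested signal-to-noise (default 2) over the
  realized buffer means, and sets β₀ = −β₁·min(m) + 4σ to keep expected
  counts off the zero floor.
* Problem sizes in the shipped experiments — 250×250-pixel scenes, 45
  sites, 100 recovery replicates, 25 null shuffles × 3000 cells, 1000 CSR
  replicates — give Monte-Carlo error comfortably below the decision
  bands while keeping a full run in tens of seconds.

## Known limitations

GeoTIFFs are read and written with plain geotransform tags but no CRS
metadata — all inputs must share one projected, metre-based CRS, and no
reprojection or resampling is offered. The quadrat window choice is the
user's responsibility. The stepwise/VIF stage inherits the classical
fragilities of those procedures (documented above) by design, since the
goal is the standard pipeline, not its repair.
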