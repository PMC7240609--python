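# steppescan

**Which spectral index, at which spatial scale, best explains site-level
insect abundance?**

Ground-dwelling insects such as carabid beetles respond to vegetation and
moisture not only at their trap location but across the surrounding
landscape, and the radius at which a landscape covariate matters — its
*scale of effect* — is unknown in advance. `steppescan` implements the
standard multiscale design used to find it from satellite imagery:

1. compute spectral indices from a multiband reflectance raster
   (Landsat-8-OLI-like band set, 30 m pixels): NDVI, tasseled-cap
   brightness and wetness, MNDWI, Gao's NDWI2 and SATVI;
2. for every sampling site, extract the mean of each index inside circles
   of radius 25, 50, …, 1500 m (60 scales);
3. check each stratum's site layout for complete spatial randomness with a
   two-sided chi-square quadrat test (and optionally identify the points
   driving non-randomness);
4. scan the Pearson correlation of site abundance with every
   (index, radius, date) cell and pick the significant cell with the
   largest |r|;
5. screen collinearity with variance inflation factors (drop VIF ≥ 10) and
   select a multiple regression by bidirectional stepwise AIC.

A synthetic-scene module generates autocorrelated reflectance fields, CSR
or clustered site layouts with a minimum separation, and abundances planted
on one index at one known radius — so the whole chain is testable end to
end without downloading imagery.

## The statistics in brief

For abundance *y* and buffer mean *m* of index *I* at radius *r* the scan
computes the product-moment correlation *r*<sub>P</sub> with two-sided
*p* from *t* = *r*<sub>P</sub>·√((n−2)/(1−*r*<sub>P</sub>²)) on *n*−2 df.
The CSR test compares quadrat counts *n<sub>i</sub>* over an *nx*×*ny*
partition to the Poisson expectation via χ² = Σ(*n<sub>i</sub>*−n̄)²/n̄,
df = *nx·ny*−1, with the two-sided p = min(1, 2·min(P(X≤χ²), P(X≥χ²)))
so both clustering and excess regularity reject. VIF<sub>j</sub> =
1/(1−R²<sub>j</sub>) from regressing predictor *j* on the others; the final
model reports the overall *F*, its df pair, *p* and *r*².

## Worked example

```bash
python examples/04_scale_scan_and_models.py
```

plants an abundance response on NDVI at a 300 m radius over 45 sites and
scans all six indices; the run prints

```
best scale per index (max |r| among p < 0.05 cells):
  NDVI    radius    300 m   r = +0.979   p = 1.60e-31
  TC-B    no significant scale
  TC-W    radius    400 m   r = +0.533   p = 1.65e-04
  MNDWI   radius    450 m   r = +0.484   p = 7.57e-04
  NDWI2   radius    350 m   r = +0.838   p = 6.96e-13
  SATVI   radius    300 m   r = +0.716   p = 3.14e-08

stepwise model (after VIF filtering):
  terms: NDWI2(+) @350m ***; SATVI(+) @300m ***; MNDWI(-) @450m
  F = 288.73 on (3, 41) df, p = 1.37e-27, r2 = 0.955
```

The scan recovers the planted 300 m scale exactly (r = 0.979 at 300 m);
correlated moisture indices peak nearby because they share latent spatial
structure with NDVI. See `examples/` for scene simulation, buffer
extraction and the CSR test, and `steppescan --help` for the command-line
pipeline (`simulate`, `extract`, `csr-test`, `scan`, `model`, `run-all`).

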