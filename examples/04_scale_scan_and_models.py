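"""The core analysis: find the index and scale that explain abundance.

Plants an abundance response on NDVI at a 300 m radius, scans all six
indices across the full scale grid, reports the best scale per index, and
fits the VIF-filtered stepwise regression model.
"""

from steppescan import (
    DEFAULT_INDICES,
    PlantSpec,
    SceneSpec,
    best_scale,
    compute_index,
    correlation_scan,
    extract_cube,
    generate_reflectance_scene,
    generate_sites,
    make_scale_grid,
    per_scale_models,
    plant_abundance,
)

scene = generate_reflectance_scene(
    SceneSpec(n_rows=250, n_cols=250, origin_y=7500.0, corr_length=300.0, seed=3, date="2017-05")
)
sites = generate_sites(
    45, (1550.0, 1550.0, 5950.0, 5950.0), min_sep=150.0, seed=4, stratum="typical"
)
scales = make_scale_grid()
plant = PlantSpec("NDVI", radius_star=300.0, beta0=150.0, beta1=400.0, sigma=15.0, seed=5)
sites = plant_abundance(scene, sites, plant, scales=scales)

grids = {"2017-05": {n: compute_index(scene, n) for n in DEFAULT_INDICES}}
cube = extract_cube(grids, sites, scales)
scan = correlation_scan(cube, sites, "typical")

print("best scale per index (max |r| among p < 0.05 cells):")
for name in DEFAULT_INDICES:
    bs = best_scale(scan, name)
    if bs is None:
        print(f"  {name:6s}  no significant scale")
    else:
        print(f"  {name:6s}  radius {bs.radius_m:6.0f} m   r = {bs.r:+.3f}   p = {bs.p:.2e}")

reports = per_scale_models(cube, sites, "typical", scan=scan)
report = reports[0]
print("\nstepwise model (after VIF filtering):")
print("  terms:", "; ".join(report.formatted_terms()))
print(
    f"  F = {report.f_statistic:.2f} on ({report.df1}, {report.df2}) df, "
    f"p = {report.p:.2e}, r2 = {report.r2:.3f}"
)
print(
    "\nThe planted driver is NDVI at 300 m: the scan pins it exactly. Note "
    "the model may carry collinear proxies instead of NDVI itself — the VIF "
    "filter drops the most collinear column first, and with all indices "
    "sharing latent fields that can be the true driver. The scan, not the "
    "regression, is the scale-of-effect instrument."
)
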