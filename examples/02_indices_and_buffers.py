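"""Compute spectral indices on a scene and extract circular-buffer means.

Shows the six shipped indices on a synthetic reflectance scene and how one
site's NDVI buffer mean varies across the 60-radius scale grid.
"""

import numpy as np

from steppescan import (
    DEFAULT_INDICES,
    SceneSpec,
    buffer_mean,
    compute_index,
    generate_reflectance_scene,
    make_scale_grid,
)

scene = generate_reflectance_scene(
    SceneSpec(n_rows=250, n_cols=250, origin_y=7500.0, corr_length=300.0, seed=7, date="2017-05")
)

print("index value ranges over the scene:")
grids = {}
for name in DEFAULT_INDICES:
    grid = compute_index(scene, name)
    grids[name] = grid
    v = grid.values[~grid.mask]
    print(f"  {name:6s}  min {v.min():+.3f}  mean {v.mean():+.3f}  max {v.max():+.3f}")

# one site in the scene interior; buffer means from 25 m to 1500 m
x, y = 3750.0, 3750.0
scales = make_scale_grid()
means = [buffer_mean(grids["NDVI"], x, y, r)[0] for r in scales]
print(f"\nNDVI buffer means at site ({x:.0f}, {y:.0f}):")
for r, m in list(zip(scales, means))[::10]:
    print(f"  radius {r:6.0f} m  mean {m:+.4f}")
print(
    "\nSmall radii see the local pixel neighbourhood; large radii smooth "
    "toward the landscape average — the scale profile a scan exploits."
)
assert abs(means[-1] - np.nanmean(grids["NDVI"].values)) < 0.05
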