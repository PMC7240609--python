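"""Calibration experiments: scale recovery, null rates, type-I error.

These are the package's own operating-characteristic checks, run on
synthetic studies whose ground truth is known:

* **Scale recovery** — plant an abundance response on one index at one
  radius with signal-to-noise |beta1| * SD(m) / sigma = 2 over n = 45
  sites, scan the full 25-1500 m grid, and ask how often the best
  significant cell lands within one grid step (+/- 50 m) of the planted
  radius across replicate seeds.
* **Null calibration** — shuffle abundance against extracted buffer means
  (destroying any real association) and measure the fraction of scan cells
  significant at alpha; and draw CSR layouts and measure the quadrat
  test's rejection rate at alpha.  Both should sit near alpha.

Each experiment is deterministic given its seed and scales linearly in its
replicate count, so callers can trade precision for runtime.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .buffers import extract_cube, make_scale_grid
from .indices import compute_index
from .pointpattern import quadrat_test
from .scan import best_scale, correlation_scan
from .synthetic import (
    PlantSpec,
    SceneSpec,
    generate_reflectance_scene,
    generate_sites,
    plant_abundance,
)

#: geometry shared by the planted-recovery replicates: a 250 x 250 pixel
#: scene (7.5 km square, 30 m pixels) whose interior window keeps the full
#: 1500 m buffer inside the raster for every site
_SCENE_ROWS = _SCENE_COLS = 250
_SITE_WINDOW = (1550.0, 1550.0, 5950.0, 5950.0)


def scale_recovery_experiment(
    n_seeds: int = 100,
    n_sites: int = 45,
    radius_star: float = 300.0,
    snr: float = 2.0,
    beta1: float = 400.0,
    corr_length: float = 300.0,
    min_sep: float = 150.0,
    tolerance_m: float = 50.0,
    index_name: str = "NDVI",
    seed: int = 0,
) -> dict:
    """Fraction of replicates whose best scan scale is within tolerance.

    Noise is calibrated per replicate so that |beta1| * SD(m) / sigma =
    ``snr`` over the realized buffer means m at ``radius_star``; the
    intercept keeps expected counts positive.  Returns a dict with the hit
    rate, per-replicate recovered radii, and the replicate count.
    """
    scales = make_scale_grid()
    rng = np.random.default_rng(seed)
    recovered: list[float | None] = []
    hits = 0
    for rep in range(n_seeds):
        s = int(rng.integers(2**31 - 1))
        scene = generate_reflectance_scene(
            SceneSpec(
                n_rows=_SCENE_ROWS, n_cols=_SCENE_COLS, origin_y=_SCENE_ROWS * 30.0,
                corr_length=corr_length, seed=s, date="d1",
            )
        )
        sites = generate_sites(
            n_sites, _SITE_WINDOW, pattern="csr", min_sep=min_sep, seed=s + 1, stratum="s"
        )
        grid = compute_index(scene, index_name)
        # realized driver SD sets the noise for the requested SNR
        from .synthetic import planted_buffer_means

        probe = PlantSpec(index_name, radius_star, 0.0, 1.0, 0.0)
        m = planted_buffer_means(scene, sites, probe)
        sd_m = float(np.std(m, ddof=1))
        sigma = abs(beta1) * sd_m / snr
        beta0 = float(-beta1 * m.min() + 4 * sigma)  # keep mu off the zero floor
        plant = PlantSpec(index_name, radius_star, beta0, beta1, sigma, seed=s + 2)
        planted = plant_abundance(scene, sites, plant, scales=scales)
        cube = extract_cube({"d1": {index_name: grid}}, planted, scales)
        scan = correlation_scan(cube, planted, "s")
        bs = best_scale(scan, index_name)
        if bs is None:
            recovered.append(None)
        else:
            recovered.append(bs.radius_m)
            if abs(bs.radius_m - radius_star) <= tolerance_m:
                hits += 1
    return {
        "rate": hits / n_seeds,
        "n_seeds": n_seeds,
        "radius_star": radius_star,
        "tolerance_m": tolerance_m,
        "recovered": recovered,
    }


def null_scan_experiment(
    n_shuffles: int = 25,
    n_sites: int = 30,
    n_indices: int = 3,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Rejection rate of scan cells when abundance is shuffled.

    Builds one synthetic cube (independent standard-normal values per cell
    so cells are exchangeable under the null), then scans ``n_shuffles``
    independent permutations of a site abundance vector.  The pooled
    fraction of cells with p < alpha estimates the scan's false-positive
    rate.
    """
    rng = np.random.default_rng(seed)
    radii = tuple(np.arange(25.0, 1025.0, 25.0))
    rows = []
    for k in range(n_indices):
        for r in radii:
            vals = rng.normal(size=n_sites)
            for i, v in enumerate(vals):
                rows.append((f"s{i}", f"I{k}", r, "d1", float(v), 1))
    cube = pd.DataFrame(
        rows, columns=["site_id", "index", "radius_m", "date", "value", "n_pixels"]
    )
    base_abundance = rng.integers(0, 200, size=n_sites).astype(float)
    cells = 0
    rejections = 0
    for _ in range(n_shuffles):
        sites = pd.DataFrame(
            {
                "site_id": [f"s{i}" for i in range(n_sites)],
                "x": np.arange(n_sites, dtype=float),
                "y": np.arange(n_sites, dtype=float),
                "stratum": "all",
                "abundance": rng.permutation(base_abundance),
            }
        )
        scan = correlation_scan(cube, sites, alpha=alpha)
        rejections += int(scan["significant"].sum())
        cells += len(scan)
    return {"rate": rejections / cells, "n_cells": cells, "alpha": alpha}


def csr_type1_experiment(
    n_reps: int = 1000,
    n_points: int = 15,
    nx: int = 5,
    ny: int = 5,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Type-I error of the quadrat CSR test on true CSR layouts.

    Draws ``n_reps`` uniform layouts in a fixed window (the generating
    window is passed to the test, not the bounding box) and reports the
    fraction rejected at ``alpha``.
    """
    window = (0.0, 0.0, 1000.0, 1000.0)
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        pts = np.column_stack(
            [rng.uniform(0, 1000, n_points), rng.uniform(0, 1000, n_points)]
        )
        if quadrat_test(pts, window, nx=nx, ny=ny).p < alpha:
            rejections += 1
    return {"rate": rejections / n_reps, "n_reps": n_reps, "alpha": alpha}
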