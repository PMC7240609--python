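"""Synthetic scenes, site layouts and abundances with known planted structure.

Real acquisitions and trap counts from the field campaign the pipeline was
designed around are not redistributable, so every stage is exercised on
synthetic data whose ground truth is known:

* **Reflectance scenes** are built from two latent spatial fields — a
  "vegetation" field and a "moisture" field — each a Gaussian random field
  obtained by Gaussian-kernel smoothing of white noise (kernel SD =
  ``corr_length / 2``).  The seven OLI-like bands mix the two latents with
  fixed loadings chosen so that greenness-type indices (NDVI) respond mainly
  to the vegetation latent while moisture-type indices (NDWI2, MNDWI, TC
  wetness) respond mainly to the moisture latent.  Values are clipped to
  [0, 1].
* **Site layouts** are either CSR (uniform in the window) or clustered
  (Thomas-like: parents then Gaussian offsets), optionally with a minimum
  pairwise separation enforced by dart throwing (bounded retries).  The
  study design used at least 150 m between sites.
* **Abundances** follow a linear response to ONE index's buffer mean at ONE
  planted radius — the "scale of effect" the scan must recover:
  ``abundance_i = max(0, round(beta0 + beta1 * m_i + eps_i))`` with
  Gaussian noise.  Gaussian-then-round (not Poisson) noise matches the
  ordinary-least-squares analyses downstream; a Poisson option exists.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .buffers import ScaleGrid, buffer_mean
from .indices import compute_index
from .scene import BAND_NAMES, RasterScene

# mean reflectance of a semi-arid grassland pixel per band, and loadings of
# the two latent fields; loadings keep clipped pixels rare at latent SD 1
_BASE = {
    "coastal": 0.10,
    "blue": 0.10,
    "green": 0.13,
    "red": 0.18,
    "nir": 0.28,
    "swir1": 0.30,
    "swir2": 0.25,
}
_VEG_LOADING = {
    "coastal": 0.000,
    "blue": -0.005,
    "green": 0.010,
    "red": -0.050,
    "nir": 0.080,
    "swir1": -0.030,
    "swir2": -0.030,
}
_MOIST_LOADING = {
    "coastal": 0.000,
    "blue": 0.005,
    "green": 0.020,
    "red": -0.005,
    "nir": 0.010,
    "swir1": -0.060,
    "swir2": -0.050,
}
_BAND_NOISE_SD = 0.01


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic reflectance scene."""

    n_rows: int
    n_cols: int
    pixel_size: float = 30.0
    origin_x: float = 0.0
    origin_y: float = 0.0
    band_names: tuple[str, ...] = BAND_NAMES
    corr_length: float = 300.0
    seed: int = 0
    date: str = ""
    date_offset: float = 0.0  # additive shift of the vegetation latent mean

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("scene dimensions must be >= 1")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.corr_length < 0:
            raise ValueError("corr_length must be >= 0")
        if tuple(self.band_names) != BAND_NAMES:
            raise ValueError(f"band_names must be the complete ordered set {BAND_NAMES}")


@dataclass(frozen=True)
class PlantSpec:
    """Ground truth of the planted abundance response.

    ``abundance = max(0, round(beta0 + beta1 * m + eps))`` where ``m`` is
    the buffer mean of ``index_name`` at ``radius_star`` and
    ``eps ~ N(0, sigma^2)``.
    """

    index_name: str
    radius_star: float
    beta0: float
    beta1: float
    sigma: float
    seed: int = 0
    noise: str = "gaussian"  # or "poisson"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.noise not in ("gaussian", "poisson"):
            raise ValueError("noise must be 'gaussian' or 'poisson'")


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma_px: float) -> np.ndarray:
    """Unit-variance Gaussian random field via kernel-smoothed white noise."""
    z = rng.standard_normal(shape)
    if sigma_px <= 0:
        return z
    f = ndimage.gaussian_filter(z, sigma=sigma_px, mode="wrap")
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_reflectance_scene(spec: SceneSpec) -> RasterScene:
    """Build a multiband scene from the spec's latent-field model.

    Bit-identical output for identical spec (the seed is part of the spec).
    """
    rng = np.random.default_rng(spec.seed)
    shape = (spec.n_rows, spec.n_cols)
    sigma_px = spec.corr_length / (2.0 * spec.pixel_size)
    veg = _smooth_field(rng, shape, sigma_px) + spec.date_offset
    moist = _smooth_field(rng, shape, sigma_px)
    bands = {}
    for name in spec.band_names:
        noise = _smooth_field(rng, shape, sigma_px) * _BAND_NOISE_SD
        grid = _BASE[name] + _VEG_LOADING[name] * veg + _MOIST_LOADING[name] * moist + noise
        bands[name] = np.clip(grid, 0.0, 1.0)
    return RasterScene(
        bands=bands,
        origin_x=spec.origin_x,
        origin_y=spec.origin_y,
        pixel_size=spec.pixel_size,
        date=spec.date,
    )


class PackingError(RuntimeError):
    """Requested layout could not be packed at the minimum separation."""


def generate_sites(
    n: int,
    window: tuple[float, float, float, float],
    pattern: str = "csr",
    min_sep: float = 0.0,
    seed: int = 0,
    stratum: str = "all",
    cluster_sd: float = 60.0,
    n_clusters: int | None = None,
    max_attempts: int = 100_000,
) -> pd.DataFrame:
    """Random site layout inside `window` = (xmin, ymin, xmax, ymax).

    ``pattern="csr"`` draws uniform points; ``"clustered"`` draws Thomas-like
    clusters (parents uniform, children Gaussian offsets with SD
    ``cluster_sd``) that fail the quadrat CSR test for tight clusters.
    ``min_sep`` enforces a minimum pairwise distance by rejection
    (dart throwing), raising :class:`PackingError` after ``max_attempts``.

    Returns a frame with columns ``site_id, x, y, stratum``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    xmin, ymin, xmax, ymax = window
    if xmax <= xmin or ymax <= ymin:
        raise ValueError("degenerate window")
    rng = np.random.default_rng(seed)
    if pattern == "clustered":
        k = n_clusters if n_clusters is not None else max(1, n // 6)
        parents = np.column_stack(
            [rng.uniform(xmin, xmax, size=k), rng.uniform(ymin, ymax, size=k)]
        )

        def propose() -> tuple[float, float]:
            p = parents[rng.integers(k)]
            return (
                float(p[0] + rng.normal(0, cluster_sd)),
                float(p[1] + rng.normal(0, cluster_sd)),
            )

    elif pattern == "csr":

        def propose() -> tuple[float, float]:
            return float(rng.uniform(xmin, xmax)), float(rng.uniform(ymin, ymax))

    else:
        raise ValueError("pattern must be 'csr' or 'clustered'")

    pts: list[tuple[float, float]] = []
    attempts = 0
    min_sep2 = min_sep * min_sep
    while len(pts) < n:
        attempts += 1
        if attempts > max_attempts:
            raise PackingError(
                f"could not place {n} points with min_sep={min_sep} m in window "
                f"{window} after {max_attempts} attempts"
            )
        x, y = propose()
        if not (xmin <= x <= xmax and ymin <= y <= ymax):
            continue
        if min_sep > 0 and any((x - px) ** 2 + (y - py) ** 2 < min_sep2 for px, py in pts):
            continue
        pts.append((x, y))
    arr = np.asarray(pts)
    return pd.DataFrame(
        {
            "site_id": [f"{stratum}-{i + 1:03d}" for i in range(n)],
            "x": arr[:, 0],
            "y": arr[:, 1],
            "stratum": stratum,
        }
    )


def planted_buffer_means(
    scene: RasterScene, sites: pd.DataFrame, plant: PlantSpec, rule: str = "center"
) -> np.ndarray:
    """The m_i the abundance model is driven by: buffer mean of the planted
    index at radius_star for each site, in site order."""
    grid = compute_index(scene, plant.index_name)
    return np.array(
        [
            buffer_mean(grid, float(s.x), float(s.y), plant.radius_star, rule=rule)[0]
            for s in sites.itertuples(index=False)
        ]
    )


def plant_abundance(
    scene: RasterScene,
    sites: pd.DataFrame,
    plant: PlantSpec,
    scales: ScaleGrid | None = None,
    rule: str = "center",
) -> pd.DataFrame:
    """Attach planted abundance counts to a site table.

    ``radius_star`` must be a member of the scale grid when one is given, so
    the planted scale is recoverable by the scan.  Returns a copy of
    ``sites`` with an integer ``abundance`` column (and ``m_true`` carrying
    the driving buffer means, for diagnostics).
    """
    if scales is not None and plant.radius_star not in set(scales.radii):
        raise ValueError(
            f"radius_star={plant.radius_star} is not on the scale grid {scales.radii[:3]}..."
        )
    m = planted_buffer_means(scene, sites, plant, rule=rule)
    rng = np.random.default_rng(plant.seed)
    mu = plant.beta0 + plant.beta1 * m
    if plant.noise == "poisson":
        counts = rng.poisson(np.clip(mu, 0, None)).astype(int)
    else:
        eps = rng.normal(0.0, plant.sigma, size=len(m)) if plant.sigma > 0 else 0.0
        counts = np.maximum(0, np.round(mu + eps)).astype(int)
    out = sites.copy()
    out["abundance"] = counts
    out["m_true"] = m
    return out


def plant_trap_samples(
    scene: RasterScene,
    sites: pd.DataFrame,
    plant: PlantSpec,
    n_traps: int = 5,
    n_dates: int = 5,
    scales: ScaleGrid | None = None,
    rule: str = "center",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Trap-level emulation of the study design, pooled by summation.

    Each site holds ``n_traps`` pitfall traps sampled on ``n_dates``
    occasions (the study design: 5 x 5 = 25 samples per site, 90 x 25 =
    2250 trap-samples).  Each trap-sample draws
    ``max(0, round((beta0 + beta1*m_i)/K + eps))`` with
    ``eps ~ N(0, (sigma/K)^2)``, ``K = n_traps*n_dates``; the pooled site
    abundance is the exact sum of its trap-samples.

    Returns ``(trap_samples, pooled_sites)``.
    """
    if scales is not None and plant.radius_star not in set(scales.radii):
        raise ValueError(f"radius_star={plant.radius_star} is not on the scale grid")
    m = planted_buffer_means(scene, sites, plant, rule=rule)
    K = n_traps * n_dates
    rng = np.random.default_rng(plant.seed)
    recs = []
    for i, s in enumerate(sites.itertuples(index=False)):
        mu = (plant.beta0 + plant.beta1 * m[i]) / K
        for d in range(n_dates):
            for t in range(n_traps):
                eps = rng.normal(0.0, plant.sigma / K) if plant.sigma > 0 else 0.0
                recs.append((s.site_id, d + 1, t + 1, max(0, int(round(mu + eps)))))
    traps = pd.DataFrame(recs, columns=["site_id", "visit", "trap", "count"])
    pooled = sites.copy()
    pooled["abundance"] = traps.groupby("site_id", sort=False)["count"].sum().to_numpy()
    pooled["m_true"] = m
    return traps, pooled
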