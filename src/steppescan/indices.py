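"""Spectral vegetation and moisture indices.

The six indices retained by the analysis are shipped in a registry:

=========  ====================================================  =============
name       formula                                               responds to
=========  ====================================================  =============
NDVI       (NIR - Red) / (NIR + Red)                             green biomass
NDWI2      (NIR - SWIR1) / (NIR + SWIR1)                         canopy water
MNDWI      (Green - SWIR1) / (Green + SWIR1)                     open water
SATVI      ((SWIR1-Red)/(SWIR1+Red+L))*(1+L) - SWIR2/2           green + senescent
TC-B       tasseled-cap brightness (fixed linear transform)      albedo / bare soil
TC-W       tasseled-cap wetness                                  surface moisture
=========  ====================================================  =============

Normalized-difference indices are masked (not zeroed) where the denominator
vanishes: a zero would be a fake value inside the valid range.  Tasseled-cap
components and SATVI are *not* scale invariant, so reflectance must be in
[0, 1] before calling them; :func:`normalize_reflectance` converts integer
DN grids given a scale factor.

The default tasseled-cap coefficient set is the published Landsat-8 OLI
at-sensor-reflectance set (Baig et al. 2014), stored as a packaged CSV and
user-overridable through :func:`tasseled_cap`.
"""

from __future__ import annotations

from importlib import resources
from typing import Callable

import numpy as np
import pandas as pd

from .scene import BAND_NAMES, IndexGrid, RasterScene

#: Default soil-adjustment factor for SATVI.
SATVI_L = 0.5

#: The six index names the pipeline retains by default.
DEFAULT_INDICES = ("NDVI", "TC-B", "TC-W", "MNDWI", "NDWI2", "SATVI")


def _check_shapes(*arrays: np.ndarray) -> None:
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"band grids disagree on shape: {shapes}")


def _normalized_difference(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(a-b)/(a+b) with a mask where the denominator is zero."""
    _check_shapes(a, b)
    denom = a + b
    bad = denom == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(bad, np.nan, (a - b) / np.where(bad, 1.0, denom))
    return out, bad


def ndvi(nir: np.ndarray, red: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normalized difference vegetation index; returns (values, undefined-mask)."""
    return _normalized_difference(nir, red)


def ndwi2(nir: np.ndarray, swir1: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Gao's normalized difference water index (canopy liquid water)."""
    return _normalized_difference(nir, swir1)


def mndwi(green: np.ndarray, swir1: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Modified NDWI; isolates open-water features."""
    return _normalized_difference(green, swir1)


def satvi(
    red: np.ndarray, swir1: np.ndarray, swir2: np.ndarray, L: float = SATVI_L
) -> tuple[np.ndarray, np.ndarray]:
    """Soil-adjusted total vegetation index.

    ((SWIR1 - Red) / (SWIR1 + Red + L)) * (1 + L) - SWIR2 / 2, with soil
    factor ``L >= 0`` (default 0.5).  Pixels where the adjusted denominator
    vanishes are masked.
    """
    if L < 0:
        raise ValueError("soil factor L must be >= 0")
    _check_shapes(red, swir1, swir2)
    denom = swir1 + red + L
    bad = denom == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(
            bad, np.nan, (swir1 - red) / np.where(bad, 1.0, denom) * (1.0 + L) - swir2 / 2.0
        )
    return out, bad


def load_tasseled_cap_coefficients() -> pd.DataFrame:
    """The packaged OLI tasseled-cap coefficient table.

    Rows indexed by component (brightness, greenness, wetness); columns are
    the band names in :data:`steppescan.scene.BAND_NAMES` order.
    """
    with resources.files("steppescan.data").joinpath("tasseled_cap_oli.csv").open() as fh:
        table = pd.read_csv(fh, comment="#", index_col="component")
    return table[list(BAND_NAMES)]


def tasseled_cap(
    scene: RasterScene, coeffs: pd.DataFrame | None = None
) -> dict[str, np.ndarray]:
    """Tasseled-cap transform of a band stack.

    Each output pixel is the dot product of its reflectance vector with one
    coefficient row.  ``coeffs`` must have one column per scene band, in the
    scene's band order; defaults to the packaged OLI set.
    """
    if coeffs is None:
        coeffs = load_tasseled_cap_coefficients()
    names = list(scene.band_names)
    if list(coeffs.columns) != names:
        if set(coeffs.columns) != set(names):
            raise ValueError(
                f"coefficient bands {list(coeffs.columns)} do not match scene bands {names}"
            )
        coeffs = coeffs[names]
    stack = np.stack([scene.bands[b] for b in names], axis=-1)
    out = {}
    for component, row in coeffs.iterrows():
        out[str(component)] = stack @ row.to_numpy(dtype=float)
    return out


def apply_mask(scene: RasterScene, mask: np.ndarray) -> RasterScene:
    """Return a scene whose mask additionally excludes `mask` pixels.

    Band values are left untouched; every downstream index and buffer mean
    honours the combined mask.
    """
    if mask.shape != scene.shape:
        raise ValueError("mask shape does not match scene shape")
    return RasterScene(
        bands=scene.bands,
        origin_x=scene.origin_x,
        origin_y=scene.origin_y,
        pixel_size=scene.pixel_size,
        date=scene.date,
        mask=scene.mask | mask.astype(bool),
    )


# ---------------------------------------------------------------------------
# registry

IndexFunc = Callable[..., IndexGrid]
_REGISTRY: dict[str, Callable[[RasterScene, dict], IndexGrid]] = {}


def register_index(name: str, func: Callable[[RasterScene, dict], IndexGrid], overwrite: bool = False) -> None:
    """Register a custom index computable from a :class:`RasterScene`.

    ``func(scene, params) -> IndexGrid``.  Names are unique unless
    ``overwrite`` is set.
    """
    if name in _REGISTRY and not overwrite:
        raise ValueError(f"index {name!r} already registered")
    _REGISTRY[name] = func


def registered_indices() -> tuple[str, ...]:
    return tuple(_REGISTRY)


def compute_index(scene: RasterScene, name: str, params: dict | None = None) -> IndexGrid:
    """Dispatch an index computation by registry name.

    Raises ``KeyError`` naming the registry contents for unknown names.
    """
    if name not in _REGISTRY:
        raise KeyError(f"unknown index {name!r}; registered: {sorted(_REGISTRY)}")
    return _REGISTRY[name](scene, params or {})


def _make_nd_entry(index_name: str, band_a: str, band_b: str, func) -> None:
    def entry(scene: RasterScene, params: dict) -> IndexGrid:
        values, bad = func(scene.bands[band_a], scene.bands[band_b])
        return IndexGrid.from_scene(scene, values, extra_mask=bad, name=index_name)

    register_index(index_name, entry)


_make_nd_entry("NDVI", "nir", "red", ndvi)
_make_nd_entry("NDWI2", "nir", "swir1", ndwi2)
_make_nd_entry("MNDWI", "green", "swir1", mndwi)


def _satvi_entry(scene: RasterScene, params: dict) -> IndexGrid:
    L = params.get("L", SATVI_L)
    values, bad = satvi(scene.bands["red"], scene.bands["swir1"], scene.bands["swir2"], L=L)
    return IndexGrid.from_scene(scene, values, extra_mask=bad, name="SATVI")


register_index("SATVI", _satvi_entry)


def _tc_entry(component: str, index_name: str):
    def entry(scene: RasterScene, params: dict) -> IndexGrid:
        comps = tasseled_cap(scene, coeffs=params.get("coeffs"))
        return IndexGrid.from_scene(scene, comps[component], name=index_name)

    return entry


register_index("TC-B", _tc_entry("brightness", "TC-B"))
register_index("TC-G", _tc_entry("greenness", "TC-G"))
register_index("TC-W", _tc_entry("wetness", "TC-W"))


def normalize_reflectance(scene: RasterScene, scale: float) -> RasterScene:
    """Convert integer-DN bands to [0, 1] reflectance by dividing by `scale`.

    Normalized differences are scale invariant but the tasseled cap and
    SATVI's soil factor are not, so stacks must be normalized before index
    computation when delivered as scaled integers (e.g. scale=10000 for
    Landsat surface-reflectance products).
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    return RasterScene(
        bands={k: v.astype(float) / scale for k, v in scene.bands.items()},
        origin_x=scene.origin_x,
        origin_y=scene.origin_y,
        pixel_size=scene.pixel_size,
        date=scene.date,
        mask=scene.mask,
    )
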