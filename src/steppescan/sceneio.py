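"""File I/O: multiband GeoTIFF scenes, site tables, index cubes.

Scenes travel as multiband GeoTIFF written with :mod:`tifffile`.  The
geotransform is stored in the standard GeoTIFF tags — ModelPixelScale
(33550) and ModelTiepoint (33922) — and the band names, date and mask flag
in a JSON ImageDescription, so files round-trip exactly and stay readable
by GIS software (no CRS is written; coordinates are assumed projected
metres throughout).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .scene import RasterScene

_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922


def write_scene(path: str | Path, scene: RasterScene) -> None:
    """Write a scene as multiband GeoTIFF (bands in scene band order).

    Masked pixels are stored as NaN in every band.
    """
    path = Path(path)
    stack = np.stack([scene.bands[b] for b in scene.band_names]).astype(np.float32)
    if scene.mask.any():
        stack[:, scene.mask] = np.nan
    meta = {"band_names": list(scene.band_names), "date": scene.date}
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (scene.pixel_size, scene.pixel_size, 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, scene.origin_x, scene.origin_y, 0.0)),
    ]
    kwargs = {"planarconfig": "separate"} if stack.shape[0] > 1 else {}
    tifffile.imwrite(
        path,
        stack if stack.shape[0] > 1 else stack[0],
        photometric="minisblack",
        description=json.dumps(meta),
        extratags=extratags,
        **kwargs,
    )


def read_scene(path: str | Path, band_names: list[str] | None = None, date: str | None = None) -> RasterScene:
    """Read a multiband GeoTIFF written by :func:`write_scene`.

    ``band_names`` / ``date`` override whatever the file metadata carries
    (useful for third-party files without the JSON description).  NaN
    pixels become masked.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        stack = tif.asarray().astype(np.float64)
        desc = page.tags.get("ImageDescription")
        meta = {}
        if desc is not None:
            try:
                meta = json.loads(desc.value)
            except (json.JSONDecodeError, TypeError):
                meta = {}
        scale_tag = page.tags.get(_MODEL_PIXEL_SCALE)
        tie_tag = page.tags.get(_MODEL_TIEPOINT)
        pixel_size = float(scale_tag.value[0]) if scale_tag is not None else 1.0
        if tie_tag is not None:
            _, _, _, origin_x, origin_y, _ = tie_tag.value[:6]
        else:
            origin_x = origin_y = 0.0
    if stack.ndim == 2:
        stack = stack[None]
    names = band_names or meta.get("band_names")
    if names is None or len(names) != stack.shape[0]:
        raise ValueError(
            f"cannot determine band names for {path} ({stack.shape[0]} bands); pass band_names"
        )
    mask = np.isnan(stack).any(axis=0)
    bands = {name: np.nan_to_num(stack[i], nan=0.0) for i, name in enumerate(names)}
    return RasterScene(
        bands=bands,
        origin_x=float(origin_x),
        origin_y=float(origin_y),
        pixel_size=pixel_size,
        date=date if date is not None else meta.get("date", ""),
        mask=mask,
    )


def merge_scenes(a: RasterScene, b: RasterScene) -> RasterScene:
    """Merge two same-grid adjacent tiles (shared pixel size and band set).

    Tiles must align on the common pixel lattice; overlapping valid pixels
    take the first tile's values.  Useful for joining two path/row tiles of
    one acquisition into a single working scene.
    """
    if a.pixel_size != b.pixel_size:
        raise ValueError("tiles differ in pixel size")
    if a.band_names != b.band_names:
        raise ValueError("tiles differ in band set")
    px = a.pixel_size
    for v in ((b.origin_x - a.origin_x) / px, (a.origin_y - b.origin_y) / px):
        if abs(v - round(v)) > 1e-6:
            raise ValueError("tiles are not aligned on a common pixel lattice")
    ox = min(a.origin_x, b.origin_x)
    oy = max(a.origin_y, b.origin_y)
    xmax = max(a.origin_x + a.n_cols * px, b.origin_x + b.n_cols * px)
    ymin = min(a.origin_y - a.n_rows * px, b.origin_y - b.n_rows * px)
    n_cols = int(round((xmax - ox) / px))
    n_rows = int(round((oy - ymin) / px))
    bands = {name: np.zeros((n_rows, n_cols)) for name in a.band_names}
    mask = np.ones((n_rows, n_cols), dtype=bool)
    for tile in (b, a):  # a last so it wins overlaps
        r0 = int(round((oy - tile.origin_y) / px))
        c0 = int(round((tile.origin_x - ox) / px))
        sl = (slice(r0, r0 + tile.n_rows), slice(c0, c0 + tile.n_cols))
        valid = ~tile.mask
        for name in a.band_names:
            bands[name][sl] = np.where(valid, tile.bands[name], bands[name][sl])
        mask[sl] &= tile.mask
    return RasterScene(
        bands=bands, origin_x=ox, origin_y=oy, pixel_size=px, date=a.date, mask=mask
    )


SITE_COLUMNS = ["site_id", "x", "y", "stratum", "abundance"]


def write_sites(path: str | Path, sites: pd.DataFrame) -> None:
    cols = [c for c in SITE_COLUMNS if c in sites.columns]
    sites[cols].to_csv(path, index=False)


def read_sites(path: str | Path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a site CSV; ``column_map`` renames file columns to the standard
    names (site_id, x, y, stratum, abundance)."""
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = {"site_id", "x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"site table missing columns: {sorted(missing)}")
    if "stratum" not in df.columns:
        df["stratum"] = "all"
    return df


def write_cube(path: str | Path, cube: pd.DataFrame) -> None:
    cube.to_csv(path, index=False)


def read_cube(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"site_id": str, "index": str, "date": str})
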