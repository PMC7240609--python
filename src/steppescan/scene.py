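"""Multiband reflectance scenes on a regular projected grid.

A :class:`RasterScene` holds one reflectance grid per spectral band, a
geotransform (north-up, square pixels), an optional validity mask and a date
label.  Pixel values are attributed to pixel centres; the grid uses the
half-open raster convention with the (row 0, col 0) origin at the top-left
corner, so for a scene with origin ``(x0, y0)`` and pixel size ``s``::

    x(col) = x0 + (col + 0.5) * s
    y(row) = y0 - (row + 0.5) * s

All geometry in the package is expressed in projected metres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Ordered Landsat-8 OLI-like band set assumed throughout the package.
BAND_NAMES: tuple[str, ...] = (
    "coastal",
    "blue",
    "green",
    "red",
    "nir",
    "swir1",
    "swir2",
)


@dataclass
class RasterScene:
    """A multiband reflectance grid with geotransform, mask and date label.

    Parameters
    ----------
    bands
        Mapping band name -> 2-D float array of reflectance, nominally in
        [0, 1].  All bands must share one shape.
    origin_x, origin_y
        Projected coordinates (metres) of the top-left corner of the raster.
    pixel_size
        Ground size of a pixel in metres (square pixels; 30 m for OLI).
    date
        Free-form acquisition label, e.g. ``"2017-05"``.
    mask
        Boolean array, ``True`` marks invalid pixels (clouds, nodata).  The
        mask propagates to every derived index and is honoured by buffer
        means.  Defaults to all-valid.
    """

    bands: dict[str, np.ndarray]
    origin_x: float
    origin_y: float
    pixel_size: float
    date: str = ""
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("scene needs at least one band")
        shapes = {b.shape for b in self.bands.values()}
        if len(shapes) != 1:
            raise ValueError(f"bands disagree on shape: {shapes}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.mask is None:
            self.mask = np.zeros(self.shape, dtype=bool)
        elif self.mask.shape != self.shape:
            raise ValueError("mask shape does not match band shape")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.bands.values())).shape

    @property
    def n_rows(self) -> int:
        return self.shape[0]

    @property
    def n_cols(self) -> int:
        return self.shape[1]

    @property
    def band_names(self) -> tuple[str, ...]:
        return tuple(self.bands)

    # -- geometry -----------------------------------------------------------

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) coordinate vectors of column / row pixel centres."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.origin_x + (cols + 0.5) * self.pixel_size
        y = self.origin_y - (rows + 0.5) * self.pixel_size
        return x, y

    def xy_to_rowcol(self, x: float, y: float) -> tuple[int, int]:
        """Index of the pixel containing projected point (x, y)."""
        col = int(np.floor((x - self.origin_x) / self.pixel_size))
        row = int(np.floor((self.origin_y - y) / self.pixel_size))
        return row, col

    def contains(self, x: float, y: float, margin: float = 0.0) -> bool:
        """True if (x, y) lies inside the raster footprint minus `margin`."""
        xmax = self.origin_x + self.n_cols * self.pixel_size
        ymin = self.origin_y - self.n_rows * self.pixel_size
        return (
            self.origin_x + margin <= x <= xmax - margin
            and ymin + margin <= y <= self.origin_y - margin
        )


@dataclass
class IndexGrid:
    """A single-band derived grid (one spectral index on a scene's lattice).

    Carries the parent scene's geotransform and a mask combining the scene
    mask with pixels where the index is undefined (e.g. zero denominators).
    """

    values: np.ndarray
    mask: np.ndarray
    origin_x: float
    origin_y: float
    pixel_size: float
    name: str = ""
    date: str = ""

    @classmethod
    def from_scene(
        cls, scene: RasterScene, values: np.ndarray, extra_mask: np.ndarray | None = None, name: str = ""
    ) -> "IndexGrid":
        mask = scene.mask.copy()
        if extra_mask is not None:
            mask |= extra_mask
        return cls(
            values=values,
            mask=mask,
            origin_x=scene.origin_x,
            origin_y=scene.origin_y,
            pixel_size=scene.pixel_size,
            name=name,
            date=scene.date,
        )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def masked(self) -> np.ma.MaskedArray:
        return np.ma.MaskedArray(self.values, mask=self.mask)
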