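import numpy as np
import pytest

from steppescan.scene import IndexGrid, RasterScene
from steppescan.synthetic import SceneSpec, generate_reflectance_scene


def make_grid(values, pixel_size=30.0, origin_x=0.0, origin_y=None, mask=None, name="test"):
    """IndexGrid wrapping a plain array (origin_y defaults so y spans [0, H])."""
    values = np.asarray(values, dtype=float)
    if origin_y is None:
        origin_y = values.shape[0] * pixel_size
    if mask is None:
        mask = np.zeros(values.shape, dtype=bool)
    return IndexGrid(
        values=values, mask=np.asarray(mask, dtype=bool),
        origin_x=origin_x, origin_y=origin_y, pixel_size=pixel_size, name=name,
    )


def constant_scene(value=0.3, n=8, pixel_size=30.0, date="d"):
    from steppescan.scene import BAND_NAMES

    bands = {b: np.full((n, n), value) for b in BAND_NAMES}
    return RasterScene(
        bands=bands, origin_x=0.0, origin_y=n * pixel_size, pixel_size=pixel_size, date=date
    )


@pytest.fixture(scope="session")
def small_scene():
    """128x128 autocorrelated scene used by several extraction tests."""
    spec = SceneSpec(
        n_rows=128, n_cols=128, origin_y=3840.0, corr_length=300.0, seed=11, date="d1"
    )
    return generate_reflectance_scene(spec)


def brute_force_buffer_mean(grid: IndexGrid, x, y, radius):
    """Oracle: scan every pixel, include centres within the circle."""
    rows, cols = grid.shape
    total, count = 0.0, 0
    for r in range(rows):
        for c in range(cols):
            if grid.mask[r, c]:
                continue
            cx = grid.origin_x + (c + 0.5) * grid.pixel_size
            cy = grid.origin_y - (r + 0.5) * grid.pixel_size
            if (cx - x) ** 2 + (cy - y) ** 2 <= radius**2:
                total += grid.values[r, c]
                count += 1
    if count == 0:
        c = int(np.floor((x - grid.origin_x) / grid.pixel_size))
        r = int(np.floor((grid.origin_y - y) / grid.pixel_size))
        if grid.mask[r, c]:
            return float("nan"), 0
        return float(grid.values[r, c]), 1
    return total / count, count
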