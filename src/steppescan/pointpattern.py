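"""Quadrat-count tests of complete spatial randomness (CSR).

The observation window is partitioned into an nx x ny grid of equal cells;
under the homogeneous-Poisson null the counts are equidistributed, and the
index of dispersion

    chi2 = sum_i (n_i - nbar)^2 / nbar,   nbar = n / (nx * ny)

is compared to a chi-square distribution with nx*ny - 1 degrees of freedom.
The p-value is two sided (doubled smaller tail, capped at 1): layouts more
*regular* than Poisson sit in the lower tail and are rejected too, matching
the convention of spatstat's ``quadrat.test``.

The default quadrat grid is 5x5 (df = 24).  The window defaults to the
bounding box of the points; pass an explicit window whenever the generating
region is known, since a bounding-box window shrinks to the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class QuadratTestResult:
    """Chi-square quadrat test summary."""

    statistic: float
    df: int
    p: float
    counts: np.ndarray  # (ny, nx) integer counts
    nx: int
    ny: int

    @property
    def n_points(self) -> int:
        return int(self.counts.sum())


def quadrat_counts(
    points: np.ndarray,
    window: tuple[float, float, float, float] | None = None,
    nx: int = 5,
    ny: int = 5,
) -> tuple[np.ndarray, tuple[float, float, float, float]]:
    """Point counts over an nx x ny partition of the window.

    ``points`` is (n, 2) of (x, y); ``window`` is (xmin, ymin, xmax, ymax),
    default the bounding box.  Cells are half-open: a point exactly on an
    interior edge belongs to the right/upper cell; points on the outer
    maximum edge stay in the last cell.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if window is None:
        window = (pts[:, 0].min(), pts[:, 1].min(), pts[:, 0].max(), pts[:, 1].max())
    xmin, ymin, xmax, ymax = window
    if xmax <= xmin or ymax <= ymin:
        raise ValueError("degenerate window")
    if np.any(pts[:, 0] < xmin) or np.any(pts[:, 0] > xmax) or np.any(
        pts[:, 1] < ymin
    ) or np.any(pts[:, 1] > ymax):
        raise ValueError("all points must lie inside the window")
    ix = np.floor((pts[:, 0] - xmin) / (xmax - xmin) * nx).astype(int)
    iy = np.floor((pts[:, 1] - ymin) / (ymax - ymin) * ny).astype(int)
    ix = np.clip(ix, 0, nx - 1)
    iy = np.clip(iy, 0, ny - 1)
    counts = np.zeros((ny, nx), dtype=int)
    np.add.at(counts, (iy, ix), 1)
    return counts, window


def two_sided_chisq_p(stat: float, df: int) -> float:
    """Two-sided chi-square probability: min(1, 2*min(lower, upper tail))."""
    if stat < 0:
        raise ValueError("chi-square statistic must be non-negative")
    lo = stats.chi2.cdf(stat, df)
    hi = stats.chi2.sf(stat, df)
    return float(min(1.0, 2.0 * min(lo, hi)))


def quadrat_chisq(counts: np.ndarray) -> QuadratTestResult:
    """Dispersion chi-square test from a quadrat count grid."""
    counts = np.asarray(counts, dtype=int)
    n = counts.sum()
    if n == 0:
        raise ValueError("no points: quadrat test undefined")
    ncells = counts.size
    expected = n / ncells
    stat = float(((counts - expected) ** 2 / expected).sum())
    df = ncells - 1
    ny, nx = counts.shape if counts.ndim == 2 else (1, counts.size)
    return QuadratTestResult(
        statistic=stat, df=df, p=two_sided_chisq_p(stat, df), counts=counts.reshape(ny, nx),
        nx=nx, ny=ny,
    )


def quadrat_test(
    points: np.ndarray,
    window: tuple[float, float, float, float] | None = None,
    nx: int = 5,
    ny: int = 5,
) -> QuadratTestResult:
    """CSR test straight from point coordinates."""
    counts, _ = quadrat_counts(points, window, nx=nx, ny=ny)
    return quadrat_chisq(counts)


def exclusion_helper(
    points: np.ndarray,
    window: tuple[float, float, float, float] | None = None,
    nx: int = 5,
    ny: int = 5,
    alpha: float = 0.05,
    max_remove: int = 5,
) -> tuple[list[int], QuadratTestResult, bool]:
    """Greedily remove points until the layout passes the CSR test.

    At each step the point whose removal most increases the two-sided
    p-value is dropped (ties broken toward the lowest point index).  Returns
    ``(removed_indices, final_result, is_random)``; ``is_random`` is False
    when ``max_remove`` removals did not reach ``p > alpha``.

    This is a diagnostic helper: it identifies candidate points driving
    non-randomness, it does not decide which points *should* be excluded.
    """
    pts = np.asarray(points, dtype=float)
    if window is None:
        window = (pts[:, 0].min(), pts[:, 1].min(), pts[:, 0].max(), pts[:, 1].max())
    active = list(range(len(pts)))
    removed: list[int] = []
    result = quadrat_test(pts[active], window, nx=nx, ny=ny)
    while result.p <= alpha and len(removed) < max_remove and len(active) > 1:
        best_p, best_i = -1.0, None
        for i in active:
            trial = [j for j in active if j != i]
            p = quadrat_test(pts[trial], window, nx=nx, ny=ny).p
            if p > best_p:  # strict: ties keep the lowest index
                best_p, best_i = p, i
        active.remove(best_i)
        removed.append(best_i)
        result = quadrat_test(pts[active], window, nx=nx, ny=ny)
    return removed, result, bool(result.p > alpha)
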