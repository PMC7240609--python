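"""Scale-of-effect correlation scans and supporting screens.

The core question: *which index, at which buffer radius, on which date,
best explains site abundance?*  For one stratum the scan computes a Pearson
correlation (with its two-sided p) between abundance and each index's
buffer mean, for every radius and date — 60 radii x 6 indices x dates of
cells.  The radius maximizing |r| among significant cells is the scale of
effect.

Supporting screens:

* an inter-index correlation pre-screen drops indices nearly duplicating
  the reference (NDVI) at |r| > 0.9 unless kept for their distinct
  ecological meaning;
* variance-vs-scale profiles (spatial heterogeneity proxy);
* Tukey-HSD homogeneous groups of index values across radii.

No multiple-testing correction is applied across the scan by default; a
Benjamini-Hochberg option exists for those who want it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Product-moment correlation and its two-sided p.

    p comes from t = r*sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom.
    Raises ``ValueError`` for n < 3 or constant input (r undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class PrescreenReport:
    """Outcome of the inter-index redundancy screen."""

    corr: dict[str, pd.DataFrame]  # per-date inter-index correlation matrix
    dropped: list[str]
    kept_flagged: list[str]  # above-threshold but on the keep-list
    retained: list[str]
    reference: str
    threshold: float
    radius: float


def prescreen_indices(
    cube: pd.DataFrame,
    reference: str = "NDVI",
    threshold: float = 0.9,
    keep: tuple[str, ...] = (),
    radius: float | None = None,
) -> PrescreenReport:
    """Drop indices that nearly duplicate the reference index.

    Correlations are computed across sites at one stated radius per date
    (default: the largest radius in the cube, where buffer means are most
    stable).  An index with |r| > ``threshold`` against ``reference`` on
    *any* date is dropped unless listed in ``keep``; the reference itself is
    always retained.
    """
    if radius is None:
        radius = float(cube["radius_m"].max())
    sub = cube[cube["radius_m"] == radius]
    if sub.empty:
        raise ValueError(f"no cube cells at radius {radius}")
    indices = list(dict.fromkeys(cube["index"]))
    if reference not in indices:
        raise ValueError(f"reference index {reference!r} not in cube")
    corr = {}
    max_abs = {name: 0.0 for name in indices}
    for date, group in sub.groupby("date"):
        wide = group.pivot(index="site_id", columns="index", values="value")[indices]
        cmat = wide.corr(method="pearson")
        corr[date] = cmat
        for name in indices:
            if name != reference:
                max_abs[name] = max(max_abs[name], abs(float(cmat.loc[name, reference])))
    dropped, kept_flagged, retained = [], [], []
    for name in indices:
        if name == reference:
            retained.append(name)
        elif max_abs[name] > threshold:
            if name in keep:
                kept_flagged.append(name)
                retained.append(name)
            else:
                dropped.append(name)
        else:
            retained.append(name)
    return PrescreenReport(
        corr=corr,
        dropped=dropped,
        kept_flagged=kept_flagged,
        retained=retained,
        reference=reference,
        threshold=threshold,
        radius=radius,
    )


def correlation_scan(
    cube: pd.DataFrame,
    sites: pd.DataFrame,
    stratum: str | None = None,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Pearson r and p of abundance vs buffer mean per (index, radius, date).

    Uses only sites of ``stratum`` (all sites when None).  Cells with fewer
    than 3 sites or a constant variable carry NaN r/p and are never
    significant.  Returns a long frame with columns
    ``stratum, index, radius_m, date, n, r, p, significant``.
    """
    use = sites if stratum is None else sites[sites["stratum"] == stratum]
    label = stratum if stratum is not None else "all"
    abundance = use.set_index("site_id")["abundance"]
    sub = cube[cube["site_id"].isin(abundance.index)]
    records = []
    for (index_name, radius, date), group in sub.groupby(
        ["index", "radius_m", "date"], sort=True
    ):
        vals = group.set_index("site_id")["value"].reindex(abundance.index).dropna()
        y = abundance.loc[vals.index].to_numpy(dtype=float)
        x = vals.to_numpy(dtype=float)
        n = len(x)
        if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            records.append((label, index_name, radius, date, n, np.nan, np.nan))
        else:
            r, p = pearson_with_p(x, y)
            records.append((label, index_name, radius, date, n, r, p))
    out = pd.DataFrame(
        records, columns=["stratum", "index", "radius_m", "date", "n", "r", "p"]
    )
    pvals = out["p"]
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        ok = pvals.notna()
        adj = pvals.copy()
        if ok.any():
            adj.loc[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
        out["p_adjusted"] = adj
        pvals = adj
    out["significant"] = pvals < alpha
    return out


def variance_profile(cube: pd.DataFrame, sites: pd.DataFrame, stratum: str | None = None) -> pd.DataFrame:
    """Across-site sample variance of buffer means per (index, radius, date).

    Variance falling with radius signals averaging-out of fine-grained
    heterogeneity; plateaus mark the grain of the landscape.
    """
    use = sites if stratum is None else sites[sites["stratum"] == stratum]
    sub = cube[cube["site_id"].isin(use["site_id"])]
    prof = (
        sub.groupby(["index", "radius_m", "date"], sort=True)["value"]
        .agg(variance=lambda v: v.var(ddof=1), n="count")
        .reset_index()
    )
    prof.insert(0, "stratum", stratum if stratum is not None else "all")
    return prof


def tukey_scale_groups(
    values: np.ndarray, radii: np.ndarray, alpha: float = 0.05
) -> dict[float, str]:
    """Homogeneous-group letters for index values compared across radii.

    Runs Tukey's HSD over all radius pairs at ``alpha``; radii between which
    no significant difference exists share a letter (compact letter
    display, insert-and-absorb).  Labels are assigned in order of
    increasing group mean and are invariant to the input ordering.
    """
    values = np.asarray(values, dtype=float)
    radii = np.asarray(radii, dtype=float)
    levels = np.unique(radii)
    if len(levels) == 1:
        return {float(levels[0]): "a"}
    groups = [values[radii == lv] for lv in levels]
    res = stats.tukey_hsd(*groups)
    k = len(levels)
    means = np.array([g.mean() for g in groups])
    order = np.argsort(means, kind="stable")  # letters follow increasing mean
    differ = res.pvalue < alpha
    # compact letter display: grow maximal cliques of mutually similar levels
    letters: list[set[int]] = []
    for pos in order:
        placed = False
        for clique in letters:
            if all(not differ[pos, other] for other in clique):
                clique.add(pos)
                placed = True
        if not placed:
            letters.append({pos})
    # absorb cliques fully contained in another
    letters = [c for c in letters if not any(c < d for d in letters)]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out: dict[float, str] = {}
    for i, lv in enumerate(levels):
        tags = sorted(j for j, clique in enumerate(letters) if i in clique)
        out[float(lv)] = "".join(alphabet[j % 26] for j in tags)
    return out


@dataclass(frozen=True)
class BestScale:
    """The scan cell maximizing |r| among significant cells for one index."""

    index: str
    radius_m: float
    date: str
    r: float
    p: float


def best_scale(scan: pd.DataFrame, index: str, alpha: float = 0.05) -> BestScale | None:
    """Scale of effect for one index: the significant cell with max |r|.

    Ties break toward the smaller radius, then the earlier date label.
    Returns None when no cell is significant at ``alpha``.
    """
    sub = scan[(scan["index"] == index) & (scan["p"] < alpha)].copy()
    if sub.empty:
        return None
    sub["abs_r"] = sub["r"].abs()
    sub = sub.sort_values(
        ["abs_r", "radius_m", "date"], ascending=[False, True, True], kind="stable"
    )
    row = sub.iloc[0]
    return BestScale(
        index=index,
        radius_m=float(row["radius_m"]),
        date=str(row["date"]),
        r=float(row["r"]),
        p=float(row["p"]),
    )
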