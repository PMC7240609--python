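"""Collinearity screening and stepwise regression of abundance on
index-at-scale predictors.

The multi-predictor stage never enters all 60 radii of every index — the
columns are far too collinear.  Instead each candidate index contributes
one column (by default its scale-of-effect cell from the scan), the set is
screened with variance inflation factors (iteratively dropping the worst
predictor with VIF >= 10), and a bidirectional stepwise search over
ordinary-least-squares fits picks the model minimizing AIC (BIC or
p-to-enter/remove are options).  The final report carries the overall
F-test, its p, r-squared, and each retained term with its sign, scale and
significance stars.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .scan import best_scale

VIF_THRESHOLD = 10.0


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per predictor column.

    VIF_j = 1 / (1 - R^2_j) with R^2_j from regressing column j (with
    intercept) on all other columns.  Perfect collinearity yields ``inf``
    rather than an exception.
    """
    X = design.to_numpy(dtype=float)
    n, k = X.shape
    out = {}
    for j, name in enumerate(design.columns):
        if k == 1:
            out[name] = 1.0
            continue
        others = sm.add_constant(np.delete(X, j, axis=1))
        r2 = sm.OLS(X[:, j], others).fit().rsquared
        out[name] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


@dataclass
class VifReport:
    """Iterative VIF exclusion trace."""

    threshold: float
    exclusion_order: list[str]
    final_vif: pd.Series
    retained: list[str]


def vif_filter(design: pd.DataFrame, threshold: float = VIF_THRESHOLD) -> tuple[pd.DataFrame, VifReport]:
    """Iteratively drop the worst-VIF predictor until all VIF < threshold.

    Ties break toward the earliest column.  Returns the retained design and
    a replayable report.
    """
    cols = list(design.columns)
    dropped: list[str] = []
    while len(cols) > 1:
        v = vif(design[cols])
        worst = v.idxmax()  # idxmax returns the first maximal column
        if v[worst] < threshold:
            break
        cols.remove(worst)
        dropped.append(worst)
    final = vif(design[cols])
    return design[cols], VifReport(
        threshold=threshold, exclusion_order=dropped, final_vif=final, retained=cols
    )


def f_test_p(F: float, df1: int, df2: int) -> float:
    """Upper-tail probability of the F distribution (overall model test)."""
    if F < 0:
        raise ValueError("F must be non-negative")
    return float(stats.f.sf(F, df1, df2))


def significance_stars(p: float) -> str:
    """Conventional significance codes: *** .001, ** .01, * .05, . 0.1."""
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "."
    return ""


@dataclass
class ModelReport:
    """Final regression summary in the signed-term style.

    Terms render like ``"MNDWI(+) @1500m **"`` — predictor, coefficient
    sign, the scale it acts at, and significance stars for its t-test.
    """

    stratum: str
    date: str
    terms: list[dict] = field(default_factory=list)  # name, scale, coef, p, sign, stars
    f_statistic: float = float("nan")
    df1: int = 0
    df2: int = 0
    p: float = float("nan")
    r2: float = float("nan")
    intercept: float = float("nan")
    intercept_only: bool = False
    n: int = 0

    def formatted_terms(self) -> list[str]:
        out = []
        for t in self.terms:
            scale = f" @{t['scale']:.0f}m" if t.get("scale") is not None else ""
            stars = f" {t['stars']}" if t["stars"] else ""
            out.append(f"{t['name']}({t['sign']}){scale}{stars}")
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stratum": self.stratum,
                    "date": self.date,
                    "terms": "; ".join(self.formatted_terms()) or "(intercept only)",
                    "F": self.f_statistic,
                    "df1": self.df1,
                    "df2": self.df2,
                    "p": self.p,
                    "r2": self.r2,
                    "n": self.n,
                }
            ]
        )


def _fit_ols(y: np.ndarray, design: pd.DataFrame, cols: list[str]):
    X = sm.add_constant(design[cols].to_numpy(dtype=float)) if cols else np.ones((len(y), 1))
    return sm.OLS(y, X).fit()


def _criterion(fit, criterion: str) -> float:
    return float(fit.bic) if criterion == "BIC" else float(fit.aic)


def stepwise_lm(
    y: np.ndarray | pd.Series,
    design: pd.DataFrame,
    direction: str = "both",
    criterion: str = "AIC",
    stratum: str = "",
    date: str = "",
    scales: dict[str, float] | None = None,
) -> ModelReport:
    """Bidirectional stepwise OLS selection by information criterion.

    Starting from the intercept-only model, the move (add or drop one
    predictor) most improving the criterion is taken until no move
    improves it.  ``direction`` may be "both", "forward" or "backward"
    (backward starts from the full model).  ``scales`` optionally maps
    predictor name -> buffer radius for the report's term formatting.

    The report is flagged ``intercept_only`` when no predictor survives.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n <= design.shape[1] + 1 and direction == "backward":
        raise ValueError("backward selection needs n > n_predictors + 1")
    candidates = list(design.columns)
    current = candidates.copy() if direction == "backward" else []
    best = _criterion(_fit_ols(y, design, current), criterion)
    allow_add = direction in ("both", "forward")
    allow_drop = direction in ("both", "backward")
    while True:
        moves: list[tuple[float, str, str]] = []
        if allow_add:
            for c in candidates:
                if c not in current and n > len(current) + 2:
                    moves.append(
                        (_criterion(_fit_ols(y, design, current + [c]), criterion), "add", c)
                    )
        if allow_drop:
            for c in current:
                trial = [k for k in current if k != c]
                moves.append((_criterion(_fit_ols(y, design, trial), criterion), "drop", c))
        if not moves:
            break
        moves.sort(key=lambda t: (t[0], t[2]))
        score, action, col = moves[0]
        if score >= best - 1e-10:
            break
        best = score
        if action == "add":
            current.append(col)
        else:
            current.remove(col)
    fit = _fit_ols(y, design, current)
    report = ModelReport(stratum=stratum, date=date, n=n)
    if not current:
        report.intercept_only = True
        report.intercept = float(np.mean(y))
        report.r2 = 0.0
        report.df1 = 0
        report.df2 = n - 1
        return report
    report.intercept = float(fit.params[0])
    report.r2 = float(fit.rsquared)
    report.f_statistic = float(fit.fvalue)
    report.df1 = int(fit.df_model)
    report.df2 = int(fit.df_resid)
    report.p = f_test_p(report.f_statistic, report.df1, report.df2)
    for i, name in enumerate(current, start=1):
        coef = float(fit.params[i])
        pval = float(fit.pvalues[i])
        report.terms.append(
            {
                "name": name,
                "coef": coef,
                "sign": "+" if coef >= 0 else "-",
                "p": pval,
                "stars": significance_stars(pval),
                "scale": (scales or {}).get(name),
            }
        )
    return report


def build_candidate_design(
    cube: pd.DataFrame,
    scan: pd.DataFrame,
    sites: pd.DataFrame,
    date: str,
    indices: list[str] | None = None,
    explicit: dict[str, float] | None = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """One candidate column per index for the multi-predictor model.

    By default each index contributes its scale-of-effect column for
    ``date`` (its best significant scan cell; indices with no significant
    cell on that date fall back to their max-|r| cell).  ``explicit`` maps
    index name -> radius and overrides the scan choice, so externally
    chosen candidate sets can be reproduced.

    Returns (design aligned to ``sites`` order, index -> radius map).
    """
    if indices is None:
        indices = list(dict.fromkeys(cube["index"]))
    scan_d = scan[scan["date"] == date]
    chosen: dict[str, float] = {}
    for name in indices:
        if explicit and name in explicit:
            chosen[name] = float(explicit[name])
            continue
        bs = best_scale(scan_d, name, alpha=alpha)
        if bs is not None:
            chosen[name] = bs.radius_m
        else:
            sub = scan_d[scan_d["index"] == name].dropna(subset=["r"])
            if sub.empty:
                continue
            chosen[name] = float(sub.loc[sub["r"].abs().idxmax(), "radius_m"])
    cols = {}
    for name, radius in chosen.items():
        cell = cube[
            (cube["index"] == name) & (cube["radius_m"] == radius) & (cube["date"] == date)
        ]
        series = cell.set_index("site_id")["value"].reindex(sites["site_id"])
        cols[name] = series.to_numpy(dtype=float)
    design = pd.DataFrame(cols, index=sites["site_id"])
    return design, chosen


def per_scale_models(
    cube: pd.DataFrame,
    sites: pd.DataFrame,
    stratum: str,
    scan: pd.DataFrame | None = None,
    vif_threshold: float = VIF_THRESHOLD,
    direction: str = "both",
    criterion: str = "AIC",
    explicit: dict[str, dict[str, float]] | None = None,
) -> list[ModelReport]:
    """Best regression model per date for one stratum.

    Pipeline: scan (if not supplied) -> candidate design of index-at-scale
    columns -> iterative VIF exclusion -> stepwise OLS.  ``explicit`` maps
    date -> {index: radius} to force candidate scales.
    """
    from .scan import correlation_scan

    use = sites[sites["stratum"] == stratum]
    if scan is None:
        scan = correlation_scan(cube, sites, stratum)
    reports = []
    for date in sorted(cube["date"].unique()):
        design, chosen = build_candidate_design(
            cube, scan, use, date, explicit=(explicit or {}).get(date)
        )
        design = design.dropna(axis=1, how="any")
        y = use.set_index("site_id")["abundance"].reindex(design.index).to_numpy(dtype=float)
        if design.shape[1] == 0 or len(y) < 4:
            reports.append(
                ModelReport(stratum=stratum, date=date, intercept_only=True, n=len(y))
            )
            continue
        design = design.loc[:, design.std(ddof=0) > 0]
        filtered, _ = vif_filter(design, threshold=vif_threshold)
        report = stepwise_lm(
            y,
            filtered,
            direction=direction,
            criterion=criterion,
            stratum=stratum,
            date=date,
            scales=chosen,
        )
        reports.append(report)
    return reports
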