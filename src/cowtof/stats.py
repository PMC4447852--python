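"""Dataset assembly and descriptive statistics for the camera traits.

Per-frame trait values are cleaned from outliers and averaged to one value
per cow and day, then per cow and (ISO) week to match the weekly backfat
reference.  The layer then provides Pearson correlations with significance,
coefficients of determination from a generalized linear model with a
piecewise linear link (overall and restricted to individual cows), the
calendar-week season grouping, and one-way-ANOVA effect sizes (eta squared)
for cow and season groupings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

#: consistency constant of the MAD as a scale estimator
_MAD_SCALE = 1.4826

TRAIT_COLS = (
    "HH", "DL", "DR", "VL", "VR",
    "DPL", "APL", "DML", "AML", "DPR", "APR", "DMR", "AMR",
)


# ---------------------------------------------------------------------------
# cleaning and aggregation
# ---------------------------------------------------------------------------


def clean_outliers_daily(values: np.ndarray | pd.Series) -> np.ndarray:
    """Drop values outside ``median +- 3 * scaled MAD``.

    With a zero MAD (e.g. repeated identical values) only values equal to
    the median survive; a single value is always kept.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size <= 1:
        return v
    med = np.median(v)
    mad = _MAD_SCALE * np.median(np.abs(v - med))
    return v[np.abs(v - med) <= 3 * mad]


def aggregate_daily(frame_table: pd.DataFrame, trait_cols=TRAIT_COLS) -> pd.DataFrame:
    """Outlier-clean and average frame values to one row per cow and day."""
    def _agg(series: pd.Series) -> float:
        kept = clean_outliers_daily(series.to_numpy())
        return float(kept.mean()) if kept.size else np.nan

    cols = [c for c in trait_cols if c in frame_table.columns]
    out = (
        frame_table.groupby(["cow_id", "date"], as_index=False)[cols]
        .agg(_agg)
    )
    return out


def aggregate_weekly(
    daily: pd.DataFrame,
    reference: pd.DataFrame | None = None,
    trait_cols=TRAIT_COLS,
) -> pd.DataFrame:
    """Mean of the daily values per cow and ISO week, joined to the weekly
    reference measurements (BFT, and BCS where gathered)."""
    daily = daily.copy()
    dates = pd.to_datetime(daily["date"])
    iso = dates.dt.isocalendar()
    daily["iso_year"] = iso["year"].astype(int)
    daily["iso_week"] = iso["week"].astype(int)
    cols = [c for c in trait_cols if c in daily.columns]
    weekly = (
        daily.groupby(["cow_id", "iso_year", "iso_week"], as_index=False)[cols]
        .mean()
    )
    if reference is not None:
        ref = reference.copy()
        rdates = pd.to_datetime(ref["date"])
        riso = rdates.dt.isocalendar()
        ref["iso_year"] = riso["year"].astype(int)
        ref["iso_week"] = riso["week"].astype(int)
        keep = [c for c in ref.columns if c not in ("date",)]
        weekly = weekly.merge(
            ref[keep], on=["cow_id", "iso_year", "iso_week"], how="left"
        )
    weekly["season"] = season_of_week(np.minimum(weekly["iso_week"].to_numpy(), 52))
    return weekly


def add_starting_levels(records: pd.DataFrame, trait_cols=TRAIT_COLS) -> pd.DataFrame:
    """Attach ``start_<trait>``: each cow's first recorded weekly value."""
    records = records.sort_values(["cow_id", "iso_year", "iso_week"]) if (
        "iso_year" in records.columns
    ) else records.sort_values(["cow_id"])
    out = records.copy()
    for col in trait_cols:
        if col in out.columns:
            out[f"start_{col}"] = out.groupby("cow_id")[col].transform("first")
    return out


def season_of_week(week):
    """Season of a calendar week: weeks 49-52 and 1-9 form season 1; weeks
    10-22, 23-35 and 36-48 form seasons 2, 3 and 4."""
    w = np.asarray(week)
    if np.any((w < 1) | (w > 52)):
        raise ValueError("calendar week must be within 1..52")
    season = np.select(
        [(w >= 49) | (w <= 9), (w >= 10) & (w <= 22), (w >= 23) & (w <= 35)],
        [1, 2, 3],
        default=4,
    )
    return season if season.shape else int(season)


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------


def corr_with_significance(
    x, y, alpha: float = 0.05
) -> tuple[float, bool]:
    """Pearson correlation of the paired non-missing values and whether the
    linear connection is significant at ``alpha`` (two-sided); degenerate
    input reports (nan, False) — printed as "NS"."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), False
    r, p = sp_stats.pearsonr(x, y)
    return float(r), bool(p < alpha)


# ---------------------------------------------------------------------------
# piecewise-linear-link GLM
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """A fitted piecewise-linear-link model ``f(y) = X b``.

    The link is continuous with one knot: ``f(y) = y`` below the knot and
    ``f(y) = knot + slope2 * (y - knot)`` above it.  ``r2`` is the
    coefficient of determination on the transformed (link) scale.
    """

    coefficients: np.ndarray
    knot: float
    slope2: float
    deviance: float
    r2: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2 <= 1.0 + 1e-12):
            raise ValueError("R^2 must lie within [0, 1]")


def fit_glm_piecewise(
    y, X, knot_grid=None
) -> FitResult:
    """Least-squares fit of ``f(y) = X b`` with a one-knot piecewise link.

    For each candidate knot the link's second slope is estimated jointly
    with the coefficients as one linear problem (``f(y) = y + (s-1) *
    max(y-knot, 0)``, linear in ``s-1``); the knot minimising the residual
    sum of squares wins.  The default grid is the observed deciles of y.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if n != y.size:
        raise ValueError("y and X have incompatible shapes")
    if n <= p + 1:
        raise ValueError("more coefficients than observations")
    if np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError("singular design matrix")
    if knot_grid is None:
        knot_grid = np.quantile(y, np.arange(0.1, 0.95, 0.1))
    best = None
    for knot in np.atleast_1d(knot_grid):
        hinge = np.maximum(y - knot, 0.0)
        if hinge.std() == 0:  # knot outside the data: plain linear link
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            gamma = 0.0
            resid = y - X @ coef
        else:
            A = np.column_stack([X, hinge])
            theta, *_ = np.linalg.lstsq(A, y, rcond=None)
            coef, gamma = theta[:p], theta[p]
            resid = y - A @ theta
        sse = float(resid @ resid)
        if best is None or sse < best[0]:
            best = (sse, float(knot), coef, float(gamma))
    sse, knot, coef, gamma = best
    # transformed-scale R^2:  z = f(y) = y + (s-1)*hinge  with  s = 1 - gamma
    slope2 = 1.0 - gamma
    z = y + (slope2 - 1.0) * np.maximum(y - knot, 0.0)
    sst = float(((z - z.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    return FitResult(
        coefficients=coef, knot=knot, slope2=slope2,
        deviance=sse, r2=float(np.clip(r2, 0.0, 1.0)),
    )


def overall_r2(
    records: pd.DataFrame, trait: str, knot_grid=None
) -> FitResult:
    """Whole-dataset coefficient of determination for one trait.

    Predictors: constant, lactation week, and the trait's starting level.
    """
    d = records.dropna(subset=[trait, "lactation_week", f"start_{trait}"])
    X = np.column_stack([
        np.ones(len(d)),
        d["lactation_week"].to_numpy(dtype=float),
        d[f"start_{trait}"].to_numpy(dtype=float),
    ])
    return fit_glm_piecewise(d[trait].to_numpy(dtype=float), X, knot_grid)


def r2_per_cow(
    records: pd.DataFrame, trait: str, min_weeks: int = 16, knot_grid=None
) -> pd.Series:
    """Coefficient of determination restricted to each individual cow.

    The starting-level column is constant within a cow and is dropped from
    the design; cows with fewer than ``min_weeks`` records are skipped.
    """
    out = {}
    for cow, d in records.dropna(subset=[trait]).groupby("cow_id"):
        if len(d) < min_weeks:
            continue
        X = np.column_stack([
            np.ones(len(d)), d["lactation_week"].to_numpy(dtype=float)
        ])
        out[cow] = fit_glm_piecewise(d[trait].to_numpy(dtype=float), X, knot_grid).r2
    return pd.Series(out, name=f"r2_{trait}", dtype=float)


# ---------------------------------------------------------------------------
# effect sizes and group means
# ---------------------------------------------------------------------------


def anova_eta2(values, groups, alpha: float = 0.05) -> tuple[float, bool]:
    """One-way ANOVA effect size: eta squared = SS_between / SS_total,
    with significance from the F test at ``alpha``."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ok = ~np.isnan(values)
    values, groups = values[ok], groups[ok]
    levels = np.unique(groups)
    if levels.size < 2:
        raise ValueError("eta squared needs at least two groups")
    grand = values.mean()
    ss_total = float(((values - grand) ** 2).sum())
    ss_between = float(
        sum(
            (values[groups == g]).size * (values[groups == g].mean() - grand) ** 2
            for g in levels
        )
    )
    eta2 = ss_between / ss_total if ss_total > 0 else 0.0
    samples = [values[groups == g] for g in levels]
    if min(len(s) for s in samples) < 2 and ss_total > 0:
        significant = False
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            _, p = sp_stats.f_oneway(*samples)
        significant = bool(np.isfinite(p) and p < alpha) or (
            eta2 == 1.0 and ss_total > 0
        )
    return eta2, significant


def group_means_table(
    records: pd.DataFrame, trait: str, grouping: str, confidence: float = 0.95
) -> pd.DataFrame:
    """Group means with t-based confidence intervals."""
    rows = []
    for g, d in records.dropna(subset=[trait]).groupby(grouping):
        v = d[trait].to_numpy(dtype=float)
        mean = v.mean()
        if v.size > 1 and v.std(ddof=1) > 0:
            half = sp_stats.t.ppf(0.5 + confidence / 2, v.size - 1) * (
                v.std(ddof=1) / np.sqrt(v.size)
            )
        else:
            half = 0.0
        rows.append({grouping: g, "n": v.size, "mean": mean,
                     "ci_lo": mean - half, "ci_hi": mean + half})
    return pd.DataFrame(rows)


def group_mean_plot(
    records: pd.DataFrame,
    trait: str,
    grouping: str = "season",
    out_path=None,
    confidence: float = 0.95,
):
    """Plot group means with confidence intervals; non-intersecting
    intervals indicate significant mean differences.  Returns the numeric
    table; writes the figure when ``out_path`` is given."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    table = group_means_table(records, trait, grouping, confidence)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    x = np.arange(len(table))
    err = np.vstack([
        table["mean"] - table["ci_lo"], table["ci_hi"] - table["mean"]
    ])
    ax.errorbar(x, table["mean"], yerr=err, fmt="o", capsize=4)
    ax.set_xticks(x, [str(g) for g in table[grouping]])
    ax.set_xlabel(grouping)
    ax.set_ylabel(trait)
    ax.set_title(f"{trait}: group means by {grouping}")
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return table


def descriptive_table(
    records: pd.DataFrame,
    trait_cols=TRAIT_COLS,
    reference_cols=("BFT", "BCS"),
    min_weeks: int = 16,
) -> pd.DataFrame:
    """Descriptive statistics per trait: N, min, max, mean, std, overall
    R^2, mean/max per-cow R^2, and correlations to the reference measures."""
    rows = []
    cols = [c for c in (*reference_cols, *trait_cols) if c in records.columns]
    for col in cols:
        v = records[col].dropna().to_numpy(dtype=float)
        if v.size == 0:
            continue
        row = {
            "trait": col, "N": v.size, "min": v.min(), "max": v.max(),
            "mean": v.mean(), "std": v.std(ddof=1) if v.size > 1 else 0.0,
        }
        try:
            row["R2"] = overall_r2(records, col).r2
        except (KeyError, ValueError):
            row["R2"] = np.nan
        per_cow = r2_per_cow(records, col, min_weeks=min_weeks)
        row["R2cow_mean"] = per_cow.mean() if len(per_cow) else np.nan
        row["R2cow_max"] = per_cow.max() if len(per_cow) else np.nan
        for ref in reference_cols:
            if ref in records.columns and col != ref:
                r, sig = corr_with_significance(records[col], records[ref])
                row[f"corr{ref}"] = r if sig else np.nan
                row[f"corr{ref}_sig"] = sig
        rows.append(row)
    return pd.DataFrame(rows)


def effect_size_table(
    records: pd.DataFrame, trait_cols=TRAIT_COLS, reference_cols=("BFT", "BCS")
) -> pd.DataFrame:
    """Eta-squared effect sizes of the cow and season groupings per trait."""
    rows = []
    for col in (*reference_cols, *trait_cols):
        if col not in records.columns or records[col].dropna().empty:
            continue
        row = {"trait": col}
        for grouping in ("cow_id", "season"):
            try:
                eta2, sig = anova_eta2(records[col], records[grouping])
            except ValueError:  # a single level in this grouping
                eta2, sig = np.nan, False
            row[f"eta2_{'cow' if grouping == 'cow_id' else 'season'}"] = (
                eta2 if sig else np.nan
            )
            row[f"eta2_{'cow' if grouping == 'cow_id' else 'season'}_sig"] = sig
        rows.append(row)
    return pd.DataFrame(rows)
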