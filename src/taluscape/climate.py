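"""Daily station-record QC, imputation, annual summaries and trend tests.

The workflow mirrors standard co-op station practice: count missing days
per year *before* imputation, linearly impute interior daily gaps, build
annual aggregates (mean annual temperature, June–August mean summer
temperature, April snow depth), flag years for inclusion by missing-day
thresholds, then fit OLS trends and epoch contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "TrendResult",
    "ComparisonResult",
    "read_daily_csv",
    "read_ghcn_long_csv",
    "impute_daily",
    "summarize_years",
    "fit_trend",
    "compare_epochs",
    "compare_slopes",
    "delta_offset",
]

TEMP_VARS = ("tmax", "tmin")
#: inclusion thresholds: a year is used only if it is missing fewer than
#: this many daily values (annual window / June–August window).
MAX_MISSING_ANNUAL = 15
MAX_MISSING_SUMMER = 10


@dataclass(frozen=True)
class TrendResult:
    slope: float  # units per year
    slope_se: float
    p_two_sided: float
    n_years: int
    total_change: float  # slope × (last included year − first included year)
    intercept: float = float("nan")
    first_year: int = 0
    last_year: int = 0


@dataclass(frozen=True)
class ComparisonResult:
    test: str
    statistic: float
    p_two_sided: float
    n_a: int
    n_b: int
    estimate_a: float = float("nan")
    estimate_b: float = float("nan")


# ---------------------------------------------------------------------------
# I/O


def read_daily_csv(path) -> pd.DataFrame:
    """Read a wide daily CSV with columns date, tmax, tmin[, snow_depth]."""
    df = pd.read_csv(path, parse_dates=["date"])
    if df["date"].duplicated().any():
        raise ValueError("daily series has duplicate dates")
    return df.sort_values("date").reset_index(drop=True)


def read_ghcn_long_csv(path) -> pd.DataFrame:
    """Read a GHCN-daily-style long CSV into the wide daily layout.

    Expected columns: ``station, date, element, value`` with TMAX/TMIN in
    tenths of °C and SNWD in mm; converted to °C and cm respectively.
    """
    raw = pd.read_csv(path, parse_dates=["date"])
    conv = {"TMAX": ("tmax", 0.1), "TMIN": ("tmin", 0.1), "SNWD": ("snow_depth", 0.1)}
    frames = {}
    for element, (name, factor) in conv.items():
        sub = raw[raw["element"] == element]
        frames[name] = (sub.set_index("date")["value"] * factor).rename(name)
    wide = pd.concat(frames.values(), axis=1).sort_index()
    wide.index.name = "date"
    return wide.reset_index()


# ---------------------------------------------------------------------------
# QC and aggregation


def impute_daily(series: pd.DataFrame) -> pd.DataFrame:
    """Linearly impute interior daily gaps.

    Only gaps strictly between recorded days are filled (interpolation in
    time); leading/trailing runs of missing values stay missing and
    recorded values are never modified.  Pre-imputation availability is
    preserved in ``<var>_observed`` boolean columns so that missing-day
    counts can be taken before imputation.  An all-missing variable is
    left untouched.
    """
    out = series.sort_values("date").reset_index(drop=True).copy()
    dates = pd.DatetimeIndex(out["date"])
    if dates.duplicated().any():
        raise ValueError("daily series has duplicate dates")
    # reindex to a complete daily range so absent rows count as gaps too
    full = pd.date_range(dates.min(), dates.max(), freq="D")
    out = out.set_index("date").reindex(full)
    out.index.name = "date"
    for var in (*TEMP_VARS, "snow_depth"):
        if var not in out.columns:
            continue
        col = out[var]
        out[f"{var}_observed"] = col.notna()
        if col.notna().sum() == 0:
            continue
        out[var] = col.interpolate(method="time", limit_area="inside")
    return out.reset_index()


def _observed_mask(df: pd.DataFrame, var: str) -> pd.Series:
    col = f"{var}_observed"
    return df[col] if col in df.columns else df[var].notna()


def summarize_years(
    series: pd.DataFrame,
    april_snow_stat: str = "mean",
    exclude_years: tuple[int, ...] = (),
) -> pd.DataFrame:
    """Annual aggregates with inclusion flags from pre-imputation gap counts.

    ``april_snow_stat`` is ``"mean"`` (mean of daily April readings) or
    ``"first"`` (the April 1 reading).  ``exclude_years`` force-excludes
    named years regardless of the automatic missing-day rule.
    """
    if april_snow_stat not in {"mean", "first"}:
        raise ValueError(f"unknown april_snow_stat {april_snow_stat!r}")
    df = series.copy()
    dates = pd.DatetimeIndex(df["date"])
    df["year"] = dates.year
    df["month"] = dates.month
    daily_mean = (df["tmax"] + df["tmin"]) / 2.0
    # a temperature day is missing if either extreme was unrecorded
    temp_observed = _observed_mask(df, "tmax") & _observed_mask(df, "tmin")

    rows = []
    for year, idx in df.groupby("year").groups.items():
        sub = df.loc[idx]
        summer = sub["month"].isin((6, 7, 8))
        n_days = len(sub)
        missing_annual = int((~temp_observed.loc[idx]).sum())
        missing_summer = int((~temp_observed.loc[idx][summer]).sum())
        mat = float(daily_mean.loc[idx].mean())
        mst = float(daily_mean.loc[idx][summer].mean()) if summer.any() else np.nan
        april = sub[sub["month"] == 4]
        if "snow_depth" in sub.columns and len(april):
            if april_snow_stat == "mean":
                april_snow = float(april["snow_depth"].mean())
            else:
                first = april.sort_values("date")["snow_depth"]
                april_snow = float(first.iloc[0]) if len(first) else np.nan
        else:
            april_snow = np.nan
        excluded = int(year) in set(exclude_years)
        rows.append(
            {
                "year": int(year),
                "mat": mat,
                "mst": mst,
                "april_snow": april_snow,
                "n_days": n_days,
                "missing_annual": missing_annual,
                "missing_summer": missing_summer,
                "included_annual": (missing_annual < MAX_MISSING_ANNUAL) and not excluded and n_days > 0,
                "included_summer": (missing_summer < MAX_MISSING_SUMMER) and not excluded and summer.any(),
            }
        )
    return pd.DataFrame(rows).sort_values("year").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Trends and contrasts


def fit_trend(values_by_year: pd.Series, years_included=None) -> TrendResult:
    """OLS of an annual value on calendar year.

    ``values_by_year`` is indexed by integer year.  ``years_included``
    optionally restricts the fit.  ``total_change`` is the slope applied
    across the span of the included years.
    """
    s = pd.Series(values_by_year).dropna()
    if years_included is not None:
        s = s[s.index.isin(list(years_included))]
    if len(s) < 3:
        raise ValueError(f"need at least 3 included years, got {len(s)}")
    years = s.index.to_numpy(dtype=float)
    if np.ptp(years) == 0:
        raise ValueError("all observations share one year; trend undefined")
    X = sm.add_constant(years)
    fit = sm.OLS(s.to_numpy(dtype=float), X).fit()
    slope = float(fit.params[1])
    span = float(years.max() - years.min())
    return TrendResult(
        slope=slope,
        slope_se=float(fit.bse[1]),
        p_two_sided=float(fit.pvalues[1]),
        n_years=len(s),
        total_change=slope * span,
        intercept=float(fit.params[0]),
        first_year=int(years.min()),
        last_year=int(years.max()),
    )


def compare_epochs(
    values_by_year: pd.Series,
    split_year: int = 1955,
    test: str = "welch_t",
    predicate=None,
) -> ComparisonResult:
    """Contrast years ≤ ``split_year`` (epoch A) against later years (epoch B).

    ``test`` is one of ``welch_t``, ``mann_whitney``, ``spearman_trend``
    (value vs year over all years, reported with epoch means for context)
    or ``two_proportion_z``, in which case ``predicate`` maps the annual
    value to the binary event (e.g. ``lambda s: s < 2`` for negligible
    April snow).
    """
    s = pd.Series(values_by_year).dropna().sort_index()
    a = s[s.index <= split_year]
    b = s[s.index > split_year]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both epochs must be nonempty")

    if test == "welch_t":
        res = stats.ttest_ind(a, b, equal_var=False)
        return ComparisonResult(test, float(res.statistic), float(res.pvalue), len(a), len(b),
                                float(a.mean()), float(b.mean()))
    if test == "mann_whitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        return ComparisonResult(test, float(res.statistic), float(res.pvalue), len(a), len(b),
                                float(a.median()), float(b.median()))
    if test == "spearman_trend":
        rho, p = stats.spearmanr(s.index.to_numpy(), s.to_numpy())
        return ComparisonResult(test, float(rho), float(p), len(a), len(b),
                                float(a.mean()), float(b.mean()))
    if test == "two_proportion_z":
        if predicate is None:
            raise ValueError("two_proportion_z requires a predicate")
        ea, eb = predicate(a).astype(bool), predicate(b).astype(bool)
        counts = [int(ea.sum()), int(eb.sum())]
        if sum(counts) in (0, len(ea) + len(eb)):  # degenerate: identical proportions
            return ComparisonResult(test, 0.0, 1.0, len(a), len(b),
                                    float(ea.mean()), float(eb.mean()))
        from statsmodels.stats.proportion import proportions_ztest

        stat, p = proportions_ztest(counts, [len(ea), len(eb)])
        return ComparisonResult(test, float(stat), float(p), len(a), len(b),
                                float(ea.mean()), float(eb.mean()))
    raise ValueError(f"unknown test {test!r}")


def compare_slopes(trend_a: TrendResult, trend_b: TrendResult) -> ComparisonResult:
    """Welch-style t-test on two independently estimated slopes.

    t = (b₁ − b₂) / sqrt(se₁² + se₂²) with Welch–Satterthwaite degrees of
    freedom built from each regression's residual df (n − 2).
    """
    se_a, se_b = trend_a.slope_se, trend_b.slope_se
    if se_a == 0 and se_b == 0:
        raise ValueError("both slope standard errors are zero")
    pooled = np.hypot(se_a, se_b)
    t = (trend_a.slope - trend_b.slope) / pooled
    df_a, df_b = max(trend_a.n_years - 2, 1), max(trend_b.n_years - 2, 1)
    num = (se_a**2 + se_b**2) ** 2
    den = se_a**4 / df_a + se_b**4 / df_b
    dof = num / den if den > 0 else df_a + df_b
    p = 2.0 * stats.t.sf(abs(t), dof)
    return ComparisonResult(
        "welch_t_slopes", float(t), float(min(p, 1.0)),
        trend_a.n_years, trend_b.n_years, trend_a.slope, trend_b.slope,
    )


def delta_offset(
    summaries: pd.DataFrame,
    variable: str = "mst",
    base_period: tuple[int, int] = (2001, 2010),
    hist_period: tuple[int, int] = (1910, 1955),
    inclusion_column: str | None = None,
) -> float:
    """Delta-method offset: mean(variable, historical) − mean(variable, base).

    Adding the offset to a current-period grid reconstructs the historical
    grid.  Only years flagged as included (``inclusion_column``, default
    chosen from the variable) enter the means.
    """
    if inclusion_column is None:
        inclusion_column = "included_summer" if variable == "mst" else "included_annual"
    df = summaries
    if inclusion_column in df.columns:
        df = df[df[inclusion_column]]

    def period_mean(lo: int, hi: int) -> float:
        sel = df[(df["year"] >= lo) & (df["year"] <= hi)][variable].dropna()
        if len(sel) == 0:
            raise ValueError(f"no included years with {variable!r} in [{lo}, {hi}]")
        return float(sel.mean())

    return period_mean(*hist_period) - period_mean(*base_period)
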