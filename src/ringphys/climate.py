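"""Seasonal climate aggregation and growth-climate Spearman correlations.

Monthly series are aggregated into ring-year seasons (previous-year months
shift forward one calendar year so that, e.g., previous-July precipitation
attaches to the ring formed the following summer). A preliminary per-month
screen identifies the months driving growth; per-tree, per-period Spearman
correlations and centered running correlations quantify how the
increment-climate relationship changes through time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import climate_matrix


@dataclass
class SeasonDefinition:
    """A named month window of one climate variable.

    ``months`` is a list of (month, lag) pairs with lag 0 = current ring year
    and lag 1 = previous calendar year. ``aggregator`` is 'mean' or 'sum'
    (sums for precipitation, means otherwise).
    """

    variable: str
    months: list[tuple[int, int]]
    aggregator: str = "mean"

    def __post_init__(self) -> None:
        if not self.months:
            raise ValueError("months must be non-empty")
        for m, lag in self.months:
            if not 1 <= m <= 12 or lag not in (0, 1):
                raise ValueError(f"invalid (month, lag) pair ({m}, {lag})")
        if self.aggregator not in ("mean", "sum"):
            raise ValueError("aggregator must be 'mean' or 'sum'")


#: the four season windows with the strongest increment-climate links:
#: growing-season temperature (May-Sep), early-season cloud cover (May-Jul),
#: previous late-growing-season precipitation (prev Jul-Sep) and previous
#: September drought (PDSI).
DEFAULT_SEASONS: dict[str, SeasonDefinition] = {
    "temperature": SeasonDefinition("temperature", [(m, 0) for m in range(5, 10)], "mean"),
    "cloud_cover": SeasonDefinition("cloud_cover", [(m, 0) for m in (5, 6, 7)], "mean"),
    "precipitation": SeasonDefinition("precipitation", [(m, 1) for m in (7, 8, 9)], "sum"),
    "pdsi": SeasonDefinition("pdsi", [(9, 1)], "mean"),
}


def aggregate_season(climate: pd.DataFrame, season: SeasonDefinition) -> pd.Series:
    """Per-ring-year seasonal value; years with any month missing are NaN."""
    mat = climate_matrix(climate, season.variable)
    years = mat.index.to_numpy()
    cols = []
    for month, lag in season.months:
        if month not in mat.columns:
            # absent month column: that month is missing for every year
            col = pd.Series(np.nan, index=mat.index)
        else:
            col = mat[month]
        if lag:
            col = col.copy()
            col.index = col.index + 1  # prev-year value attaches to next ring year
        cols.append(col)
    aligned = pd.concat(cols, axis=1, join="outer")
    aligned = aligned.reindex(range(int(years.min()), int(years.max()) + 1 + 1))
    agg = aligned.sum(axis=1) if season.aggregator == "sum" else aligned.mean(axis=1)
    agg[aligned.isna().any(axis=1)] = np.nan
    agg.index.name = "year"
    return agg.dropna()


def screen_months(
    chronology: pd.Series,
    climate: pd.DataFrame,
    variable: str,
    window: tuple[int, int] = (1901, 2007),
) -> pd.DataFrame:
    """Spearman rho of the mean chronology against each candidate month.

    Candidates are the 24 single months of the current and previous year.
    Exploratory: two-sided p-values carry no multiplicity correction.
    """
    lo, hi = window
    chron = chronology[(chronology.index >= lo) & (chronology.index <= hi)].dropna()
    mat = climate_matrix(climate, variable)
    rows = []
    for lag in (1, 0):
        for month in range(1, 13):
            if month not in mat.columns:
                continue
            col = mat[month]
            if lag:
                col = col.copy()
                col.index = col.index + 1
            joint = pd.concat([chron, col], axis=1, join="inner").dropna()
            if len(joint) < 30:
                raise ValueError(
                    f"only {len(joint)} overlapping years for {variable} month {month} "
                    f"(lag {lag}); need >= 30"
                )
            rho, p = stats.spearmanr(joint.iloc[:, 0], joint.iloc[:, 1])
            rows.append(
                {"variable": variable, "month": month, "lag": lag, "rho": rho,
                 "p_value": p, "n": len(joint)}
            )
    return pd.DataFrame(rows)


def spearman_by_period(
    tree_series: dict[str, pd.Series],
    seasonal: pd.Series,
    periods,
    variable: str = "",
    min_years: int = 5,
) -> pd.DataFrame:
    """Per-tree, per-period Spearman rho between detrended increments and one
    detrended seasonal climate series (average-rank tie handling).

    Periods with fewer than ``min_years`` overlapping years are reported with
    NaN rho and flagged.
    """
    rows = []
    for tid, series in tree_series.items():
        for period in periods:
            years = [
                y for y in range(period.start_year, period.end_year + 1)
                if y in series.index and y in seasonal.index
            ]
            if len(years) < min_years:
                rows.append(
                    {"tree_id": tid, "period": period.label, "variable": variable,
                     "rho": np.nan, "n": len(years)}
                )
                continue
            rho, _ = stats.spearmanr(series.loc[years], seasonal.loc[years])
            rows.append(
                {"tree_id": tid, "period": period.label, "variable": variable,
                 "rho": rho, "n": len(years)}
            )
    return pd.DataFrame(rows)


def running_correlation(x: pd.Series, y: pd.Series, window_years: int = 31) -> pd.Series:
    """Centered moving-window Spearman correlation, indexed by center year."""
    if window_years % 2 == 0 or window_years < 11:
        raise ValueError("window must be odd and >= 11")
    joint = pd.concat([x, y], axis=1, join="inner").dropna()
    n = len(joint)
    if window_years > n:
        raise ValueError(f"window {window_years} exceeds series length {n}")
    half = window_years // 2
    years = joint.index.to_numpy()
    out = {}
    for i in range(half, n - half):
        chunk = joint.iloc[i - half : i + half + 1]
        rho, _ = stats.spearmanr(chunk.iloc[:, 0], chunk.iloc[:, 1])
        out[years[i]] = rho
    s = pd.Series(out, name="rho")
    s.index.name = "center_year"
    return s
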