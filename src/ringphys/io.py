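"""Readers, writers and validation for the formats the pipeline touches.

Ring widths travel as Tucson (.rwl) decadal text, everything else as plain
CSV: isotope segments (``tree_id,start_year,end_year,d13c_wood``), the annual
atmospheric record (``year,d13c_air,ca_ppm``) and monthly climate in long form
(``variable,year,month,value``). Validated tables are plain pandas DataFrames;
ring-width series get a small dataclass because they carry per-series metadata
(site, pith offset) that a flat frame handles poorly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: sentinel values ending a Tucson series measured in 0.01 mm units
_RWL_TERMINATORS = {999, -9999}

CLIMATE_VARIABLES = ("temperature", "cloud_cover", "precipitation", "pdsi")

# wood delta13C outside this range is physically implausible for conifers
_WOOD_D13C_RANGE = (-35.0, -15.0)


@dataclass
class RingWidthSeries:
    """Dated annual ring widths of one increment core.

    Widths are in mm (0.01 mm measurement precision); ``pith_offset_mm`` is
    the estimated radial distance from the innermost measured ring to the
    stem centre. A width of exactly 0 encodes a locally absent (missing)
    ring. Years are inclusive calendar years; the ring dated Y formed in the
    growing season of year Y.
    """

    tree_id: str
    site: str
    first_year: int
    widths: np.ndarray
    pith_offset_mm: float = 0.0

    def __post_init__(self) -> None:
        self.widths = np.asarray(self.widths, dtype=float)
        if self.widths.ndim != 1 or self.widths.size == 0:
            raise ValueError(f"series {self.tree_id}: widths must be a non-empty 1-d array")
        if np.any(self.widths < 0) or not np.all(np.isfinite(self.widths)):
            raise ValueError(f"series {self.tree_id}: widths must be finite and >= 0")
        if self.pith_offset_mm < 0:
            raise ValueError(f"series {self.tree_id}: pith_offset_mm must be >= 0")

    @property
    def last_year(self) -> int:
        return self.first_year + len(self.widths) - 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.last_year + 1)

    def __len__(self) -> int:
        return len(self.widths)


# ---------------------------------------------------------------------------
# Tucson .rwl
# ---------------------------------------------------------------------------

def read_rwl(path, site: str = "") -> list[RingWidthSeries]:
    """Read a decadal Tucson ring-width file (0.01 mm units) into mm series.

    The id occupies the first 8 characters of each line, followed by the year
    of the line's first value and up to ten integer widths; 999 or -9999
    terminates a series. Widths of 9.99 mm cannot be stored in the 0.01 mm
    dialect because 999 is reserved as the terminator.
    """
    with open(path) as fh:
        lines = fh.readlines()
    if not any(line.strip() for line in lines):
        logger.warning("rwl file %s is empty", path)
        return []

    active: dict[str, dict] = {}
    finished: list[RingWidthSeries] = []
    done_ids: set[str] = set()

    for lineno, raw in enumerate(lines, start=1):
        if not raw.strip():
            continue
        sid = raw[:8].strip()
        rest = raw[8:].split()
        if not sid or not rest:
            raise ValueError(f"{path}: malformed line {lineno}: {raw.rstrip()!r}")
        try:
            year = int(rest[0])
        except ValueError:
            raise ValueError(
                f"{path}: malformed year field on line {lineno}: {rest[0]!r}"
            ) from None
        if sid in done_ids:
            raise ValueError(f"{path}: duplicated series id {sid!r} on line {lineno}")
        state = active.get(sid)
        if state is None:
            state = active[sid] = {"first_year": year, "values": []}
        else:
            expected = state["first_year"] + len(state["values"])
            if year != expected:
                raise ValueError(
                    f"{path}: line {lineno}: year {year} for series {sid!r}, "
                    f"expected {expected}"
                )
        ended = False
        for tok in rest[1:]:
            try:
                val = int(tok)
            except ValueError:
                raise ValueError(
                    f"{path}: malformed value {tok!r} on line {lineno}"
                ) from None
            if val in _RWL_TERMINATORS:
                ended = True
                break
            if val < 0:
                raise ValueError(f"{path}: negative ring width on line {lineno}")
            state["values"].append(val / 100.0)
        if ended:
            finished.append(
                RingWidthSeries(
                    tree_id=sid,
                    site=site,
                    first_year=state["first_year"],
                    widths=np.array(state["values"]),
                )
            )
            done_ids.add(sid)
            del active[sid]

    for sid, state in active.items():
        logger.warning("series %s has no terminator; accepting as-is", sid)
        finished.append(
            RingWidthSeries(
                tree_id=sid,
                site=site,
                first_year=state["first_year"],
                widths=np.array(state["values"]),
            )
        )
    return finished


def write_rwl(series: list[RingWidthSeries], path) -> None:
    """Write series in the decadal Tucson dialect (0.01 mm units, 999 end)."""
    with open(path, "w") as fh:
        for s in series:
            vals = np.round(np.asarray(s.widths) * 100).astype(int)
            year = s.first_year
            i = 0
            pending_terminator = True
            while i < len(vals):
                row_end_year = (year // 10) * 10 + 9
                n = min(row_end_year - year + 1, len(vals) - i)
                row = vals[i : i + n]
                cells = "".join(f"{v:6d}" for v in row)
                if i + n == len(vals) and n < 10:
                    cells += f"{999:6d}"
                    pending_terminator = False
                fh.write(f"{s.tree_id:<8s}{year:4d}{cells}\n")
                year += n
                i += n
            if pending_terminator:
                fh.write(f"{s.tree_id:<8s}{year:4d}{999:6d}\n")


def apply_site_map(series: list[RingWidthSeries], site_map: dict[str, str]) -> None:
    """Attach catchment labels to series in place; unknown ids raise."""
    for s in series:
        if s.tree_id not in site_map:
            raise KeyError(f"no site entry for series {s.tree_id!r}")
        s.site = site_map[s.tree_id]


def read_site_map(path) -> dict[str, str]:
    df = pd.read_csv(path)
    if not {"tree_id", "site"} <= set(df.columns):
        raise ValueError(f"{path}: site map needs columns tree_id,site")
    return dict(zip(df["tree_id"].astype(str), df["site"].astype(str)))


# ---------------------------------------------------------------------------
# isotope segments
# ---------------------------------------------------------------------------

def validate_isotopes(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a wood-isotope segment table.

    Enforces 1-5 year segment spans; warns on wood delta13C outside the
    plausible (-35, -15) permil range and on overlapping segments within a
    tree (overlaps are kept — the measurement protocol does not forbid them).
    """
    required = {"tree_id", "start_year", "end_year", "d13c_wood"}
    if not required <= set(df.columns):
        raise ValueError(f"isotope table needs columns {sorted(required)}")
    df = df.copy()
    df["start_year"] = df["start_year"].astype(int)
    df["end_year"] = df["end_year"].astype(int)
    span = df["end_year"] - df["start_year"] + 1
    if ((span < 1) | (span > 5)).any():
        bad = df.loc[(span < 1) | (span > 5)]
        raise ValueError(f"segment spans outside 1-5 years:\n{bad}")
    lo, hi = _WOOD_D13C_RANGE
    outside = (df["d13c_wood"] < lo) | (df["d13c_wood"] > hi)
    if outside.any():
        warnings.warn(
            f"{int(outside.sum())} wood d13C values outside the plausible "
            f"({lo}, {hi}) permil range",
            stacklevel=2,
        )
    for tid, g in df.groupby("tree_id"):
        g = g.sort_values("start_year")
        if (g["start_year"].values[1:] <= g["end_year"].values[:-1]).any():
            warnings.warn(f"overlapping isotope segments for tree {tid}", stacklevel=2)
    return df


def read_isotope_csv(path) -> pd.DataFrame:
    return validate_isotopes(pd.read_csv(path))


def write_isotope_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# atmospheric record
# ---------------------------------------------------------------------------

def validate_atmosphere(df: pd.DataFrame) -> pd.DataFrame:
    required = {"year", "d13c_air", "ca_ppm"}
    if not required <= set(df.columns):
        raise ValueError(f"atmosphere table needs columns {sorted(required)}")
    df = df.copy()
    df["year"] = df["year"].astype(int)
    if not df["year"].is_monotonic_increasing or df["year"].duplicated().any():
        raise ValueError("atmosphere years must be strictly increasing")
    if (df["ca_ppm"] <= 0).any():
        raise ValueError("ca_ppm must be positive")
    if (df["d13c_air"] >= 0).any():
        raise ValueError("d13c_air must be negative (permil vs VPDB)")
    return df


def read_atmosphere_csv(path) -> pd.DataFrame:
    return validate_atmosphere(pd.read_csv(path))


def write_atmosphere_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def interpolate_atmosphere(atmosphere: pd.DataFrame, years) -> pd.DataFrame:
    """Linearly interpolate (d13c_air, ca_ppm) at the requested (possibly
    fractional) years; exact at tabulated years; extrapolation is an error.
    """
    atmosphere = validate_atmosphere(atmosphere)
    years = np.atleast_1d(np.asarray(years, dtype=float))
    lo, hi = atmosphere["year"].iloc[0], atmosphere["year"].iloc[-1]
    out = (years < lo) | (years > hi)
    if out.any():
        raise ValueError(
            f"years outside the atmospheric record [{lo}, {hi}]: {years[out]}"
        )
    return pd.DataFrame(
        {
            "year": years,
            "d13c_air": np.interp(years, atmosphere["year"], atmosphere["d13c_air"]),
            "ca_ppm": np.interp(years, atmosphere["year"], atmosphere["ca_ppm"]),
        }
    )


# ---------------------------------------------------------------------------
# monthly climate
# ---------------------------------------------------------------------------

def validate_climate(df: pd.DataFrame) -> pd.DataFrame:
    required = {"variable", "year", "month", "value"}
    if not required <= set(df.columns):
        raise ValueError(f"climate table needs columns {sorted(required)}")
    df = df.copy()
    df["year"] = df["year"].astype(int)
    df["month"] = df["month"].astype(int)
    if ((df["month"] < 1) | (df["month"] > 12)).any():
        raise ValueError("month must be in 1..12")
    if df.duplicated(["variable", "year", "month"]).any():
        raise ValueError("duplicated (variable, year, month) entries")
    precip = df.loc[df["variable"] == "precipitation", "value"]
    if (precip < 0).any():
        raise ValueError("precipitation must be >= 0")
    cloud = df.loc[df["variable"] == "cloud_cover", "value"]
    if ((cloud < 0) | (cloud > 100)).any():
        raise ValueError("cloud cover must be within [0, 100]")
    return df


def read_climate_csv(path) -> pd.DataFrame:
    return validate_climate(pd.read_csv(path))


def write_climate_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def climate_matrix(climate: pd.DataFrame, variable: str) -> pd.DataFrame:
    """Pivot one climate variable to a year x month matrix."""
    sub = climate[climate["variable"] == variable]
    if sub.empty:
        raise KeyError(f"climate variable {variable!r} not present")
    return sub.pivot(index="year", columns="month", values="value")
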