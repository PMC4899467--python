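"""Synthetic data with the statistical structure the analysis assumes.

The generators stand in for the (undeposited) field and archive data:

* an annual atmospheric record with a smooth anthropogenic rise of Ca
  (~296 -> ~385 ppm over 1850-2011, period means ~339 ppm in 1971-1989 and
  ~381 ppm in 2006-2011) and mirrored decline of d13C_air (~-6.4 -> ~-8.3);
* monthly mountain climate (annual mean temperature ~4 degC, precipitation
  ~1250 mm/yr, cloud cover anti-correlated with temperature, PDSI as damped
  precipitation anomalies);
* age-trended AR(1) ring-width series sharing a growing-season temperature
  signal, tuned to realistic chronology statistics (mean sensitivity ~0.2,
  lag-1 autocorrelation ~0.85-0.9);
* wood-d13C segments generated on the Delta13C scale as
  intercept + period effect + tree intercept + noise and inverted through the
  discrimination model to delta13C_wood, so the full physiology -> period
  -> mixed-model chain can be validated end to end.

All generators are deterministic under a fixed seed and emit the formats the
io module consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import RingWidthSeries
from .periods import DEFAULT_PERIODS, PeriodDefinition, period_of, validate_periods
from .physiology import foliage_from_discrimination, foliage_to_wood

# logistic Ca(t) solved once against the calibration targets above
_CA_LO = 295.642
_CA_AMP = 163.986
_CA_YEAR0 = 2006.401
_CA_SCALE = 25.532

_D13C_AIR_START = -6.4
_D13C_AIR_END = -8.3


@dataclass
class SimulationConfig:
    """Study-condition defaults for every generator.

    Tree counts mirror the sampling design (25 + 6 isotope trees, 105
    increment trees per catchment); period effects default to the published
    best-model estimates for Delta13C; variance components are set so the
    fitted model's conditional pseudo-R2 lands near 0.87.
    """

    seed: int = 0
    start_year: int = 1850
    end_year: int = 2011
    periods: tuple[PeriodDefinition, ...] = DEFAULT_PERIODS

    # isotopes
    n_isotope_trees: dict = field(default_factory=lambda: {"Certovo": 25, "Plesne": 6})
    delta13c_intercept: float = 19.635
    delta13c_period_effects: dict = field(
        default_factory=lambda: {"pollution": -1.876, "post1": -0.696, "post2": -0.480}
    )
    tree_sd: float = 0.57
    segment_sd: float = 0.7
    segment_length_max: int = 5

    # ring widths
    n_increment_trees: dict = field(default_factory=lambda: {"Certovo": 105, "Plesne": 105})
    ar1: float = 0.85
    ar1_innovation_sd: float = 0.25
    climate_beta: float = 0.12
    agetrend_scale_mm: float = 2.5
    agetrend_rate: float = 1.0 / 80.0
    agetrend_floor_mm: float = 0.5
    tree_growth_sd: float = 0.3
    recruit_years: tuple[int, int] = (1780, 1860)
    pith_offset_max_mm: float = 10.0

    # climate
    temp_mean_c: float = 4.0
    temp_seasonal_amp_c: float = 8.5
    temp_year_sd_c: float = 0.8
    temp_month_sd_c: float = 1.5
    temp_trend_c_per_year: float = 0.008
    precip_month_mean_mm: float = 105.0
    precip_shape: float = 4.0
    cloud_mean_pct: float = 60.0
    cloud_temp_slope: float = -2.5
    cloud_sd_pct: float = 6.0
    pdsi_ar1: float = 0.7

    def __post_init__(self) -> None:
        if not -1 < self.ar1 < 1:
            raise ValueError("AR(1) coefficient must lie in (-1, 1)")
        for name in ("tree_sd", "segment_sd", "ar1_innovation_sd", "tree_growth_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        validate_periods(self.periods)

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.end_year + 1)


def simulate_atmosphere(config: SimulationConfig) -> pd.DataFrame:
    """Smooth monotone annual Ca / d13C_air record (no stochastic part)."""
    years = config.years
    ca = _CA_LO + _CA_AMP / (1.0 + np.exp(-(years - _CA_YEAR0) / _CA_SCALE))
    frac = (ca - ca[0]) / (ca[-1] - ca[0])
    d13c_air = _D13C_AIR_START + (_D13C_AIR_END - _D13C_AIR_START) * frac
    return pd.DataFrame({"year": years, "d13c_air": d13c_air, "ca_ppm": ca})


def simulate_climate(config: SimulationConfig) -> pd.DataFrame:
    """Monthly temperature, precipitation, cloud cover and PDSI (long form)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    years = config.years
    n_years = len(years)
    months = np.arange(1, 13)
    mid = years.mean()

    seasonal = config.temp_seasonal_amp_c * np.cos(2 * np.pi * (months - 7) / 12.0)
    year_eff = rng.normal(0.0, config.temp_year_sd_c, size=n_years)
    temp = (
        config.temp_mean_c
        + config.temp_trend_c_per_year * (years[:, None] - mid)
        + seasonal[None, :]
        + year_eff[:, None]
        + rng.normal(0.0, config.temp_month_sd_c, size=(n_years, 12))
    )

    scale = config.precip_month_mean_mm / config.precip_shape
    precip = rng.gamma(config.precip_shape, scale, size=(n_years, 12))

    temp_anom = temp - (config.temp_mean_c + seasonal[None, :])
    cloud = np.clip(
        config.cloud_mean_pct
        + config.cloud_temp_slope * temp_anom
        + rng.normal(0.0, config.cloud_sd_pct, size=(n_years, 12)),
        0.0,
        100.0,
    )

    precip_z = (precip - precip.mean()) / precip.std()
    pdsi = np.empty((n_years, 12))
    prev = 0.0
    for i in range(n_years):
        for j in range(12):
            prev = config.pdsi_ar1 * prev + 0.5 * precip_z[i, j] + rng.normal(0.0, 0.2)
            pdsi[i, j] = prev

    frames = []
    for name, mat in (
        ("temperature", temp),
        ("cloud_cover", cloud),
        ("precipitation", precip),
        ("pdsi", pdsi),
    ):
        frames.append(
            pd.DataFrame(
                {
                    "variable": name,
                    "year": np.repeat(years, 12),
                    "month": np.tile(months, n_years),
                    "value": mat.ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def growing_season_signal(climate: pd.DataFrame) -> pd.Series:
    """Standardized May-September mean temperature per year."""
    from .climate import DEFAULT_SEASONS, aggregate_season

    t = aggregate_season(climate, DEFAULT_SEASONS["temperature"])
    return (t - t.mean()) / t.std()


def simulate_ring_widths(config: SimulationConfig, climate: pd.DataFrame) -> list[RingWidthSeries]:
    """Age-trended multiplicative AR(1) ring-width series with a shared
    growing-season temperature signal.

    width(t) = (scale*exp(-age/tau) + floor)
               * exp(beta * z_T(t) + AR(1) noise + tree effect).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 22]))
    z = growing_season_signal(climate)
    series: list[RingWidthSeries] = []
    for site, n_trees in config.n_increment_trees.items():
        for i in range(n_trees):
            pith_year = int(rng.integers(config.recruit_years[0], config.recruit_years[1] + 1))
            years = np.arange(pith_year, config.end_year + 1)
            ages = years - pith_year + 1
            trend = (
                config.agetrend_scale_mm * np.exp(-ages * config.agetrend_rate)
                + config.agetrend_floor_mm
            )
            eps = np.empty(len(years))
            stat_sd = config.ar1_innovation_sd / np.sqrt(1 - config.ar1**2)
            eps[0] = rng.normal(0.0, stat_sd)
            innov = rng.normal(0.0, config.ar1_innovation_sd, size=len(years) - 1)
            for t in range(1, len(years)):
                eps[t] = config.ar1 * eps[t - 1] + innov[t - 1]
            tree_eff = rng.normal(0.0, config.tree_growth_sd)
            zt = z.reindex(years).fillna(0.0).to_numpy()
            widths = trend * np.exp(config.climate_beta * zt + eps + tree_eff)
            widths = np.round(np.clip(widths, 0.0, 9.98), 2)
            series.append(
                RingWidthSeries(
                    tree_id=f"{site[:3].upper()}{i + 1:03d}",
                    site=site,
                    first_year=pith_year,
                    widths=widths,
                    pith_offset_mm=float(rng.uniform(0.0, config.pith_offset_max_mm)),
                )
            )
    return series


def _segment_spans(start: int, end: int, boundaries: set[int], max_len: int, rng) -> list[tuple[int, int]]:
    """Random 1..max_len-year segments never straddling a period boundary.

    ``boundaries`` holds the first years of periods (a segment may not span
    across one) and the years after period ends.
    """
    spans = []
    y = start
    while y <= end:
        length = int(rng.integers(1, max_len + 1))
        stop = min(y + length - 1, end)
        for b in sorted(boundaries):
            if y < b <= stop:
                stop = b - 1
                break
        spans.append((y, stop))
        y = stop + 1
    return spans


def simulate_isotopes(config: SimulationConfig, atmosphere: pd.DataFrame) -> pd.DataFrame:
    """Wood-d13C segments carrying configured period effects on Delta13C.

    Delta13C(segment) = intercept + period effect (by segment midpoint)
    + tree intercept + segment noise, inverted through the discrimination
    model and the foliage/wood relation at the segment midpoint atmosphere.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 33]))
    boundaries: set[int] = set()
    for p in config.periods:
        boundaries.add(p.start_year)
        boundaries.add(p.end_year + 1)
    years = atmosphere["year"].to_numpy()
    rows = []
    for site, n_trees in config.n_isotope_trees.items():
        for i in range(n_trees):
            tid = f"ISO{site[:3].upper()}{i + 1:03d}"
            tree_eff = rng.normal(0.0, config.tree_sd)
            for s, e in _segment_spans(
                config.start_year, config.end_year, boundaries,
                config.segment_length_max, rng,
            ):
                mid = (s + e) / 2.0
                label = period_of(mid, config.periods)
                effect = config.delta13c_period_effects.get(label, 0.0) if label else 0.0
                delta = (
                    config.delta13c_intercept + effect + tree_eff
                    + rng.normal(0.0, config.segment_sd)
                )
                d13c_air = np.interp(mid, years, atmosphere["d13c_air"])
                foliage = foliage_from_discrimination(d13c_air, delta)
                rows.append(
                    {
                        "tree_id": tid,
                        "site": site,
                        "start_year": s,
                        "end_year": e,
                        "d13c_wood": float(foliage_to_wood(foliage)),
                    }
                )
    return pd.DataFrame(rows)


def simulate_dataset(config: SimulationConfig) -> dict:
    """All four inputs from one seed: atmosphere, climate, ring widths,
    isotope segments."""
    atmosphere = simulate_atmosphere(config)
    climate = simulate_climate(config)
    return {
        "atmosphere": atmosphere,
        "climate": climate,
        "ring_widths": simulate_ring_widths(config, climate),
        "isotopes": simulate_isotopes(config, atmosphere),
    }
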