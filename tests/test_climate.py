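"""Seasonal aggregation, month screening and Spearman machinery."""

import numpy as np
import pandas as pd
import pytest

from ringphys.climate import (
    DEFAULT_SEASONS,
    SeasonDefinition,
    aggregate_season,
    running_correlation,
    screen_months,
    spearman_by_period,
)
from ringphys.periods import DEFAULT_PERIODS


def _climate_frame(variable, year_month_value):
    return pd.DataFrame(
        [{"variable": variable, "year": y, "month": m, "value": v}
         for y, m, v in year_month_value]
    )


class TestAggregateSeason:
    def test_growing_season_mean(self):
        rows = [(2000, m, v) for m, v in zip(range(5, 10), [10, 12, 14, 12, 8])]
        clim = _climate_frame("temperature", rows)
        out = aggregate_season(clim, DEFAULT_SEASONS["temperature"])
        assert out.loc[2000] == pytest.approx(11.2)

    def test_lagged_precipitation_sum_attaches_to_next_ring_year(self):
        rows = [(1999, 7, 100.0), (1999, 8, 80.0), (1999, 9, 120.0),
                (2000, 7, 1.0), (2000, 8, 1.0), (2000, 9, 1.0)]
        clim = _climate_frame("precipitation", rows)
        out = aggregate_season(clim, DEFAULT_SEASONS["precipitation"])
        assert out.loc[2000] == pytest.approx(300.0)

    def test_lagged_pdsi_passthrough(self):
        clim = _climate_frame("pdsi", [(1999, 9, -1.7)])
        out = aggregate_season(clim, DEFAULT_SEASONS["pdsi"])
        assert out.loc[2000] == pytest.approx(-1.7)

    def test_missing_month_drops_year(self):
        rows = [(2000, m, 10.0) for m in (5, 6, 7, 8)]  # September absent
        clim = _climate_frame("temperature", rows)
        out = aggregate_season(clim, DEFAULT_SEASONS["temperature"])
        assert 2000 not in out.index

    def test_invalid_season_definitions_rejected(self):
        with pytest.raises(ValueError):
            SeasonDefinition("temperature", [])
        with pytest.raises(ValueError):
            SeasonDefinition("temperature", [(13, 0)])
        with pytest.raises(ValueError):
            SeasonDefinition("temperature", [(5, 0)], aggregator="median")


class TestScreenMonths:
    def test_injected_growing_season_signal_dominates(self, small_config, climate):
        from ringphys.detrend import detrend
        from ringphys.simulate import growing_season_signal, simulate_ring_widths

        widths = simulate_ring_widths(small_config, climate)
        # mean chronology of detrended log-widths (climate enters via May-Sep T)
        frames = []
        for s in widths:
            series = pd.Series(np.log(np.clip(s.widths, 0.01, None)), index=s.years)
            frames.append(detrend(series, power=1.0)["residual"])
        chron = pd.concat(frames, axis=1).mean(axis=1)
        chron.index.name = "year"
        screen = screen_months(chron, climate, "temperature", window=(1901, 2007))
        top = screen.reindex(screen["rho"].abs().sort_values(ascending=False).index)
        top3 = top.head(3)
        assert set(top3["lag"]) == {0}
        assert set(top3["month"]) <= {5, 6, 7, 8, 9}

    def test_null_climate_yields_chance_level_hits(self, climate):
        rng = np.random.default_rng(12)
        years = np.arange(1901, 2008)
        chron = pd.Series(rng.normal(size=len(years)), index=years)
        screen = screen_months(chron, climate, "precipitation")
        assert (screen["p_value"] < 0.05).sum() <= 6  # approx 5% of 24 candidates

    def test_perfect_monotone_dependence(self, climate):
        from ringphys.io import climate_matrix

        mat = climate_matrix(climate, "temperature")
        chron = mat[7].loc[1901:2007] ** 3  # monotone map of July temperature
        screen = screen_months(chron, climate, "temperature")
        july = screen[(screen["month"] == 7) & (screen["lag"] == 0)]
        assert july["rho"].iloc[0] == pytest.approx(1.0)

    def test_insufficient_overlap_rejected(self, climate):
        chron = pd.Series([1.0] * 10, index=np.arange(1990, 2000))
        with pytest.raises(ValueError, match="overlap"):
            screen_months(chron, climate, "temperature")


class TestSpearmanByPeriod:
    def test_monotone_map_gives_one(self):
        years = np.arange(1971, 1990)
        x = pd.Series(np.linspace(0, 1, len(years)), index=years)
        out = spearman_by_period({"t": np.exp(x)}, x, DEFAULT_PERIODS)
        row = out[(out["tree_id"] == "t") & (out["period"] == "pollution")]
        assert row["rho"].iloc[0] == pytest.approx(1.0)

    def test_worked_rank_pair(self):
        # ranks differ by d^2 = 4 -> rho = 1 - 24/120 = 0.8
        years = np.arange(1971, 1976)
        x = pd.Series([1, 2, 3, 4, 5], index=years, dtype=float)
        y = pd.Series([2, 1, 4, 3, 5], index=years, dtype=float)
        out = spearman_by_period({"t": y}, x, DEFAULT_PERIODS)
        row = out[out["period"] == "pollution"]
        assert row["rho"].iloc[0] == pytest.approx(0.8)

    def test_null_distribution_calibrated(self):
        rng = np.random.default_rng(13)
        n, reps = 19, 2000
        rhos = np.empty(reps)
        years = np.arange(1971, 1990)
        clim = pd.Series(rng.normal(size=n), index=years)
        for i in range(reps):
            tree = pd.Series(rng.normal(size=n), index=years)
            out = spearman_by_period({"t": tree}, clim, DEFAULT_PERIODS)
            rhos[i] = out.loc[out["period"] == "pollution", "rho"].iloc[0]
        assert abs(rhos.mean()) < 0.02
        assert rhos.std() == pytest.approx(1 / np.sqrt(n - 1), abs=0.02)

    def test_short_overlap_flagged_missing(self):
        years = np.arange(2006, 2009)  # 3 years < 5 minimum
        x = pd.Series([1.0, 2.0, 3.0], index=years)
        out = spearman_by_period({"t": x}, x, DEFAULT_PERIODS)
        row = out[out["period"] == "post2"]
        assert np.isnan(row["rho"].iloc[0]) and row["n"].iloc[0] == 3

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(14)
        years = np.arange(1900, 1936)
        x = pd.Series(rng.normal(size=len(years)), index=years)
        y = pd.Series(rng.normal(size=len(years)), index=years)
        base = spearman_by_period({"t": y}, x, DEFAULT_PERIODS)
        mapped = spearman_by_period({"t": np.exp(y)}, x.rank(), DEFAULT_PERIODS)
        pd.testing.assert_series_equal(base["rho"], mapped["rho"])


class TestRunningCorrelation:
    def test_full_window_equals_global(self):
        rng = np.random.default_rng(15)
        years = np.arange(1900, 1931)
        x = pd.Series(rng.normal(size=31), index=years)
        y = pd.Series(rng.normal(size=31), index=years)
        run = running_correlation(x, y, window_years=31)
        from scipy.stats import spearmanr

        assert len(run) == 1
        assert run.iloc[0] == pytest.approx(spearmanr(x, y).statistic)

    def test_stationary_dependence_gives_flat_profile(self):
        rng = np.random.default_rng(16)
        n = 150
        years = np.arange(1850, 1850 + n)
        sig = rng.normal(size=n)
        x = pd.Series(sig + 0.5 * rng.normal(size=n), index=years)
        y = pd.Series(sig + 0.5 * rng.normal(size=n), index=years)
        run = running_correlation(x, y, 31)
        assert run.std() < 0.15

    def test_switched_off_dependence_detected(self):
        rng = np.random.default_rng(17)
        n = 140
        years = np.arange(1860, 1860 + n)
        sig = rng.normal(size=n)
        x = pd.Series(sig, index=years)
        y_vals = np.where(np.arange(n) < 70, sig, rng.normal(size=n))
        y = pd.Series(y_vals + 0.1 * rng.normal(size=n), index=years)
        run = running_correlation(x, y, 31)
        assert run.iloc[:30].mean() > 0.8
        assert run.iloc[-30:].mean() < 0.4

    def test_window_contract(self):
        x = pd.Series(np.arange(20.0), index=np.arange(20))
        with pytest.raises(ValueError, match="odd"):
            running_correlation(x, x, 12)
        with pytest.raises(ValueError, match="exceeds"):
            running_correlation(x, x, 31)
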