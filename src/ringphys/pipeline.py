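"""End-to-end orchestration: simulate -> physiology -> biomass -> detrend ->
correlate -> period models -> report, with a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .allometry import tree_biomass_series
from .climate import DEFAULT_SEASONS, aggregate_season, spearman_by_period
from .detrend import DetrendConfig, detrend, optimal_power
from .io import (
    RingWidthSeries,
    write_atmosphere_csv,
    write_climate_csv,
    write_isotope_csv,
    write_rwl,
)
from .periods import (
    DEFAULT_PERIODS,
    PUBLISHED_COEFFICIENTS,
    fit_period_model,
    percent_change_report,
    period_means_annual,
    period_means_segments,
    tree_period_sensitivity,
)
from .physiology import physiology_series
from .simulate import SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)


def biomass_table(ring_widths: list[RingWidthSeries]) -> pd.DataFrame:
    """Per-tree, per-year geometry/biomass/increment for a series collection."""
    return pd.concat(
        [tree_biomass_series(s) for s in ring_widths], ignore_index=True
    )


def detrended_increments(
    biomass: pd.DataFrame, config: DetrendConfig | None = None
) -> tuple[dict[str, pd.Series], float]:
    """Power-transform + spline-detrend each tree's increment series.

    Returns per-tree residual series and the pooled adaptive power p.
    """
    config = config or DetrendConfig()
    per_tree = {}
    for tid, g in biomass.groupby("tree_id"):
        inc = g.dropna(subset=["increment_kg"]).set_index("year")["increment_kg"]
        if len(inc) >= config.spline_wavelength_years / 2:
            per_tree[tid] = inc
    fit = optimal_power(per_tree.values(), config)
    residuals = {
        tid: detrend(series, config, power=fit.p)["residual"]
        for tid, series in per_tree.items()
    }
    return residuals, fit.p


def climate_correlations(
    residuals: dict[str, pd.Series],
    climate: pd.DataFrame,
    periods=DEFAULT_PERIODS,
    detrend_config: DetrendConfig | None = None,
) -> pd.DataFrame:
    """Per-tree, per-period Spearman correlations against the four detrended
    seasonal climate series (climate detrended with p = 1)."""
    detrend_config = detrend_config or DetrendConfig()
    frames = []
    for name, season in DEFAULT_SEASONS.items():
        seasonal = aggregate_season(climate, season)
        seasonal_resid = detrend(seasonal, detrend_config, power=1.0)["residual"]
        frames.append(
            spearman_by_period(residuals, seasonal_resid, periods, variable=name)
        )
    return pd.concat(frames, ignore_index=True)


def run_all(
    out_dir,
    sim_config: SimulationConfig | None = None,
    periods=DEFAULT_PERIODS,
    detrend_config: DetrendConfig | None = None,
) -> dict:
    """One-shot synthetic run of every stage, writing all outputs to out_dir.

    Returns the in-memory bundle. Re-running with the same seed and config
    produces byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_config = sim_config or SimulationConfig()
    detrend_config = detrend_config or DetrendConfig()

    logger.info("stage simulate")
    data = simulate_dataset(sim_config)
    write_atmosphere_csv(data["atmosphere"], out / "atmosphere.csv")
    write_climate_csv(data["climate"], out / "climate.csv")
    write_rwl(data["ring_widths"], out / "ring_widths.rwl")
    write_isotope_csv(data["isotopes"], out / "isotopes.csv")
    site_map = pd.DataFrame(
        {"tree_id": [s.tree_id for s in data["ring_widths"]],
         "site": [s.site for s in data["ring_widths"]]}
    )
    site_map.to_csv(out / "site_map.csv", index=False)

    logger.info("stage physiology")
    physio = physiology_series(data["isotopes"], data["atmosphere"])
    physio = physio.merge(
        data["isotopes"][["tree_id", "start_year", "end_year", "site"]],
        on=["tree_id", "start_year", "end_year"],
    )
    physio.to_csv(out / "physiology.csv", index=False)

    logger.info("stage biomass")
    biomass = biomass_table(data["ring_widths"])
    biomass.to_csv(out / "biomass.csv", index=False, float_format="%.6g")

    logger.info("stage detrend")
    residuals, power = detrended_increments(biomass, detrend_config)
    detrended = pd.concat(
        [s.rename("residual").reset_index().assign(tree_id=tid)
         for tid, s in residuals.items()],
        ignore_index=True,
    )
    detrended.to_csv(out / "detrended_increments.csv", index=False, float_format="%.6g")

    logger.info("stage correlate")
    correlations = climate_correlations(residuals, data["climate"], periods, detrend_config)
    correlations.to_csv(out / "correlations.csv", index=False, float_format="%.6g")

    logger.info("stage periods")
    site_lookup = dict(zip(site_map["tree_id"], site_map["site"]))
    results = {}
    physio_means = {}
    for response in ("delta13C", "ci_ppm", "iwue"):
        means = period_means_segments(
            physio.rename(columns={response: "value"}), periods
        )
        physio_means[response] = means
        results[response] = fit_period_model(means, periods, response_name=response)
    inc = biomass.rename(columns={"increment_kg": "value"})[
        ["tree_id", "site", "year", "value"]
    ].dropna()
    inc_means = period_means_annual(inc, periods)
    inc_means["site"] = inc_means["tree_id"].map(site_lookup)
    results["biomass_increment"] = fit_period_model(
        inc_means, periods, response_name="biomass_increment"
    )
    sens = tree_period_sensitivity(inc, periods)
    results["interannual_variability"] = fit_period_model(
        sens, periods, response_name="interannual_variability"
    )
    coef_rows = []
    for name, res in results.items():
        table = res.coefficient_table()
        frame = table.to_frame()
        frame.insert(0, "response", name)
        coef_rows.append(frame)
    pd.concat(coef_rows, ignore_index=True).to_csv(
        out / "coefficients.csv", index=False, float_format="%.6g"
    )
    with open(out / "model_summaries.txt", "w") as fh:
        for res in results.values():
            fh.write(res.summary() + "\n\n")

    logger.info("stage report")
    report = headline_report()
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)

    manifest = {
        "ringphys_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": sim_config.seed,
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(_config_dict(sim_config, detrend_config)).encode()
        ).hexdigest(),
        "adaptive_power": power,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {
        "data": data,
        "physiology": physio,
        "biomass": biomass,
        "residuals": residuals,
        "correlations": correlations,
        "models": results,
        "report": report,
        "power": power,
    }


def _config_dict(sim_config: SimulationConfig, detrend_config: DetrendConfig) -> dict:
    d = asdict(sim_config)
    d["periods"] = [list(p) for p in [(p.label, p.start_year, p.end_year) for p in sim_config.periods]]
    d["detrend"] = asdict(detrend_config)
    return d


def headline_report() -> dict:
    """The period-contrast arithmetic on the published coefficient tables:
    every headline percent change and absolute difference, with both natural
    baselines labelled where the baseline is ambiguous."""
    C = PUBLISHED_COEFFICIENTS
    pc = percent_change_report
    return {
        "delta13C": {
            "pollution_vs_pre_pct": pc(C["delta13C"], "pre", "pollution"),
            "recovery_post1_vs_pollution_pct": pc(C["delta13C"], "pollution", "post1"),
            "recovery_post2_vs_pollution_pct": pc(C["delta13C"], "pollution", "post2"),
            "pollution_reduction_permil": round(
                -pc(C["delta13C"], "pre", "pollution", mode="absolute", rounded=False), 2
            ),
        },
        "ci": {
            "pollution_vs_pre_pct": pc(C["ci"], "pre", "pollution"),
            "post1_vs_pre_pct": pc(C["ci"], "pre", "post1"),
            "post2_vs_pollution_pct": pc(C["ci"], "pollution", "post2"),
        },
        "iwue": {
            "pollution_vs_pre_pct": pc(C["iwue"], "pre", "pollution"),
            "post2_vs_pollution_pct": pc(C["iwue"], "pollution", "post2"),
            "post2_vs_pre_pct": pc(C["iwue"], "pre", "post2"),
            "pollution_minus_post2_abs": pc(
                C["iwue"], "post2", "pollution", mode="absolute"
            ),
        },
        "biomass_increment": {
            "post1_vs_pollution_certovo_pct": pc(
                C["biomass_increment"], "pollution", "post1", catchment="Certovo"
            ),
            "post1_vs_pollution_plesne_pct": pc(
                C["biomass_increment"], "pollution", "post1", catchment="Plesne"
            ),
        },
        "interannual_variability": {
            "pollution_vs_pre_pct": pc(
                C["interannual_variability"], "pre", "pollution"
            ),
            "post1_vs_pollution_pct": pc(
                C["interannual_variability"], "pollution", "post1"
            ),
        },
    }
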