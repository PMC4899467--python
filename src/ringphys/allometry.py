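"""Whole-tree biomass reconstruction from ring widths.

Per-year over-bark diameter is rebuilt from cumulative ring widths and the
pith offset, scaled by a bark/shrinkage factor (1.096, calibrated against
final-year diameter tape measurements). Height and crown length follow
site-specific diameter polynomials, cambial age comes from a pith-date
estimate, and five biomass components (needles, branches, dry branches, stem,
roots) come from log-linear allometric models in ln(diameter/10 [cm]),
ln(height), ln(age) and ln(crown length), each with a multiplicative
correction factor applied to the whole linear predictor. Annual biomass
increment is the first difference of total biomass.
"""

from __future__ import annotations

import logging
import unicodedata

import numpy as np
import pandas as pd

from .io import RingWidthSeries

logger = logging.getLogger(__name__)

#: over-bark correction: measured diameter / reconstructed under-bark diameter
BARK_FACTOR = 1.096

#: additional years from stump height (30 cm) to coring height (130 cm)
STUMP_AGE_YEARS = 10

# height (m) as polynomial in over-bark diameter (mm), per catchment
HEIGHT_POLY = {
    "Certovo": (1.3, 0.08661, -6.975e-5, 2.137e-8),
    "Plesne": (1.3, 0.05763, -2.596e-5, 0.0),
}

# crown length (m) = 0.0894 * diameter[mm] ** 0.8022, one model for both sites
CROWN_COEF = 0.0894
CROWN_EXP = 0.8022

# component models: ln(kg) = factor * (c0 + c_ld*ln(d/10) + c_ld2*ln(d/10)^2
#                                      + c_lh*ln(h) + c_lh2*ln(h)^2
#                                      + c_la*ln(age) + c_lcl*ln(cl))
BIOMASS_MODELS: dict[str, tuple[float, dict[str, float]]] = {
    "needles": (
        1.07410095,
        {"c0": -1.18863, "ld": 3.33792, "ld2": -0.24482, "lh": -3.31885,
         "lh2": 0.49368, "la": -0.13463, "lcl": 0.85797},
    ),
    "branches": (
        1.20383259,
        {"c0": 0.61063, "ld": 2.40589, "lh": -3.65994, "lh2": 0.4398,
         "lcl": 0.91027},
    ),
    "dry_branches": (
        1.22896995,
        {"c0": -3.09062, "ld": 2.04823, "lh": -1.286761, "la": 0.62836},
    ),
    "stem": (
        1.0097234,
        {"c0": -2.83958, "ld": 2.55203, "ld2": -0.14991, "lh": -0.19172,
         "lh2": 0.25739, "la": -0.08278},
    ),
    "roots": (
        1.0526828,
        {"c0": -8.15491, "ld": 4.08262, "ld2": -0.28378, "la": 0.34963,
         "lcl": 0.2452},
    ),
}

COMPONENTS = tuple(BIOMASS_MODELS)


def normalize_site(site: str) -> str:
    """Map catchment spellings (incl. diacritics) onto 'Certovo'/'Plesne'."""
    s = unicodedata.normalize("NFKD", str(site)).encode("ascii", "ignore").decode()
    s = s.strip().lower()
    if s.startswith("cert"):
        return "Certovo"
    if s.startswith("ples"):
        return "Plesne"
    raise ValueError(f"unknown catchment {site!r}; expected Certovo or Plesne")


def estimate_pith_year(series: RingWidthSeries, stump_age_years: int = STUMP_AGE_YEARS) -> int:
    """Estimate the calendar year of the pith at coring height's stump base.

    pith_year = first_year - round(pith_offset / mean width of the five
    innermost rings) - stump_age_years; cambial age at year t is then
    t - pith_year + 1.
    """
    if len(series) < 5:
        raise ValueError(f"series {series.tree_id}: need >= 5 rings to estimate pith year")
    inner_mean = float(np.mean(series.widths[:5]))
    if inner_mean <= 0:
        raise ValueError(
            f"series {series.tree_id}: five innermost rings have zero mean width"
        )
    years_to_pith = int(round(series.pith_offset_mm / inner_mean))
    return series.first_year - years_to_pith - stump_age_years


def reconstruct_diameter(series: RingWidthSeries, bark_factor: float = BARK_FACTOR) -> pd.Series:
    """Per-year over-bark breast-height diameter in mm.

    D(t) = bark_factor * (2 * cumulative width up to t + 2 * pith offset).
    """
    cum = np.cumsum(series.widths)
    d = bark_factor * (2.0 * cum + 2.0 * series.pith_offset_mm)
    return pd.Series(d, index=series.years, name="diameter_mm")


def height_model(diameter_mm, site: str):
    """Catchment-specific height (m) from over-bark diameter (mm)."""
    coefs = HEIGHT_POLY[normalize_site(site)]
    d = np.asarray(diameter_mm, dtype=float)
    return coefs[0] + coefs[1] * d + coefs[2] * d**2 + coefs[3] * d**3


def crown_length_model(diameter_mm):
    """Crown length (m) from over-bark diameter (mm); power law through 0."""
    d = np.asarray(diameter_mm, dtype=float)
    if np.any(d < 0):
        raise ValueError("diameter must be >= 0")
    return CROWN_COEF * d**CROWN_EXP


def tree_geometry(
    series: RingWidthSeries,
    bark_factor: float = BARK_FACTOR,
    stump_age_years: int = STUMP_AGE_YEARS,
) -> pd.DataFrame:
    """Per-year diameter, height, crown length and cambial age for one tree."""
    pith_year = estimate_pith_year(series, stump_age_years)
    d = reconstruct_diameter(series, bark_factor)
    out = pd.DataFrame(
        {
            "diameter_mm": d,
            "height_m": height_model(d.to_numpy(), series.site),
            "crown_length_m": crown_length_model(d.to_numpy()),
            "age_years": d.index.to_numpy() - pith_year + 1,
        },
        index=d.index,
    )
    out.index.name = "year"
    return out


def biomass_components(geometry: pd.DataFrame, tree_id: str = "") -> pd.DataFrame:
    """Component and total biomass (kg) from per-year tree geometry.

    Each component is exp(factor * linear predictor); the diameter enters the
    predictors as ln(diameter_mm / 10), i.e. in cm. All log arguments must be
    strictly positive.
    """
    d = geometry["diameter_mm"].to_numpy(dtype=float)
    h = geometry["height_m"].to_numpy(dtype=float)
    age = geometry["age_years"].to_numpy(dtype=float)
    cl = geometry["crown_length_m"].to_numpy(dtype=float)
    for name, arr in (("diameter", d), ("height", h), ("age", age), ("crown length", cl)):
        if np.any(arr <= 0):
            bad_years = geometry.index[arr <= 0].tolist()
            raise ValueError(
                f"tree {tree_id or '?'}: non-positive {name} in years {bad_years}; "
                "log-linear biomass models undefined"
            )
    ld = np.log(d / 10.0)
    lh = np.log(h)
    la = np.log(age)
    lcl = np.log(cl)
    terms = {"ld": ld, "ld2": ld**2, "lh": lh, "lh2": lh**2, "la": la, "lcl": lcl}

    out = pd.DataFrame(index=geometry.index)
    for comp, (factor, coefs) in BIOMASS_MODELS.items():
        lp = np.full_like(d, coefs["c0"])
        for key, value in terms.items():
            if key in coefs:
                lp = lp + coefs[key] * value
        out[f"{comp}_kg"] = np.exp(factor * lp)
    out["total_kg"] = out.sum(axis=1)
    return out


def biomass_increment(total_kg: pd.Series) -> pd.Series:
    """First difference of total biomass; the first year has no increment."""
    years = np.asarray(total_kg.index)
    if len(years) < 2:
        raise ValueError("need >= 2 consecutive years for an increment")
    if np.any(np.diff(years) != 1):
        raise ValueError("years must be consecutive (gap in biomass series)")
    inc = total_kg.diff().iloc[1:]
    inc.name = "increment_kg"
    n_neg = int((inc < 0).sum())
    if n_neg:
        logger.warning("%d negative biomass increments (age terms dominating)", n_neg)
    return inc


def tree_biomass_series(
    series: RingWidthSeries,
    bark_factor: float = BARK_FACTOR,
    stump_age_years: int = STUMP_AGE_YEARS,
) -> pd.DataFrame:
    """Full widths -> geometry -> biomass -> increment chain for one tree.

    Deterministic: identical inputs give bit-identical outputs.
    """
    geom = tree_geometry(series, bark_factor, stump_age_years)
    bio = biomass_components(geom, series.tree_id)
    out = pd.concat([geom, bio], axis=1)
    out["increment_kg"] = out["total_kg"].diff()
    out.insert(0, "tree_id", series.tree_id)
    out.insert(1, "site", normalize_site(series.site))
    return out.reset_index()


def bark_factor_calibration(reconstructed_mm, measured_mm) -> float:
    """Zero-intercept least-squares ratio of measured over-bark diameters on
    reconstructed under-bark diameters (the 1.096-style factor)."""
    r = np.asarray(reconstructed_mm, dtype=float)
    m = np.asarray(measured_mm, dtype=float)
    if r.shape != m.shape or r.size < 3:
        raise ValueError("need >= 3 paired diameters")
    if np.any(r <= 0) or np.any(m <= 0):
        raise ValueError("diameters must be positive")
    return float(np.dot(m, r) / np.dot(r, r))
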