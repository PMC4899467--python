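"""Chronology statistics and spline detrending.

Inter-annual variability is measured by mean sensitivity,
mean_i 2|x_i - x_{i-1}| / (x_i + x_{i-1}), bounded in [0, 2]. Low-frequency
variation (age, competition, decadal climate) is removed by subtracting a
cubic smoothing spline tuned so that a sinusoid of a chosen wavelength
(default 30 years) is attenuated to a chosen fraction of its amplitude
(default 50%) — the standard frequency-response criterion of dendro
detrending. Before splining, increment series are variance-stabilized by an
adaptive power transform x -> x^p with p = 1 - m, m being the slope of
log10(IQR) on log10(median) over non-overlapping 10-year segments.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import brentq
from scipy.sparse.linalg import spsolve

logger = logging.getLogger(__name__)


@dataclass
class DetrendConfig:
    """Tuning knobs of the detrending procedure.

    segment_length_years: segment size for the power-transform regression.
    spline_wavelength_years: wavelength at which the spline's response is
    pinned. frequency_response: amplitude fraction passed at that wavelength.
    """

    segment_length_years: int = 10
    spline_wavelength_years: int = 30
    frequency_response: float = 0.5

    def __post_init__(self) -> None:
        if self.segment_length_years <= 0 or self.spline_wavelength_years <= 0:
            raise ValueError("lengths must be positive")
        if not 0 < self.frequency_response < 1:
            raise ValueError("frequency_response must be in (0, 1)")


@dataclass
class PowerFit:
    """Result of the adaptive power-transform regression."""

    p: float
    slope: float
    r: float
    n_segments: int


def mean_sensitivity(values) -> float:
    """Mean sensitivity of a series: mean_i 2|x_i - x_{i-1}|/(x_i + x_{i-1}).

    Bounded in [0, 2] for non-negative series and invariant under positive
    rescaling. Pairs whose sum is zero are skipped with a warning.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 values")
    num = 2.0 * np.abs(np.diff(x))
    den = x[1:] + x[:-1]
    ok = den != 0
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} zero-sum pairs skipped in sensitivity", stacklevel=2)
    if not ok.any():
        raise ValueError("all year pairs degenerate (zero sums)")
    return float(np.mean(num[ok] / den[ok]))


def first_order_autocorrelation(values) -> float:
    """Lag-1 Pearson autocorrelation; NaN (with warning) for constant series."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 values")
    a, b = x[:-1], x[1:]
    if np.std(a) == 0 or np.std(b) == 0:
        warnings.warn("zero variance: lag-1 autocorrelation undefined", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def optimal_power(series_collection, config: DetrendConfig | None = None) -> PowerFit:
    """Adaptive power p = 1 - m from pooled 10-year segment (median, IQR) pairs.

    m is the least-squares slope of log10(IQR) on log10(median); p is clipped
    to [0.05, 1]. Segments shorter than the configured length (series tails)
    are dropped, as are segments with non-positive median or zero IQR.
    """
    config = config or DetrendConfig()
    seg = config.segment_length_years
    med, iqr = [], []
    for values in series_collection:
        x = np.asarray(values, dtype=float)
        for start in range(0, len(x) - seg + 1, seg):
            chunk = x[start : start + seg]
            m = np.median(chunk)
            q = np.percentile(chunk, 75) - np.percentile(chunk, 25)
            if m <= 0 or q <= 0:
                logger.warning("segment with non-positive median/IQR dropped")
                continue
            med.append(m)
            iqr.append(q)
    if len(med) < 2:
        raise ValueError("fewer than 2 usable segments for the power regression")
    lx = np.log10(med)
    ly = np.log10(iqr)
    slope, intercept = np.polyfit(lx, ly, 1)
    r = float(np.corrcoef(lx, ly)[0, 1]) if np.std(lx) > 0 else float("nan")
    p = float(np.clip(1.0 - slope, 0.05, 1.0))
    return PowerFit(p=p, slope=float(slope), r=r, n_segments=len(med))


def power_transform(values, p: float):
    """x -> x^p for non-negative series; negatives are clipped to 0 with a
    warning (possible for biomass increments in zero-growth years)."""
    x = np.asarray(values, dtype=float)
    if np.any(x < 0):
        warnings.warn(
            f"{int((x < 0).sum())} negative values clipped to 0 before power transform",
            stacklevel=2,
        )
        x = np.clip(x, 0.0, None)
    return x**p


def spline_smoothing_parameter(wavelength_years: float, frequency_response: float) -> float:
    """Penalty lambda such that the smoother passes the fraction
    ``frequency_response`` of a sinusoid of period ``wavelength_years``.

    Uses the analytic amplitude response of the second-difference penalized
    smoother, H(f) = 1 / (1 + 16 lambda sin^4(pi f)), solved by bisection.
    """
    f = 1.0 / wavelength_years

    def gap(log_lam: float) -> float:
        lam = 10.0**log_lam
        return 1.0 / (1.0 + 16.0 * lam * np.sin(np.pi * f) ** 4) - frequency_response

    log_lam = brentq(gap, -12.0, 15.0, xtol=1e-10)
    return float(10.0**log_lam)


def smoothing_spline(values, wavelength_years: float = 30.0, frequency_response: float = 0.5):
    """Cubic smoothing spline (discrete penalized form) fit to an evenly
    spaced series, tuned by the frequency-response criterion.

    Solves (I + lambda D2'D2) yhat = y with D2 the second-difference operator;
    deterministic for fixed input. Requires at least wavelength/2 points.
    """
    y = np.asarray(values, dtype=float)
    n = y.size
    if n < wavelength_years / 2:
        raise ValueError(
            f"series of length {n} too short for a {wavelength_years}-year spline"
        )
    if n < 3:
        raise ValueError("need >= 3 points")
    lam = spline_smoothing_parameter(wavelength_years, frequency_response)
    d2 = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n), dtype=float).tocsc()
    a = (sparse.eye(n, format="csc", dtype=float) + lam * (d2.T @ d2)).tocsc()
    return spsolve(a, y)


def detrend(
    series: pd.Series,
    config: DetrendConfig | None = None,
    power: float | None = 1.0,
    power_fit: PowerFit | None = None,
) -> pd.DataFrame:
    """Power-transform then subtract the smoothing spline.

    ``power`` may be given directly (1.0 = no transform, the convention for
    climate series); alternatively pass a :class:`PowerFit` from
    :func:`optimal_power`. Returns a frame with raw, transformed, spline and
    residual columns; residual + spline reconstructs transformed exactly.
    """
    config = config or DetrendConfig()
    if power_fit is not None:
        power = power_fit.p
    if power is None:
        power = 1.0
    x = series.to_numpy(dtype=float)
    transformed = power_transform(x, power) if power != 1.0 else x
    trend = smoothing_spline(
        transformed, config.spline_wavelength_years, config.frequency_response
    )
    return pd.DataFrame(
        {
            "raw": x,
            "transformed": transformed,
            "spline": trend,
            "residual": transformed - trend,
        },
        index=series.index,
    )
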