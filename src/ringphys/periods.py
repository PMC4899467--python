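"""Period-wise aggregation and mixed-effects contrasts of physiological series.

Annual (or multi-year segment) series are collapsed to one value per tree and
pollution-defined period, then modelled with a linear mixed model

    value ~ period (+ catchment) (+ period:catchment) (+ covariate),  (1|tree)

fitted by ML for AIC-based selection among candidate fixed structures and
refitted by REML for the reported estimates. Reference levels are the
pre-pollution period and the Certovo catchment. Results objects carry the
coefficient table, Nakagawa-Schielzeth marginal/conditional pseudo-R2,
single-step (Tukey-style) pairwise period comparisons with compact letter
display, and coefficient arithmetic (per-period predictions, percent changes).
"""

from __future__ import annotations

import itertools
import logging
import re
import string
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PeriodDefinition:
    """A labelled inclusive calendar-year interval."""

    label: str
    start_year: int
    end_year: int

    def __post_init__(self) -> None:
        if self.end_year < self.start_year:
            raise ValueError(f"period {self.label}: end before start")

    def contains(self, year: float) -> bool:
        return self.start_year <= year <= self.end_year

    def overlap_years(self, start: int, end: int) -> int:
        return max(0, min(self.end_year, end) - max(self.start_year, start) + 1)


#: the pollution chronology: before, during and (twice) after the deposition peak
DEFAULT_PERIODS: tuple[PeriodDefinition, ...] = (
    PeriodDefinition("pre", 1900, 1935),
    PeriodDefinition("pollution", 1971, 1989),
    PeriodDefinition("post1", 1998, 2005),
    PeriodDefinition("post2", 2006, 2011),
)

REFERENCE_CATCHMENT = "Certovo"
OTHER_CATCHMENT = "Plesne"


def validate_periods(periods) -> tuple[PeriodDefinition, ...]:
    periods = tuple(periods)
    for a, b in zip(periods, periods[1:]):
        if b.start_year <= a.end_year:
            raise ValueError(f"periods {a.label} and {b.label} overlap or are unordered")
    return periods


def period_of(year: float, periods=DEFAULT_PERIODS) -> str | None:
    for p in periods:
        if p.contains(year):
            return p.label
    return None


# ---------------------------------------------------------------------------
# aggregation to tree x period means
# ---------------------------------------------------------------------------

def period_means_annual(
    data: pd.DataFrame, periods=DEFAULT_PERIODS, value: str = "value"
) -> pd.DataFrame:
    """One mean per tree x period from an annual table (tree_id, year, value).

    Extra constant-per-tree columns (e.g. site) are carried through.
    Tree x period cells with no overlapping years are simply absent.
    """
    periods = validate_periods(periods)
    carry = [c for c in data.columns if c not in ("year", value)
             and data.groupby("tree_id")[c].nunique().max() == 1]
    rows = []
    for tid, g in data.groupby("tree_id"):
        for p in periods:
            inside = g[(g["year"] >= p.start_year) & (g["year"] <= p.end_year)]
            inside = inside.dropna(subset=[value])
            if inside.empty:
                continue
            row = {"tree_id": tid, "period": p.label,
                   "value": inside[value].mean(), "n": len(inside)}
            for c in carry:
                if c != "tree_id":
                    row[c] = g[c].iloc[0]
            rows.append(row)
    return pd.DataFrame(rows)


def period_means_segments(
    data: pd.DataFrame, periods=DEFAULT_PERIODS, value: str = "value"
) -> pd.DataFrame:
    """One mean per tree x period from a segment table
    (tree_id, start_year, end_year, value), weighting each segment by the
    number of its years falling inside the period."""
    periods = validate_periods(periods)
    carry = [c for c in data.columns
             if c not in ("start_year", "end_year", value, "tree_id")
             and data.groupby("tree_id")[c].nunique().max() == 1]
    rows = []
    for tid, g in data.groupby("tree_id"):
        for p in periods:
            w = np.array([
                p.overlap_years(int(s), int(e))
                for s, e in zip(g["start_year"], g["end_year"])
            ], dtype=float)
            if w.sum() == 0:
                continue
            vals = g[value].to_numpy(dtype=float)
            row = {"tree_id": tid, "period": p.label,
                   "value": float(np.average(vals, weights=w)), "n": int(w.sum())}
            for c in carry:
                row[c] = g[c].iloc[0]
            rows.append(row)
    return pd.DataFrame(rows)


def tree_period_sensitivity(
    data: pd.DataFrame, periods=DEFAULT_PERIODS, value: str = "value"
) -> pd.DataFrame:
    """Per tree x period mean sensitivity of an annual series (the
    inter-annual variability response)."""
    from .detrend import mean_sensitivity

    periods = validate_periods(periods)
    carry = [c for c in data.columns if c not in ("year", value, "tree_id")
             and data.groupby("tree_id")[c].nunique().max() == 1]
    rows = []
    for tid, g in data.groupby("tree_id"):
        g = g.sort_values("year")
        for p in periods:
            inside = g[(g["year"] >= p.start_year) & (g["year"] <= p.end_year)]
            inside = inside.dropna(subset=[value])
            if len(inside) < 2:
                continue
            row = {"tree_id": tid, "period": p.label,
                   "value": mean_sensitivity(inside[value].to_numpy()),
                   "n": len(inside)}
            for c in carry:
                row[c] = g[c].iloc[0]
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# coefficient tables and report arithmetic
# ---------------------------------------------------------------------------

_DECIMAL_COMMA = re.compile(r"^\s*[-–−]?\d+(,\d+)?\s*$")


def parse_estimate(text) -> float:
    """Parse a coefficient that may use a decimal comma and unicode minus."""
    if isinstance(text, (int, float)):
        return float(text)
    s = str(text).strip().replace("–", "-").replace("−", "-")
    if _DECIMAL_COMMA.match(s):
        s = s.replace(",", ".")
    return float(s)


@dataclass
class CoefficientTable:
    """Fixed-effect estimates of one fitted (or transcribed) period model.

    ``terms`` maps canonical term names -- 'intercept', 'period[<label>]',
    'catchment[Plesne]', 'period[<label>]:catchment[Plesne]', plus optional
    covariate terms -- to estimates. Terms absent from the mapping were absent
    from the best model (not zero): requesting a prediction that needs a
    missing period main effect raises.
    """

    response: str
    terms: dict[str, float]
    r2_marginal: float | None = None
    r2_conditional: float | None = None
    aic: float | None = None
    reference_period: str = "pre"

    def __post_init__(self) -> None:
        if "intercept" not in self.terms:
            raise ValueError("coefficient table must contain an intercept")

    def predict(self, period: str, catchment: str | None = None) -> float:
        """Model prediction: intercept + applicable period/catchment terms.

        ``catchment=None`` evaluates at the reference catchment (which for
        models without catchment terms is the pooled prediction).
        """
        value = self.terms["intercept"]
        if period != self.reference_period:
            key = f"period[{period}]"
            if key not in self.terms:
                raise KeyError(
                    f"term {key!r} absent from the best model for {self.response!r}"
                )
            value += self.terms[key]
        if catchment is not None and catchment != REFERENCE_CATCHMENT:
            key = f"catchment[{catchment}]"
            if key not in self.terms:
                raise KeyError(
                    f"term {key!r} absent from the best model for {self.response!r}"
                )
            value += self.terms[key]
            inter = f"period[{period}]:catchment[{catchment}]"
            value += self.terms.get(inter, 0.0)
        return value

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"term": list(self.terms), "estimate": list(self.terms.values())}
        )


def read_coefficient_csv(path, response: str = "") -> CoefficientTable:
    """Read a term,estimate CSV (decimal commas accepted) into a table."""
    df = pd.read_csv(path, dtype=str)
    if not {"term", "estimate"} <= set(df.columns):
        raise ValueError("coefficient CSV needs columns term,estimate")
    terms = {t: parse_estimate(e) for t, e in zip(df["term"], df["estimate"])}
    return CoefficientTable(response=response or str(path), terms=terms)


def percent_change_report(
    table: CoefficientTable,
    baseline: str,
    target: str,
    catchment: str | None = None,
    mode: str = "percent",
    rounded: bool = True,
) -> float:
    """Change between two period predictions assembled from a coefficient table.

    mode='percent': (target - baseline)/baseline * 100, rounded to the nearest
    integer. mode='absolute': target - baseline, rounded to one decimal.
    Pass ``rounded=False`` for the raw value.
    """
    b = table.predict(baseline, catchment)
    t = table.predict(target, catchment)
    if mode == "percent":
        if b == 0:
            raise ZeroDivisionError("baseline prediction is zero")
        v = (t - b) / b * 100.0
        return float(round(v)) if rounded else v
    if mode == "absolute":
        v = t - b
        return round(v, 1) if rounded else v
    raise ValueError("mode must be 'percent' or 'absolute'")


def _t2(response, r2m, r2c, aic, **raw) -> CoefficientTable:
    rename = {
        "intercept": "intercept",
        "pollution": "period[pollution]",
        "post1": "period[post1]",
        "post2": "period[post2]",
        "plesne": "catchment[Plesne]",
        "pollution_x_plesne": "period[pollution]:catchment[Plesne]",
        "post1_x_plesne": "period[post1]:catchment[Plesne]",
        "delta13c": "delta13C",
        "pollution_x_delta13c": "period[pollution]:delta13C",
        "post1_x_delta13c": "period[post1]:delta13C",
    }
    terms = {rename[k]: parse_estimate(v) for k, v in raw.items()}
    return CoefficientTable(response=response, terms=terms,
                            r2_marginal=r2m, r2_conditional=r2c, aic=aic)


#: transcribed best-model estimates (decimal commas in the source rendered as
#: decimal points); the published input for the report arithmetic
PUBLISHED_COEFFICIENTS: dict[str, CoefficientTable] = {
    "delta13C": _t2("delta13C", 0.52, 0.87, 143, intercept="19,635",
                    pollution="-1,876", post1="-0,696", post2="-0,480"),
    "ci": _t2("ci", 0.80, 0.94, 672, intercept="204,310",
              pollution="-4,060", post1="35,217", post2="44,241"),
    "iwue": _t2("iwue", 0.58, 0.89, 578, intercept="61,944",
                pollution="24,604", post1="21,056", post2="20,807"),
    "biomass_increment": _t2(
        "biomass_increment", 0.05, 0.71, 4157, intercept="9,945",
        pollution="1,141", post1="2,468", plesne="3,702",
        pollution_x_plesne="-1,966", post1_x_plesne="0,083"),
    "interannual_variability": _t2(
        "interannual_variability", 0.22, 0.51, -1648, intercept="0,170",
        pollution="0,090", post1="0,041"),
    "temperature_correlation": _t2(
        "temperature_correlation", 0.21, 0.29, -221, intercept="-0,018",
        pollution="0,236", post1="0,167", plesne="0,224",
        pollution_x_plesne="-0,159", post1_x_plesne="-0,080"),
    "precipitation_correlation": _t2(
        "precipitation_correlation", 0.12, 0.12, -279, intercept="0,111",
        pollution="-0,024", post1="0,039", plesne="0,065",
        pollution_x_plesne="0,029", post1_x_plesne="0,091"),
    "cloud_cover_correlation": _t2(
        "cloud_cover_correlation", 0.18, 0.18, -140, intercept="-0,039",
        pollution="-0,214", post1="-0,183", plesne="-0,067"),
    "drought_correlation": _t2(
        "drought_correlation", 0.26, 0.27, -189, intercept="0,029",
        pollution="-0,009", post1="0,137", plesne="0,013",
        pollution_x_plesne="0,039", post1_x_plesne="0,197"),
    "increment_vs_delta13C": _t2(
        "increment_vs_delta13C", 0.09, 0.84, 290, intercept="120,677",
        pollution="-108,637", post1="12,427", delta13c="-5,285",
        pollution_x_delta13c="5,473", post1_x_delta13c="-0,871"),
}


# ---------------------------------------------------------------------------
# mixed model
# ---------------------------------------------------------------------------

CANDIDATE_STRUCTURES = ("period", "period+catchment", "period*catchment", "intercept")


def _design_matrix(
    data: pd.DataFrame,
    structure: str,
    period_order: list[str],
    covariate: str | None = None,
) -> pd.DataFrame:
    """Treatment-coded fixed-effect design with pre/Certovo references."""
    n = len(data)
    X = pd.DataFrame({"intercept": np.ones(n)}, index=data.index)
    if structure == "intercept":
        if covariate is not None:
            X[covariate] = data[covariate].to_numpy(dtype=float)
        return X
    for label in period_order[1:]:
        X[f"period[{label}]"] = (data["period"] == label).astype(float)
    if structure in ("period+catchment", "period*catchment"):
        catch = data["site"].astype(str)
        X[f"catchment[{OTHER_CATCHMENT}]"] = (catch == OTHER_CATCHMENT).astype(float)
        if structure == "period*catchment":
            for label in period_order[1:]:
                X[f"period[{label}]:catchment[{OTHER_CATCHMENT}]"] = (
                    X[f"period[{label}]"] * X[f"catchment[{OTHER_CATCHMENT}]"]
                )
    if covariate is not None:
        X[covariate] = data[covariate].to_numpy(dtype=float)
    return X


def _mixedlm_fit(y, X, groups, reml):
    # lbfgs is fastest but can fail with a singular Hessian when the
    # random-intercept variance sits on the zero boundary; fall through to
    # sturdier optimizers before giving up.
    last = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(np.asarray(y, dtype=float), X, groups=groups)
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                return model.fit(reml=reml, method=method, maxiter=500)
            except (np.linalg.LinAlgError, ValueError) as exc:
                last = exc
    raise RuntimeError(f"mixed-model fit failed under all optimizers: {last}")


def _aic(result, n_fixed: int) -> float:
    # lme4 convention: k = fixed effects + random-intercept variance + residual
    return float(-2.0 * result.llf + 2.0 * (n_fixed + 2))


class PeriodMixedModel:
    """Random-intercept mixed model of tree x period means.

    Parameters
    ----------
    data
        Long table with columns tree_id, period, value and (optionally) site
        plus covariates. One row per tree x period.
    periods
        Ordered :class:`PeriodDefinition` sequence; the first period present
        in the data is the reference level.
    covariate
        Optional column entering the fixed part (with period interactions
        handled by :func:`fit_increment_vs_discrimination`, not here).
    candidates
        Candidate fixed structures for AIC selection; catchment structures
        are skipped automatically when the data hold a single catchment.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        periods=DEFAULT_PERIODS,
        covariate: str | None = None,
        candidates=CANDIDATE_STRUCTURES,
        response_name: str = "value",
        min_periods: int = 2,
    ):
        required = {"tree_id", "period", "value"}
        if not required <= set(data.columns):
            raise ValueError(f"data needs columns {sorted(required)}")
        data = data.dropna(subset=["value"]).copy()
        self.periods = validate_periods(periods)
        present = [p.label for p in self.periods if p.label in set(data["period"])]
        if len(present) < min_periods:
            raise ValueError(f"need >= {min_periods} periods with data")
        if data["tree_id"].nunique() < 5:
            raise ValueError("need >= 5 trees")
        self.period_order = present
        self.data = data
        self.covariate = covariate
        self.response_name = response_name
        multi_site = "site" in data.columns and data["site"].nunique() > 1
        self.candidates = [
            c for c in candidates if multi_site or "catchment" not in c
        ]

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "PeriodMixedModel":
        return cls(data, **kwargs)

    def fit(self, select: bool = True, structure: str | None = None) -> "PeriodMixedResults":
        """AIC-select the fixed structure under ML, then refit with REML.

        ``structure`` forces a candidate label (e.g. ``"period+catchment"`` or
        ``"period+<covariate>"``), bypassing selection.
        """
        y = self.data["value"].to_numpy(dtype=float)
        groups = self.data["tree_id"].to_numpy()
        specs: dict[str, tuple[str, str | None]] = {}
        for struct in self.candidates:
            for cov in ([None, self.covariate] if self.covariate else [None]):
                label = struct + (f"+{cov}" if cov else "")
                specs[label] = (struct, cov)
        if structure is not None:
            if structure not in specs:
                raise KeyError(f"unknown structure {structure!r}; options: {list(specs)}")
            candidates = [structure]
        elif select:
            candidates = list(specs)
        else:
            candidates = [next(iter(specs))]
        aic_table: dict[str, float] = {}
        for label in candidates:
            struct, cov = specs[label]
            X = _design_matrix(self.data, struct, self.period_order, cov)
            try:
                res = _mixedlm_fit(y, X, groups, reml=False)
            except Exception as exc:  # singular / non-converging fit
                logger.warning("ML fit failed for %s (%s); skipped", label, exc)
                continue
            aic_table[label] = _aic(res, X.shape[1])
        if not aic_table:
            raise RuntimeError("no candidate structure could be fitted")
        chosen = min(aic_table, key=aic_table.get)
        struct, cov = specs[chosen]
        X = _design_matrix(self.data, struct, self.period_order, cov)
        res = _mixedlm_fit(y, X, groups, reml=True)
        return PeriodMixedResults(self, res, X, chosen, aic_table[chosen], aic_table)


class PeriodMixedResults:
    """REML estimates, uncertainties and diagnostics of a fitted period model."""

    def __init__(self, model, smresult, X, structure, aic, aic_table):
        self.model = model
        self._res = smresult
        self.X = X
        self.structure = structure
        self.aic = aic
        self.aic_table = aic_table
        k = X.shape[1]
        self.fe_params = pd.Series(np.asarray(smresult.fe_params), index=X.columns)
        cov = np.asarray(smresult.cov_params())[:k, :k]
        self.cov_fe = pd.DataFrame(cov, index=X.columns, columns=X.columns)
        self.bse_fe = pd.Series(np.sqrt(np.diag(cov)), index=X.columns)
        self.sigma2_tree = float(np.asarray(smresult.cov_re)[0, 0])
        self.sigma2_resid = float(smresult.scale)

    # -- diagnostics --------------------------------------------------------
    def pseudo_r2(self) -> tuple[float, float]:
        """Nakagawa-Schielzeth marginal and conditional pseudo-R2."""
        pred = self.X.to_numpy() @ self.fe_params.to_numpy()
        var_f = float(np.var(pred, ddof=1))
        denom = var_f + self.sigma2_tree + self.sigma2_resid
        return var_f / denom, (var_f + self.sigma2_tree) / denom

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = -float(np.asarray(_norm_ppf(alpha / 2.0)))
        lo = self.fe_params - z * self.bse_fe
        hi = self.fe_params + z * self.bse_fe
        return pd.DataFrame({"lower": lo, "upper": hi})

    # -- predictions and contrasts -----------------------------------------
    def coefficient_table(self) -> CoefficientTable:
        r2m, r2c = self.pseudo_r2()
        return CoefficientTable(
            response=self.model.response_name,
            terms=dict(self.fe_params),
            r2_marginal=r2m,
            r2_conditional=r2c,
            aic=self.aic,
            reference_period=self.model.period_order[0],
        )

    def _marginal_mean_row(self, period: str) -> np.ndarray:
        """Design row for a period's marginal mean, averaging over the
        observed catchments (equal weights) and covariates at their mean."""
        row = np.zeros(self.X.shape[1])
        cols = list(self.X.columns)
        row[cols.index("intercept")] = 1.0
        key = f"period[{period}]"
        if key in cols:
            row[cols.index(key)] = 1.0
        ckey = f"catchment[{OTHER_CATCHMENT}]"
        if ckey in cols:
            row[cols.index(ckey)] = 0.5
            ikey = f"period[{period}]:catchment[{OTHER_CATCHMENT}]"
            if ikey in cols:
                row[cols.index(ikey)] = 0.5
        if self.model.covariate in cols:
            row[cols.index(self.model.covariate)] = float(
                self.model.data[self.model.covariate].mean()
            )
        return row

    def marginal_means(self) -> pd.Series:
        return pd.Series(
            {p: float(self._marginal_mean_row(p) @ self.fe_params.to_numpy())
             for p in self.model.period_order}
        )

    def tukey(self, alpha: float = 0.05, n_mc: int = 200_000) -> pd.DataFrame:
        """All pairwise period comparisons of marginal means with single-step
        (max-|Z|) multiplicity adjustment and a compact letter display.

        The adjustment evaluates the joint null distribution of the contrast
        z-statistics by fixed-seed Monte Carlo, so output is deterministic.
        """
        labels = self.model.period_order
        pairs = list(itertools.combinations(labels, 2))
        L = np.array([
            self._marginal_mean_row(b) - self._marginal_mean_row(a) for a, b in pairs
        ])
        est = L @ self.fe_params.to_numpy()
        cov = L @ self.cov_fe.to_numpy() @ L.T
        se = np.sqrt(np.diag(cov))
        z = est / se
        corr = cov / np.outer(se, se)
        corr = (corr + corr.T) / 2 + 1e-10 * np.eye(len(pairs))
        rng = np.random.default_rng(0)
        draws = rng.multivariate_normal(np.zeros(len(pairs)), corr,
                                        size=n_mc, method="cholesky")
        maxabs = np.abs(draws).max(axis=1)
        p_adj = np.array([(maxabs >= abs(zk)).mean() for zk in z])
        table = pd.DataFrame(
            {"period_a": [a for a, _ in pairs], "period_b": [b for _, b in pairs],
             "estimate": est, "se": se, "z": z, "p_adj": p_adj}
        )
        letters = compact_letter_display(labels, pairs, p_adj < alpha,
                                         self.marginal_means())
        table.attrs["letters"] = letters
        return table

    def summary(self) -> str:
        r2m, r2c = self.pseudo_r2()
        lines = [
            f"Period mixed model: {self.model.response_name}",
            f"  fixed structure : {self.structure}",
            f"  groups (trees)  : {self.model.data['tree_id'].nunique()}",
            f"  observations    : {len(self.model.data)}",
            f"  AIC (ML)        : {self.aic:.1f}" if self.aic is not None else "  AIC (ML)        : n/a",
            f"  sigma2 tree     : {self.sigma2_tree:.4g}",
            f"  sigma2 residual : {self.sigma2_resid:.4g}",
            f"  pseudo-R2       : marginal {r2m:.2f}, conditional {r2c:.2f}",
            "",
            f"  {'term':<38s}{'estimate':>12s}{'std err':>10s}",
        ]
        for term in self.fe_params.index:
            lines.append(
                f"  {term:<38s}{self.fe_params[term]:>12.4f}{self.bse_fe[term]:>10.4f}"
            )
        return "\n".join(lines)


def _norm_ppf(q):
    from scipy.stats import norm

    return norm.ppf(q)


def compact_letter_display(labels, pairs, significant, means) -> dict[str, str]:
    """Insert-and-absorb letter assignment consistent with a significance
    pattern: groups not sharing a letter differ significantly."""
    sets = [set(labels)]
    for (a, b), sig in zip(pairs, significant):
        if not sig:
            continue
        new_sets = []
        for s in sets:
            if a in s and b in s:
                new_sets.extend([s - {a}, s - {b}])
            else:
                new_sets.append(s)
        # absorb subsets
        sets = []
        for s in sorted(new_sets, key=len, reverse=True):
            if s and not any(s <= t for t in sets):
                sets.append(s)
    order = sorted(sets, key=lambda s: min(means[m] for m in s))
    out: dict[str, list[str]] = {lbl: [] for lbl in labels}
    for letter, s in zip(string.ascii_lowercase, order):
        for lbl in s:
            out[lbl].append(letter)
    return {lbl: "".join(sorted(v)) for lbl, v in out.items()}


# thin op-style wrappers -----------------------------------------------------

def fit_period_model(
    data: pd.DataFrame,
    periods=DEFAULT_PERIODS,
    covariate: str | None = None,
    response_name: str = "value",
) -> PeriodMixedResults:
    """AIC-selected random-intercept period model (see PeriodMixedModel)."""
    return PeriodMixedModel(
        data, periods=periods, covariate=covariate, response_name=response_name
    ).fit()


def tukey_contrasts(results: PeriodMixedResults, alpha: float = 0.05) -> pd.DataFrame:
    return results.tukey(alpha=alpha)


def pseudo_r2(results: PeriodMixedResults) -> tuple[float, float]:
    return results.pseudo_r2()


def fit_increment_vs_discrimination(
    data: pd.DataFrame, periods=DEFAULT_PERIODS
) -> PeriodMixedResults:
    """Mixed model of biomass increment on Delta13C, period and their
    interaction (random tree intercept); slopes per period are
    delta13C (+ the period's interaction term)."""
    required = {"tree_id", "period", "increment", "delta13C"}
    if not required <= set(data.columns):
        raise ValueError(f"data needs columns {sorted(required)}")
    data = data.dropna(subset=["increment", "delta13C"]).copy()
    periods = validate_periods(periods)
    present = [p.label for p in periods if p.label in set(data["period"])]
    model = PeriodMixedModel(
        data.rename(columns={"increment": "value"}),
        periods=periods,
        response_name="increment_vs_delta13C",
        min_periods=1,
    )
    n = len(model.data)
    X = pd.DataFrame({"intercept": np.ones(n)}, index=model.data.index)
    for label in present[1:]:
        X[f"period[{label}]"] = (model.data["period"] == label).astype(float)
    X["delta13C"] = model.data["delta13C"].to_numpy(dtype=float)
    for label in present[1:]:
        X[f"period[{label}]:delta13C"] = X[f"period[{label}]"] * X["delta13C"]
    res = _mixedlm_fit(model.data["value"].to_numpy(dtype=float), X,
                       model.data["tree_id"].to_numpy(), reml=True)
    ml = _mixedlm_fit(model.data["value"].to_numpy(dtype=float), X,
                      model.data["tree_id"].to_numpy(), reml=False)
    model.covariate = "delta13C"
    return PeriodMixedResults(model, res, X, "period*delta13C",
                              _aic(ml, X.shape[1]), {})


def period_slopes(results: PeriodMixedResults) -> pd.Series:
    """Per-period Delta13C slopes from an increment-vs-discrimination fit."""
    base = results.fe_params["delta13C"]
    out = {}
    for p in results.model.period_order:
        key = f"period[{p}]:delta13C"
        out[p] = base + results.fe_params.get(key, 0.0)
    return pd.Series(out)
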