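"""Directional cross-lagged regression of baseline WMH on atrophy rates.

For every (predictor, response) biomarker pair the model is an OLS of the
response's annualised rate of change on the predictor's baseline value plus
age, sex, education, log NfL, and the baseline of the response itself::

    d(response)/dt ~ predictor_baseline + age + sex + education
                     + log10(NfL) + response_baseline

All biomarkers are z-scored with constants computed over the full dataset at
baseline (WMH and NfL log-transformed first), so rates are in baseline-sd
units per year. The per-subject rate is the OLS slope of the z-scored
biomarker against visit time over all available visits, which reduces to a
difference quotient for exactly two visits. Benjamini-Hochberg FDR is applied
over one family covering every tested pair in both directions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientDataError, RankDeficiencyError

log = logging.getLogger(__name__)

#: markers log-transformed before z-scoring
_LOG_MARKERS_PREFIX = ("wmh",)
_LOG_MARKERS = ("nfl", "gfap", "ventricles")


def needs_log(marker: str) -> bool:
    return marker.startswith(_LOG_MARKERS_PREFIX) or marker in _LOG_MARKERS


@dataclass(frozen=True)
class CrossLagResult:
    predictor: str
    response: str
    n: int
    coefficient: float
    t: float
    p_raw: float
    p_fdr: float | None = None
    significant: bool | None = None


def zscore_constants(cohort: pd.DataFrame,
                     markers: list[str]) -> dict[str, tuple[float, float]]:
    """Mean/sd of each marker's (log-transformed) baseline values."""
    base = cohort[cohort["visit_time"] == 0.0]
    out = {}
    for m in markers:
        v = base[m].to_numpy(float)
        v = np.log10(v) if needs_log(m) else v
        out[m] = (float(np.nanmean(v)), float(np.nanstd(v, ddof=0)))
    return out


def _zscored(values: np.ndarray, marker: str,
             constants: dict[str, tuple[float, float]]) -> np.ndarray:
    v = np.asarray(values, float)
    if needs_log(marker):
        v = np.log10(v)
    mu, sd = constants[marker]
    return (v - mu) / sd if sd > 0 else v - mu


def annualized_change(visits: pd.DataFrame, marker: str,
                      constants: dict[str, tuple[float, float]]) -> float:
    """Per-subject OLS slope of the z-scored marker against visit time.

    ``visits`` holds one subject's rows. Requires at least two visits with
    the marker observed; raises otherwise.
    """
    t = visits["visit_time"].to_numpy(float)
    z = _zscored(visits[marker].to_numpy(float), marker, constants)
    ok = np.isfinite(z) & np.isfinite(t)
    if ok.sum() < 2:
        raise InsufficientDataError(f"fewer than 2 observed visits for {marker}")
    t, z = t[ok], z[ok]
    slope = np.polyfit(t, z, 1)[0]
    return float(slope)


def subject_rates(cohort: pd.DataFrame, marker: str,
                  constants: dict[str, tuple[float, float]]) -> pd.Series:
    """Annualised rates for every subject with >= 2 observed visits."""
    rates = {}
    n_excluded = 0
    for sid, visits in cohort.groupby("subject_id"):
        if visits["visit_time"].nunique() < 2:
            continue
        try:
            rates[sid] = annualized_change(visits, marker, constants)
        except InsufficientDataError:
            n_excluded += 1
    if n_excluded:
        log.info("subject_rates(%s): %d multi-visit subjects lacked 2 observed "
                 "values", marker, n_excluded)
    return pd.Series(rates, name=f"rate_{marker}")


def fit_pair_model(cohort: pd.DataFrame, predictor: str, response: str,
                   constants: dict[str, tuple[float, float]] | None = None,
                   min_subjects: int = 10) -> CrossLagResult:
    """OLS of the response's rate on the predictor's baseline plus covariates.

    Covariates: age, sex (male contrast), education, log10 NfL (z-scored),
    and the z-scored baseline of the response. Complete-case analysis.
    """
    from .wmh import _male_indicator

    if predictor == response:
        raise ValueError("predictor and response must differ")
    markers = sorted({predictor, response, "nfl"})
    constants = constants or zscore_constants(cohort, markers)

    base = cohort[cohort["visit_time"] == 0.0].set_index("subject_id")
    rates = subject_rates(cohort, response, constants)
    base = base.loc[base.index.intersection(rates.index)]

    data = pd.DataFrame({
        "rate": rates.loc[base.index],
        "predictor": _zscored(base[predictor].to_numpy(float), predictor, constants),
        "age": base["age"].to_numpy(float),
        "male": _male_indicator(base["sex"]),
        "education": base["education"].to_numpy(float),
        "log_nfl": _zscored(base["nfl"].to_numpy(float), "nfl", constants),
        "response_baseline": _zscored(base[response].to_numpy(float), response,
                                      constants),
    }, index=base.index).dropna()
    if len(data) < min_subjects:
        raise InsufficientDataError(
            f"{predictor} -> {response}: {len(data)} complete subjects "
            f"(need >= {min_subjects})")

    X = sm.add_constant(data.drop(columns="rate"))
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        collinear = [c for c in X.columns[1:]
                     if np.ptp(X[c].to_numpy()) == 0]
        raise RankDeficiencyError(collinear or list(X.columns[1:]))
    fit = sm.OLS(data["rate"], X).fit()
    return CrossLagResult(
        predictor=predictor,
        response=response,
        n=len(data),
        coefficient=float(fit.params["predictor"]),
        t=float(fit.tvalues["predictor"]),
        p_raw=float(fit.pvalues["predictor"]),
    )


def fdr_correct(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvals, float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def association_matrix(cohort: pd.DataFrame,
                       predictors: list[str] | None = None,
                       responses: list[str] | None = None,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Fit every (predictor, response) pair in both directions with one
    BH family over all tests.

    Returns a tidy frame with one row per directed pair: direction
    ("forward" = WMH predicts subcortical change, "reverse" = subcortical
    predicts WMH change), coefficient, t, raw and FDR-adjusted p, and the
    significance flag at ``alpha``.
    """
    from .cohort import SUBCORTICAL, WMH_PREDICTORS

    predictors = list(predictors or WMH_PREDICTORS)
    responses = list(responses or SUBCORTICAL)
    markers = sorted(set(predictors) | set(responses) | {"nfl"})
    constants = zscore_constants(cohort, markers)

    results = []
    for p_name in predictors:
        for r_name in responses:
            fwd = fit_pair_model(cohort, p_name, r_name, constants)
            rev = fit_pair_model(cohort, r_name, p_name, constants)
            results.append(("forward", fwd))
            results.append(("reverse", rev))

    raw = [r.p_raw for _, r in results]
    adj = fdr_correct(raw)
    records = []
    for (direction, r), p_fdr in zip(results, adj):
        records.append({
            "direction": direction,
            "predictor": r.predictor,
            "response": r.response,
            "n": r.n,
            "coefficient": r.coefficient,
            "t": r.t,
            "p_raw": r.p_raw,
            "p_fdr": float(p_fdr),
            "significant": bool(p_fdr < alpha),
        })
    return pd.DataFrame(records)


def t_statistic_matrix(results: pd.DataFrame) -> pd.DataFrame:
    """Square predictor x response matrix of t statistics (chord-ready)."""
    names = sorted(set(results["predictor"]) | set(results["response"]))
    mat = pd.DataFrame(np.nan, index=names, columns=names)
    for _, row in results.iterrows():
        mat.loc[row["predictor"], row["response"]] = row["t"]
    return mat
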