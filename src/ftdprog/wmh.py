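"""Normative WMH adjustment and nonparametric group comparison.

The normative model regresses log10 WMH volume (mm^3) on age and sex in the
healthy-control cohort only; every participant's *adjusted* WMH value is then
the difference between their observed log10 volume and the model prediction,
i.e. a demographically residualised lesion load. Group structure is tested
nonparametrically: Kruskal-Wallis across groups, Dunn's z for pairwise
contrasts with Bonferroni correction over the declared family, and Cliff's
delta as the effect size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, RankDeficiencyError

log = logging.getLogger(__name__)

#: Region label -> cohort column holding the raw WMH volume (mm^3).
REGION_COLUMNS: dict[str, str] = {
    "total": "wmh_total",
    "left_frontal": "wmh_lfrontal",
    "right_frontal": "wmh_rfrontal",
    "left_temporal": "wmh_ltemporal",
    "right_temporal": "wmh_rtemporal",
    "left_parietal": "wmh_lparietal",
    "right_parietal": "wmh_rparietal",
    "left_occipital": "wmh_loccipital",
    "right_occipital": "wmh_roccipital",
}


@dataclass(frozen=True)
class NormativeModel:
    """OLS fit of log10 WMH ~ age + sex on controls.

    ``sex_coefficient`` is the male-vs-female contrast; it is 0 when only one
    sex is present in the controls (the term is dropped).
    """

    intercept: float
    age_coefficient: float
    sex_coefficient: float
    residual_sd: float
    n_controls: int

    def predict(self, age: np.ndarray, male: np.ndarray) -> np.ndarray:
        return (self.intercept + self.age_coefficient * np.asarray(age, float)
                + self.sex_coefficient * np.asarray(male, float))


def _male_indicator(sex: pd.Series) -> np.ndarray:
    """Binary male contrast; anything other than male/female is NaN."""
    s = sex.astype(str).str.lower()
    out = np.where(s == "male", 1.0, np.where(s == "female", 0.0, np.nan))
    return out


def fit_normative_model(controls: pd.DataFrame,
                        value_column: str = "log10_wmh") -> NormativeModel:
    """Fit log10 WMH ~ age + sex by ordinary least squares on control records.

    Parameters
    ----------
    controls : DataFrame with columns ``value_column``, ``age``, ``sex``.
        Records with missing age, sex, or value are dropped.
    """
    male = _male_indicator(controls["sex"])
    y = controls[value_column].to_numpy(float)
    age = controls["age"].to_numpy(float)
    keep = np.isfinite(y) & np.isfinite(age) & np.isfinite(male)
    y, age, male = y[keep], age[keep], male[keep]
    if y.size < 3:
        raise InsufficientDataError(
            f"normative fit needs >= 3 complete control records, got {y.size}")

    age_constant = np.ptp(age) == 0
    single_sex = np.ptp(male) == 0
    if age_constant and single_sex:
        raise RankDeficiencyError(["age", "sex"])
    if age_constant:
        raise RankDeficiencyError(["age"])

    columns = [np.ones_like(y), age]
    if not single_sex:
        columns.append(male)
    X = np.column_stack(columns)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sex_coef = float(beta[2]) if not single_sex else 0.0
    if single_sex:
        log.info("normative fit: single sex in controls; sex term dropped")
    return NormativeModel(
        intercept=float(beta[0]),
        age_coefficient=float(beta[1]),
        sex_coefficient=sex_coef,
        residual_sd=float(np.std(resid, ddof=min(len(beta), y.size - 1))),
        n_controls=int(y.size),
    )


def fit_region_model(cohort: pd.DataFrame, region: str) -> NormativeModel:
    """Fit the normative model for one region from a raw cohort table."""
    col = _region_column(region)
    controls = cohort[cohort["status"] == "control"].copy()
    _check_positive(controls, col)
    controls["log10_wmh"] = np.log10(controls[col].to_numpy(float))
    return fit_normative_model(controls, "log10_wmh")


def _region_column(region: str) -> str:
    try:
        return REGION_COLUMNS[region]
    except KeyError:
        raise KeyError(
            f"unknown region {region!r}; expected one of {sorted(REGION_COLUMNS)}")


def _check_positive(df: pd.DataFrame, col: str) -> None:
    bad = df.index[df[col].to_numpy(float) <= 0]
    if len(bad):
        first = df.loc[bad[0]]
        raise ValueError(
            f"non-positive WMH volume in column {col} "
            f"(subject {first.get('subject_id', bad[0])})")


def adjust_wmh(cohort: pd.DataFrame, model: NormativeModel,
               region: str = "total") -> tuple[pd.DataFrame, int]:
    """Adjusted WMH = observed log10 volume minus the normative prediction.

    Records missing age or sex are excluded; the exclusion count is returned
    alongside the adjusted table (columns ``subject_id``, ``region``,
    ``adjusted``) so callers can log it.
    """
    col = _region_column(region)
    male = _male_indicator(cohort["sex"])
    age = cohort["age"].to_numpy(float)
    vol = cohort[col].to_numpy(float)
    observed = np.isfinite(vol)
    _check_positive(cohort[observed], col)
    eligible = observed & np.isfinite(age) & np.isfinite(male)
    n_excluded = int(observed.sum() - eligible.sum())
    if n_excluded:
        log.info("adjust_wmh(%s): excluded %d records with missing demographics",
                 region, n_excluded)
    sub = cohort[eligible]
    adjusted = np.log10(vol[eligible]) - model.predict(age[eligible], male[eligible])
    out = pd.DataFrame({
        "subject_id": sub["subject_id"].to_numpy(),
        "region": region,
        "adjusted": adjusted,
    })
    return out, n_excluded


def kruskal_wallis(*groups: np.ndarray) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, float) for g in groups]
    for g in arrays:
        if g.size == 0:
            raise ValueError("empty group")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:  # all values tied: H defined as 0
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def dunn_posthoc(groups: dict[str, np.ndarray],
                 family_size: int | None = None) -> pd.DataFrame:
    """Dunn's pairwise z tests on pooled ranks with tie correction.

    For groups i, j with mean ranks r_i, r_j over the pooled sample of size N,

        z = (r_i - r_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))

    where T = sum(t^3 - t) over tie groups. Raw p-values are two-sided
    normal; Bonferroni p = min(1, p * family_size), the family defaulting to
    the number of pairs tested here.
    """
    names = list(groups)
    arrays = [np.asarray(groups[k], float) for k in names]
    for k, g in zip(names, arrays):
        if g.size == 0:
            raise ValueError(f"empty group {k!r}")
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes, start = {}, {}, 0
    for k, g in zip(names, arrays):
        mean_ranks[k] = ranks[start:start + g.size].mean()
        sizes[k] = g.size
        start += g.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts ** 3 - counts))
    base_var = n_total * (n_total + 1) / 12.0
    tie_term = tie_sum / (12.0 * (n_total - 1)) if n_total > 1 else 0.0

    pairs = list(combinations(names, 2))
    m = family_size if family_size is not None else len(pairs)
    records = []
    for a, b in pairs:
        var = (base_var - tie_term) * (1.0 / sizes[a] + 1.0 / sizes[b])
        if var <= 0:  # all observations tied
            z = 0.0
        else:
            z = (mean_ranks[a] - mean_ranks[b]) / np.sqrt(var)
        p_raw = 2.0 * stats.norm.sf(abs(z))
        records.append({
            "group_a": a, "group_b": b,
            "n_a": sizes[a], "n_b": sizes[b],
            "z": float(z),
            "p_raw": float(p_raw),
            "p_bonferroni": float(min(1.0, p_raw * m)),
        })
    return pd.DataFrame(records)


def cliffs_delta(a: np.ndarray, b: np.ndarray) -> float:
    """Cliff's delta: P(a > b) - P(a < b) over all cross-group pairs."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    diff = a[:, None] - b[None, :]
    return float((np.sign(diff)).mean())


def bonferroni(p: float, family_size: int) -> float:
    return min(1.0, p * family_size)


def regional_analysis(cohort: pd.DataFrame,
                      grouping: pd.Series,
                      regions: list[str] | None = None) -> pd.DataFrame:
    """Adjusted-WMH group comparison for the total volume and each lobe.

    For each region, a normative model is fitted on controls, every subject's
    adjusted value computed, then Kruskal-Wallis plus all pairwise Dunn
    contrasts with Cliff's delta. The Bonferroni family is every pairwise
    contrast across all regions in this table; its size is logged and stored
    in the ``family_size`` column.

    Parameters
    ----------
    cohort : baseline cohort table (raw volumes).
    grouping : Series aligned with ``cohort`` giving each subject's group
        label (e.g. "genotype:status").
    """
    regions = regions or list(REGION_COLUMNS)
    for r in regions:
        _region_column(r)

    labels = sorted(grouping.dropna().unique())
    n_pairs = len(list(combinations(labels, 2)))
    family = n_pairs * len(regions)
    log.info("regional_analysis: Bonferroni family = %d pairs x %d regions = %d",
             n_pairs, len(regions), family)

    records = []
    for region in regions:
        model = fit_region_model(cohort, region)
        adjusted, _ = adjust_wmh(cohort, model, region)
        merged = adjusted.merge(
            pd.DataFrame({"subject_id": cohort["subject_id"], "group": grouping}),
            on="subject_id")
        groups = {k: g["adjusted"].to_numpy() for k, g in merged.groupby("group")}
        h, p_kw = kruskal_wallis(*groups.values())
        dunn = dunn_posthoc(groups, family_size=family)
        for _, row in dunn.iterrows():
            delta = cliffs_delta(groups[row["group_a"]], groups[row["group_b"]])
            records.append({
                "region": region,
                "kw_H": h,
                "kw_p": p_kw,
                "group_a": row["group_a"],
                "group_b": row["group_b"],
                "n_a": row["n_a"],
                "n_b": row["n_b"],
                "z": row["z"],
                "p_raw": row["p_raw"],
                "p_bonferroni": row["p_bonferroni"],
                "delta": delta,
                "family_size": family,
            })
    return pd.DataFrame(records)
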