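"""Discriminative event-based modelling of biomarker abnormality order.

An *event* is the transition of one biomarker from its normal to its abnormal
distribution. From purely cross-sectional data the model

1. residualises each (optionally log-transformed) biomarker against age and
   sex using a control-fitted linear model;
2. screens biomarkers for a significant symptomatic-vs-control difference
   (two-sided Mann-Whitney U);
3. fits a constrained two-component Gaussian mixture per biomarker (normal
   and abnormal states, mixing fraction estimated per diagnosis label) and
   admits the biomarker only if the mixture reproduces the empirical density
   (mean squared error criterion);
4. converts each observed value into a posterior probability of abnormality
   (equal component priors, so the posterior is a pure likelihood ratio);
5. aggregates subject-wise orderings into a central event ordering that
   minimises the summed probability-weighted Kendall distance;
6. quantifies ordering uncertainty with stratified bootstrap resampling
   (positional-variance counts) and assigns each subject a discrete and a
   continuous disease stage along the central ordering.

Missing values are handled throughout by computing every pairwise quantity
over observed entries only; no imputation is performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .errors import ConvergenceError, InsufficientDataError

log = logging.getLogger(__name__)

_POSTERIOR_CLIP = 1e-6


@dataclass
class BiomarkerTable:
    """Subjects-by-biomarkers matrix with labels and per-marker metadata.

    ``values`` holds analysis-scale values (log10 applied where the manifest
    says so), NaN marking missing entries. Biomarker columns are kept in
    canonical (alphabetical) order, which is also the tie-break order used
    everywhere downstream.
    """

    values: pd.DataFrame            # index: subject_id, columns: biomarkers
    labels: pd.Series               # diagnosis label per subject
    directions: dict[str, str]      # biomarker -> 'increase' | 'decrease'
    transforms: dict[str, str]      # biomarker -> 'log' | 'identity'

    def __post_init__(self) -> None:
        order = sorted(self.values.columns)
        self.values = self.values[order]
        for name in order:
            if name not in self.directions:
                raise ValueError(f"no abnormality direction declared for {name!r}")

    @property
    def biomarkers(self) -> list[str]:
        return list(self.values.columns)

    @classmethod
    def from_cohort(cls, cohort: pd.DataFrame,
                    manifest: pd.DataFrame) -> "BiomarkerTable":
        """Build from a cohort table and a manifest (name, direction, transform).

        Only baseline rows (``visit_time == 0``) enter; log-flagged markers
        must be strictly positive before transformation.
        """
        base = cohort[cohort["visit_time"] == 0.0]
        values = {}
        for _, row in manifest.iterrows():
            name = row["name"]
            v = base[name].to_numpy(float)
            if row["transform"] == "log":
                if np.any(v[np.isfinite(v)] <= 0):
                    raise ValueError(f"log-flagged biomarker {name!r} has "
                                     "non-positive values")
                v = np.where(np.isfinite(v), np.log10(np.where(v > 0, v, np.nan)), np.nan)
            values[name] = v
        frame = pd.DataFrame(values, index=base["subject_id"].to_numpy())
        labels = pd.Series(base["status"].to_numpy(), index=frame.index)
        return cls(
            values=frame,
            labels=labels,
            directions=dict(zip(manifest["name"], manifest["direction"])),
            transforms=dict(zip(manifest["name"], manifest["transform"])),
        )


def default_manifest() -> pd.DataFrame:
    """Manifest of the nine event-model biomarkers."""
    from .cohort import DEBM_ORDERING, DEFAULT_BIOMARKERS
    rows = [{"name": b.name, "direction": b.direction, "transform": b.transform}
            for b in DEFAULT_BIOMARKERS if b.name in DEBM_ORDERING]
    return pd.DataFrame(rows)


def confound_adjust(table: BiomarkerTable,
                    demographics: pd.DataFrame) -> BiomarkerTable:
    """Residualise each biomarker against age and sex using control-fitted OLS.

    ``demographics`` must carry ``subject_id``, ``age``, ``sex``. The
    missingness mask of ``table.values`` is preserved exactly.
    """
    from .wmh import _male_indicator

    demo = demographics.drop_duplicates("subject_id").set_index("subject_id")
    demo = demo.loc[table.values.index]
    age = demo["age"].to_numpy(float)
    male = _male_indicator(demo["sex"])
    is_control = (table.labels == "control").to_numpy()

    covars = np.column_stack([np.ones(len(age)), age, male])
    adjusted = table.values.copy()
    for name in table.biomarkers:
        y = table.values[name].to_numpy(float)
        fit_mask = is_control & np.isfinite(y) & np.isfinite(age) & np.isfinite(male)
        if fit_mask.sum() < 3:
            raise InsufficientDataError(
                f"confound adjustment for {name!r}: fewer than 3 complete controls")
        X = covars[fit_mask]
        keep_cols = [0] + [j for j in (1, 2) if np.ptp(X[:, j]) > 0]
        beta, _, _, _ = np.linalg.lstsq(X[:, keep_cols], y[fit_mask], rcond=None)
        pred = covars[:, keep_cols] @ beta
        adjusted[name] = y - pred  # NaN stays NaN
    return replace(table, values=adjusted)


def biomarker_screen(table: BiomarkerTable, alpha: float = 0.05) -> pd.DataFrame:
    """Mann-Whitney U screen of symptomatic carriers versus controls.

    Returns one row per biomarker with the U statistic, two-sided p, and a
    ``significant`` flag at ``alpha``. A biomarker with no observations in
    either group is flagged not significant with a warning.
    """
    sym = (table.labels == "symptomatic").to_numpy()
    ctl = (table.labels == "control").to_numpy()
    records = []
    for name in table.biomarkers:
        v = table.values[name].to_numpy(float)
        a = v[sym & np.isfinite(v)]
        b = v[ctl & np.isfinite(v)]
        if a.size == 0 or b.size == 0:
            log.warning("screen: biomarker %s entirely missing in one group", name)
            records.append({"biomarker": name, "statistic": np.nan,
                            "p": np.nan, "significant": False})
            continue
        if np.ptp(np.concatenate([a, b])) == 0:
            records.append({"biomarker": name, "statistic": a.size * b.size / 2.0,
                            "p": 1.0, "significant": False})
            continue
        u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        records.append({"biomarker": name, "statistic": float(u), "p": float(p),
                        "significant": bool(p < alpha)})
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# Constrained two-component mixture
# ---------------------------------------------------------------------------

@dataclass
class GmmFit:
    """Normal/abnormal mixture fit for one biomarker.

    Means and sds are on the (adjusted) analysis scale. ``mixing_fractions``
    maps each diagnosis label to its estimated abnormal fraction; the control
    fraction is bounded above by ``control_bound`` during fitting to prevent
    label switching. ``mse`` is measured between the fitted mixture density
    and a 50-bin empirical density of the pooled standardised values.
    """

    biomarker: str
    direction: str
    normal_mean: float
    normal_sd: float
    abnormal_mean: float
    abnormal_sd: float
    mixing_fractions: dict[str, float]
    mse: float
    converged: bool
    direction_ok: bool
    significant: bool = True
    mse_threshold: float = 0.01
    n_iter: int = 0

    @property
    def admitted(self) -> bool:
        return (self.significant and self.converged and self.direction_ok
                and self.mse <= self.mse_threshold)

    def posterior(self, x: np.ndarray) -> np.ndarray:
        """Equal-prior posterior probability of the abnormal component."""
        x = np.asarray(x, float)
        la = stats.norm.logpdf(x, self.abnormal_mean, self.abnormal_sd)
        ln = stats.norm.logpdf(x, self.normal_mean, self.normal_sd)
        with np.errstate(over="ignore"):
            p = 1.0 / (1.0 + np.exp(ln - la))
        return np.where(np.isfinite(x), p, np.nan)


def fit_gmm(values: np.ndarray, labels: np.ndarray, direction: str,
            biomarker: str = "", mse_threshold: float = 0.01,
            control_bound: float = 0.10, sd_floor_factor: float = 0.05,
            max_iter: int = 500, tol: float = 1e-4,
            significant: bool = True) -> GmmFit:
    """Constrained EM for the normal/abnormal mixture of one biomarker.

    The normal component is initialised at the control mean/sd and the
    abnormal component from the direction-side tail of the symptomatic
    values. Component sds are floored at ``sd_floor_factor`` times the pooled
    sd; each diagnosis label gets its own abnormal mixing fraction, the
    control fraction clipped to ``control_bound``. If the fitted means are
    not separated in the declared direction the fit is kept but marked not
    admitted.

    Raises
    ------
    ConvergenceError
        if EM does not converge within ``max_iter`` iterations (the error
        carries the last parameter state).
    """
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    obs = np.isfinite(values)
    x_all, lab = values[obs], labels[obs]
    is_ctl = lab == "control"
    n_ctl = int(is_ctl.sum())
    n_car = int((~is_ctl).sum())
    if n_ctl < 10 or n_car < 10:
        raise InsufficientDataError(
            f"GMM for {biomarker or 'biomarker'} needs >= 10 control and >= 10 "
            f"carrier values (got {n_ctl}/{n_car})")

    # work on a flipped axis so 'abnormal' is always the upper component
    sign = 1.0 if direction == "increase" else -1.0
    x = sign * x_all

    pooled_sd = float(np.std(x, ddof=1))
    if pooled_sd == 0:  # degenerate: all values identical
        fit = GmmFit(biomarker, direction, float(x_all[0]), 0.0, float(x_all[0]), 0.0,
                     {str(g): 0.0 for g in np.unique(lab)}, mse=np.inf,
                     converged=False, direction_ok=False, significant=significant,
                     mse_threshold=mse_threshold)
        return fit
    sd_floor = sd_floor_factor * pooled_sd

    m_n = float(np.mean(x[is_ctl]))
    s_n = max(float(np.std(x[is_ctl], ddof=1)), sd_floor)
    # initialise the abnormal component from the clearly-abnormal tail
    # (beyond one control sd) so EM starts in the separated mode rather than
    # absorbing normal-state values of symptomatic carriers
    sym_tail = x[(lab == "symptomatic") & (x > m_n + s_n)]
    if sym_tail.size >= 5:
        m_a = float(np.mean(sym_tail))
        s_a = max(float(np.std(sym_tail, ddof=1)), sd_floor)
    else:
        m_a, s_a = m_n + 2.0 * s_n, s_n

    groups = np.unique(lab)
    pi = {g: (0.05 if g == "control" else 0.5) for g in groups}
    params = np.array([m_n, s_n, m_a, s_a])
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        pi_vec = np.array([pi[g] for g in lab])
        log_a = stats.norm.logpdf(x, m_a, s_a) + np.log(np.maximum(pi_vec, 1e-12))
        log_n = stats.norm.logpdf(x, m_n, s_n) + np.log(np.maximum(1 - pi_vec, 1e-12))
        top = np.maximum(log_a, log_n)
        resp = np.exp(log_a - top) / (np.exp(log_a - top) + np.exp(log_n - top))

        w_a, w_n = resp, 1.0 - resp
        if w_a.sum() < 1e-8 or w_n.sum() < 1e-8:
            break
        m_a = float(np.sum(w_a * x) / w_a.sum())
        s_a = max(float(np.sqrt(np.sum(w_a * (x - m_a) ** 2) / w_a.sum())), sd_floor)
        m_n = float(np.sum(w_n * x) / w_n.sum())
        s_n = max(float(np.sqrt(np.sum(w_n * (x - m_n) ** 2) / w_n.sum())), sd_floor)
        for g in groups:
            frac = float(resp[lab == g].mean())
            pi[g] = min(frac, control_bound) if g == "control" else frac

        new_params = np.array([m_n, s_n, m_a, s_a])
        if np.max(np.abs(new_params - params)) < tol:
            converged = True
            params = new_params
            break
        params = new_params

    direction_ok = m_a > m_n
    mse = _density_mse(x, m_n, s_n, m_a, s_a,
                       float(np.mean([pi[g] for g in lab])))

    # map back to the original axis
    normal_mean, abnormal_mean = sign * m_n, sign * m_a
    fit = GmmFit(biomarker, direction, normal_mean, s_n, abnormal_mean, s_a,
                 {str(g): float(pi[g]) for g in groups}, mse=mse,
                 converged=converged, direction_ok=direction_ok,
                 significant=significant, mse_threshold=mse_threshold,
                 n_iter=n_iter)
    if not converged:
        raise ConvergenceError(
            f"GMM for {biomarker or 'biomarker'} did not converge in "
            f"{max_iter} iterations", last_params=fit)
    return fit


def _density_mse(x: np.ndarray, m_n: float, s_n: float, m_a: float, s_a: float,
                 frac_abnormal: float, bins: int = 50) -> float:
    """MSE between the fitted mixture pdf and a binned empirical density.

    Computed on standardised values so the criterion is scale free. The
    sampling noise floor of a 50-bin histogram at n ~ 500 is about 2e-3, so
    admission thresholds should sit above that.
    """
    mu, sd = float(np.mean(x)), float(np.std(x, ddof=1))
    z = (x - mu) / sd
    hist, edges = np.histogram(z, bins=bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    pdf = (frac_abnormal * stats.norm.pdf(centers, (m_a - mu) / sd, s_a / sd)
           + (1 - frac_abnormal) * stats.norm.pdf(centers, (m_n - mu) / sd, s_n / sd))
    return float(np.mean((hist - pdf) ** 2))


def fit_all_gmms(table: BiomarkerTable, screen: pd.DataFrame | None = None,
                 **kwargs) -> dict[str, GmmFit]:
    """Fit the mixture for every biomarker, carrying over screen flags."""
    if screen is None:
        screen = biomarker_screen(table)
    sig = dict(zip(screen["biomarker"], screen["significant"]))
    fits = {}
    for name in table.biomarkers:
        fits[name] = fit_gmm(
            table.values[name].to_numpy(float),
            table.labels.to_numpy(),
            table.directions[name],
            biomarker=name,
            significant=bool(sig.get(name, True)),
            **kwargs,
        )
    return fits


def event_probabilities(table: BiomarkerTable,
                        fits: dict[str, GmmFit]) -> pd.DataFrame:
    """Posterior abnormality probability per subject and admitted biomarker.

    Entries for missing measurements are NaN. Uses equal component priors so
    P is independent of cohort composition.
    """
    admitted = [n for n in table.biomarkers if n in fits and fits[n].admitted]
    out = {}
    for name in admitted:
        out[name] = fits[name].posterior(table.values[name].to_numpy(float))
    return pd.DataFrame(out, index=table.values.index)


# ---------------------------------------------------------------------------
# Central ordering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EventOrdering:
    sequence: tuple[str, ...]
    cost: float

    def position(self, name: str) -> int:
        return self.sequence.index(name)


def subject_ordering(p_row: pd.Series) -> list[str]:
    """One subject's biomarker ranking by descending abnormality posterior.

    Ties are broken by canonical (alphabetical) biomarker-name order. Raises
    if fewer than two biomarkers are observed.
    """
    observed = p_row.dropna()
    if observed.size < 2:
        raise InsufficientDataError("fewer than 2 observed biomarkers")
    names = np.array(sorted(observed.index))
    values = observed[names].to_numpy(float)
    order = np.lexsort((names, -values))
    return [str(n) for n in names[order]]


def _pairwise_weights(P: pd.DataFrame) -> np.ndarray:
    """W[k, l] = sum_i max(0, P_il - P_ik): cost of placing k before l."""
    values = P.to_numpy(float)
    diff = values[:, None, :] - values[:, :, None]  # diff[i, k, l] = P_il - P_ik
    return np.nansum(np.maximum(diff, 0.0), axis=0)


def ordering_cost(ordering: EventOrdering | tuple[str, ...],
                  P: pd.DataFrame) -> float:
    """Probability-weighted Kendall cost of a central ordering.

    Sum over subjects and observed biomarker pairs discordant between the
    central ordering and the subject's posterior ranking, each weighted by
    the absolute posterior difference |P_ik - P_il|.
    """
    seq = ordering.sequence if isinstance(ordering, EventOrdering) else tuple(ordering)
    W = _pairwise_weights(P[list(seq)])
    return float(np.triu(W, k=1).sum())


def _cost_from_weights(perm: np.ndarray, W: np.ndarray) -> float:
    sub = W[np.ix_(perm, perm)]
    return float(np.triu(sub, k=1).sum())


def estimate_ordering(P: pd.DataFrame, seed: int = 0,
                      exhaustive_limit: int = 7,
                      n_restarts: int = 10) -> EventOrdering:
    """Central ordering minimising the summed weighted Kendall distance.

    Exhaustive search over all K! permutations for K <= ``exhaustive_limit``;
    otherwise greedy best-improvement pairwise swaps initialised from the
    descending column means of P, with ``n_restarts`` seeded random restarts.
    Cost ties are broken by the lexicographically smallest sequence in
    canonical name order.
    """
    names = sorted(P.columns)
    P = P[names]
    eligible = P.notna().sum(axis=1) >= 2
    n_excluded = int((~eligible).sum())
    if n_excluded:
        log.info("estimate_ordering: excluded %d subjects with < 2 observed "
                 "biomarkers", n_excluded)
    P = P[eligible]
    if len(P) == 0:
        raise InsufficientDataError("no subjects with >= 2 observed biomarkers")
    K = len(names)
    if K < 2:
        raise InsufficientDataError("need at least 2 admitted biomarkers")

    W = _pairwise_weights(P)

    if K <= exhaustive_limit:
        best_perm, best_cost = None, np.inf
        for perm in permutations(range(K)):
            c = _cost_from_weights(np.array(perm), W)
            if c < best_cost - 1e-12 or (abs(c - best_cost) <= 1e-12
                                         and (best_perm is None or perm < best_perm)):
                best_perm, best_cost = perm, c
        seq = tuple(names[j] for j in best_perm)
        return EventOrdering(seq, best_cost)

    rng = np.random.default_rng(seed)
    col_means = np.nanmean(P.to_numpy(float), axis=0)
    init = np.lexsort((np.arange(K), -col_means))
    candidates = [init] + [rng.permutation(K) for _ in range(n_restarts)]

    best_perm, best_cost = None, np.inf
    for start in candidates:
        perm = np.array(start)
        cost = _cost_from_weights(perm, W)
        improved = True
        while improved:
            improved = False
            best_swap, best_delta = None, -1e-12
            for a in range(K):
                for b in range(a + 1, K):
                    trial = perm.copy()
                    trial[a], trial[b] = trial[b], trial[a]
                    delta = cost - _cost_from_weights(trial, W)
                    if delta > best_delta + 1e-12:
                        best_swap, best_delta = (a, b), delta
            if best_swap is not None and best_delta > 1e-12:
                a, b = best_swap
                perm[a], perm[b] = perm[b], perm[a]
                cost -= best_delta
                improved = True
        key = tuple(int(j) for j in perm)
        if cost < best_cost - 1e-12 or (abs(cost - best_cost) <= 1e-12
                                        and (best_perm is None or key < best_perm)):
            best_perm, best_cost = key, cost
    seq = tuple(names[j] for j in best_perm)
    return EventOrdering(seq, best_cost)


# ---------------------------------------------------------------------------
# Bootstrap positional variance
# ---------------------------------------------------------------------------

@dataclass
class PositionalVariance:
    """Bootstrap position counts: counts[k, j] = replicates placing biomarker
    k (row, in ``biomarkers`` order) at position j."""

    biomarkers: tuple[str, ...]
    counts: np.ndarray
    n_replicates: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.biomarkers),
                            columns=[f"pos_{j + 1}" for j in range(len(self.biomarkers))])


def bootstrap_ordering(table: BiomarkerTable, fits: dict[str, GmmFit],
                       refit: bool = True, n_replicates: int = 100,
                       seed: int = 0, max_retries: int = 10,
                       row_order: tuple[str, ...] | None = None,
                       **gmm_kwargs) -> PositionalVariance:
    """Positional-variance counts over stratified bootstrap replicates.

    Subjects are resampled with replacement within each diagnosis label so
    every replicate preserves the three-diagnosis design. By default the
    mixtures are refit on each replicate (the admitted biomarker set stays
    fixed); a replicate whose refit fails is redrawn, up to ``max_retries``
    times, then the run errors out.
    """
    admitted = tuple(n for n in table.biomarkers if n in fits and fits[n].admitted)
    rows = row_order or admitted
    K = len(admitted)
    counts = np.zeros((K, K), dtype=int)
    rng = np.random.default_rng(seed)
    labels = table.labels
    strata = {g: np.flatnonzero((labels == g).to_numpy()) for g in labels.unique()}

    for _ in range(n_replicates):
        for attempt in range(max_retries + 1):
            idx = np.concatenate([rng.choice(s, size=s.size, replace=True)
                                  for s in strata.values()])
            sub_values = table.values.iloc[idx].reset_index(drop=True)
            sub_values.index = [f"b{i}" for i in range(len(idx))]
            sub = BiomarkerTable(values=sub_values[list(admitted)],
                                 labels=pd.Series(labels.iloc[idx].to_numpy(),
                                                  index=sub_values.index),
                                 directions=table.directions,
                                 transforms=table.transforms)
            try:
                if refit:
                    rep_fits = {}
                    for name in admitted:
                        f = fit_gmm(sub.values[name].to_numpy(float),
                                    sub.labels.to_numpy(),
                                    table.directions[name], biomarker=name,
                                    **gmm_kwargs)
                        if not (f.converged and f.direction_ok):
                            raise ConvergenceError(f"bootstrap refit failed for {name}")
                        rep_fits[name] = f
                else:
                    rep_fits = {n: fits[n] for n in admitted}
                P = pd.DataFrame(
                    {n: rep_fits[n].posterior(sub.values[n].to_numpy(float))
                     for n in admitted}, index=sub.values.index)
                ordering = estimate_ordering(
                    P, seed=int(rng.integers(0, 2 ** 31 - 1)))
                break
            except (ConvergenceError, InsufficientDataError) as exc:
                if attempt == max_retries:
                    raise ConvergenceError(
                        f"bootstrap replicate failed {max_retries + 1} times") from exc
                log.info("bootstrap replicate redrawn after failure: %s", exc)
        for j, name in enumerate(ordering.sequence):
            counts[rows.index(name), j] += 1
    return PositionalVariance(rows, counts, n_replicates)


# ---------------------------------------------------------------------------
# Staging and validation
# ---------------------------------------------------------------------------

def stage_subjects(P: pd.DataFrame, ordering: EventOrdering) -> pd.DataFrame:
    """Discrete and continuous stage per subject along the central ordering.

    The discrete stage k in {0..K} maximises the event-position likelihood

        sum_{j <= k} log P_sigma(j) + sum_{j > k} log(1 - P_sigma(j))

    over observed biomarkers (posteriors clipped away from 0/1); ties go to
    the smallest k. The continuous stage is the mean observed posterior.
    Subjects with no observed biomarker are excluded (logged).
    """
    seq = list(ordering.sequence)
    values = P[seq].to_numpy(float)
    observed = np.isfinite(values)
    n_dropped = int((observed.sum(axis=1) == 0).sum())
    if n_dropped:
        log.info("stage_subjects: %d subjects with no observed biomarkers excluded",
                 n_dropped)
    clipped = np.clip(values, _POSTERIOR_CLIP, 1.0 - _POSTERIOR_CLIP)
    log_p = np.where(observed, np.log(clipped), 0.0)
    log_q = np.where(observed, np.log1p(-clipped), 0.0)
    K = len(seq)
    # score at stage k = sum of log_p over first k positions + log_q over rest
    cum_p = np.concatenate([np.zeros((len(values), 1)), np.cumsum(log_p, axis=1)], axis=1)
    total_q = log_q.sum(axis=1, keepdims=True)
    cum_q = np.concatenate([np.zeros((len(values), 1)), np.cumsum(log_q, axis=1)], axis=1)
    scores = cum_p + (total_q - cum_q)  # shape (n, K+1)
    discrete = scores.argmax(axis=1)   # argmax takes the first (smallest k) tie
    has_obs = observed.sum(axis=1) > 0
    continuous = np.full(len(values), np.nan)
    masked = np.where(observed, values, np.nan)
    if has_obs.any():
        continuous[has_obs] = np.nanmean(masked[has_obs], axis=1)
    out = pd.DataFrame({
        "discrete_stage": discrete,
        "continuous_stage": continuous,
    }, index=P.index)
    return out[has_obs]


def validate_auc(stages: pd.DataFrame, labels: pd.Series, folds: int = 10,
                 seed: int = 0) -> tuple[float, float]:
    """Cross-validated AUC of the continuous stage, symptomatic vs control.

    Stratified k-fold split; per fold, the rank-based AUC on the held-out
    subjects. Returns (mean, sd) across folds. The stage is computed from a
    label-free ordering, so the held-out AUC measures discriminative power of
    the staging itself.
    """
    merged = stages.join(labels.rename("label"))
    merged = merged[merged["label"].isin(["symptomatic", "control"])]
    y = (merged["label"] == "symptomatic").to_numpy(int)
    s = merged["continuous_stage"].to_numpy(float)
    if y.sum() < folds or (1 - y).sum() < folds:
        raise InsufficientDataError(
            f"need >= {folds} subjects per class for {folds}-fold stratification")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs = [roc_auc_score(y[test], s[test]) for _, test in skf.split(s, y)]
    return float(np.mean(aucs)), float(np.std(aucs, ddof=1))


def clinical_correlation(stages: pd.DataFrame,
                         scores: pd.DataFrame,
                         score_names: list[str] | None = None) -> pd.DataFrame:
    """Spearman correlation of estimated stage with each clinical score.

    Pairwise-complete; scores with fewer than 3 paired observations are
    skipped with a log message.
    """
    from .cohort import CLINICAL_SCORES
    score_names = score_names or [c for c in (score_names or CLINICAL_SCORES)
                                  if c in scores.columns]
    merged = stages.join(scores, how="inner")
    records = []
    for name in score_names:
        pair = merged[["continuous_stage", name]].dropna()
        if len(pair) < 3:
            log.info("clinical_correlation: %s skipped (%d pairs)", name, len(pair))
            continue
        rho, p = stats.spearmanr(pair["continuous_stage"], pair[name])
        records.append({"score": name, "rho": float(rho), "p": float(p),
                        "n": len(pair)})
    return pd.DataFrame(records)


def kendall_tau_distance(a: tuple[str, ...] | list[str],
                         b: tuple[str, ...] | list[str]) -> int:
    """Number of discordant pairs between two orderings of the same items."""
    pos = {name: i for i, name in enumerate(b)}
    mapped = [pos[name] for name in a]
    return sum(1 for i in range(len(mapped)) for j in range(i + 1, len(mapped))
               if mapped[i] > mapped[j])
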